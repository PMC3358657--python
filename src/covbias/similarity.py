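"""Experiment similarity, UPGMA clustering and the within/between-lab test.

The experiment-similarity matrix holds, for each pair of experiments, the
Pearson correlation of their coverage profiles computed per gene and then
averaged over genes.  Correlations undefined for a gene (a constant
profile) are skipped in the average, not imputed as zero — imputation
would bias pairs with low-complexity coverage toward dissimilarity.
Experiments are clustered by UPGMA on a distance transform of the
similarities, and within-laboratory pairs are compared with between-
laboratory pairs by the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

from .coverage import ProfileSet
from .genome_io import ExperimentMeta


def pearson(x, y) -> float | None:
    """Product-moment correlation; ``None`` when either vector is constant.

    Invariant to affine rescaling with positive slope: pearson(x, a*x + b)
    is 1 for a > 0, which is why raw (depth-unnormalized) coverage counts
    can be compared directly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    valid = np.isfinite(x) & np.isfinite(y)
    if not valid.all():
        # Masked positions (e.g. zero mappability) are excluded pairwise.
        x, y = x[valid], y[valid]
        if x.size < 2:
            return None
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        return None
    r = float((xc @ yc) / (sx * sy))
    return max(-1.0, min(1.0, r))


@dataclass
class SimilarityMatrix:
    """Experiment x experiment matrix of gene-averaged Pearson correlations.

    Undefined entries (no gene yielded a defined correlation for the pair)
    are stored as NaN — flagged, never zero.
    """

    experiment_ids: list
    values: np.ndarray
    per_gene: dict | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.experiment_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match experiment count")

    def entry(self, a: str, b: str) -> float:
        i = self.experiment_ids.index(a)
        j = self.experiment_ids.index(b)
        return float(self.values[i, j])


def similarity_matrix(
    pset: ProfileSet,
    genes: Sequence[str] | None = None,
    *,
    keep_per_gene: bool = False,
) -> SimilarityMatrix:
    """Mean-over-genes Pearson correlation for every experiment pair.

    For each pair, genes whose correlation is undefined are skipped; the
    entry is NaN when no gene yields a defined correlation.
    """
    exp_ids = pset.experiment_ids
    if len(exp_ids) < 2:
        raise ValueError("need at least 2 experiments")
    gene_ids = list(genes) if genes is not None else pset.gene_ids
    if not gene_ids:
        raise ValueError("empty gene list")
    n = len(exp_ids)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    per_gene: dict[str, np.ndarray] = {}
    for gid in gene_ids:
        mat = np.full((n, n), np.nan)
        profiles = [np.asarray(pset.profile(gid, e).values, dtype=float) for e in exp_ids]
        for i in range(n):
            mat[i, i] = 1.0
            for j in range(i + 1, n):
                r = pearson(profiles[i], profiles[j])
                if r is not None:
                    mat[i, j] = mat[j, i] = r
                    sums[i, j] += r
                    sums[j, i] += r
                    counts[i, j] += 1
                    counts[j, i] += 1
        if keep_per_gene:
            per_gene[gid] = mat
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(exp_ids), values, per_gene if keep_per_gene else None)


def correlation_to_distance(
    matrix: SimilarityMatrix, transform: str = "1-r"
) -> np.ndarray:
    """Map correlations to distances: ``1 - r`` (default) or ``(1 - r)/2``."""
    r = matrix.values
    if transform == "1-r":
        d = 1.0 - r
    elif transform == "(1-r)/2":
        d = (1.0 - r) / 2.0
    else:
        raise ValueError(f"unknown transform {transform!r}")
    d = np.array(d, dtype=float)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Dendrogram:
    """UPGMA tree as a merge sequence.

    ``merges[k] = (a, b, height, size)`` joins clusters ``a`` and ``b``
    into cluster ``n + k`` (leaves are clusters ``0 .. n-1``); ``height``
    is the ultrametric height (half the average inter-cluster distance)
    and ``size`` the leaf count of the new cluster.
    """

    merges: list
    labels: list

    def __post_init__(self):
        if len(self.merges) != len(self.labels) - 1:
            raise ValueError("a dendrogram on n leaves needs n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cluster_leafsets(self) -> list[frozenset]:
        """Leaf-label sets of every cluster, leaves first then merges in order."""
        n = self.n_leaves
        sets: list[frozenset] = [frozenset([lab]) for lab in self.labels]
        for a, b, _h, _s in self.merges:
            sets.append(sets[a] | sets[b])
        return sets

    def leaf_order(self) -> list:
        """Left-to-right leaf permutation implied by the merge sequence."""
        n = self.n_leaves
        children = {n + k: (a, b) for k, (a, b, _h, _s) in enumerate(self.merges)}
        order: list = []

        def walk(node: int) -> None:
            if node < n:
                order.append(self.labels[node])
            else:
                a, b = children[node]
                walk(a)
                walk(b)

        walk(n + len(self.merges) - 1)
        return order

    def cophenetic(self) -> np.ndarray:
        """Matrix of cophenetic distances (2x the merge height joining each pair)."""
        n = self.n_leaves
        sets = [set([i]) for i in range(n)]
        coph = np.zeros((n, n))
        for a, b, h, _s in self.merges:
            for i in sets[a]:
                for j in sets[b]:
                    coph[i, j] = coph[j, i] = 2.0 * h
            sets.append(sets[a] | sets[b])
        return coph

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge-height differences."""
        n = self.n_leaves
        heights = [0.0] * n + [h for _a, _b, h, _s in self.merges]
        children = {n + k: (a, b) for k, (a, b, _h, _s) in enumerate(self.merges)}

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - heights[node]
            if node < n:
                return f"{self.labels[node]}:{bl:.10g}"
            a, b = children[node]
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

        root = n + len(self.merges) - 1
        a, b = children[root]
        h = heights[root]
        return f"({render(a, h)},{render(b, h)});"


def upgma(distance: np.ndarray, labels: Sequence | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    At each step the pair of clusters with minimal average inter-cluster
    distance is merged at height = half that distance; the distance from
    the merged cluster to any other is the size-weighted mean of the two
    parts' distances (equivalently, the arithmetic mean over all cross
    leaf pairs).  Ties are broken by the lowest pair of cluster indices in
    creation order, making the output deterministic.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError(
            "distance matrix has undefined entries; impute them or drop the "
            "offending experiments before clustering"
        )
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if labels is None:
        labels = list(range(n))
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")
    if n < 2:
        raise ValueError("need at least 2 leaves")

    # active: cluster id -> (row index into working matrix is the id itself)
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d[i, j])
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        best_pair = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                key = (a, b) if a < b else (b, a)
                val = dist[key]
                if best is None or val < best:
                    best = val
                    best_pair = (a, b)
        a, b = best_pair
        new_size = sizes[a] + sizes[b]
        merges.append((a, b, best / 2.0, new_size))
        for c in active:
            if c in (a, b):
                continue
            ka = (a, c) if a < c else (c, a)
            kb = (b, c) if b < c else (c, b)
            dnew = (sizes[a] * dist[ka] + sizes[b] * dist[kb]) / new_size
            dist[(c, next_id)] = dnew
        sizes[next_id] = new_size
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(merges, labels)


@dataclass
class LabComparison:
    """Within-lab vs between-lab similarity contrast."""

    within: np.ndarray
    between: np.ndarray
    statistic: float  # Mann-Whitney U of the within group
    p_value: float
    alternative: str
    method: str  # "exact" or "asymptotic"
    within_mean: float = field(init=False)
    within_sd: float = field(init=False)
    between_mean: float = field(init=False)
    between_sd: float = field(init=False)

    def __post_init__(self):
        self.within = np.asarray(self.within, dtype=float)
        self.between = np.asarray(self.between, dtype=float)
        self.within_mean = float(self.within.mean())
        self.within_sd = float(self.within.std(ddof=1)) if len(self.within) > 1 else 0.0
        self.between_mean = float(self.between.mean())
        self.between_sd = float(self.between.std(ddof=1)) if len(self.between) > 1 else 0.0


def _exact_ranksum_p(ranks_within, all_ranks, alternative: str) -> float:
    """Exact rank-sum p by counting all equally likely label assignments.

    Counts subsets via a subset-sum dynamic program over doubled midranks
    (doubling makes tied midranks integral), which enumerates the same
    C(n+m, n) assignments as brute force without materialising them.
    """
    vals = [int(round(2 * r)) for r in all_ranks]
    nw = len(ranks_within)
    w_obs = int(round(2 * sum(ranks_within)))
    total_sum = sum(vals)
    # ways[j][s] = number of size-j subsets with doubled-rank sum s
    ways = [dict() for _ in range(nw + 1)]
    ways[0][0] = 1
    for v in vals:
        for j in range(min(nw, len(vals)) - 1, -1, -1):
            if not ways[j]:
                continue
            tgt = ways[j + 1]
            for s, c in ways[j].items():
                tgt[s + v] = tgt.get(s + v, 0) + c
    dist = ways[nw]
    total = sum(dist.values())  # == C(n+m, n)
    ge = sum(c for s, c in dist.items() if s >= w_obs)
    le = sum(c for s, c in dist.items() if s <= w_obs)
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge, le) / total)


EXACT_ENUMERATION_LIMIT = 10_000  # on |within| * |between|


def rank_sum_test(within, between, alternative: str = "greater"):
    """Wilcoxon rank-sum with midrank ties.

    Exact by enumeration when ``|within| * |between|`` is at most
    :data:`EXACT_ENUMERATION_LIMIT`; otherwise the normal approximation
    with tie and continuity correction.  Returns ``(U, p, method)`` where
    U is the Mann-Whitney statistic of the within group.
    """
    within = np.asarray(within, dtype=float)
    between = np.asarray(between, dtype=float)
    nw, nb = len(within), len(between)
    if nw == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    ranks = scipy.stats.rankdata(np.concatenate([within, between]))
    w = float(ranks[:nw].sum())
    u = w - nw * (nw + 1) / 2.0
    if nw * nb <= EXACT_ENUMERATION_LIMIT:
        p = _exact_ranksum_p(ranks[:nw], ranks, alternative)
        return u, p, "exact"
    res = scipy.stats.mannwhitneyu(
        within, between, alternative=alternative, method="asymptotic"
    )
    return u, float(res.pvalue), "asymptotic"


def lab_comparison(
    matrix: SimilarityMatrix,
    meta: Sequence[ExperimentMeta],
    alternative: str = "greater",
) -> LabComparison:
    """Partition experiment pairs by shared laboratory and rank-sum test them.

    ``alternative="greater"`` tests whether within-lab similarity exceeds
    between-lab similarity, the directional form of the question.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    lab_of = {m.experiment_id: m.lab for m in meta}
    ids = matrix.experiment_ids
    missing = [e for e in ids if e not in lab_of]
    if missing:
        raise ValueError(f"experiments missing from metadata: {missing}")
    within, between = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            v = matrix.values[i, j]
            if math.isnan(v):
                raise ValueError(
                    f"undefined similarity for pair ({ids[i]}, {ids[j]})"
                )
            (within if lab_of[ids[i]] == lab_of[ids[j]] else between).append(v)
    if not within:
        raise ValueError("no within-lab pairs (all labs singleton)")
    if not between:
        raise ValueError("no between-lab pairs (all experiments share one lab)")
    u, p, method = rank_sum_test(within, between, alternative)
    return LabComparison(
        np.array(within), np.array(between), u, p, alternative, method
    )
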