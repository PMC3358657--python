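"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes a quantity by the most literal method available —
per-position interval scans, recompute-everything average linkage,
all-pairs Hamming comparison — deliberately sharing no code with the
package paths it checks.
"""

import numpy as np

_COMP = dict(zip(b"ACGTN", b"TGCAN"))


def coverage_brute_force(reads, gene):
    """Per-position overlap count by scanning every (position, read) pair."""
    values = []
    for pos in range(gene.start, gene.end):
        c = 0
        for r in reads:
            if r.chrom == gene.chrom and r.start <= pos < r.start + r.length:
                c += 1
        values.append(c)
    if gene.strand == "-":
        values = values[::-1]
    return np.array(values)


def upgma_brute_force(dist):
    """Average linkage recomputing every cross-pair leaf mean at each step.

    Returns the sorted merge heights (half the merged clusters' average
    leaf-to-leaf distance).  Clusters are kept as explicit leaf sets and
    the inter-cluster distance is re-averaged from the original matrix
    every iteration, so no linkage-update formula is shared with the
    implementation under test.
    """
    dist = np.asarray(dist, dtype=float)
    clusters = [frozenset([i]) for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        best_pair = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best:
                    best = d
                    best_pair = (a, b)
        a, b = best_pair
        heights.append(best / 2.0)
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return sorted(heights)


def uniqueness_brute_force(genome, L, k):
    """All-pairs Hamming scan of every L-mer against both genome strands."""
    enc = {
        name: np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        for name, seq in genome.sequences.items()
    }
    windows = np.concatenate(
        [np.lib.stride_tricks.sliding_window_view(a, L) for a in enc.values()], axis=0
    )
    out = {}
    for name, a in enc.items():
        n = len(a)
        u = np.zeros(n - L + 1, dtype=bool)
        for s in range(n - L + 1):
            q = a[s : s + L]
            if ord("N") in q:
                continue
            rc = np.array([_COMP[c] for c in q[::-1]], dtype=np.uint8)
            hits = int(((windows != q).sum(axis=1) <= k).sum())
            hits += int(((windows != rc).sum(axis=1) <= k).sum())
            u[s] = hits == 1
        out[name] = u
    return out


def ranksum_enumeration(within, between, alternative="greater"):
    """Exact rank-sum p by literally enumerating every label assignment."""
    from itertools import combinations

    import scipy.stats

    pooled = list(within) + list(between)
    ranks = scipy.stats.rankdata(pooled)
    nw = len(within)
    w_obs = ranks[:nw].sum()
    ge = le = total = 0
    for combo in combinations(range(len(pooled)), nw):
        w = ranks[list(combo)].sum()
        total += 1
        if w >= w_obs - 1e-12:
            ge += 1
        if w <= w_obs + 1e-12:
            le += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge, le) / total)
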