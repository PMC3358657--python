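"""5'–3' linear coverage-bias estimation and correction.

An experiment's gene-body trend is summarised by averaging its coverage
profiles over relative gene position: each gene's profile is scaled to
mean 1 (so expression level does not weight the average), positions are
mapped to (i + 0.5) / length in [0, 1], and values are averaged within
bins.  An ordinary least-squares line through the binned means gives the
experiment's linear bias model; dividing each profile by the fitted line
(with a positivity floor) removes the linear trend.  Division rather than
subtraction is used because coverage is multiplicative in sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coverage import CoverageProfile, ProfileSet


@dataclass
class RelativeProfile:
    """Mean normalized coverage per relative-position bin for one experiment."""

    experiment_id: str
    bin_centers: np.ndarray
    bin_means: np.ndarray  # NaN where a bin received no positions
    n_positions: np.ndarray
    n_bins: int

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        self.n_positions = np.asarray(self.n_positions, dtype=int)

    @property
    def nonempty(self) -> np.ndarray:
        return self.n_positions > 0


@dataclass
class LinearBiasModel:
    """Fitted line: mean relative coverage = intercept + slope * x, x in [0,1]."""

    experiment_id: str
    slope: float
    intercept: float


def relative_profile(
    pset: ProfileSet,
    experiment_id: str,
    genes: Sequence[str] | None = None,
    n_bins: int = 100,
    trim: int = 0,
) -> RelativeProfile:
    """Aggregate an experiment's profiles over relative gene position.

    Each gene is scaled to mean 1 before pooling (genes with an all-zero
    profile are skipped — their scaling is undefined).  Bins are
    half-open ``[k/n, (k+1)/n)`` with the last bin closed; bins receiving
    no positions are flagged empty (NaN mean) and excluded from fitting.

    ``trim`` excludes that many positions at each gene end: positions
    within a read length of the ends are covered by fewer than L read
    placements, so their coverage is attenuated by interval geometry
    rather than by sampling bias, and including them distorts the linear
    fit.  Passing ``trim = read_length - 1`` removes exactly the censored
    region.  Trimming is capped per gene so at least two positions
    always remain; relative coordinates refer to the full gene.
    """
    if experiment_id not in pset.experiment_ids:
        raise ValueError(f"experiment {experiment_id!r} not in profile set")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if trim < 0:
        raise ValueError("trim must be >= 0")
    gene_ids = list(genes) if genes is not None else pset.gene_ids
    if not gene_ids:
        raise ValueError("empty gene list")
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for gid in gene_ids:
        vals = np.asarray(pset.profile(gid, experiment_id).values, dtype=float)
        n = len(vals)
        t = min(trim, (n - 2) // 2)
        sl = slice(t, n - t)
        finite = np.isfinite(vals[sl])
        if not finite.any():
            continue
        mean = vals[sl][finite].mean()
        if mean == 0:
            continue
        scaled = vals[sl] / mean
        x = (np.arange(t, n - t) + 0.5) / n
        idx = np.minimum((x * n_bins).astype(int), n_bins - 1)
        sums += np.bincount(idx[finite], weights=scaled[finite], minlength=n_bins)
        counts += np.bincount(idx[finite], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return RelativeProfile(experiment_id, centers, means, counts, n_bins)


def fit_linear_bias(profile: RelativeProfile) -> LinearBiasModel:
    """OLS of bin means on bin centers over non-empty bins."""
    mask = profile.nonempty & np.isfinite(profile.bin_means)
    if mask.sum() < 2:
        raise ValueError("need at least 2 non-empty bins to fit a line")
    slope, intercept = np.polyfit(
        profile.bin_centers[mask], profile.bin_means[mask], 1
    )
    return LinearBiasModel(profile.experiment_id, float(slope), float(intercept))


#: Positivity floor for the fitted line, as a fraction of the intercept.
LINE_FLOOR_FRACTION = 0.01


def normalize_5p3p(
    profile: CoverageProfile, model: LinearBiasModel
) -> CoverageProfile:
    """Divide a profile by its experiment's fitted 5'–3' line.

    Position i is divided by ``max(intercept + slope * x_i, floor)`` with
    ``x_i = (i + 0.5) / length`` and floor = 1% of the intercept, so a
    line crossing zero inside the gene cannot flip signs.  The result is
    real-valued.
    """
    if model.intercept <= 0:
        raise ValueError(
            f"degenerate fit for {model.experiment_id}: intercept "
            f"{model.intercept:g} <= 0"
        )
    n = len(profile)
    x = (np.arange(n) + 0.5) / n
    line = model.intercept + model.slope * x
    floor = LINE_FLOOR_FRACTION * model.intercept
    denom = np.maximum(line, floor)
    return CoverageProfile(
        profile.gene_id,
        profile.experiment_id,
        np.asarray(profile.values, dtype=float) / denom,
    )


def experiment_trim(pset: ProfileSet, experiment_id: str) -> int:
    """Default end-trim for an experiment: its read length minus one."""
    for meta in pset.experiments:
        if meta.experiment_id == experiment_id:
            return max(0, meta.read_length - 1)
    return 0


def fit_all(
    pset: ProfileSet,
    genes: Sequence[str] | None = None,
    n_bins: int = 100,
    trim: int | str = "auto",
) -> dict[str, LinearBiasModel]:
    """Fit one linear bias model per experiment.

    ``trim="auto"`` trims each experiment's read length minus one from
    both gene ends (the geometrically censored region); an integer
    applies uniformly.
    """
    out = {}
    for eid in pset.experiment_ids:
        t = experiment_trim(pset, eid) if trim == "auto" else int(trim)
        out[eid] = fit_linear_bias(relative_profile(pset, eid, genes, n_bins, t))
    return out


def normalize_set(
    pset: ProfileSet, models: dict[str, LinearBiasModel]
) -> ProfileSet:
    """Apply each experiment's linear correction to all of its profiles.

    Returns a new ProfileSet; the original is never modified, so
    initial-vs-normalized comparisons are a diff of two objects.
    """
    profiles = {
        key: normalize_5p3p(prof, models[key[1]])
        for key, prof in pset.profiles.items()
    }
    return ProfileSet(profiles, list(pset.genes), list(pset.experiments))
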