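"""Per-nucleotide gene coverage profiles and the gene presence filter.

Coverage of a gene position is the number of uniquely mapped reads whose
genomic interval contains it.  Profiles are strand-oriented at
construction: index 0 is always the transcript's 5' end, so all downstream
5'–3' analysis is uniform regardless of the gene's genomic strand.
Counts are raw integers — profiles are deliberately not scaled by the
experiment's total read count, because the Pearson correlation used
downstream is invariant to such scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import AlignedRead, ExperimentMeta, GeneModel


@dataclass
class CoverageProfile:
    """Per-nucleotide coverage over one gene in one experiment, 5'->3'.

    ``values`` holds raw read counts for an unnormalized profile; the
    normalization passes reuse this container with real-valued entries.
    """

    gene_id: str
    experiment_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("profile values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ProfileSet:
    """All profiles of a study: (gene_id, experiment_id) -> CoverageProfile."""

    profiles: dict
    genes: list
    experiments: list

    def __post_init__(self):
        lengths: dict[str, int] = {}
        for (gid, _eid), prof in self.profiles.items():
            if gid in lengths and lengths[gid] != len(prof):
                raise ValueError(f"gene {gid}: inconsistent profile lengths")
            lengths[gid] = len(prof)

    def profile(self, gene_id: str, experiment_id: str) -> CoverageProfile:
        return self.profiles[(gene_id, experiment_id)]

    @property
    def experiment_ids(self) -> list[str]:
        return [m.experiment_id for m in self.experiments]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def compute_coverage(
    reads: Iterable[AlignedRead], gene: GeneModel, experiment_id: str = ""
) -> CoverageProfile:
    """Count reads spanning each position of ``gene``.

    Reads on other chromosomes contribute zero.  For a minus-strand gene
    the vector is reversed so index 0 is the transcript's 5' end.  Read
    strand is ignored: coverage counts both strands equally.
    """
    n = gene.length
    diff = np.zeros(n + 1, dtype=np.int64)
    for read in reads:
        if read.chrom != gene.chrom:
            continue
        lo = max(read.start, gene.start) - gene.start
        hi = min(read.end, gene.end) - gene.start
        if lo < hi:
            diff[lo] += 1
            diff[hi] -= 1
    values = np.cumsum(diff[:-1])
    if gene.strand == "-":
        values = values[::-1].copy()
    return CoverageProfile(gene.gene_id, experiment_id, values)


def coverage_from_start_counts(
    start_counts: np.ndarray, read_length: int, gene: GeneModel, experiment_id: str = ""
) -> CoverageProfile:
    """Coverage profile from per-start read counts in transcript orientation.

    ``start_counts[j]`` is the number of reads whose 5' end sits at
    transcript position ``j`` (valid starts ``0 .. length - read_length``).
    Coverage at transcript position ``t`` sums the starts within
    ``[t - L + 1, t]``, i.e. a convolution with a length-L window.  This is
    exactly what :func:`compute_coverage` produces for the same reads and
    is used as a fast path by the simulator.
    """
    counts = np.asarray(start_counts, dtype=np.int64)
    n = gene.length
    if len(counts) != n - read_length + 1:
        raise ValueError("start_counts length must be gene length - L + 1")
    values = np.convolve(counts, np.ones(read_length, dtype=np.int64))
    assert len(values) == n
    return CoverageProfile(gene.gene_id, experiment_id, values)


def build_profile_set(
    reads_by_experiment: Mapping[str, Sequence[AlignedRead]],
    genes: Sequence[GeneModel],
    experiments: Sequence[ExperimentMeta],
) -> ProfileSet:
    profiles = {}
    for meta in experiments:
        reads = reads_by_experiment[meta.experiment_id]
        for gene in genes:
            profiles[(gene.gene_id, meta.experiment_id)] = compute_coverage(
                reads, gene, meta.experiment_id
            )
    return ProfileSet(profiles, list(genes), list(experiments))


def is_covered(profile: CoverageProfile, min_mean: float = 0.0) -> bool:
    """Presence predicate: at least one read overlaps the gene.

    The weakest reading of "covered by reads" — any nonzero position.  An
    optional minimum mean coverage makes stricter readings testable
    (default off).
    """
    if min_mean > 0:
        return bool(profile.values.mean() >= min_mean)
    return bool(np.any(profile.values > 0))


def filter_genes(
    pset: ProfileSet,
    presence_fraction: float = 0.90,
    min_mean: float = 0.0,
) -> list[str]:
    """Genes covered in at least ``presence_fraction`` of experiments.

    A gene is retained when (experiments where it is covered) / (total
    experiments) >= presence_fraction; input gene order is preserved.
    """
    if not 0 <= presence_fraction <= 1:
        raise ValueError("presence_fraction must be in [0, 1]")
    if not pset.experiments:
        raise ValueError("profile set has no experiments")
    n_exp = len(pset.experiments)
    retained = []
    for gene in pset.genes:
        n_cov = sum(
            is_covered(pset.profile(gene.gene_id, eid), min_mean)
            for eid in pset.experiment_ids
        )
        if n_cov / n_exp >= presence_fraction:
            retained.append(gene.gene_id)
    return retained
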