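"""Read-length-specific unique-mappability tracks and normalization.

For read length L, the L-mer starting at every genomic position is
re-aligned against both strands of the whole genome under the same
mismatch allowance as the original reads; a start is uniquely mappable
when it has exactly one alignment location (its own origin).  The
per-position mappability m_i is the fraction of the read placements
physically covering position i whose starts are unique — coverage at a
position aggregates up to L placements, so normalizing by the placement
fraction (rather than the start indicator) matches what coverage loses
when placements become ambiguous.  Positions with m = 0 are masked, not
zeroed: dividing by zero mappability is meaningless and zero-filling
would create spurious anti-correlation.

The k-mismatch search uses pigeonhole seed partitioning: a query with at
most k mismatches against a window must match one of k+1 disjoint seed
slices exactly, so exact-match seed lookups enumerate a complete
candidate set which is then verified by Hamming distance.  Results are
exact; suitable for desk-scale genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coverage import CoverageProfile
from .genome_io import GeneModel, Genome

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MismatchPolicy:
    """Read-length-dependent mismatch allowance.

    ``breakpoints`` is an ordered tuple of (max_length, mismatches) pairs;
    the first pair whose max_length (inclusive, None = unbounded) covers
    the read length applies.  Allowances must be non-decreasing in length.
    """

    breakpoints: tuple = ((25, 1), (50, 2), (None, 3))

    def __post_init__(self):
        ks = [k for _m, k in self.breakpoints]
        if any(b > a for a, b in zip(ks[1:], ks)):
            raise ValueError("mismatch allowance must be non-decreasing in length")

    def allowed(self, read_length: int) -> int:
        if read_length < 1:
            raise ValueError("read_length must be >= 1")
        for max_len, k in self.breakpoints:
            if max_len is None or read_length <= max_len:
                return k
        raise AssertionError("policy has no unbounded breakpoint")


DEFAULT_POLICY = MismatchPolicy()


def allowed_mismatches(read_length: int, policy: MismatchPolicy = DEFAULT_POLICY) -> int:
    """Mismatches allowed for a read: 1 below 26 nt, 2 for 26-50 nt, 3 above 50."""
    return policy.allowed(read_length)


@dataclass
class MappabilityTrack:
    """Unique-alignability of one chromosome at one read length.

    ``start_unique[s]`` — the L-mer starting at s aligns to exactly one
    location genome-wide (both strands) within the mismatch allowance.
    ``positional[i]`` — fraction of valid placements covering i that are
    unique, in [0, 1].
    """

    chrom: str
    read_length: int
    start_unique: np.ndarray
    positional: np.ndarray

    def __post_init__(self):
        self.start_unique = np.asarray(self.start_unique, dtype=bool)
        self.positional = np.asarray(self.positional, dtype=float)
        if np.any((self.positional < 0) | (self.positional > 1)):
            raise ValueError("positional mappability must lie in [0, 1]")


def _seed_layout(L: int, k: int) -> list[tuple[int, int]]:
    """Split [0, L) into k+1 contiguous near-equal (offset, length) slices."""
    parts = k + 1
    base, extra = divmod(L, parts)
    layout = []
    off = 0
    for i in range(parts):
        ln = base + (1 if i < extra else 0)
        layout.append((off, ln))
        off += ln
    return layout


def _hamming_le(a: np.ndarray, b: np.ndarray, k: int) -> bool:
    return int(np.count_nonzero(a != b)) <= k


_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
_ENCODE[ord("N")] = 4


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def start_uniqueness(genome: Genome, L: int, k: int) -> dict[str, np.ndarray]:
    """Per-chromosome boolean arrays: the forward L-mer at each start is
    globally unique under <= k mismatches, counting both strands.

    An L-mer containing N is never unique (N poisons its window), and
    windows containing N never match an ACGT query.  A reverse-palindromic
    L-mer matches its own position on both strands and is therefore a
    multi-mapper.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    for name, seq in genome.sequences.items():
        if L > len(seq):
            raise ValueError(f"L={L} exceeds chromosome {name!r} length {len(seq)}")
    if k == 0:
        return _start_uniqueness_exact(genome, L)

    layout = _seed_layout(L, k)
    enc = {name: _encode(seq) for name, seq in genome.sequences.items()}
    # Seed indexes: one dict per slice, substring -> list of (chrom, window_start).
    indexes: list[dict[str, list[tuple[str, int]]]] = []
    for off, ln in layout:
        idx: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.sequences.items():
            n = len(seq)
            for s in range(n - L + 1):
                key = seq[s + off : s + off + ln]
                idx.setdefault(key, []).append((name, s))
        indexes.append(idx)

    def count_hits(query: str, q_enc: np.ndarray, limit: int) -> set:
        hits: set[tuple[str, int]] = set()
        for (off, ln), idx in zip(layout, indexes):
            for name, s in idx.get(query[off : off + ln], ()):
                if (name, s) in hits:
                    continue
                if _hamming_le(q_enc, enc[name][s : s + L], k):
                    hits.add((name, s))
                    if len(hits) >= limit:
                        return hits
        return hits

    result: dict[str, np.ndarray] = {}
    for name, seq in genome.sequences.items():
        n = len(seq)
        u = np.zeros(n - L + 1, dtype=bool)
        for s in range(n - L + 1):
            q = seq[s : s + L]
            if "N" in q:
                continue
            fwd = count_hits(q, _encode(q), 2)
            if len(fwd) >= 2:
                continue
            rc = revcomp(q)
            rev = count_hits(rc, _encode(rc), 2)
            u[s] = (len(fwd) + len(rev)) == 1
        result[name] = u
    return result


def _start_uniqueness_exact(genome: Genome, L: int) -> dict[str, np.ndarray]:
    """k = 0 fast path: hash-count every L-mer once."""
    counts: dict[str, int] = {}
    for seq in genome.sequences.values():
        for s in range(len(seq) - L + 1):
            kmer = seq[s : s + L]
            counts[kmer] = counts.get(kmer, 0) + 1
    result = {}
    for name, seq in genome.sequences.items():
        n = len(seq)
        u = np.zeros(n - L + 1, dtype=bool)
        for s in range(n - L + 1):
            kmer = seq[s : s + L]
            if "N" in kmer:
                continue
            total = counts.get(kmer, 0) + counts.get(revcomp(kmer), 0)
            u[s] = total == 1
        result[name] = u
    return result


def positional_mappability(u: np.ndarray, L: int, chrom_length: int) -> np.ndarray:
    """Fraction of placements covering each position whose starts are unique.

    ``m_i = sum(u_s for s in [max(0, i-L+1), min(i, n-L)]) / window size``
    — the denominator counts the placements that physically cover i, so
    edges (with fewer covering placements) are handled without bias.
    """
    u = np.asarray(u, dtype=float)
    n = chrom_length
    if len(u) != n - L + 1:
        raise ValueError("u must have length chrom_length - L + 1")
    csum = np.concatenate([[0.0], np.cumsum(u)])
    i = np.arange(n)
    lo = np.maximum(0, i - L + 1)
    hi = np.minimum(i, n - L)
    num = csum[hi + 1] - csum[lo]
    den = (hi - lo + 1).astype(float)
    return num / den


def compute_track(
    genome: Genome,
    chrom: str,
    read_length: int,
    policy: MismatchPolicy = DEFAULT_POLICY,
    k: int | None = None,
) -> MappabilityTrack:
    """Full mappability track for one chromosome at one read length.

    ``k`` overrides the mismatch policy when given; the default follows
    the length-dependent allowance used for the original alignments.
    """
    if k is None:
        k = policy.allowed(read_length)
    u = start_uniqueness(genome, read_length, k)[chrom]
    m = positional_mappability(u, read_length, genome.length(chrom))
    return MappabilityTrack(chrom, read_length, u, m)


@dataclass
class MaskedProfile:
    """A mappability-normalized profile; False mask entries are positions
    with zero mappability, excluded from downstream correlation and
    aggregation (values there are NaN, never 0)."""

    gene_id: str
    experiment_id: str
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have identical shape")


def normalize_mappability(
    profile: CoverageProfile, track: MappabilityTrack, gene: GeneModel
) -> MaskedProfile:
    """Divide a coverage profile by positional mappability over the gene.

    The track slice is reversed for minus-strand genes so it lines up with
    the transcript-oriented profile.
    """
    if track.chrom != gene.chrom:
        raise ValueError(
            f"track is for {track.chrom!r} but gene {gene.gene_id} is on "
            f"{gene.chrom!r}"
        )
    m = track.positional[gene.start : gene.end]
    if gene.strand == "-":
        m = m[::-1]
    if len(m) != len(profile):
        raise ValueError("track does not cover the gene")
    mask = m > 0
    values = np.full(len(profile), np.nan)
    values[mask] = np.asarray(profile.values, dtype=float)[mask] / m[mask]
    return MaskedProfile(profile.gene_id, profile.experiment_id, values, mask)
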