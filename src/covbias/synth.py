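"""Synthetic genomes, single-exon gene sets, and laboratory-biased reads.

Stands in for a multi-laboratory sequencing study with known ground
truth.  Each laboratory has a reproducible positional sampling-bias
density over relative gene position — a linear 5'–3' trend plus
lab-specific Gaussian bumps — from which read 5' start positions are
drawn in transcript orientation.  Experiments within a lab share the
bias density but differ in their per-gene expression vectors ("tissues").
Reads are error-free copies of the genome; the object of study is
positional bias, not sequencing error.  All randomness flows from named
seeds; two runs with equal configs produce identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from . import genome_io
from .coverage import CoverageProfile, ProfileSet, coverage_from_start_counts
from .genome_io import ExperimentMeta, GeneModel, Genome

#: Density floor keeping every start position reachable, so no gene can
#: degenerate to zero coverage and interact with the presence filter
#: nondeterministically.
DENSITY_EPS = 1e-3


@dataclass(frozen=True)
class LabBiasSpec:
    """A laboratory's positional sampling-bias signature.

    The read-start density over relative position x in [0, 1] is
    ``max(eps, 1 + slope * (x - 0.5) + sum of Gaussian bumps)``,
    renormalized to integrate to 1.  ``bumps`` is a sequence of
    (center, width, amplitude) triples.
    """

    lab_id: str
    slope: float = 0.0
    bumps: tuple = ()

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        b = 1.0 + self.slope * (x - 0.5)
        for center, width, amplitude in self.bumps:
            if width <= 0:
                raise ValueError("bump width must be > 0")
            b = b + amplitude * np.exp(-((x - center) ** 2) / (2.0 * width**2))
        return np.maximum(DENSITY_EPS, b)

    def start_probabilities(self, n_starts: int, gene_length: int | None = None) -> np.ndarray:
        """Start-position probabilities for a gene, normalized to sum 1.

        The density is defined over relative gene position, so start j is
        evaluated at ``(j + 0.5) / gene_length`` — the unreachable tail
        beyond the last valid start is simply renormalized away.  This
        keeps a linear density slope exactly recoverable from interior
        coverage (the start window only shifts the coordinate by a
        constant).  With ``gene_length`` omitted, starts are spread over
        the whole unit interval.
        """
        denom = gene_length if gene_length is not None else n_starts
        x = (np.arange(n_starts) + 0.5) / denom
        b = self.density(x)
        return b / b.sum()


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic study.

    ``read_length`` may be a single value or one value per laboratory
    (read length is a property of a lab's instrument/protocol).
    """

    seed: int = 0
    n_genes: int = 20
    gene_length_range: tuple = (500, 1000)
    n_labs: int = 3
    experiments_per_lab: int = 3
    reads_per_experiment: int = 100_000
    read_length: int | tuple = 50
    expression_sigma: float = 1.0
    share_expression_within_lab: bool = False
    duplication_spec: tuple | None = None  # (segment_length, copies)

    def __post_init__(self):
        if min(self.n_genes, self.n_labs, self.experiments_per_lab,
               self.reads_per_experiment) < 1:
            raise ValueError("all counts must be positive")
        lo, hi = self.gene_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid gene_length_range")
        if lo < self.max_read_length:
            raise ValueError("min gene length must be >= read length")

    def read_length_for_lab(self, lab_index: int) -> int:
        if isinstance(self.read_length, (tuple, list)):
            return int(self.read_length[lab_index % len(self.read_length)])
        return int(self.read_length)

    @property
    def max_read_length(self) -> int:
        if isinstance(self.read_length, (tuple, list)):
            return int(max(self.read_length))
        return int(self.read_length)


def generate_genome(config: SimulationConfig) -> tuple[Genome, list[GeneModel]]:
    """One chromosome of i.i.d. uniform A/C/G/T with non-overlapping genes.

    Genes are separated by intergenic gaps of at least the maximum read
    length and assigned alternating strands, so minus-strand genes
    exercise the profile-reversal path.  With ``duplication_spec`` set,
    one intergenic segment is repeated verbatim, creating a known
    multi-mapping (mappability-zero) region.  Deterministic given the
    config seed.
    """
    rng = np.random.default_rng([config.seed, 0xC0FFEE % (2**31)])
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    gap = max(config.max_read_length, 1)
    pieces: list[str] = []
    genes: list[GeneModel] = []
    pos = 0

    def random_seq(n: int) -> str:
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])

    for i, glen in enumerate(lengths):
        pieces.append(random_seq(gap))
        pos += gap
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(f"g{i + 1:03d}", "chr1", pos, pos + int(glen), strand))
        pieces.append(random_seq(int(glen)))
        pos += int(glen)
    if config.duplication_spec is not None:
        seg_len, copies = config.duplication_spec
        if copies < 2:
            raise ValueError("duplication needs at least 2 copies")
        segment = random_seq(int(seg_len))
        for _ in range(int(copies)):
            pieces.append(random_seq(gap))
            pieces.append(segment)
            pos += gap + int(seg_len)
    pieces.append(random_seq(gap))
    genome = Genome({"chr1": "".join(pieces)})
    return genome, genes


def duplicated_intervals(config: SimulationConfig, genes: Sequence[GeneModel]) -> list[tuple[int, int]]:
    """Genomic intervals of the duplicated copies laid out by generate_genome."""
    if config.duplication_spec is None:
        return []
    seg_len, copies = config.duplication_spec
    gap = max(config.max_read_length, 1)
    pos = genes[-1].end
    out = []
    for _ in range(int(copies)):
        pos += gap
        out.append((pos, pos + int(seg_len)))
        pos += int(seg_len)
    return out


def _experiment_rng(config: SimulationConfig, experiment_seed: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, int(experiment_seed) % (2**31)])


def draw_expression(
    n_genes: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal per-gene read weights, normalized to sum 1."""
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n_genes)
    return w / w.sum()


def sample_start_counts(
    genes: Sequence[GeneModel],
    bias: LabBiasSpec,
    read_length: int,
    n_reads: int,
    rng: np.random.Generator,
    gene_weights: np.ndarray | None = None,
    expression_sigma: float = 1.0,
) -> dict[str, np.ndarray]:
    """Per-gene arrays of read counts at each transcript-oriented start.

    Reads are allocated to genes multinomially by the expression vector,
    then start positions within each gene are drawn multinomially from
    the lab's bias density mapped onto the valid starts
    ``0 .. length - L``.
    """
    if gene_weights is None:
        gene_weights = draw_expression(len(genes), expression_sigma, rng)
    per_gene = rng.multinomial(n_reads, gene_weights)
    out = {}
    for gene, m in zip(genes, per_gene):
        n_starts = gene.length - read_length + 1
        if n_starts < 1:
            raise ValueError(
                f"gene {gene.gene_id} shorter than read length {read_length}"
            )
        p = bias.start_probabilities(n_starts, gene.length)
        out[gene.gene_id] = rng.multinomial(int(m), p)
    return out


def simulate_profiles(
    genes: Sequence[GeneModel],
    bias: LabBiasSpec,
    config: SimulationConfig,
    experiment_seed: int,
    experiment_id: str,
    read_length: int | None = None,
    gene_weights: np.ndarray | None = None,
) -> tuple[dict[str, CoverageProfile], ExperimentMeta]:
    """Simulate an experiment directly to coverage profiles.

    Consumes the same RNG stream as :func:`simulate_experiment`; the
    profiles are identical to aligning that SAM output and running the
    coverage module (coverage of error-free ungapped reads is exactly the
    convolution of start counts with a length-L window).
    """
    L = int(read_length) if read_length is not None else config.max_read_length
    rng = _experiment_rng(config, experiment_seed)
    counts = sample_start_counts(
        genes, bias, L, config.reads_per_experiment, rng,
        gene_weights, config.expression_sigma,
    )
    profiles = {
        g.gene_id: coverage_from_start_counts(counts[g.gene_id], L, g, experiment_id)
        for g in genes
    }
    meta = ExperimentMeta(experiment_id, bias.lab_id, "Illumina", "RNA", L, None)
    return profiles, meta


def simulate_experiment(
    genome: Genome,
    genes: Sequence[GeneModel],
    bias: LabBiasSpec,
    config: SimulationConfig,
    experiment_seed: int,
    experiment_id: str,
    sam_path,
    read_length: int | None = None,
    gene_weights: np.ndarray | None = None,
) -> ExperimentMeta:
    """Simulate an experiment and write it as a mapped SAM file.

    Reads are verbatim genome copies (error-free) with NH:i:1 tags.  A
    read starting at transcript position j of a plus-strand gene maps to
    genomic start ``gene.start + j`` on the forward strand; on a
    minus-strand gene it covers ``[gene.end - j - L, gene.end - j)`` and
    is flagged reverse.  Deterministic given (config.seed,
    experiment_seed).
    """
    L = int(read_length) if read_length is not None else config.max_read_length
    rng = _experiment_rng(config, experiment_seed)
    counts = sample_start_counts(
        genes, bias, L, config.reads_per_experiment, rng,
        gene_weights, config.expression_sigma,
    )
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": len(seq)}
                for name, seq in genome.sequences.items()
            ],
        }
    )
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for gene in genes:
            gcounts = counts[gene.gene_id]
            for j in np.nonzero(gcounts)[0]:
                if gene.strand == "+":
                    gstart = gene.start + int(j)
                    reverse = False
                else:
                    gstart = gene.end - int(j) - L
                    reverse = True
                seq = genome.sequences[gene.chrom][gstart : gstart + L]
                for r in range(int(gcounts[j])):
                    a = pysam.AlignedSegment(header)
                    a.query_name = f"{experiment_id}:{gene.gene_id}:{int(j)}:{r}"
                    a.flag = 16 if reverse else 0
                    a.reference_name = gene.chrom
                    a.reference_start = gstart
                    a.mapping_quality = 255
                    a.cigarstring = f"{L}M"
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array("I" * L)
                    a.set_tag("NH", 1)
                    out.write(a)
    return ExperimentMeta(
        experiment_id, bias.lab_id, "Illumina", "RNA", L, str(sam_path)
    )


def default_bias_specs(n_labs: int, slopes=None, bump_amplitude: float = 0.5,
                       bump_width: float = 0.05) -> list[LabBiasSpec]:
    """One bias signature per lab: a slope plus a bump at a lab-specific center.

    Bump centers are spread over (0, 1) so each laboratory's over-covered
    gene region is unique, emulating lab-specific protocol signatures.
    """
    specs = []
    for i in range(n_labs):
        slope = 0.0 if slopes is None else slopes[i % len(slopes)]
        center = (i + 1) / (n_labs + 1)
        bumps = ((center, bump_width, bump_amplitude),) if bump_amplitude else ()
        specs.append(LabBiasSpec(f"lab{i + 1}", slope, bumps))
    return specs


@dataclass
class StudyPaths:
    genome_fasta: Path
    genes_bed: Path
    metadata_tsv: Path
    sam_paths: list


def make_study(
    config: SimulationConfig,
    bias_specs: Sequence[LabBiasSpec],
    outdir,
) -> StudyPaths:
    """Write a complete synthetic study: FASTA, BED, one SAM per experiment,
    and the metadata TSV the pipeline consumes.  Deterministic given the
    master seed."""
    if len(bias_specs) != config.n_labs:
        raise ValueError("need one bias spec per lab")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = generate_genome(config)
    fasta = outdir / "genome.fasta"
    bed = outdir / "genes.bed"
    genome_io.write_fasta(genome, fasta)
    genome_io.write_bed(genes, bed)
    metas: list[ExperimentMeta] = []
    sam_paths: list[Path] = []
    seen_ids: set[str] = set()
    exp_counter = 0
    for lab_idx, spec in enumerate(bias_specs):
        L = config.read_length_for_lab(lab_idx)
        lab_weights = None
        if config.share_expression_within_lab:
            lab_rng = np.random.default_rng([config.seed, 7_000_000 + lab_idx])
            lab_weights = draw_expression(len(genes), config.expression_sigma, lab_rng)
        for e in range(config.experiments_per_lab):
            exp_counter += 1
            eid = f"{spec.lab_id}_e{e + 1}"
            if eid in seen_ids:
                raise ValueError(f"duplicate experiment id {eid!r}")
            seen_ids.add(eid)
            sam = outdir / f"{eid}.sam"
            meta = simulate_experiment(
                genome, genes, spec, config,
                experiment_seed=exp_counter,
                experiment_id=eid, sam_path=sam,
                read_length=L, gene_weights=lab_weights,
            )
            # store the path relative to the metadata file for portability
            metas.append(replace(meta, alignment_path=sam.name))
            sam_paths.append(sam)
    metadata = outdir / "metadata.tsv"
    genome_io.write_metadata(metas, metadata)
    return StudyPaths(fasta, bed, metadata, sam_paths)


def simulate_study_profiles(
    config: SimulationConfig, bias_specs: Sequence[LabBiasSpec]
) -> ProfileSet:
    """In-memory study: the same experiments as make_study, as a ProfileSet.

    Uses the profile fast path (identical RNG stream and results to the
    SAM route); intended for large simulation studies where writing and
    re-reading alignments would dominate runtime.
    """
    if len(bias_specs) != config.n_labs:
        raise ValueError("need one bias spec per lab")
    _genome, genes = generate_genome(config)
    profiles: dict = {}
    metas: list[ExperimentMeta] = []
    exp_counter = 0
    for lab_idx, spec in enumerate(bias_specs):
        L = config.read_length_for_lab(lab_idx)
        lab_weights = None
        if config.share_expression_within_lab:
            lab_rng = np.random.default_rng([config.seed, 7_000_000 + lab_idx])
            lab_weights = draw_expression(len(genes), config.expression_sigma, lab_rng)
        for e in range(config.experiments_per_lab):
            exp_counter += 1
            eid = f"{spec.lab_id}_e{e + 1}"
            profs, meta = simulate_profiles(
                genes, spec, config,
                experiment_seed=exp_counter, experiment_id=eid,
                read_length=L, gene_weights=lab_weights,
            )
            for gid, prof in profs.items():
                profiles[(gid, eid)] = prof
            metas.append(meta)
    return ProfileSet(profiles, list(genes), metas)
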