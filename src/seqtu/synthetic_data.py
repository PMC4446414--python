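"""Seeded synthetic genomes, TU structures, coverage and spanning evidence.

The generator emulates the statistical structure that junction
classification relies on for a bacterial strand-specific RNA-seq
experiment:

* genes laid out TU by TU, with short intergenic gaps inside TUs (~50 bp)
  and longer gaps between TUs (~200 bp);
* coding sequence at GC 0.40 vs intergenic sequence at GC 0.33 (the
  constructed-TU placement exploits this contrast);
* per-TU lognormal expression, realised as discrete 50 bp reads placed
  within TU spans (so depth-titration experiments have real read sets to
  subsample), with gamma-weighted positional overdispersion;
* most inter-TU gaps left with zero-coverage runs, a minority bridged by
  read-through to create hard negative junctions;
* a small antisense read fraction (0.5%);
* spanning evidence: ~225 bp long reads or ~170 bp paired-end fragment
  spans sampled inside true TU spans, never crossing TU boundaries.

Everything is reproducible byte-for-byte from (config, seed), and the
ground-truth TU membership of every gene yields exact junction labels for
evaluation.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .annotation_io import Gene, GenomeAnnotation, write_fasta, write_gff3
from .coverage import CoverageTrack, Reads, build_coverage, write_bed6
from .model import TU, TUSet

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Knobs of the synthetic transcriptome; defaults are the study
    conditions every stochastic check runs under.

    Lengths are arithmetic means of lognormal draws (``*_sigma`` are
    log-scale standard deviations); ``depth`` is the target estimated
    sequencing depth in fold coverage over coding sequence.
    """

    n_genes: int = 700
    gene_len_mean: float = 900.0
    gene_len_sigma: float = 0.45
    gene_len_min: int = 150
    intra_gap_mean: float = 50.0
    intra_gap_sigma: float = 0.7
    intra_gap_min: int = 1
    inter_gap_mean: float = 200.0
    inter_gap_sigma: float = 0.9
    inter_gap_min: int = 30
    # P(TU has 1..4 genes, or 5+); ~56% single-gene TUs, and of the
    # multi-gene remainder roughly a quarter with five or more genes
    tu_size_probs: tuple[float, ...] = (0.56, 0.16, 0.10, 0.07, 0.11)
    tu_size_tail_p: float = 0.45  # geometric extension beyond 5 genes
    strand_switch_prob: float = 0.3
    coding_gc: float = 0.40
    intergenic_gc: float = 0.33
    depth: float = 100.0
    read_length: int = 50
    expression_sigma: float = 1.0
    overdispersion: float = 0.3  # CV of gamma bin weights for read placement
    bin_size: int = 200
    boundary_gap_prob: float = 0.85
    readthrough_coverage: float = 3.0
    antisense_rate: float = 0.005
    long_read_mean_len: float = 225.0
    long_read_sd_len: float = 15.0
    fragment_mean_len: float = 170.0
    fragment_sd_len: float = 25.0
    n_evidence: int = 20000
    max_genome_len: int = 50_000_000
    genome_id: str = "simchr"
    seed: int = 17

    def __post_init__(self) -> None:
        probs = np.asarray(self.tu_size_probs, dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("tu_size_probs must be a probability vector")
        for name in ("gene_len_mean", "intra_gap_mean", "inter_gap_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("boundary_gap_prob", "antisense_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "tu_size_probs" in payload:
            payload["tu_size_probs"] = tuple(payload["tu_size_probs"])
        return cls(**payload)

    def to_yaml(self, path: str | os.PathLike) -> None:
        payload = asdict(self)
        payload["tu_size_probs"] = list(payload["tu_size_probs"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class SimTruth:
    """Ground truth: annotation, true TU memberships, per-TU expression."""

    annotation: GenomeAnnotation
    true_tus: TUSet
    tu_expression: np.ndarray

    def junction_labels(self) -> dict[tuple[str, str], bool]:
        """True co-transcription label for every joined consecutive pair."""
        return {key: True for key in self.true_tus.joined_junctions()}

    def tu_spans(self) -> list[tuple[int, int, str]]:
        return [(tu.start, tu.end, tu.strand) for tu in self.true_tus.tus]


def _lognormal_lengths(
    rng: np.random.Generator, mean: float, sigma: float, minimum: int, size: int
) -> np.ndarray:
    mu = np.log(mean) - sigma**2 / 2.0
    draws = np.round(rng.lognormal(mu, sigma, size=size)).astype(np.int64)
    return np.maximum(draws, minimum)


def _draw_tu_sizes(rng: np.random.Generator, config: SimConfig) -> list[int]:
    sizes: list[int] = []
    total = 0
    while total < config.n_genes:
        cat = int(rng.choice(len(config.tu_size_probs), p=config.tu_size_probs)) + 1
        if cat == len(config.tu_size_probs):  # the open-ended 5+ category
            cat += int(rng.geometric(1.0 - config.tu_size_tail_p) - 1)
        size = min(cat, config.n_genes - total)
        sizes.append(size)
        total += size
    return sizes


def _draw_sequence(
    rng: np.random.Generator, length: int, gc_prob: np.ndarray
) -> str:
    u_gc = rng.random(length) < gc_prob
    u_which = rng.random(length) < 0.5
    codes = np.where(u_gc, np.where(u_which, ord("G"), ord("C")), np.where(u_which, ord("A"), ord("T")))
    return codes.astype(np.uint8).tobytes().decode("ascii")


def simulate_genome(config: SimConfig, seed: int | None = None) -> SimTruth:
    """Lay out a genome TU by TU and draw its nucleotide sequence.

    Genes inside a TU share a strand and are separated by short gaps;
    consecutive TUs are separated by longer gaps and switch strand with
    probability ``strand_switch_prob``. Coding positions are drawn at
    ``coding_gc``, all other positions at ``intergenic_gc``. Per-TU
    expression levels (lognormal, median 1) are drawn here so that
    coverage and evidence simulation share them.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = _draw_tu_sizes(rng, config)
    n_tus = len(sizes)
    strands: list[str] = []
    current = "+" if rng.random() < 0.5 else "-"
    for _ in range(n_tus):
        strands.append(current)
        if rng.random() < config.strand_switch_prob:
            current = "+" if current == "-" else "-"

    genes: list[Gene] = []
    tus: list[TU] = []
    pos = int(
        _lognormal_lengths(rng, config.inter_gap_mean, config.inter_gap_sigma, config.inter_gap_min, 1)[0]
    )
    gene_index = 0
    for t, (size, strand) in enumerate(zip(sizes, strands)):
        lengths = _lognormal_lengths(rng, config.gene_len_mean, config.gene_len_sigma, config.gene_len_min, size)
        gaps = _lognormal_lengths(rng, config.intra_gap_mean, config.intra_gap_sigma, config.intra_gap_min, size - 1) if size > 1 else np.array([], dtype=np.int64)
        member_ids: list[str] = []
        tu_start = pos
        for k in range(size):
            gid = f"g{gene_index:04d}"
            genes.append(Gene(id=gid, strand=strand, start=pos, end=pos + int(lengths[k])))
            member_ids.append(gid)
            pos += int(lengths[k])
            if k < size - 1:
                pos += int(gaps[k])
            gene_index += 1
        tus.append(TU(gene_ids=tuple(member_ids), strand=strand, start=tu_start, end=pos, dataset_id="truth"))
        pos += int(
            _lognormal_lengths(rng, config.inter_gap_mean, config.inter_gap_sigma, config.inter_gap_min, 1)[0]
        )
    length = pos
    if length > config.max_genome_len:
        raise ValueError("infeasible config: genome overflow")

    gc_prob = np.full(length, config.intergenic_gc)
    for g in genes:
        gc_prob[g.start : g.end] = config.coding_gc
    sequence = _draw_sequence(rng, length, gc_prob)

    annotation = GenomeAnnotation(
        genome_id=config.genome_id, length=length, genes=tuple(genes), sequence=sequence
    )
    expression = rng.lognormal(0.0, config.expression_sigma, size=n_tus)
    return SimTruth(
        annotation=annotation,
        true_tus=TUSet(tus=tus, annotation_ref=config.genome_id),
        tu_expression=expression,
    )


def simulate_coverage(
    truth: SimTruth, config: SimConfig, seed: int | None = None
) -> tuple[Reads, CoverageTrack]:
    """Place discrete reads within TU spans and build the coverage track.

    Expected total read mass equals ``depth * coding_length`` so the
    realised estimated depth matches ``config.depth`` up to Poisson noise.
    Read starts are drawn from gamma-weighted bins within each TU span
    (overdispersion), a fraction ``antisense_rate`` of reads is flipped to
    the opposite strand, and each inter-TU boundary is bridged by
    read-through reads with probability ``1 - boundary_gap_prob``.
    """
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    annotation = truth.annotation
    tus = truth.true_tus.tus
    rl = config.read_length
    spans = np.array([(tu.start, tu.end) for tu in tus], dtype=np.int64)
    span_lens = spans[:, 1] - spans[:, 0]
    weights = truth.tu_expression * span_lens
    total_reads = config.depth * annotation.coding_length / rl
    lam = total_reads * weights / weights.sum()
    counts = rng.poisson(lam)

    starts_all: list[np.ndarray] = []
    for t, n in enumerate(counts):
        if n == 0:
            continue
        s, e = spans[t]
        lo, hi = s, max(e - rl, s + 1)
        n_bins = max(1, int(np.ceil((hi - lo) / config.bin_size)))
        if config.overdispersion > 0 and n_bins > 1:
            shape = 1.0 / config.overdispersion**2
            w = rng.gamma(shape, 1.0 / shape, size=n_bins)
        else:
            w = np.ones(n_bins)
        bin_idx = rng.choice(n_bins, size=n, p=w / w.sum())
        offsets = rng.integers(0, config.bin_size, size=n)
        starts = np.minimum(lo + bin_idx * config.bin_size + offsets, hi - 1)
        starts_all.append(starts)
    starts = np.concatenate(starts_all) if starts_all else np.empty(0, dtype=np.int64)
    ends = np.minimum(starts + rl, annotation.length)
    tu_of_read = np.searchsorted(spans[:, 0], starts, side="right") - 1
    plus = np.array([tus[t].strand == "+" for t in tu_of_read]) if len(starts) else np.empty(0, dtype=bool)

    # read-through across a minority of inter-TU boundaries: hard negatives
    rt_starts: list[int] = []
    rt_plus: list[bool] = []
    for t, (left_tu, right_tu) in enumerate(zip(tus, tus[1:])):
        gap_start, gap_end = left_tu.end, right_tu.start
        if gap_end <= gap_start:
            continue
        # read-through requires both flanking TUs to be transcribed
        if truth.tu_expression[t] == 0 or truth.tu_expression[t + 1] == 0:
            continue
        if rng.random() < config.boundary_gap_prob:
            continue
        n_rt = max(1, int(round(config.readthrough_coverage * (gap_end - gap_start + rl) / rl)))
        s_lo = max(gap_start - rl + 1, 0)
        rt = rng.integers(s_lo, gap_end, size=n_rt)
        rt_starts.extend(int(v) for v in rt)
        rt_plus.extend([left_tu.strand == "+"] * n_rt)
    if rt_starts:
        rt_starts_arr = np.array(rt_starts, dtype=np.int64)
        starts = np.concatenate([starts, rt_starts_arr])
        ends = np.concatenate([ends, np.minimum(rt_starts_arr + rl, annotation.length)])
        plus = np.concatenate([plus, np.array(rt_plus)])

    flip = rng.random(len(starts)) < config.antisense_rate
    plus = np.where(flip, ~plus, plus)
    reads = Reads(starts, ends, plus).sorted()
    track = build_coverage(reads, annotation, "stranded-forward")
    return reads, track


def simulate_evidence(
    truth: SimTruth,
    config: SimConfig,
    seed: int | None = None,
    kind: str = "long_read",
    n: int | None = None,
) -> Reads:
    """Sample spanning-evidence intervals inside true TU spans.

    ``kind`` selects the length model: ~225 bp long reads or ~170 bp
    paired-end fragment spans. Intervals never cross a true TU boundary
    (they are clipped to the span when longer than it), and TUs are
    sampled proportionally to expression times span length.
    """
    if kind == "long_read":
        mean_len, sd_len = config.long_read_mean_len, config.long_read_sd_len
    elif kind == "fragment":
        mean_len, sd_len = config.fragment_mean_len, config.fragment_sd_len
    else:
        raise ValueError(f"unknown evidence kind {kind!r}")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n = config.n_evidence if n is None else n
    tus = truth.true_tus.tus
    spans = np.array([(tu.start, tu.end) for tu in tus], dtype=np.int64)
    span_lens = spans[:, 1] - spans[:, 0]
    weights = truth.tu_expression * span_lens
    tu_idx = rng.choice(len(tus), size=n, p=weights / weights.sum())
    lengths = np.maximum(np.round(rng.normal(mean_len, sd_len, size=n)).astype(np.int64), 30)
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    for i, t in enumerate(tu_idx):
        s, e = spans[t]
        L = min(int(lengths[i]), e - s)
        starts[i] = s if e - s == L else rng.integers(s, e - L)
        ends[i] = starts[i] + L
    plus = np.array([tus[t].strand == "+" for t in tu_idx])
    return Reads(starts, ends, plus).sorted()


def write_truth_tsv(truth: SimTruth, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("tu_id\tstrand\tstart\tend\tn_genes\tgene_ids\texpression\n")
        for i, tu in enumerate(truth.true_tus.tus):
            fh.write(
                f"tu{i:04d}\t{tu.strand}\t{tu.start}\t{tu.end}\t{tu.n_genes}\t"
                f"{','.join(tu.gene_ids)}\t{truth.tu_expression[i]:.6g}\n"
            )


def write_simulation(
    truth: SimTruth,
    reads: Reads,
    evidence: Reads | None,
    outdir: str | os.PathLike,
) -> None:
    """Write FASTA, GFF3, truth TSV, reads BED6 and evidence BED6."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_fasta(truth.annotation, os.path.join(outdir, "genome.fa"))
    write_gff3(truth.annotation, os.path.join(outdir, "ann.gff3"))
    write_truth_tsv(truth, os.path.join(outdir, "truth_tus.tsv"))
    write_bed6(reads, os.path.join(outdir, "reads.bed"), truth.annotation.genome_id)
    if evidence is not None:
        write_bed6(evidence, os.path.join(outdir, "evidence.bed"), truth.annotation.genome_id)
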