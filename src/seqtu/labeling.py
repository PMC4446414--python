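"""Training-label construction for the junction classifier.

Three label sources:

* negative pairs — consecutive gene pairs whose intergenic region is mostly
  unexpressed (gap fraction > 0.5) AND whose flanking genes differ by more
  than 10-fold in expression;
* positive pairs from spanning evidence — pairs whose intergenic region is
  fully contained in a single long read or paired-end fragment and whose
  genes differ by at most 2-fold;
* constructed TUs (cTUs) — single genes partitioned into two pseudo-coding
  flanks around a made-up intergenic region (cIR) placed on the gene's
  lowest-GC window, exploiting the lower GC content of real intergenic
  sequence. cTUs extend the positive set to junctions with intergenic
  regions longer than the evidence read length.

Expression level of any interval is its mean RAPSN on its strand; ratios
use a pseudocount of 1 on both means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .annotation_io import GenePair, GenomeAnnotation, STRANDS
from .coverage import CoverageTrack, Reads
from .features import PSEUDOCOUNT, continuity_features

logger = logging.getLogger(__name__)

NEGATIVE_GAP_THRESHOLD = 0.5  # strict >: gap fraction of the intergenic region
NEGATIVE_RATIO_THRESHOLD = 10.0  # strict >: fold change between flanking genes
POSITIVE_RATIO_THRESHOLD = 2.0  # inclusive <=
MIN_CIR_LENGTH = 225  # bp; the evidence read length the cTUs must exceed


@dataclass(frozen=True)
class CTU:
    """A constructed TU: one gene split into left flank | cIR | right flank."""

    source_gene_id: str
    strand: str
    p: float
    q: float
    cir_start: int
    cir_end: int
    left_part: tuple[int, int]
    right_part: tuple[int, int]

    @property
    def cir_length(self) -> int:
        return self.cir_end - self.cir_start


@dataclass(frozen=True)
class LabeledPair:
    pair: Union[GenePair, CTU]
    label: str  # "positive" | "negative"
    source: str  # "long_read" | "cTU" | "gap_filter"

    def __post_init__(self) -> None:
        expected = "negative" if self.source == "gap_filter" else "positive"
        if self.label != expected:
            raise ValueError(f"label {self.label!r} inconsistent with source {self.source!r}")


@dataclass
class LengthDensity:
    """Empirical density of intergenic-length or gene-length-difference
    ratios, sampled by resampling the observed values with replacement."""

    observations: np.ndarray
    kind: str  # "IR" | "GD"

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float)
        if np.any((self.observations < 0) | (self.observations > 1)):
            raise ValueError("ratio observations must lie in [0, 1]")
        if len(self.observations) < 2:
            raise ValueError("insufficient pairs for density")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.choice(self.observations, size=size, replace=True)


def interval_mean(track: CoverageTrack, interval: tuple[int, int], strand: str) -> float:
    s, e = interval
    if e <= s:
        return 0.0
    return float(track.strand_array(strand)[s:e].mean())


def expression_ratio(
    track: CoverageTrack,
    a: tuple[int, int],
    b: tuple[int, int],
    strand: str,
) -> float:
    """Max/min ratio of mean RAPSN of two intervals, pseudocount-guarded."""
    ma = interval_mean(track, a, strand) + PSEUDOCOUNT
    mb = interval_mean(track, b, strand) + PSEUDOCOUNT
    return max(ma, mb) / min(ma, mb)


def pair_expression_ratio(track: CoverageTrack, pair: GenePair) -> float:
    return expression_ratio(
        track,
        (pair.left.start, pair.left.end),
        (pair.right.start, pair.right.end),
        pair.strand,
    )


def select_negative_pairs(pairs: Sequence[GenePair], track: CoverageTrack) -> list[LabeledPair]:
    """Pairs deemed not co-transcribed: intergenic gap fraction > 0.5 AND
    gene expression ratio > 10-fold (both conditions strict)."""
    out: list[LabeledPair] = []
    for pair in pairs:
        _, gap_fraction = continuity_features(
            track, (pair.intergenic.start, pair.intergenic.end), pair.strand
        )
        if gap_fraction > NEGATIVE_GAP_THRESHOLD and pair_expression_ratio(track, pair) > NEGATIVE_RATIO_THRESHOLD:
            out.append(LabeledPair(pair=pair, label="negative", source="gap_filter"))
    return out


def _spanning_lookup(evidence: Reads, stranded: bool):
    """Per-strand (starts sorted, running max of ends) for containment queries."""
    lookup: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for strand in STRANDS:
        sel = np.ones(len(evidence), dtype=bool) if not stranded else (
            evidence.plus if strand == "+" else ~evidence.plus
        )
        starts = evidence.starts[sel]
        ends = evidence.ends[sel]
        order = np.argsort(starts, kind="stable")
        starts = starts[order]
        ends_cummax = np.maximum.accumulate(ends[order]) if len(ends) else ends
        lookup[strand] = (starts, ends_cummax)
    return lookup


def _is_spanned(lookup, strand: str, start: int, end: int) -> bool:
    starts, ends_cummax = lookup[strand]
    idx = int(np.searchsorted(starts, start, side="right"))
    return idx > 0 and int(ends_cummax[idx - 1]) >= end


def select_positive_pairs_by_spanning(
    pairs: Sequence[GenePair],
    evidence: Reads,
    track: CoverageTrack,
    stranded: bool = True,
) -> list[LabeledPair]:
    """Pairs whose intergenic region is entirely contained in at least one
    single evidence interval (long read, or full paired-end fragment span)
    and whose gene expression ratio is <= 2-fold (inclusive)."""
    lookup = _spanning_lookup(evidence, stranded)
    out: list[LabeledPair] = []
    for pair in pairs:
        if not _is_spanned(lookup, pair.strand, pair.intergenic.start, pair.intergenic.end):
            continue
        if pair_expression_ratio(track, pair) <= POSITIVE_RATIO_THRESHOLD:
            out.append(LabeledPair(pair=pair, label="positive", source="long_read"))
    return out


def fit_length_densities(
    annotation: GenomeAnnotation,
    pairs: Sequence[GenePair] | None = None,
) -> dict[str, tuple[LengthDensity, LengthDensity]]:
    """Per-strand empirical densities of the intergenic-length ratio
    ``|ir| / (|ir| + |g_i| + |g_{i+1}|)`` and the gene-length-difference
    ratio ``||g_i| - |g_{i+1}|| / (|ir| + |g_i| + |g_{i+1}|)``.

    Only consecutive same-strand pairs with no opposite-strand gene in
    between contribute. Raises if a strand has fewer than two eligible
    pairs.
    """
    from .annotation_io import derive_gene_pairs

    if pairs is None:
        pairs = derive_gene_pairs(annotation)
    densities: dict[str, tuple[LengthDensity, LengthDensity]] = {}
    for strand in STRANDS:
        ir_obs: list[float] = []
        gd_obs: list[float] = []
        for pair in pairs:
            if pair.strand != strand or pair.has_opposite_strand_gene_between:
                continue
            denom = pair.intergenic.length + pair.left.length + pair.right.length
            ir_obs.append(pair.intergenic.length / denom)
            gd_obs.append(abs(pair.left.length - pair.right.length) / denom)
        if len(ir_obs) < 2:
            raise ValueError(f"insufficient pairs for density on strand {strand!r}")
        densities[strand] = (
            LengthDensity(np.array(ir_obs), "IR"),
            LengthDensity(np.array(gd_obs), "GD"),
        )
    return densities


def _gc_cumsum(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    gc = (arr == ord("G")) | (arr == ord("C"))
    return np.concatenate(([0], np.cumsum(gc, dtype=np.int64)))


def construct_ctus(
    annotation: GenomeAnnotation,
    densities: dict[str, tuple[LengthDensity, LengthDensity]],
    track: CoverageTrack,
    seed: int,
    min_cir_length: int = MIN_CIR_LENGTH,
    max_gap_fraction: float = NEGATIVE_GAP_THRESHOLD,
    max_flank_ratio: float = NEGATIVE_RATIO_THRESHOLD,
) -> list[CTU]:
    """Build constructed TUs by partitioning genes around a low-GC window.

    For each gene of length ``|g|`` (midpoint ``m = |g|/2``) a cIR-length
    ratio ``p`` and a gene-length-difference ratio ``q`` are drawn from the
    strand's densities. The cIR length is ``L = round(p * |g|)`` and its
    start offset is searched over the window
    ``[m - L/2 - q*|g|/2, m - L/2 + q*|g|/2]`` (clamped so both flanks keep
    at least one base), choosing the start minimising the window's GC
    fraction, leftmost on ties.

    A cTU is emitted only if it behaves like a genuine co-transcribed
    junction: cIR zero-coverage fraction <= ``max_gap_fraction``, flank
    expression ratio <= ``max_flank_ratio``, and ``L >= min_cir_length``
    (so cIRs exceed the spanning-evidence read length). Genes too short to
    partition are skipped.
    """
    if annotation.sequence is None:
        raise ValueError("annotation sequence required for cTU construction")
    rng = np.random.default_rng(seed)
    gc_cs = _gc_cumsum(annotation.sequence)
    out: list[CTU] = []
    for strand in STRANDS:
        ir_density, gd_density = densities[strand]
        for gene in annotation.genes_on_strand(strand):
            p = float(ir_density.sample(rng))
            q = float(gd_density.sample(rng))
            glen = gene.length
            L = int(round(p * glen))
            if L < 1 or L > glen - 2:
                logger.debug("gene %s skipped: infeasible cIR length %d", gene.id, L)
                continue
            m = glen / 2.0
            lo = int(round(m - L / 2.0 - q * glen / 2.0))
            hi = int(round(m - L / 2.0 + q * glen / 2.0))
            lo = min(max(lo, 1), glen - L - 1)
            hi = min(max(hi, 1), glen - L - 1)
            offsets = np.arange(lo, hi + 1)
            gc_counts = gc_cs[gene.start + offsets + L] - gc_cs[gene.start + offsets]
            best = int(offsets[np.argmin(gc_counts)])  # argmin -> leftmost tie
            cir_start = gene.start + best
            cir_end = cir_start + L
            ctu = CTU(
                source_gene_id=gene.id,
                strand=strand,
                p=p,
                q=q,
                cir_start=cir_start,
                cir_end=cir_end,
                left_part=(gene.start, cir_start),
                right_part=(cir_end, gene.end),
            )
            _, gap_fraction = continuity_features(track, (cir_start, cir_end), strand)
            if gap_fraction > max_gap_fraction:
                continue
            if expression_ratio(track, ctu.left_part, ctu.right_part, strand) > max_flank_ratio:
                continue
            if L < min_cir_length:
                continue
            out.append(ctu)
    return out
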