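"""Evaluation of predicted transcription units.

Four procedures:

* confirmed TUs — gene runs entirely contained in a single long
  read/fragment, the evaluation gold standard;
* sensitivity — fraction of confirmed TUs recovered by a prediction (all
  internal junctions predicted co-transcribed);
* TU-set similarity — Jaccard agreement between the joined-junction sets
  of two predictions over the same annotation;
* depth resampling — read subsampling without replacement across a grid of
  target sequencing depths, re-running the prediction pipeline per
  replicate to profile how sensitivity degrades with depth;
* intergenic expression contrast — inside-TU vs outside-TU intergenic
  regions compared by a one-sided rank-sum test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .annotation_io import GenomeAnnotation, STRANDS, derive_gene_pairs
from .coverage import CoverageTrack, Reads, build_coverage, estimated_depth
from .model import TUSet


@dataclass(frozen=True)
class ConfirmedTU:
    """A gene run certified by at least one fully containing evidence read."""

    gene_ids: tuple[str, ...]
    strand: str
    supporting_read_count: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ResampleResult:
    """Sensitivity across a sequencing-depth grid, replicated."""

    depth_grid: np.ndarray
    replicates: int
    sensitivities: np.ndarray  # shape (n_depths, replicates)

    @property
    def mean_sensitivity(self) -> np.ndarray:
        return self.sensitivities.mean(axis=1)


def confirmed_tus(
    evidence: Reads,
    annotation: GenomeAnnotation,
    stranded: bool = True,
) -> list[ConfirmedTU]:
    """Derive confirmed TUs from spanning-evidence intervals.

    For each evidence interval, every maximal run of consecutive
    same-strand genes fully contained in the interval becomes a confirmed
    TU; identical runs found by several reads are merged with their
    support counts summed. With ``stranded=False`` (e.g. non-strand-
    specific long reads) every interval is tested against both strands.
    """
    support: Counter[tuple[str, tuple[str, ...]]] = Counter()
    for strand in STRANDS:
        genes = annotation.genes_on_strand(strand)
        if not genes:
            continue
        starts = np.array([g.start for g in genes])
        ends = np.array([g.end for g in genes])
        if stranded:
            sel = evidence.plus if strand == "+" else ~evidence.plus
        else:
            sel = np.ones(len(evidence), dtype=bool)
        for iv_start, iv_end in zip(evidence.starts[sel], evidence.ends[sel]):
            lo = int(np.searchsorted(starts, iv_start, side="left"))
            run: list[str] = []
            for k in range(lo, len(genes)):
                if starts[k] >= iv_end:
                    break
                if starts[k] >= iv_start and ends[k] <= iv_end:
                    run.append(genes[k].id)
                elif run:
                    support[(strand, tuple(run))] += 1
                    run = []
            if run:
                support[(strand, tuple(run))] += 1
    out = [
        ConfirmedTU(gene_ids=ids, strand=strand, supporting_read_count=count)
        for (strand, ids), count in support.items()
    ]
    out.sort(key=lambda c: (c.strand, c.gene_ids))
    return out


def truth_confirmed(tuset: TUSet) -> list[ConfirmedTU]:
    """Treat a ground-truth TU set as the confirmed gold standard."""
    return [
        ConfirmedTU(gene_ids=tu.gene_ids, strand=tu.strand, supporting_read_count=1)
        for tu in tuset.tus
    ]


def sensitivity(predicted: TUSet, confirmed: Sequence[ConfirmedTU]) -> float:
    """Fraction of confirmed TUs recovered by the prediction.

    A confirmed TU is recovered when all its genes lie consecutively within
    one predicted TU, i.e. every internal junction of the confirmed run is
    predicted co-transcribed. (A confirmed TU may be a sub-run of a longer
    predicted TU: short evidence reads cannot certify full TU extent.)
    """
    if not confirmed:
        raise ValueError("nothing to evaluate: empty confirmed set")
    joined = predicted.joined_junctions()
    present = predicted.gene_ids()
    recovered = 0
    for ctu in confirmed:
        if not all(g in present for g in ctu.gene_ids):
            continue
        if all((a, b) in joined for a, b in zip(ctu.gene_ids, ctu.gene_ids[1:])):
            recovered += 1
    return recovered / len(confirmed)


def similarity_score(a: TUSet, b: TUSet) -> float:
    """Agreement between two TU sets on which consecutive gene pairs are
    co-transcribed: Jaccard index of their joined-junction sets. Defined
    as 1.0 when neither set joins any pair."""
    if a.annotation_ref != b.annotation_ref:
        raise ValueError("TU sets cover different annotations")
    ja, jb = a.joined_junctions(), b.joined_junctions()
    union = ja | jb
    if not union:
        return 1.0
    return len(ja & jb) / len(union)


def depth_resample(
    reads: Reads,
    annotation: GenomeAnnotation,
    target_depths: Sequence[float],
    pipeline: Callable[[CoverageTrack], TUSet],
    confirmed: Sequence[ConfirmedTU],
    seed: int,
    replicates: int = 25,
    strand_mode: str = "stranded-forward",
) -> ResampleResult:
    """Profile prediction sensitivity across sequencing depths.

    For each target depth ``d`` and replicate, ``round(N * d / D_full)``
    reads are drawn without replacement (seeded independently per cell),
    coverage is rebuilt, the prediction pipeline re-run and its
    sensitivity against the confirmed set recorded. A target equal to the
    full depth reproduces the full-data result exactly.
    """
    full_track = build_coverage(reads, annotation, strand_mode)
    full_depth = estimated_depth(full_track, annotation)
    depths = np.asarray(target_depths, dtype=float)
    if np.any(depths > full_depth * (1 + 1e-9)):
        raise ValueError("target depth exceeds full depth")
    n_reads = len(reads)
    sens = np.empty((len(depths), replicates))
    for di, d in enumerate(depths):
        n_draw = int(round(n_reads * d / full_depth))
        for ri in range(replicates):
            rng = np.random.default_rng([seed, di, ri])
            idx = rng.choice(n_reads, size=n_draw, replace=False)
            track = build_coverage(reads.subset(idx), annotation, strand_mode)
            sens[di, ri] = sensitivity(pipeline(track), confirmed)
    return ResampleResult(depth_grid=depths, replicates=replicates, sensitivities=sens)


def intergenic_contrast(
    tuset: TUSet,
    track: CoverageTrack,
    annotation: GenomeAnnotation,
) -> tuple[float, float, float]:
    """Compare expression of inside-TU vs outside-TU intergenic regions.

    Inside-TU regions lie between genes of one TU; outside-TU regions lie
    between consecutive same-strand genes assigned to distinct TUs.
    Returns the mean of per-region mean RAPSN for both groups and the
    one-sided rank-sum p-value for inside > outside. Zero-length regions
    are skipped.
    """
    joined = tuset.joined_junctions()
    inside: list[float] = []
    outside: list[float] = []
    for pair in derive_gene_pairs(annotation):
        ir = pair.intergenic
        if ir.length == 0:
            continue
        mean = float(track.strand_array(pair.strand)[ir.start : ir.end].mean())
        (inside if pair.key in joined else outside).append(mean)
    if not inside or not outside:
        raise ValueError("need at least one intergenic region in each group")
    stat = stats.mannwhitneyu(inside, outside, alternative="greater")
    return float(np.mean(inside)), float(np.mean(outside)), float(stat.pvalue)
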