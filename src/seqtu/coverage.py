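"""Strand-specific per-base read-abundance tracks and coverage statistics.

The central quantity is the read abundance per single nucleotide (RAPSN):
the number of aligned reads covering each genomic position, kept separately
for the two strands. Tracks are built from SAM/BAM alignments, BED6 read
intervals, or per-strand bedGraph files, and feed every downstream feature
and filter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .annotation_io import GenomeAnnotation

STRAND_MODES = ("stranded-forward", "stranded-reverse", "unstranded")


@dataclass
class Reads:
    """A set of aligned read (or fragment) intervals on one replicon.

    Stored as parallel numpy arrays: half-open ``[start, end)`` spans and a
    boolean ``plus`` flag per read.
    """

    starts: np.ndarray
    ends: np.ndarray
    plus: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.plus = np.asarray(self.plus, dtype=bool)
        if not (len(self.starts) == len(self.ends) == len(self.plus)):
            raise ValueError("reads arrays must have equal length")
        if np.any(self.ends < self.starts):
            raise ValueError("read end before start")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def subset(self, index: np.ndarray) -> "Reads":
        return Reads(self.starts[index], self.ends[index], self.plus[index])

    def sorted(self) -> "Reads":
        order = np.lexsort((self.ends, self.starts))
        return self.subset(order)


@dataclass
class CoverageTrack:
    """Per-strand RAPSN arrays over one replicon."""

    genome_id: str
    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus)
        self.minus = np.asarray(self.minus)
        if self.plus.shape != self.minus.shape:
            raise ValueError("strand arrays must have equal length")
        if np.any(self.plus < 0) or np.any(self.minus < 0):
            raise ValueError("coverage must be non-negative")

    @property
    def length(self) -> int:
        return len(self.plus)

    def strand_array(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        if strand == "both":
            return self.plus + self.minus
        raise ValueError(f"unknown strand {strand!r}")

    @property
    def total_mass(self) -> int:
        return int(self.plus.sum() + self.minus.sum())


@dataclass(frozen=True)
class CoverageStats:
    """Dataset-level summaries: depth, covered fractions, antisense load."""

    estimated_depth: float
    coding_covered_fraction: float
    intergenic_covered_fraction: float
    antisense_fraction: float


def read_bed6(path: str | os.PathLike) -> Reads:
    df = pd.read_csv(
        os.fspath(path),
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    return Reads(df["start"].to_numpy(), df["end"].to_numpy(), (df["strand"] == "+").to_numpy())


def write_bed6(reads: Reads, path: str | os.PathLike, genome_id: str, name_prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i in range(len(reads)):
            strand = "+" if reads.plus[i] else "-"
            fh.write(
                f"{genome_id}\t{reads.starts[i]}\t{reads.ends[i]}\t{name_prefix}{i}\t0\t{strand}\n"
            )


def _accumulate(diff: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> None:
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)


def _reads_from_sam(path: str, genome_id: str, length: int) -> Reads:
    """Flatten SAM/BAM alignments to aligned blocks (one span per block).

    Gapped alignments (N/D CIGAR operations) contribute only their aligned
    bases; soft-clipped bases never count.
    """
    starts: list[int] = []
    ends: list[int] = []
    plus: list[bool] = []
    mode = "rb" if os.fspath(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(os.fspath(path), mode) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.reference_name != genome_id:
                raise ValueError(
                    f"unknown reference {aln.reference_name!r} (expected {genome_id!r})"
                )
            is_plus = not aln.is_reverse
            for bstart, bend in aln.get_blocks():
                starts.append(bstart)
                ends.append(bend)
                plus.append(is_plus)
    return Reads(np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64), np.array(plus))


def build_coverage(
    source: Reads | str | os.PathLike,
    annotation: GenomeAnnotation,
    strand_mode: str = "stranded-forward",
) -> CoverageTrack:
    """Build a per-strand RAPSN track from read intervals.

    Every aligned base of every read increments the position's count on the
    read's assigned strand. ``stranded-reverse`` flips read strands (for
    dUTP-style libraries); ``unstranded`` pools everything onto ``plus``,
    which disables downstream strand-specific statistics.

    Raises
    ------
    ValueError
        If a read extends past the genome end ("read out of bounds"), the
        reference name is unknown, or the strand mode is unrecognised.
    """
    if strand_mode not in STRAND_MODES:
        raise ValueError(f"unknown strand mode {strand_mode!r}")
    if isinstance(source, (str, os.PathLike)):
        path = os.fspath(source)
        if path.endswith((".sam", ".bam")):
            reads = _reads_from_sam(path, annotation.genome_id, annotation.length)
        else:
            reads = read_bed6(path)
    else:
        reads = source

    length = annotation.length
    if len(reads) and (reads.starts.min() < 0 or reads.ends.max() > length):
        raise ValueError("read out of bounds: alignment extends past genome end")

    plus_sel = reads.plus
    if strand_mode == "stranded-reverse":
        plus_sel = ~plus_sel
    diff_plus = np.zeros(length + 1, dtype=np.int64)
    diff_minus = np.zeros(length + 1, dtype=np.int64)
    if strand_mode == "unstranded":
        _accumulate(diff_plus, reads.starts, reads.ends)
    else:
        _accumulate(diff_plus, reads.starts[plus_sel], reads.ends[plus_sel])
        _accumulate(diff_minus, reads.starts[~plus_sel], reads.ends[~plus_sel])
    return CoverageTrack(
        genome_id=annotation.genome_id,
        plus=np.cumsum(diff_plus[:-1]),
        minus=np.cumsum(diff_minus[:-1]),
    )


def estimated_depth(track: CoverageTrack, annotation: GenomeAnnotation) -> float:
    """Average sequencing depth: total RAPSN mass over the whole genome
    (both strands) divided by the total coding length (union of gene
    intervals, overlaps counted once). Intergenic positions contribute to
    the numerator but not the denominator."""
    coding = annotation.coding_length
    if coding == 0:
        raise ValueError("no coding sequence: cannot estimate depth")
    return track.total_mass / coding


def region_covered_fraction(
    track: CoverageTrack,
    regions: list[tuple[int, int]],
    strand: str = "both",
) -> float:
    """Fraction of positions in the union of ``regions`` with RAPSN >= 1."""
    if not regions:
        raise ValueError("empty region set")
    mask = np.zeros(track.length, dtype=bool)
    for s, e in regions:
        if s < 0 or e > track.length:
            raise ValueError("region outside genome")
        mask[s:e] = True
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty region set")
    covered = int((track.strand_array(strand)[mask] >= 1).sum())
    return covered / n


def _gene_body_masks(annotation: GenomeAnnotation) -> tuple[np.ndarray, np.ndarray]:
    plus_mask = np.zeros(annotation.length, dtype=bool)
    minus_mask = np.zeros(annotation.length, dtype=bool)
    for g in annotation.genes:
        (plus_mask if g.strand == "+" else minus_mask)[g.start : g.end] = True
    return plus_mask, minus_mask


def antisense_fraction(track: CoverageTrack, annotation: GenomeAnnotation) -> float:
    """Ratio of antisense to sense RAPSN mass over annotated gene bodies.

    Antisense mass is coverage on the strand opposite each gene's
    annotation; positions outside annotated genes are excluded. Raises if
    there is no sense signal at all.
    """
    plus_mask, minus_mask = _gene_body_masks(annotation)
    sense = int(track.plus[plus_mask].sum() + track.minus[minus_mask].sum())
    antisense = int(track.minus[plus_mask].sum() + track.plus[minus_mask].sum())
    if sense == 0:
        raise ValueError("no sense expression")
    return antisense / sense


def coverage_stats(track: CoverageTrack, annotation: GenomeAnnotation) -> CoverageStats:
    """Aggregate the dataset-level characteristics of one track."""
    coding = annotation.coding_union()
    intergenic: list[tuple[int, int]] = []
    prev = 0
    for s, e in coding:
        if s > prev:
            intergenic.append((prev, s))
        prev = max(prev, e)
    if prev < annotation.length:
        intergenic.append((prev, annotation.length))
    return CoverageStats(
        estimated_depth=estimated_depth(track, annotation),
        coding_covered_fraction=region_covered_fraction(track, coding, "both"),
        intergenic_covered_fraction=(
            region_covered_fraction(track, intergenic, "both") if intergenic else 0.0
        ),
        antisense_fraction=antisense_fraction(track, annotation),
    )


def write_bedgraph(track: CoverageTrack, plus_path: str | os.PathLike, minus_path: str | os.PathLike) -> None:
    """Write one bedGraph per strand; zero runs are omitted."""
    for arr, path in ((track.plus, plus_path), (track.minus, minus_path)):
        boundaries = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(arr)]))
        with open(path, "w") as fh:
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v != 0:
                    fh.write(f"{track.genome_id}\t{s}\t{e}\t{v}\n")


def track_from_bedgraph(
    plus_path: str | os.PathLike,
    minus_path: str | os.PathLike,
    genome_id: str,
    length: int,
) -> CoverageTrack:
    arrays = []
    for path in (plus_path, minus_path):
        arr = np.zeros(length, dtype=np.int64)
        df = pd.read_csv(
            os.fspath(path),
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
        )
        for s, e, v in zip(df["start"], df["end"], df["value"]):
            if e > length:
                raise ValueError("bedGraph interval outside genome")
            arr[int(s) : int(e)] = int(v)
        arrays.append(arr)
    return CoverageTrack(genome_id=genome_id, plus=arrays[0], minus=arrays[1])
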