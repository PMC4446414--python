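"""Genome annotation parsing and consecutive gene-pair derivation.

Gene coordinates are held internally as 0-based half-open intervals; the
1-based inclusive convention of GFF3 and GenBank flat files is converted at
the I/O boundary. All downstream machinery (coverage windows, intergenic
regions, constructed-TU partitions) relies on this convention so that
lengths are always ``end - start``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

STRANDS = ("+", "-")

_GENBANK_SUFFIXES = {".gb", ".gbk", ".gbff", ".genbank"}


@dataclass(frozen=True)
class Gene:
    """An annotated gene: ``[start, end)`` on one strand."""

    id: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for gene {self.id}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.id}: start must precede end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IntergenicRegion:
    """The interval between two consecutive same-strand genes.

    Zero-length regions (``end == start``) represent abutting or
    overlapping gene pairs.
    """

    start: int
    end: int
    strand: str
    left_gene_id: str
    right_gene_id: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("intergenic region must have end >= start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenePair:
    """A candidate junction: two consecutive genes on the same strand."""

    left: Gene
    right: Gene
    intergenic: IntergenicRegion
    has_opposite_strand_gene_between: bool
    overlapping: bool

    def __post_init__(self) -> None:
        if self.left.strand != self.right.strand:
            raise ValueError("paired genes must share a strand")

    @property
    def strand(self) -> str:
        return self.left.strand

    @property
    def key(self) -> tuple[str, str]:
        return (self.left.id, self.right.id)


@dataclass
class GenomeAnnotation:
    """A single replicon's gene annotation, position-sorted.

    Parameters
    ----------
    genome_id:
        Replicon / contig identifier (matches alignment reference names).
    length:
        Replicon length in bp.
    genes:
        Genes sorted by start coordinate.
    sequence:
        Optional nucleotide sequence of length ``length``; required only
        for GC-dependent operations (constructed-TU placement).
    """

    genome_id: str
    length: int
    genes: tuple[Gene, ...] = field(default_factory=tuple)
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.genes = tuple(sorted(self.genes, key=lambda g: (g.start, g.end, g.id)))
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique within an annotation")
        for g in self.genes:
            if g.start < 0 or g.end > self.length:
                raise ValueError(f"gene {g.id} outside genome bounds")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != genome length {self.length}"
            )

    def genes_on_strand(self, strand: str) -> tuple[Gene, ...]:
        return tuple(g for g in self.genes if g.strand == strand)

    def coding_union(self) -> list[tuple[int, int]]:
        """Merged (strand-agnostic) gene intervals; overlaps counted once."""
        merged: list[tuple[int, int]] = []
        for g in self.genes:
            if merged and g.start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], g.end))
            else:
                merged.append((g.start, g.end))
        return merged

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.coding_union())

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def with_sequence(self, sequence: str) -> "GenomeAnnotation":
        return replace(self, sequence=sequence)


def _feature_id(feature: gffutils.Feature, index: int) -> str:
    for key in ("ID", "locus_tag", "Name", "gene"):
        if key in feature.attributes and feature.attributes[key]:
            return str(feature.attributes[key][0])
    return f"{feature.featuretype}_{index}"


def _load_gff3(path: str, feature_types: Sequence[str]) -> tuple[str, int | None, list[Gene]]:
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        force=True,
    )
    genes: list[Gene] = []
    seqids: set[str] = set()
    for i, feat in enumerate(db.all_features()):
        if feat.featuretype not in feature_types:
            continue
        if feat.strand not in STRANDS:
            continue
        seqids.add(feat.seqid)
        genes.append(
            Gene(id=_feature_id(feat, i), strand=feat.strand, start=feat.start - 1, end=feat.end)
        )
    if not genes:
        raise ValueError("empty annotation: no gene features found")
    if len(seqids) > 1:
        raise ValueError(
            "multiple contigs in annotation; split the input and process each "
            "replicon independently"
        )
    genome_id = seqids.pop()
    length: int | None = None
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4 and parts[1] == genome_id:
            length = int(parts[3])
    return genome_id, length, genes


def _load_genbank(path: str, feature_types: Sequence[str]) -> tuple[str, int, list[Gene], str]:
    record = SeqIO.read(path, "genbank")
    genes: list[Gene] = []
    for i, feat in enumerate(record.features):
        if feat.type not in feature_types:
            continue
        strand = "+" if (feat.location.strand or 1) >= 0 else "-"
        qualifiers = feat.qualifiers
        gid = None
        for key in ("locus_tag", "gene", "protein_id"):
            if key in qualifiers and qualifiers[key]:
                gid = str(qualifiers[key][0])
                break
        if gid is None:
            gid = f"{feat.type}_{i}"
        genes.append(
            Gene(id=gid, strand=strand, start=int(feat.location.start), end=int(feat.location.end))
        )
    if not genes:
        raise ValueError("empty annotation: no gene features found")
    return record.id, len(record.seq), genes, str(record.seq)


def load_annotation(
    annotation_file: str | os.PathLike,
    fasta: str | os.PathLike | None = None,
    feature_types: Sequence[str] = ("gene",),
) -> GenomeAnnotation:
    """Load a GFF3 or GenBank annotation, optionally with its FASTA sequence.

    GenBank files carry their own sequence; an explicit FASTA overrides it.
    Gene ids collide across duplicated features are rejected.

    Raises
    ------
    ValueError
        If no gene features are present ("empty annotation") or the FASTA
        sequence length disagrees with the annotation.
    """
    path = os.fspath(annotation_file)
    suffix = os.path.splitext(path)[1].lower()
    sequence: str | None = None
    if suffix in _GENBANK_SUFFIXES:
        genome_id, length, genes, sequence = _load_genbank(path, feature_types)
    else:
        genome_id, length, genes = _load_gff3(path, feature_types)

    if fasta is not None:
        record = next(SeqIO.parse(os.fspath(fasta), "fasta"))
        sequence = str(record.seq).upper()
        fasta_len = len(sequence)
        if length is not None and fasta_len != length:
            raise ValueError(
                f"FASTA length {fasta_len} does not match annotated genome length {length}"
            )
        length = fasta_len
    if length is None:
        length = max(g.end for g in genes)
    return GenomeAnnotation(genome_id=genome_id, length=length, genes=tuple(genes), sequence=sequence)


def write_gff3(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write genes back out as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.genome_id} 1 {annotation.length}\n")
        for g in annotation.genes:
            fh.write(
                "\t".join(
                    [
                        annotation.genome_id,
                        "seqtu",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.id}",
                    ]
                )
                + "\n"
            )


def write_fasta(annotation: GenomeAnnotation, path: str | os.PathLike, width: int = 70) -> None:
    if annotation.sequence is None:
        raise ValueError("annotation carries no sequence")
    with open(path, "w") as fh:
        fh.write(f">{annotation.genome_id}\n")
        seq = annotation.sequence
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def derive_gene_pairs(annotation: GenomeAnnotation) -> list[GenePair]:
    """Enumerate consecutive same-strand gene pairs, per strand in genome order.

    For each pair the intergenic region is ``[left.end, right.start)``;
    overlapping genes yield a zero-length region anchored at ``left.end``.
    ``has_opposite_strand_gene_between`` marks pairs with any opposite-strand
    gene lying (wholly or partly) between the two genes; such pairs remain
    candidates for classification but are excluded from length-density
    fitting.
    """
    if not annotation.genes:
        raise ValueError("empty annotation")
    pairs: list[GenePair] = []
    for strand in STRANDS:
        opposite = annotation.genes_on_strand("-" if strand == "+" else "+")
        strand_genes = annotation.genes_on_strand(strand)
        for left, right in zip(strand_genes, strand_genes[1:]):
            ir_start = left.end
            ir_end = max(right.start, left.end)
            overlapping = right.start < left.end
            between = any(o.end > ir_start and o.start < ir_end for o in opposite)
            pairs.append(
                GenePair(
                    left=left,
                    right=right,
                    intergenic=IntergenicRegion(
                        start=ir_start,
                        end=ir_end,
                        strand=strand,
                        left_gene_id=left.id,
                        right_gene_id=right.id,
                    ),
                    has_opposite_strand_gene_between=between,
                    overlapping=overlapping,
                )
            )
    return pairs


def pairs_to_rows(pairs: Iterable[GenePair]) -> list[dict]:
    """Tabular form used by the TSV writers in the command-line layer."""
    return [
        {
            "left_id": p.left.id,
            "right_id": p.right.id,
            "strand": p.strand,
            "ir_start": p.intergenic.start,
            "ir_end": p.intergenic.end,
            "opposite_between": p.has_opposite_strand_gene_between,
            "overlapping": p.overlapping,
        }
        for p in pairs
    ]
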