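"""Genomic coordinate model, gene annotations, and interval arithmetic.

All coordinates are 0-based half-open internally; GTF's 1-based inclusive
convention is converted at the parsing boundary.  Strand affects only the
placement of the transcription start site (TSS), never signal counting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths for one genome build.

    Build labels (rn5/rn6/...) are treated as opaque metadata; nothing in the
    pipeline lifts coordinates between builds.
    """

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("GenomeSpec needs at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene: coordinates, strand, derived TSS, and gene-set memberships.

    ``gene_sets`` carries labels such as ``"ERG"`` (estrogen-responsive gene,
    the Hallmark early+late estrogen-response membership) used downstream for
    over-representation and ERG summaries.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    gene_sets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """TSS position: ``start`` on the + strand, ``end - 1`` on the − strand."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def body(self) -> Region:
        return Region(self.chrom, self.start, self.end, self.strand)


def distance_to_tss(region: Region, gene: GeneModel) -> float:
    """Distance in bp from a region to a gene's TSS.

    Zero if the TSS falls inside the region; otherwise the distance from the
    region edge nearest the TSS.  Regions on another chromosome are infinitely
    far away (``math.inf``).
    """
    if region.chrom != gene.chrom:
        return math.inf
    tss = gene.tss
    if region.start <= tss < region.end:
        return 0
    return min(abs(region.start - tss), abs(region.end - 1 - tss))


def gene_window(gene: GeneModel, flank: int, genome: GenomeSpec | None = None) -> Region:
    """Gene body extended by ``flank`` bp on both sides, clipped to the chromosome."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    start = max(0, gene.start - flank)
    end = gene.end + flank
    if genome is not None:
        end = min(end, genome.length(gene.chrom))
    return Region(gene.chrom, start, end)


def _validate_gene(gene: GeneModel, genome: GenomeSpec | None, lineno: int) -> None:
    if genome is not None:
        if gene.chrom not in genome:
            raise AnnotationParseError(
                f"line {lineno}: unknown chromosome {gene.chrom!r}"
            )
        if gene.end > genome.length(gene.chrom):
            raise AnnotationParseError(
                f"line {lineno}: gene {gene.gene_id} ends beyond chromosome "
                f"{gene.chrom} ({gene.end} > {genome.length(gene.chrom)})"
            )


def read_bed(path: str | Path, genome: GenomeSpec | None = None) -> list[GeneModel]:
    """Read genes from BED4/BED6 (chrom, start, end, name[, score, strand])."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise AnnotationParseError(
                    f"line {lineno}: expected >=4 BED fields, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "+"
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise AnnotationParseError(
                    f"line {lineno}: end <= start ({end} <= {start})"
                )
            if name in seen:
                raise AnnotationParseError(f"line {lineno}: duplicate gene id {name!r}")
            seen.add(name)
            gene = GeneModel(name, chrom, start, end, strand)
            _validate_gene(gene, genome, lineno)
            genes.append(gene)
    if not genes:
        logger.warning("annotation file %s contained no gene records", path)
    return genes


def read_gtf(path: str | Path, genome: GenomeSpec | None = None) -> list[GeneModel]:
    """Read ``gene`` features from a minimal GTF (1-based inclusive → half-open)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(
                    f"line {lineno}: expected 9 GTF fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"line {lineno}: non-integer coordinates"
                ) from exc
            if end1 < start1:
                raise AnnotationParseError(
                    f"line {lineno}: end < start ({end1} < {start1})"
                )
            gene_id = _gtf_attribute(attrs, "gene_id")
            if gene_id is None:
                raise AnnotationParseError(f"line {lineno}: missing gene_id attribute")
            if gene_id in seen:
                raise AnnotationParseError(
                    f"line {lineno}: duplicate gene id {gene_id!r}"
                )
            seen.add(gene_id)
            gene = GeneModel(gene_id, chrom, start1 - 1, end1, strand)
            _validate_gene(gene, genome, lineno)
            genes.append(gene)
    if not genes:
        logger.warning("annotation file %s contained no gene records", path)
    return genes


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key):
            value = chunk[len(key):].strip()
            return value.strip('"')
    return None


def read_annotation(path: str | Path, genome: GenomeSpec | None = None) -> list[GeneModel]:
    """Read gene annotations from BED or GTF, dispatching on file extension."""
    suffix = Path(path).suffix.lower()
    if suffix in {".gtf", ".gff"}:
        return read_gtf(path, genome)
    return read_bed(path, genome)


def write_bed(path: str | Path, records: Iterable[GeneModel | Region], *,
              names: Sequence[str] | None = None) -> None:
    """Write genes or regions as BED6 (score column '.')."""
    with open(path, "w") as handle:
        for i, rec in enumerate(records):
            if isinstance(rec, GeneModel):
                name, strand = rec.gene_id, rec.strand
            else:
                name = names[i] if names is not None else f"region_{i}"
                strand = rec.strand or "."
            handle.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{name}\t.\t{strand}\n"
            )


def read_gene_set(path: str | Path) -> set[str]:
    """Read a gene set: one gene symbol per line, '#' comments allowed."""
    out: set[str] = set()
    with open(path) as handle:
        for line in handle:
            token = line.strip()
            if token and not token.startswith("#"):
                out.add(token)
    return out
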