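"""Readers and writers for the genomic file formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals.  GTF is
1-based closed on disk and is converted on the boundary in both directions;
BED and bedGraph are already 0-based half-open and pass through verbatim.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "MarkRegion",
    "SchemaError",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "read_table",
    "write_table",
    "EVENT_COUNTS_COLUMNS",
    "PHENOTYPE_COLUMNS",
    "TERM_MAP_COLUMNS",
    "check_chromosome_overlap",
]


class SchemaError(ValueError):
    """A tabular input does not carry the columns its schema requires."""


@dataclass
class TranscriptModel:
    """An exon chain: ordered, non-overlapping 0-based half-open intervals."""

    transcript_id: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon ({s},{e})"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class GeneModel:
    """Strand-aware container of the transcript isoforms of one gene."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: empty span")
        for t in self.transcripts:
            if t.start < self.start or t.end > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} "
                    "outside gene span"
                )

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand != "-" else self.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site (strand-aware)."""
        return self.end - 1 if self.strand != "-" else self.start


@dataclass
class MarkRegion:
    """A histone-mark-enriched interval with a mean occupancy score."""

    chrom: str
    start: int
    end: int
    occupancy: float = 1.0
    condition: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.chrom}:{self.start}-{self.end} empty")
        if self.occupancy < 0:
            raise ValueError("occupancy must be nonnegative")

    @property
    def width(self) -> int:
        return self.end - self.start


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path) -> list[GeneModel]:
    """Read exon features from a GTF file into :class:`GeneModel` objects.

    1-based closed GTF coordinates become 0-based half-open.  Exons are
    grouped by ``transcript_id`` within ``gene_id``; gene spans are the
    union span of their transcripts.  Strand '.' is accepted with a warning
    (downstream event typing rejects it where donor/acceptor sides matter).
    """
    exons: dict[str, dict[str, list[tuple[int, int]]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene_id -> (chrom, strand)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            attributes = _parse_gtf_attributes(attrs)
            gene_id = attributes.get("gene_id")
            transcript_id = attributes.get("transcript_id")
            if not gene_id:
                raise ValueError(f"{path}: line {lineno}: exon without gene_id")
            if not transcript_id:
                raise ValueError(
                    f"{path}: line {lineno}: exon without transcript_id"
                )
            if strand == ".":
                warnings.warn(
                    f"{path}: line {lineno}: exon with strand '.'", stacklevel=2
                )
            if gene_id not in exons:
                exons[gene_id] = {}
                meta[gene_id] = (chrom, strand)
                order.append(gene_id)
            elif meta[gene_id][0] != chrom:
                raise ValueError(
                    f"{path}: line {lineno}: gene {gene_id} spans chromosomes"
                )
            exons[gene_id].setdefault(transcript_id, []).append((start1 - 1, end1))

    genes: list[GeneModel] = []
    for gene_id in order:
        chrom, strand = meta[gene_id]
        transcripts = [
            TranscriptModel(tid, sorted(ex)) for tid, ex in exons[gene_id].items()
        ]
        start = min(t.start for t in transcripts)
        end = max(t.end for t in transcripts)
        genes.append(GeneModel(gene_id, chrom, strand, start, end, transcripts))
    return genes


def write_gtf(genes: list[GeneModel], path) -> None:
    """Write exon features; inverse of :func:`read_gtf` on its output."""
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                for s, e in t.exons:
                    fh.write(
                        f"{gene.chrom}\tthermosplice\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t"
                        f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";\n'
                    )


def read_bed(path, condition: str = "") -> list[MarkRegion]:
    """Read BED3+ intervals as :class:`MarkRegion`.

    Column 5 (the BED score) is taken as the occupancy; BED3/BED4 records
    default to occupancy 1.0.
    """
    regions: list[MarkRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else ""
            occupancy = float(fields[4]) if len(fields) > 4 else 1.0
            regions.append(MarkRegion(chrom, start, end, occupancy, condition, name))
    return regions


def write_bed(regions: list[MarkRegion], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = r.name or f"region{i + 1}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.occupancy:g}\n")


EVENT_COUNTS_COLUMNS = [
    "event_id", "sample_id", "condition", "replicate", "n_incl", "n_excl",
]
PHENOTYPE_COLUMNS = ["genotype", "condition", "replicate_tray", "plant_id", "dtb", "rln"]
TERM_MAP_COLUMNS = ["term_id", "gene_id", "description"]


def read_table(path, required_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a tab-separated table with a header, checking required columns."""
    df = pd.read_csv(path, sep="\t")
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {missing}")
    return df


def write_table(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    """Write a TSV with a deterministic column order."""
    if columns is not None:
        df = df[columns]
    df.to_csv(path, sep="\t", index=False)


def check_chromosome_overlap(genes: list[GeneModel], regions: list[MarkRegion]) -> None:
    """Warn (never raise) when gene and region chromosome sets do not meet."""
    gchroms = {g.chrom for g in genes}
    rchroms = {r.chrom for r in regions}
    if gchroms and rchroms and not (gchroms & rchroms):
        warnings.warn(
            "no shared chromosome names between gene models and mark regions: "
            f"{sorted(gchroms)[:3]} vs {sorted(rchroms)[:3]}",
            stacklevel=2,
        )
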