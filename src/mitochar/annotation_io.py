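"""Annotations of circular mitochondrial genomes.

Insect mitogenomes are closed circular molecules of ~15-16 kb carrying 13
protein-coding genes (PCGs), 22 tRNAs, two rRNAs and one non-coding,
A+T-rich control region.  This module holds the in-memory representation of
such an annotation (1-based inclusive coordinates, GenBank convention), a
TSV feature-table dialect for it, and the coordinate arithmetic everything
downstream relies on: feature lengths, intergenic spacers (negative values
denote gene overlap), strand census and strand-corrected sequence
extraction, all aware of features that wrap the circular origin.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "FeatureRecord",
    "MitoAnnotation",
    "AnnotationError",
    "FeatureTableParseError",
    "normalize_gene_name",
    "categorize_gene",
    "parse_feature_table",
    "write_feature_table",
    "feature_length",
    "intergenic_lengths",
    "strand_census",
    "extract_feature_sequence",
    "read_fasta",
    "write_fasta",
]

CATEGORIES = ("PCG", "tRNA", "rRNA", "control")

#: Aliases used interchangeably in the literature for the same features.
NAME_ALIASES = {
    "16S": "rrnL",
    "12S": "rrnS",
    "lrRNA": "rrnL",
    "srRNA": "rrnS",
    "A + T-rich": "control_region",
    "A+T-rich": "control_region",
    "AT-rich": "control_region",
    "CR": "control_region",
    "D-loop": "control_region",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AnnotationError(ValueError):
    """Invalid annotation content (duplicate names, bad coordinates...)."""


class FeatureTableParseError(AnnotationError):
    """Malformed feature-table input; message names the offending line."""


def normalize_gene_name(name: str) -> str:
    """Map published aliases (16S, 12S, "A + T-rich", ...) onto canonical
    names (rrnL, rrnS, control_region).  Unknown names pass through."""
    return NAME_ALIASES.get(name.strip(), name.strip())


def categorize_gene(name: str) -> str:
    """Infer the feature category from a canonical gene name."""
    n = normalize_gene_name(name)
    if n.startswith("trn"):
        return "tRNA"
    if n.startswith("rrn"):
        return "rRNA"
    if n == "control_region":
        return "control"
    return "PCG"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A (usually circular) genome sequence over the {A,C,G,T,N} alphabet."""

    identifier: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise AnnotationError("genome sequence must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated gene or region, 1-based inclusive coordinates.

    A feature with ``end < start`` wraps the circular origin.  The
    ``anticodon`` is stored in the DNA alphabet (T, not U) regardless of
    how the source table spelled it; ``stop_codon`` may be an incomplete
    stop ("T" or "TA") completed to TAA by transcript polyadenylation.
    """

    name: str
    category: str
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise AnnotationError(f"unknown category {self.category!r} for {self.name}")
        if self.strand not in ("F", "R"):
            raise AnnotationError(f"unknown strand {self.strand!r} for {self.name}")
        if self.start < 1 or self.end < 1:
            raise AnnotationError(f"{self.name}: coordinates must be >= 1")
        if self.anticodon is not None:
            ac = self.anticodon.upper().replace("U", "T")
            if len(ac) != 3 or any(b not in "ACGT" for b in ac):
                raise AnnotationError(f"{self.name}: bad anticodon {self.anticodon!r}")
            object.__setattr__(self, "anticodon", ac)

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start


@dataclass
class MitoAnnotation:
    """Ordered collection of features over a circular genome of known length.

    Order is by feature start along the majority strand.  A "complete"
    metazoan mitogenome annotation holds 13 PCGs + 22 tRNAs + 2 rRNAs and
    one control region; :meth:`is_complete` reports (but never enforces)
    that expectation.
    """

    genome_length: int
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise AnnotationError("genome_length must be positive")
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise AnnotationError(f"duplicate gene names: {sorted(dupes)}")
        n_control = sum(f.category == "control" for f in self.features)
        if n_control > 1:
            raise AnnotationError("more than one control region")
        for f in self.features:
            if max(f.start, f.end) > self.genome_length:
                raise AnnotationError(
                    f"{f.name}: coordinates exceed genome length {self.genome_length}"
                )

    def __iter__(self) -> Iterator[FeatureRecord]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> FeatureRecord:
        target = normalize_gene_name(name)
        for f in self.features:
            if normalize_gene_name(f.name) == target:
                return f
        raise KeyError(name)

    @property
    def control_region(self) -> Optional[FeatureRecord]:
        for f in self.features:
            if f.category == "control":
                return f
        return None

    def genes(self) -> list[FeatureRecord]:
        """Gene features only — the control region is not a gene."""
        return [f for f in self.features if f.category != "control"]

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for f in self.features:
            out[f.category] += 1
        return out

    def is_complete(self) -> bool:
        c = self.category_counts()
        return c == {"PCG": 13, "tRNA": 22, "rRNA": 2, "control": 1}

    def sorted_by_start(self) -> "MitoAnnotation":
        feats = sorted(self.features, key=lambda f: f.start)
        return MitoAnnotation(self.genome_length, feats)

    def is_sorted(self) -> bool:
        starts = [f.start for f in self.features]
        return starts == sorted(starts)


# ---------------------------------------------------------------------------
# Feature-table TSV dialect
# ---------------------------------------------------------------------------

_HEADER = ["Gene", "Category", "Strand", "Start", "End", "Anticodon", "StartCodon", "StopCodon"]


def _parse_location(text: str, lineno: int) -> tuple[int, int]:
    # accept en-dash and hyphen range delimiters, strip thousands separators
    cleaned = text.replace(",", "").replace("–", "-")
    parts = cleaned.split("-")
    if len(parts) != 2:
        raise FeatureTableParseError(f"line {lineno}: malformed Location {text!r}")
    try:
        return int(parts[0]), int(parts[1])
    except ValueError:
        raise FeatureTableParseError(f"line {lineno}: malformed coordinate in {text!r}") from None


def _parse_int(text: str, column: str, lineno: int) -> int:
    try:
        return int(text.replace(",", ""))
    except ValueError:
        raise FeatureTableParseError(
            f"line {lineno}: malformed {column} value {text!r}"
        ) from None


def parse_feature_table(
    stream: TextIO | Iterable[str], genome_length: Optional[int] = None
) -> MitoAnnotation:
    """Parse a feature table into a :class:`MitoAnnotation`.

    Two header dialects are accepted: the native one with separate
    ``Start``/``End`` columns, and a published-table style with a single
    ``Location`` column formatted ``start–end`` (en-dash or hyphen,
    thousands separators tolerated).  A declared ``Size`` column, when
    present, is cross-checked against the computed length; mismatches are
    reported as warnings, never silently accepted.  An empty strand cell is
    allowed for the control region only (stored as F).

    When *genome_length* is not given it is inferred as the maximum end
    coordinate in the table.
    """
    if hasattr(stream, "read"):
        lines = stream.read().splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FeatureTableParseError("empty input: header line required")

    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter="\t")
    rows = list(reader)
    header = [h.strip() for h in rows[0]]
    col = {name: i for i, name in enumerate(header)}
    if "Gene" not in col:
        raise FeatureTableParseError("line 1: header must contain a Gene column")
    has_location = "Location" in col
    if not has_location and not ("Start" in col and "End" in col):
        raise FeatureTableParseError(
            "line 1: header must contain either Location or Start+End columns"
        )

    def cell(row: list[str], name: str) -> str:
        i = col.get(name)
        if i is None or i >= len(row):
            return ""
        v = row[i].strip()
        return "" if v in ("-", "–", "") else v

    features: list[FeatureRecord] = []
    for lineno, row in enumerate(rows[1:], start=2):
        name = cell(row, "Gene")
        if not name:
            raise FeatureTableParseError(f"line {lineno}: missing gene name")
        name = normalize_gene_name(name)
        category = cell(row, "Category") or categorize_gene(name)
        strand = cell(row, "Strand")
        if not strand and category == "control":
            strand = "F"  # the control region is non-coding; strand is nominal
        if strand not in ("F", "R"):
            raise FeatureTableParseError(
                f"line {lineno}: unknown strand symbol {strand!r} (expected F or R)"
            )
        if has_location and cell(row, "Location"):
            start, end = _parse_location(cell(row, "Location"), lineno)
        else:
            start = _parse_int(cell(row, "Start"), "Start", lineno)
            end = _parse_int(cell(row, "End"), "End", lineno)
        feat = FeatureRecord(
            name=name,
            category=category,
            strand=strand,
            start=start,
            end=end,
            anticodon=cell(row, "Anticodon") or None,
            start_codon=cell(row, "StartCodon") or None,
            stop_codon=cell(row, "StopCodon") or None,
        )
        features.append(feat)
        declared_size = cell(row, "Size") or cell(row, "Size (bp)")
        if declared_size:
            declared = _parse_int(declared_size, "Size", lineno)
            length = (
                end - start + 1
                if end >= start
                else None  # wrapping length needs genome_length; checked below
            )
            if length is not None and declared != length:
                warnings.warn(
                    f"line {lineno}: declared size {declared} != computed {length} "
                    f"for {name}",
                    stacklevel=2,
                )

    if genome_length is None:
        genome_length = max(max(f.start, f.end) for f in features)
    return MitoAnnotation(genome_length=genome_length, features=features)


def write_feature_table(annotation: MitoAnnotation, stream: Optional[TextIO] = None) -> str:
    """Serialize an annotation to the native TSV dialect.

    Deterministic column order; coordinates written as plain integers (no
    thousands separators).  Round-trips through :func:`parse_feature_table`.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(_HEADER)
    for f in annotation.features:
        writer.writerow(
            [
                f.name,
                f.category,
                f.strand,
                f.start,
                f.end,
                f.anticodon or "",
                f.start_codon or "",
                f.stop_codon or "",
            ]
        )
    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Coordinate arithmetic
# ---------------------------------------------------------------------------


def feature_length(f: FeatureRecord, genome_length: int) -> int:
    """Length in bp of a feature; origin-wrapping features span
    ``genome_length - start + 1 + end``."""
    if max(f.start, f.end) > genome_length:
        raise AnnotationError(f"{f.name}: coordinates exceed genome length {genome_length}")
    if f.wraps_origin:
        return genome_length - f.start + 1 + f.end
    return f.end - f.start + 1


def intergenic_lengths(annotation: MitoAnnotation) -> list[tuple[str, int]]:
    """Spacer following each feature: ``start(next) - end(this) - 1``.

    Negative values denote overlap with the next feature.  The last feature
    pairs with the first across the circular origin, so the spacers close
    the circle: sum(lengths) + sum(spacers) == genome_length for any
    annotation whose features tile the circle (overlaps enter as negative
    spacers).
    """
    if len(annotation) < 2:
        raise AnnotationError("need at least two features for intergenic lengths")
    if not annotation.is_sorted():
        raise AnnotationError("annotation not ordered by start; sort by start first")
    feats = annotation.features
    out: list[tuple[str, int]] = []
    for i, f in enumerate(feats[:-1]):
        out.append((f.name, feats[i + 1].start - f.end - 1))
    last, first = feats[-1], feats[0]
    out.append((last.name, first.start + annotation.genome_length - last.end - 1))
    return out


def strand_census(annotation: MitoAnnotation) -> tuple[int, int]:
    """(majority-strand, minority-strand) gene counts; control region excluded."""
    genes = annotation.genes()
    n_f = sum(f.strand == "F" for f in genes)
    return n_f, len(genes) - n_f


def extract_feature_sequence(genome: GenomeRecord, f: FeatureRecord) -> str:
    """Strand-corrected feature sequence: R-strand features are returned as
    the reverse complement of the genomic slice."""
    if max(f.start, f.end) > genome.length:
        raise AnnotationError(f"{f.name}: coordinates exceed genome length {genome.length}")
    if f.wraps_origin:
        if not genome.circular:
            raise AnnotationError(f"{f.name}: wraps origin of a non-circular genome")
        sub = genome.sequence[f.start - 1 :] + genome.sequence[: f.end]
    else:
        sub = genome.sequence[f.start - 1 : f.end]
    return reverse_complement(sub) if f.strand == "R" else sub


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_fasta(path_or_handle, circular: bool = True) -> GenomeRecord:
    """Read a single-record FASTA into a :class:`GenomeRecord`."""
    records = list(SeqIO.parse(path_or_handle, "fasta"))
    if len(records) != 1:
        raise AnnotationError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return GenomeRecord(identifier=rec.id, sequence=str(rec.seq).upper(), circular=circular)


def write_fasta(genome: GenomeRecord, handle) -> None:
    """Write a genome as FASTA, wrapped at 70 columns."""
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        writer = FastaWriter(handle, wrap=70)
        writer.write_file([SeqRecord(Seq(genome.sequence), id=genome.identifier, description="")])
    finally:
        if close:
            handle.close()
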