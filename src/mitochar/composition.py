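"""Nucleotide composition and strand-skew statistics.

Strand compositional asymmetry of a mitogenome is summarized by
AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C), computed over the
majority strand.  Both are dimensionless in [-1, 1] and scale-invariant, so
they can equally be computed from base counts or from base percentages.
Region-class tables (full genome, PCGs, tRNAs, rRNAs, control region)
concatenate the strand-corrected sequences of member features; bases shared
by overlapping features are counted once per feature, so a region size is
the plain sum of its feature lengths.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .annotation_io import (
    GenomeRecord,
    MitoAnnotation,
    extract_feature_sequence,
)

__all__ = [
    "BaseCounts",
    "RegionComposition",
    "SkewUndefinedError",
    "count_bases",
    "at_skew",
    "gc_skew",
    "at_content",
    "gc_content",
    "region_sequences",
    "composition_table",
    "composition_table_tsv",
    "composition_table_json",
    "round_half_up",
]

REGION_ORDER = ("full_genome", "PCGs", "tRNAs", "rRNAs", "control_region")

_CATEGORY_TO_REGION = {"PCG": "PCGs", "tRNA": "tRNAs", "rRNA": "rRNAs", "control": "control_region"}


class SkewUndefinedError(ZeroDivisionError):
    """Skew requested for a sequence with a zero denominator (A+T or G+C)."""


def round_half_up(value: float, ndigits: int) -> float:
    """Round-half-up at *ndigits* decimals (the convention of printed
    tables; Python's built-in round is half-to-even)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BaseCounts:
    """Counts of the four bases; anything else (N, gaps...) lands in other."""

    A: float = 0
    C: float = 0
    G: float = 0
    T: float = 0
    other: float = 0

    @property
    def total(self) -> float:
        return self.A + self.C + self.G + self.T + self.other


def count_bases(seq: str) -> BaseCounts:
    """Case-insensitive base tally of a DNA string."""
    s = seq.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    return BaseCounts(A=a, C=c, G=g, T=t, other=len(s) - a - c - g - t)


def at_skew(counts: BaseCounts) -> float:
    """(A - T)/(A + T); raises :class:`SkewUndefinedError` when A+T == 0."""
    denom = counts.A + counts.T
    if denom == 0:
        raise SkewUndefinedError("AT-skew undefined: A + T == 0")
    return (counts.A - counts.T) / denom


def gc_skew(counts: BaseCounts) -> float:
    """(G - C)/(G + C); raises :class:`SkewUndefinedError` when G+C == 0."""
    denom = counts.G + counts.C
    if denom == 0:
        raise SkewUndefinedError("GC-skew undefined: G + C == 0")
    return (counts.G - counts.C) / denom


def at_content(counts: BaseCounts) -> float:
    """A+T as a percentage of all counted bases."""
    if counts.total == 0:
        raise ValueError("AT content undefined for empty input")
    return 100.0 * (counts.A + counts.T) / counts.total


def gc_content(counts: BaseCounts) -> float:
    if counts.total == 0:
        raise ValueError("GC content undefined for empty input")
    return 100.0 * (counts.G + counts.C) / counts.total


@dataclass(frozen=True)
class RegionComposition:
    """One row of a per-region composition table.

    Skews are ``None`` when their denominator vanishes (flagged undefined
    rather than raising, so one degenerate region cannot abort a report).
    Raw doubles are stored; rounding happens only at presentation time.
    """

    region: str
    size: int
    percent_A: float
    percent_C: float
    percent_G: float
    percent_T: float
    at_percent: float
    gc_percent: float
    at_skew: Optional[float]
    gc_skew: Optional[float]


def region_sequences(genome: GenomeRecord, annotation: MitoAnnotation) -> dict[str, str]:
    """Concatenated strand-corrected sequence per region class, in fixed
    table order; ``full_genome`` maps to the genome itself.  A region class
    with no member features is omitted with a warning."""
    parts: dict[str, list[str]] = {r: [] for r in REGION_ORDER[1:]}
    for f in annotation.features:
        parts[_CATEGORY_TO_REGION[f.category]].append(extract_feature_sequence(genome, f))
    out: dict[str, str] = {"full_genome": genome.sequence}
    for region in REGION_ORDER[1:]:
        if parts[region]:
            out[region] = "".join(parts[region])
        else:
            warnings.warn(f"no features of region class {region}; omitted", stacklevel=2)
    return out


def _row(region: str, seq: str) -> RegionComposition:
    c = count_bases(seq)
    try:
        ats: Optional[float] = at_skew(c)
    except SkewUndefinedError:
        ats = None
    try:
        gcs: Optional[float] = gc_skew(c)
    except SkewUndefinedError:
        gcs = None
    return RegionComposition(
        region=region,
        size=len(seq),
        percent_A=100.0 * c.A / c.total,
        percent_C=100.0 * c.C / c.total,
        percent_G=100.0 * c.G / c.total,
        percent_T=100.0 * c.T / c.total,
        at_percent=100.0 * (c.A + c.T) / c.total,
        gc_percent=100.0 * (c.G + c.C) / c.total,
        at_skew=ats,
        gc_skew=gcs,
    )


def composition_table(genome: GenomeRecord, annotation: MitoAnnotation) -> list[RegionComposition]:
    """Composition and skew per region class, one row per region present."""
    return [_row(region, seq) for region, seq in region_sequences(genome, annotation).items()]


def _fmt(value: Optional[float], ndigits: int) -> str:
    if value is None:
        return "undefined"
    return f"{round_half_up(value, ndigits):.{ndigits}f}"


def composition_table_tsv(rows: list[RegionComposition]) -> str:
    """TSV rendering mirroring the conventional column order (Regions,
    Size, T, C, A, G, AT%, GC%, AT skewness, GC skewness); percentages at
    1 dp, skews at 3 dp, round-half-up."""
    lines = ["Regions\tSize (bp)\tT\tC\tA\tG\tAT (%)\tGC (%)\tAT Skewness\tGC Skewness"]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.region,
                    str(r.size),
                    _fmt(r.percent_T, 1),
                    _fmt(r.percent_C, 1),
                    _fmt(r.percent_A, 1),
                    _fmt(r.percent_G, 1),
                    _fmt(r.at_percent, 1),
                    _fmt(r.gc_percent, 1),
                    _fmt(r.at_skew, 3),
                    _fmt(r.gc_skew, 3),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def composition_table_json(rows: list[RegionComposition]) -> str:
    """Full-precision JSON rendering (undefined skews as null)."""
    return json.dumps([r.__dict__ for r in rows], indent=2) + "\n"
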