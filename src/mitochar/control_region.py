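"""Structural element scanning for mitochondrial control regions.

The A+T-rich control region of an insect mitogenome carries the initiation
sites for replication and transcription.  Its recurring landmarks are a
short conserved motif (ATAGG-like, often marking the origin of
minority-strand replication) followed by a poly-T stretch, microsatellite
(AT)n arrays, a poly-A stretch in front of the downstream tRNA, and —
in many species, though not all — longer tandem repeats.  The scanners
here are exact (no mismatches): motif search with N wildcards, maximal
homopolymer runs, maximal perfect microsatellite arrays, and maximal
tandem arrays reported once at their smallest period.

Coordinates are 1-based inclusive within the scanned sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

from .annotation_io import GenomeRecord, MitoAnnotation, extract_feature_sequence

__all__ = [
    "SequenceHit",
    "CRScanConfig",
    "find_motif",
    "find_homopolymer_runs",
    "find_microsatellites",
    "find_tandem_repeats",
    "control_region_report",
    "hits_tsv",
    "hits_json",
]

HIT_KINDS = ("motif", "homopolymer", "microsatellite", "tandem_repeat")


@dataclass(frozen=True)
class SequenceHit:
    """One located element; for exact repeats end-start+1 == |unit|*copies
    (a trailing partial unit extends *end* but not *copies*)."""

    kind: str
    start: int  # 1-based inclusive
    end: int
    unit: str
    copies: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in HIT_KINDS:
            raise ValueError(f"unknown hit kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad hit span {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def verify(self, seq: str) -> bool:
        """Re-extract this hit from *seq* and check it literally matches its
        unit/copies description (self-consistency of scanner output)."""
        span = seq[self.start - 1 : self.end].upper()
        unit = self.unit.upper()
        if self.kind == "motif":
            return len(span) == len(unit) and all(
                u == "N" or u == s for u, s in zip(unit, span)
            )
        full = int(self.copies)
        expected = unit * full + unit[: self.length - full * len(unit)]
        return span == expected


def _check_dna(seq: str) -> str:
    return seq.upper()


def find_motif(seq: str, motif: str) -> list[SequenceHit]:
    """All (possibly overlapping) occurrences of *motif* (N = wildcard),
    scanning the given strand 5'->3' only."""
    if not motif:
        raise ValueError("motif must be non-empty")
    s = _check_dna(seq)
    m = motif.upper()
    hits = []
    for i in range(len(s) - len(m) + 1):
        if all(mb == "N" or mb == s[i + j] for j, mb in enumerate(m)):
            hits.append(SequenceHit("motif", i + 1, i + len(m), m, 1.0))
    return hits


def find_homopolymer_runs(seq: str, base: str, min_len: int) -> list[SequenceHit]:
    """Maximal runs of *base* with length >= min_len."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    b = base.upper()
    if len(b) != 1:
        raise ValueError("base must be a single nucleotide")
    s = _check_dna(seq)
    hits = []
    i = 0
    n = len(s)
    while i < n:
        if s[i] == b:
            j = i
            while j < n and s[j] == b:
                j += 1
            if j - i >= min_len:
                hits.append(SequenceHit("homopolymer", i + 1, j, b, float(j - i)))
            i = j
        else:
            i += 1
    return hits


def find_microsatellites(seq: str, unit: str, min_copies: int) -> list[SequenceHit]:
    """Maximal perfect tandem arrays of *unit* with >= min_copies copies.

    The array starts at a full unit and cannot be extended left by a whole
    unit; a trailing partial unit is included in *end* but *copies* reports
    the whole-unit count.
    """
    u = unit.upper()
    if not 1 <= len(u) <= 6:
        raise ValueError("microsatellite unit length must be 1-6")
    if min_copies < 3:
        raise ValueError("min_copies must be >= 3")
    s = _check_dna(seq)
    n, ul = len(s), len(u)
    hits = []
    i = 0
    while i + ul <= n:
        if s[i : i + ul] != u:
            i += 1
            continue
        k = 1
        while s[i + k * ul : i + (k + 1) * ul] == u:
            k += 1
        if k >= min_copies:
            end = i + k * ul
            # trailing partial unit
            while end < n and s[end] == u[(end - i) % ul]:
                end += 1
            hits.append(SequenceHit("microsatellite", i + 1, end, u, float(k)))
        i += k * ul
    return hits


def _smallest_period(s: str) -> int:
    # KMP failure function; smallest period = len - fail[-1]
    fail = [0] * len(s)
    k = 0
    for i in range(1, len(s)):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return len(s) - fail[-1] if s else 0


def find_tandem_repeats(
    seq: str, min_unit: int, min_copies: int, max_unit: Optional[int] = None
) -> list[SequenceHit]:
    """Maximal perfect tandem arrays with unit length >= min_unit, reported
    once at their smallest period.

    An array whose smallest period falls below *min_unit* (homopolymers,
    dinucleotide microsatellites...) is not reported at all; that keeps the
    three scanner families disjoint.  Partial trailing/leading periodicity
    extends the reported span; *copies* is span length // period.
    """
    if min_unit < 2:
        raise ValueError("min_unit must be >= 2")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    s = _check_dna(seq)
    n = len(s)
    cap = max_unit if max_unit is not None else n // min_copies
    hits = []
    for p in range(min_unit, cap + 1):
        i = 0
        limit = n - p
        while i < limit:
            if s[i] != s[i + p]:
                i += 1
                continue
            j = i
            while j < limit and s[j] == s[j + p]:
                j += 1
            # periodic run covers [i, j+p-1]
            run = s[i : j + p]
            if len(run) // p >= min_copies and _smallest_period(run) == p:
                hits.append(
                    SequenceHit("tandem_repeat", i + 1, j + p, run[:p], float(len(run) // p))
                )
            i = j + 1
    hits.sort(key=lambda h: (h.start, len(h.unit)))
    return hits


@dataclass(frozen=True)
class CRScanConfig:
    """Thresholds for the control-region report.

    Defaults target the landmark set typical of lepidopteran control
    regions: the exact ATAGG motif (with an optional trailing A reported
    when present), poly-T/poly-A stretches, (AT)n microsatellites, and
    tandem repeats of unit >= 5 — dinucleotide arrays are classified as
    microsatellites, not tandem repeats.
    """

    motif: str = "ATAGG"
    motif_optional_a: bool = True
    polyt_min_len: int = 10
    polya_min_len: int = 8
    microsat_unit: str = "AT"
    microsat_min_copies: int = 5
    tandem_min_unit: int = 5
    tandem_min_copies: int = 2
    scan_reverse: bool = False


def _scan_one_strand(seq: str, config: CRScanConfig) -> list[SequenceHit]:
    hits: list[SequenceHit] = []
    for h in find_motif(seq, config.motif):
        if config.motif_optional_a and h.end < len(seq) and seq[h.end].upper() == "A":
            h = SequenceHit("motif", h.start, h.end + 1, h.unit + "A", 1.0)
        hits.append(h)
    hits += find_homopolymer_runs(seq, "T", config.polyt_min_len)
    hits += find_homopolymer_runs(seq, "A", config.polya_min_len)
    hits += find_microsatellites(seq, config.microsat_unit, config.microsat_min_copies)
    hits += find_tandem_repeats(seq, config.tandem_min_unit, config.tandem_min_copies)
    return hits


def control_region_report(
    genome: GenomeRecord,
    annotation: MitoAnnotation,
    config: CRScanConfig = CRScanConfig(),
) -> list[SequenceHit]:
    """Run all scanners over the annotated control region.

    Coordinates in the returned hits are 1-based within the control region
    as annotated (its own strand); only that strand is scanned unless
    ``config.scan_reverse`` is set, in which case reverse-strand hits are
    mapped back to forward coordinates.
    """
    cr = annotation.control_region
    if cr is None:
        raise ValueError("annotation has no control region")
    seq = extract_feature_sequence(genome, cr)
    if not seq:
        raise ValueError("control region is empty")
    hits = _scan_one_strand(seq, config)
    if config.scan_reverse:
        from .annotation_io import reverse_complement

        n = len(seq)
        for h in _scan_one_strand(reverse_complement(seq), config):
            hits.append(replace(h, start=n - h.end + 1, end=n - h.start + 1))
    hits.sort(key=lambda h: (h.start, h.end, h.kind))
    for h in hits:
        if not config.scan_reverse and not h.verify(seq):  # pragma: no cover
            raise AssertionError(f"inconsistent hit {h}")
    return hits


def hits_tsv(hits: list[SequenceHit]) -> str:
    """BED-like TSV, 1-based inclusive coordinates."""
    lines = ["kind\tstart\tend\tunit\tcopies"]
    for h in hits:
        lines.append(f"{h.kind}\t{h.start}\t{h.end}\t{h.unit}\t{h.copies:g}")
    return "\n".join(lines) + "\n"


def hits_json(hits: list[SequenceHit]) -> str:
    return json.dumps([h.__dict__ for h in hits], indent=2) + "\n"
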