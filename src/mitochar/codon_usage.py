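"""Codon usage under the invertebrate mitochondrial genetic code.

Mitochondrial protein-coding genes are read in-frame from their annotated
start; insect mitogenomes routinely truncate the final stop to "T" or "TA"
at a tRNA junction (completed to TAA by polyadenylation of the transcript),
so a gene's annotated length need not be a multiple of three.  This module
decomposes coding sequences into codons, classifies start and stop codons,
tallies codon counts, and computes relative synonymous codon usage

    RSCU(c) = n_c / mean(n over the synonymous family of c),

so RSCU == 1 means a codon is used exactly as often as expected were all
synonymous codons used equally.  The genetic code (NCBI translation table
5 by default: ATA=Met, TGA=Trp, AGA/AGG=Ser, stops TAA/TAG) is injected,
not hardcoded, so the module applies to any mitogenome.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from .composition import round_half_up

__all__ = [
    "GeneticCode",
    "INVERTEBRATE_MITO",
    "StopStatus",
    "GeneCodonDecomposition",
    "CodonCountTable",
    "RSCUTable",
    "decompose_gene",
    "classify_start",
    "count_codons",
    "terminal_stop_counts",
    "compute_rscu",
    "amino_acid_totals",
    "total_sense_codons",
    "rscu_table_tsv",
    "rscu_table_json",
]

ALL_CODONS = tuple("".join(p) for p in itertools.product("TCAG", repeat=3))


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map plus its synonymous-family partition.

    Families group sense codons by encoded amino acid; the stop codons form
    their own family so stop usage can be expressed on the RSCU scale too.
    """

    table_id: int
    codon_map: Mapping[str, str]  # sense codon -> one-letter amino acid
    stop_codons: frozenset[str]

    @classmethod
    def from_ncbi_table(cls, table_id: int) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            table_id=table_id,
            codon_map=dict(t.forward_table),
            stop_codons=frozenset(t.stop_codons),
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c in self.codon_map)

    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families keyed by one-letter amino acid ('*' = stops)."""
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = "*" if codon in self.stop_codons else self.codon_map[codon]
            fams.setdefault(aa, []).append(codon)
        return {aa: tuple(members) for aa, members in fams.items()}


INVERTEBRATE_MITO = GeneticCode.from_ncbi_table(5)


class StopStatus(str, Enum):
    COMPLETE_TAA = "complete(TAA)"
    COMPLETE_TAG = "complete(TAG)"
    INCOMPLETE_T = "incomplete(T)"
    INCOMPLETE_TA = "incomplete(TA)"
    NON_CANONICAL = "non_canonical"


@dataclass(frozen=True)
class GeneCodonDecomposition:
    """In-frame codon reading of one coding sequence.

    Invariant: ``3 * len(codons) + len(trailing_bases) == input length``.
    """

    gene: str
    codons: tuple[str, ...]
    start_codon: str
    stop_status: StopStatus
    trailing_bases: str

    @property
    def length(self) -> int:
        return 3 * len(self.codons) + len(self.trailing_bases)

    @property
    def has_terminal_stop(self) -> bool:
        return self.stop_status in (StopStatus.COMPLETE_TAA, StopStatus.COMPLETE_TAG)


def decompose_gene(
    seq: str, gene: str = "", code: GeneticCode = INVERTEBRATE_MITO
) -> GeneCodonDecomposition:
    """Read codons in frame from position 1 of a strand-corrected coding
    sequence; the length-mod-3 remainder becomes ``trailing_bases``.

    Stop classification: a remainder of "T" or "TA" is an incomplete stop;
    remainder 0 with a terminal TAA/TAG is a complete stop; anything else
    (remainder 0 without a stop, or a remainder not starting with T) is
    flagged non_canonical rather than guessed at.
    """
    s = seq.upper()
    if len(s) < 3:
        raise ValueError(f"{gene or 'sequence'}: too short to contain a codon ({len(s)} bp)")
    n_full = len(s) // 3
    codons = tuple(s[3 * i : 3 * i + 3] for i in range(n_full))
    trailing = s[3 * n_full :]
    if trailing == "T":
        status = StopStatus.INCOMPLETE_T
    elif trailing == "TA":
        status = StopStatus.INCOMPLETE_TA
    elif trailing == "":
        if codons[-1] == "TAA":
            status = StopStatus.COMPLETE_TAA
        elif codons[-1] == "TAG":
            status = StopStatus.COMPLETE_TAG
        else:
            status = StopStatus.NON_CANONICAL
    else:
        status = StopStatus.NON_CANONICAL
    return GeneCodonDecomposition(
        gene=gene, codons=codons, start_codon=codons[0], stop_status=status, trailing_bases=trailing
    )


def classify_start(codon: str) -> str:
    """Classify a start codon as "ATN" (canonical mitochondrial ATN start),
    "CGA" (the cox1-specific start conserved across insects), or "other"."""
    c = codon.upper()
    if len(c) != 3 or any(b not in "ACGT" for b in c):
        raise ValueError(f"not a DNA triplet: {codon!r}")
    if c.startswith("AT"):
        return "ATN"
    if c == "CGA":
        return "CGA"
    return "other"


@dataclass(frozen=True)
class CodonCountTable:
    """Counts over all 64 codons (DNA alphabet)."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        filled = {c: 0 for c in ALL_CODONS}
        for codon, n in dict(self.counts).items():
            key = codon.upper().replace("U", "T")
            if key not in filled:
                raise ValueError(f"not a codon: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            filled[key] += n
        object.__setattr__(self, "counts", filled)

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon.upper().replace("U", "T")]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable({c: self.counts[c] + other.counts[c] for c in ALL_CODONS})


def count_codons(
    decompositions: Iterable[GeneCodonDecomposition], include_stops: bool = False
) -> CodonCountTable:
    """Tally all full codons over a set of genes.

    With ``include_stops=False`` the terminal codon of each gene is excluded
    when it is a complete TAA/TAG stop; internal in-frame TAA/TAG (read-
    through positions present in some published tallies) are still counted.
    """
    tally: Counter[str] = Counter()
    for d in decompositions:
        codons = d.codons
        if not include_stops and d.has_terminal_stop:
            codons = codons[:-1]
        tally.update(codons)
    return CodonCountTable(tally)


def terminal_stop_counts(decompositions: Iterable[GeneCodonDecomposition]) -> dict[str, int]:
    """How many genes end in each complete stop codon (the companion tally
    to ``count_codons(include_stops=False)``)."""
    out: Counter[str] = Counter()
    for d in decompositions:
        if d.has_terminal_stop:
            out[d.codons[-1]] += 1
    return dict(out)


@dataclass(frozen=True)
class RSCUTable:
    """Per-codon RSCU with its synonymous-family bookkeeping.

    Within every family with a nonzero total the mean RSCU is exactly 1.
    Codons of a family never observed at all get RSCU 0 and the family is
    listed in ``unused_families``.
    """

    rscu: Mapping[str, float]
    families: Mapping[str, tuple[str, ...]]
    unused_families: frozenset[str] = field(default_factory=frozenset)

    def __getitem__(self, codon: str) -> float:
        return self.rscu[codon.upper().replace("U", "T")]

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {c: round_half_up(v, ndigits) for c, v in self.rscu.items()}


def compute_rscu(counts: CodonCountTable, code: GeneticCode = INVERTEBRATE_MITO) -> RSCUTable:
    """RSCU(c) = n_c / (family total / family size), per synonymous family."""
    families = code.families()
    rscu: dict[str, float] = {}
    unused: set[str] = set()
    for aa, members in families.items():
        total = sum(counts[c] for c in members)
        if total == 0:
            unused.add(aa)
            for c in members:
                rscu[c] = 0.0
        else:
            mean = total / len(members)
            for c in members:
                rscu[c] = counts[c] / mean
    return RSCUTable(rscu=rscu, families=families, unused_families=frozenset(unused))


def _aa_class(codon: str, code: GeneticCode) -> Optional[str]:
    """Amino-acid class label, with Leu split into UUR/CUN and Ser into
    UCN/AGN (the conventional mitochondrial two-tRNA split)."""
    if codon in code.stop_codons:
        return None
    aa = code.codon_map[codon]
    if aa == "L":
        return "Leu(UUR)" if codon.startswith("TT") else "Leu(CUN)"
    if aa == "S":
        return "Ser(AGN)" if codon.startswith("AG") else "Ser(UCN)"
    return seq3(aa)


def amino_acid_totals(
    counts: CodonCountTable, code: GeneticCode = INVERTEBRATE_MITO
) -> dict[str, int]:
    """Codon counts aggregated per amino-acid class (stops excluded)."""
    out: dict[str, int] = {}
    for codon in ALL_CODONS:
        cls = _aa_class(codon, code)
        if cls is not None:
            out[cls] = out.get(cls, 0) + counts[codon]
    return out


def total_sense_codons(counts: CodonCountTable, code: GeneticCode = INVERTEBRATE_MITO) -> int:
    """Sum of counts over the sense codons (stops excluded)."""
    return sum(counts[c] for c in code.sense_codons)


def _display_codon(codon: str) -> str:
    return codon.replace("T", "U")


def rscu_table_tsv(
    counts: CodonCountTable,
    rscu: RSCUTable,
    code: GeneticCode = INVERTEBRATE_MITO,
    include_stops: bool = False,
) -> str:
    """TSV of codon, amino acid, count and RSCU (RNA spelling, 2 dp)."""
    lines = ["Codon\tAA\tCount\tRSCU"]
    for codon in ALL_CODONS:
        is_stop = codon in code.stop_codons
        if is_stop and not include_stops:
            continue
        aa = "*" if is_stop else code.codon_map[codon]
        lines.append(
            f"{_display_codon(codon)}\t{aa}\t{counts[codon]}\t{round_half_up(rscu[codon], 2):.2f}"
        )
    return "\n".join(lines) + "\n"


def rscu_table_json(counts: CodonCountTable, rscu: RSCUTable) -> str:
    return json.dumps(
        {c: {"count": counts[c], "rscu": rscu[c]} for c in ALL_CODONS}, indent=2
    ) + "\n"
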