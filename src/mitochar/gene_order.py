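"""Signed gene orders of circular mitogenomes and rearrangement detection.

Mitochondrial gene order is strongly conserved in insects, which makes the
few rearrangements that do occur phylogenetically informative.  In
Lepidoptera (Ditrysia) the textbook example is the translocation of trnM:
the ancestral insect arrangement trnI-trnQ-trnM-nad2 becomes
trnM-trnI-trnQ-nad2.  A circular gene order is compared to a reference by
linearizing both at a shared anchor gene and taking the complement of a
longest common subsequence (LCS): the genes outside the LCS form a minimum
set whose removal makes the two orders agree — i.e. a minimal set of moved
genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .annotation_io import MitoAnnotation, normalize_gene_name

__all__ = [
    "GeneOrder",
    "GeneOrderDiff",
    "GeneOrderError",
    "extract_gene_order",
    "compare_orders",
    "ancestral_insect_order",
]


class GeneOrderError(ValueError):
    pass


#: Single-letter tRNA labels used in compact gene-order strings
#: (S1 = AGN, S2 = UCN, L1 = CUN, L2 = UUR serine/leucine isoacceptors).
_TRNA_SHORT = {
    "trnA": "A", "trnR": "R", "trnN": "N", "trnD": "D", "trnC": "C",
    "trnQ": "Q", "trnE": "E", "trnG": "G", "trnH": "H", "trnI": "I",
    "trnL1": "L1", "trnL2": "L2", "trnK": "K", "trnM": "M", "trnF": "F",
    "trnP": "P", "trnS1": "S1", "trnS2": "S2", "trnT": "T", "trnW": "W",
    "trnY": "Y", "trnV": "V",
}


@dataclass(frozen=True)
class GeneOrder:
    """Ordered (gene name, strand sign) pairs around the circle; entry 0 is
    the linearization origin."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = self.names()
        if len(set(names)) != len(names):
            raise GeneOrderError("gene names not unique in order")
        for _, sign in self.entries:
            if sign not in (1, -1):
                raise GeneOrderError("strand sign must be +1 or -1")

    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)

    @property
    def linearization_origin(self) -> str:
        return self.entries[0][0]

    def rotate_to(self, anchor: str) -> "GeneOrder":
        """Rotate the circular order so *anchor* comes first."""
        target = normalize_gene_name(anchor)
        names = self.names()
        if target not in names:
            raise GeneOrderError(f"anchor gene {anchor!r} not in order")
        i = names.index(target)
        return GeneOrder(self.entries[i:] + self.entries[:i])

    def to_string(self) -> str:
        """One-line signed order; tRNAs abbreviated to single letters and a
        leading '-' marking minority-strand genes."""
        parts = []
        for name, sign in self.entries:
            label = _TRNA_SHORT.get(name, name)
            parts.append(("-" if sign < 0 else "") + label)
        return " ".join(parts)

    def to_json(self) -> str:
        return json.dumps(
            {"origin": self.linearization_origin,
             "entries": [{"gene": n, "strand": "+" if s > 0 else "-"} for n, s in self.entries]},
            indent=2,
        )


@dataclass(frozen=True)
class GeneOrderDiff:
    """Outcome of an order comparison: the (minimal) moved-gene set."""

    moved_genes: frozenset[str]

    @property
    def identical(self) -> bool:
        return not self.moved_genes


def extract_gene_order(annotation: MitoAnnotation) -> GeneOrder:
    """Gene order by start coordinate on the majority strand; the control
    region is excluded and names are alias-normalized."""
    genes = sorted(annotation.genes(), key=lambda f: f.start)
    starts = [f.start for f in genes]
    if len(set(starts)) != len(starts):
        raise GeneOrderError("tied start coordinates: cannot order genes")
    return GeneOrder(
        tuple(
            (normalize_gene_name(f.name), 1 if f.strand == "F" else -1) for f in genes
        )
    )


def _lcs(a: tuple, b: tuple) -> tuple:
    """Longest common subsequence via standard dynamic programming."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = dp[i], dp[i + 1]
        for j in range(m - 1, -1, -1):
            row[j] = nxt[j + 1] + 1 if a[i] == b[j] else max(nxt[j], row[j + 1])
    out = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            out.append(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return tuple(out)


def compare_orders(
    observed: GeneOrder,
    reference: GeneOrder,
    anchor: str = "cox1",
    strict_strand: bool = False,
) -> GeneOrderDiff:
    """Minimal moved-gene set between two circular orders over the same
    gene set.

    Both orders are linearized at *anchor* and compared by LCS on gene
    names; with ``strict_strand=True`` a gene must also keep its strand to
    count as unmoved, so inversions are flagged as well as translocations.
    """
    obs_set, ref_set = set(observed.names()), set(reference.names())
    if obs_set != ref_set:
        diff = sorted(obs_set.symmetric_difference(ref_set))
        raise GeneOrderError(f"gene sets differ; symmetric difference: {diff}")
    a = observed.rotate_to(anchor)
    b = reference.rotate_to(anchor)
    if strict_strand:
        seq_a: tuple = a.entries
        seq_b: tuple = b.entries
        common = _lcs(seq_a, seq_b)
        kept = {name for name, _ in common}
    else:
        common = _lcs(a.names(), b.names())
        kept = set(common)
    return GeneOrderDiff(moved_genes=frozenset(obs_set - kept))


#: Putative ancestral insect (Drosophila-like) arrangement, linearized at
#: trnI as customary; strands relative to the majority strand.
_ANCESTRAL = (
    ("trnI", 1), ("trnQ", -1), ("trnM", 1), ("nad2", 1), ("trnW", 1),
    ("trnC", -1), ("trnY", -1), ("cox1", 1), ("trnL2", 1), ("cox2", 1),
    ("trnK", 1), ("trnD", 1), ("atp8", 1), ("atp6", 1), ("cox3", 1),
    ("trnG", 1), ("nad3", 1), ("trnA", 1), ("trnR", 1), ("trnN", 1),
    ("trnS1", 1), ("trnE", 1), ("trnF", -1), ("nad5", -1), ("trnH", -1),
    ("nad4", -1), ("nad4L", -1), ("trnT", 1), ("trnP", -1), ("nad6", 1),
    ("cob", 1), ("trnS2", 1), ("nad1", -1), ("trnL1", -1), ("rrnL", -1),
    ("trnV", -1), ("rrnS", -1),
)


def ancestral_insect_order() -> GeneOrder:
    """The canonical 37-gene ancestral insect mitochondrial gene order,
    with trnI-trnQ-trnM preceding nad2."""
    return GeneOrder(_ANCESTRAL)
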