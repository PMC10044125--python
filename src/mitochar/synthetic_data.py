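"""Seeded generator of circular mitogenomes with known ground truth.

Every analysis stage in this package is exercised against synthetic
genomes built here: sequence is sampled i.i.d. from per-region-class base
distributions, then the discrete features that matter — start codons,
(possibly incomplete) stop codons, gene overlaps, and the control-region
landmark elements — are overwritten at fixed positions, so the emitted
genome has an exactly known annotation, composition target, codon tally,
gene order and control-region hit list.  The realized ground truth is
recorded in a :class:`GroundTruthManifest` computed by direct tallies over
the emitted sequence at generation time and verified before return.

The control region is assembled with a seeded repair loop: filler bases
are resampled wherever a chance element (a spurious homopolymer run,
microsatellite array or tandem repeat) would make the scanner report
differ from the planted plan, so the scanners find exactly the planted
elements.

All randomness flows through one ``numpy`` generator seeded from the
config; identical configs give byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .annotation_io import (
    FeatureRecord,
    GenomeRecord,
    MitoAnnotation,
    categorize_gene,
)
from .control_region import CRScanConfig, SequenceHit, _scan_one_strand

__all__ = [
    "GeneSpec",
    "PlantedElement",
    "GeneratorConfig",
    "GroundTruthManifest",
    "GeneratorError",
    "generate_mitogenome",
    "perspectalis_like_profile",
]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


class GeneratorError(ValueError):
    """Infeasible generator configuration; message names the constraint."""


@dataclass(frozen=True)
class GeneSpec:
    """Plan for one feature: name, strand, length, and for PCGs the start
    codon and stop plan ("TAA"/"TAG" complete, "T"/"TA" incomplete)."""

    name: str
    strand: str
    length: int
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_plan: Optional[str] = None

    @property
    def category(self) -> str:
        return categorize_gene(self.name)


@dataclass(frozen=True)
class PlantedElement:
    """A control-region element to plant at a fixed 0-based CR offset."""

    kind: str  # motif | homopolymer | microsatellite
    unit: str
    copies: int
    offset: int

    @property
    def sequence(self) -> str:
        if self.kind == "motif":
            return self.unit
        return self.unit * self.copies

    @property
    def length(self) -> int:
        return len(self.sequence)

    def expected_hit(self) -> SequenceHit:
        """The hit the scanners must report for this element (1-based CR
        coordinates)."""
        return SequenceHit(
            kind=self.kind,
            start=self.offset + 1,
            end=self.offset + self.length,
            unit=self.unit,
            copies=1.0 if self.kind == "motif" else float(self.copies),
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full plan for a synthetic circular mitogenome.

    ``spacers[i]`` is the gap following ``genes[i]`` (negative = overlap
    with the next feature); the last spacer closes the circle back to the
    first feature.  ``composition`` maps region classes (full_genome, PCGs,
    tRNAs, rRNAs, control_region) to base->probability dicts; the
    full_genome entry also fills intergenic spacers.
    """

    seed: int
    genes: tuple[GeneSpec, ...]
    spacers: tuple[int, ...]
    composition: dict[str, dict[str, float]]
    cr_elements: tuple[PlantedElement, ...] = ()
    scan_config: CRScanConfig = field(default_factory=CRScanConfig)

    def validate(self) -> None:
        if len(self.genes) != len(self.spacers):
            raise GeneratorError("need one spacer per feature (last closes the circle)")
        for g in self.genes:
            if g.length <= 0:
                raise GeneratorError(f"{g.name}: non-positive length")
        for i, (g, sp) in enumerate(zip(self.genes, self.spacers)):
            nxt = self.genes[(i + 1) % len(self.genes)]
            if sp < 0 and -sp >= min(g.length, nxt.length):
                raise GeneratorError(
                    f"{g.name}/{nxt.name}: overlap {-sp} bp not smaller than both genes"
                )
        for region, probs in self.composition.items():
            if abs(sum(probs.values()) - 1.0) > 0.02:
                raise GeneratorError(f"{region}: base probabilities must sum to 1")


_REGION_OF = {"PCG": "PCGs", "tRNA": "tRNAs", "rRNA": "rRNAs", "control": "control_region"}


@dataclass
class GroundTruthManifest:
    """Ground truth realized by the generator, from direct tallies of the
    emitted sequence."""

    genome_length: int
    annotation: MitoAnnotation
    region_base_counts: dict[str, dict[str, int]]
    codon_counts: dict[str, int]  # sense tally, terminal complete stops excluded
    stop_statuses: dict[str, str]
    start_codons: dict[str, str]
    cr_hits: list[SequenceHit]
    gene_order: list[tuple[str, int]]

    def to_json(self) -> str:
        payload = {
            "genome_length": self.genome_length,
            "region_base_counts": self.region_base_counts,
            "codon_counts": self.codon_counts,
            "stop_statuses": self.stop_statuses,
            "start_codons": self.start_codons,
            "cr_hits": [h.__dict__ for h in self.cr_hits],
            "gene_order": [[n, s] for n, s in self.gene_order],
            "features": [
                {k: v for k, v in asdict(f).items()} for f in self.annotation.features
            ],
        }
        return json.dumps(payload, indent=2)


def _sample(rng: np.random.Generator, probs: dict[str, float], n: int) -> np.ndarray:
    p = np.array([probs.get(b, 0.0) for b in "ACGT"], dtype=float)
    p = p / p.sum()
    return rng.choice(_BASES, size=n, p=p)


def _coords(config: GeneratorConfig) -> tuple[list[tuple[int, int]], int]:
    coords = []
    start = 1
    for g, sp in zip(config.genes, config.spacers):
        end = start + g.length - 1
        if start < 1:
            raise GeneratorError(f"{g.name}: overlap pushes start before position 1")
        coords.append((start, end))
        start = end + sp + 1
    genome_length = coords[-1][1] + config.spacers[-1]
    if genome_length < coords[-1][1]:
        raise GeneratorError("closing spacer truncates the final feature")
    return coords, genome_length


def _build_cr(
    rng: np.random.Generator,
    length: int,
    probs: dict[str, float],
    elements: tuple[PlantedElement, ...],
    scan_config: CRScanConfig,
    max_repairs: int = 2000,
) -> tuple[str, list[SequenceHit]]:
    """Assemble the control region: planted elements at fixed offsets over
    sampled filler, filler repaired until the scanners report exactly the
    planted hits."""
    planted_pos: set[int] = set()
    for el in elements:
        if el.offset < 0 or el.offset + el.length > length:
            raise GeneratorError(
                f"planted {el.kind} {el.unit!r} exceeds control region ({length} bp)"
            )
        span = set(range(el.offset, el.offset + el.length))
        if span & planted_pos:
            raise GeneratorError(f"planted {el.kind} {el.unit!r} overlaps another element")
        planted_pos |= span

    cr = list(_sample(rng, probs, length))
    for el in elements:
        cr[el.offset : el.offset + el.length] = list(el.sequence)
    expected = {
        (h.kind, h.start, h.end, h.unit, h.copies)
        for h in (el.expected_hit() for el in elements)
    }

    for _ in range(max_repairs):
        found = _scan_one_strand("".join(cr), scan_config)
        wrong = [
            h for h in found if (h.kind, h.start, h.end, h.unit, h.copies) not in expected
        ]
        missing = expected - {(h.kind, h.start, h.end, h.unit, h.copies) for h in found}
        if not wrong and not missing:
            return "".join(cr), [el.expected_hit() for el in sorted(elements, key=lambda e: e.offset)]
        if missing and not wrong:
            raise GeneratorError(f"planted elements not recoverable by scanners: {missing}")
        h = wrong[0]
        free = [i for i in range(h.start - 1, h.end) if i not in planted_pos]
        if not free:
            raise GeneratorError(
                f"spurious {h.kind} at {h.start}-{h.end} lies entirely inside planted elements"
            )
        fresh = _sample(rng, probs, len(free))
        for i, b in zip(free, fresh):
            cr[i] = b
    raise GeneratorError("control-region repair did not converge; relax planted layout")


def _set_coding_base(
    genome: list[str], start: int, end: int, strand: str, idx: int, base: str,
    constraints: dict[int, str], owner: str,
) -> None:
    """Record base *idx* (0-based along the coding strand) as a constraint
    on the majority strand."""
    if strand == "F":
        pos, b = start - 1 + idx, base
    else:
        pos, b = end - 1 - idx, _COMP[base]
    prev = constraints.get(pos)
    if prev is not None and prev != b:
        raise GeneratorError(f"{owner}: planned base at position {pos + 1} conflicts")
    constraints[pos] = b


def _extract(genome: str, start: int, end: int, strand: str) -> str:
    sub = genome[start - 1 : end]
    if strand == "R":
        sub = "".join(_COMP[b] for b in reversed(sub))
    return sub


def _stop_status(seq: str) -> str:
    trailing = seq[3 * (len(seq) // 3) :]
    if trailing == "T":
        return "incomplete(T)"
    if trailing == "TA":
        return "incomplete(TA)"
    if trailing == "":
        last = seq[-3:]
        if last == "TAA":
            return "complete(TAA)"
        if last == "TAG":
            return "complete(TAG)"
    return "non_canonical"


def generate_mitogenome(
    config: GeneratorConfig,
) -> tuple[GenomeRecord, MitoAnnotation, GroundTruthManifest]:
    """Emit a synthetic circular mitogenome, its annotation, and the
    realized ground-truth manifest.

    Deterministic for a fixed config (including its seed).  Raises
    :class:`GeneratorError` for infeasible plans (overlap at least as long
    as a gene, planted elements outside the control region, conflicting
    planned codons...).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    coords, genome_length = _coords(config)

    default_probs = config.composition.get(
        "full_genome", {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    genome = list(_sample(rng, default_probs, genome_length))

    # per-feature fill (later features overwrite shared overlap bases)
    cr_spec: Optional[tuple[GeneSpec, int, int]] = None
    for g, (start, end) in zip(config.genes, coords):
        if g.category == "control":
            cr_spec = (g, start, end)
            continue
        probs = config.composition.get(_REGION_OF[g.category], default_probs)
        block = _sample(rng, probs, g.length)
        if g.strand == "F":
            genome[start - 1 : end] = list(block)
        else:
            genome[start - 1 : end] = [_COMP[b] for b in block][::-1]

    # planned start/stop codons as strand-aware constraints
    constraints: dict[int, str] = {}
    for g, (start, end) in zip(config.genes, coords):
        if g.category != "PCG":
            continue
        if g.start_codon:
            for i, b in enumerate(g.start_codon.upper()):
                _set_coding_base(genome, start, end, g.strand, i, b, constraints, g.name)
        if g.stop_plan:
            stop = g.stop_plan.upper()
            for i, b in enumerate(stop):
                _set_coding_base(
                    genome, start, end, g.strand, g.length - len(stop) + i, b,
                    constraints, g.name,
                )
    for pos, b in constraints.items():
        genome[pos] = b

    # control region, repaired so scanners report exactly the planted set
    cr_hits: list[SequenceHit] = []
    if cr_spec is not None:
        g, start, end = cr_spec
        if any(start - 1 <= pos <= end - 1 for pos in constraints):
            raise GeneratorError("planned codon constraint falls inside the control region")
        cr_seq, cr_hits = _build_cr(
            rng,
            g.length,
            config.composition.get("control_region", default_probs),
            config.cr_elements,
            config.scan_config,
        )
        genome[start - 1 : end] = list(cr_seq)

    seq = "".join(genome)

    # realized annotation
    features = []
    for g, (start, end) in zip(config.genes, coords):
        coding = _extract(seq, start, end, g.strand)
        features.append(
            FeatureRecord(
                name=g.name,
                category=g.category,
                strand=g.strand,
                start=start,
                end=end,
                anticodon=g.anticodon,
                start_codon=coding[:3] if g.category == "PCG" else None,
                stop_codon=g.stop_plan if g.category == "PCG" else None,
            )
        )
    annotation = MitoAnnotation(genome_length=genome_length, features=features)

    # ---- ground-truth tallies straight off the emitted sequence ----
    region_counts: dict[str, dict[str, int]] = {}

    def tally(region: str, s: str) -> None:
        d = region_counts.setdefault(region, {b: 0 for b in "ACGT"})
        for b in s:
            d[b] = d.get(b, 0) + 1

    tally("full_genome", seq)
    for g, (start, end) in zip(config.genes, coords):
        tally(_REGION_OF[g.category], _extract(seq, start, end, g.strand))

    codon_tally: dict[str, int] = {}
    stop_statuses: dict[str, str] = {}
    start_codons: dict[str, str] = {}
    for g, (start, end) in zip(config.genes, coords):
        if g.category != "PCG":
            continue
        coding = _extract(seq, start, end, g.strand)
        codons = [coding[3 * i : 3 * i + 3] for i in range(len(coding) // 3)]
        status = _stop_status(coding)
        stop_statuses[g.name] = status
        start_codons[g.name] = codons[0]
        if status.startswith("complete"):
            codons = codons[:-1]
        for c in codons:
            codon_tally[c] = codon_tally.get(c, 0) + 1

    manifest = GroundTruthManifest(
        genome_length=genome_length,
        annotation=annotation,
        region_base_counts=region_counts,
        codon_counts=codon_tally,
        stop_statuses=stop_statuses,
        start_codons=start_codons,
        cr_hits=cr_hits,
        gene_order=[
            (g.name, 1 if g.strand == "F" else -1)
            for g in config.genes
            if g.category != "control"
        ],
    )

    # verification before return: constraints present, hits literal
    for pos, b in constraints.items():
        assert seq[pos] == b
    if cr_spec is not None:
        g, start, end = cr_spec
        cr_str = _extract(seq, start, end, g.strand)
        for h in cr_hits:
            if not h.verify(cr_str):  # pragma: no cover
                raise GeneratorError(f"manifest hit {h} not present in emitted sequence")
    genome_rec = GenomeRecord(
        identifier=f"synthetic_mitogenome_seed{config.seed}", sequence=seq, circular=True
    )
    return genome_rec, annotation, manifest


def perspectalis_like_profile(seed: int = 0) -> GeneratorConfig:
    """A box-tree-moth-like generator profile: the published 37-gene +
    control-region layout (lengths, strands, overlaps, anticodons, start
    codons and stop plans of KY865331), region compositions matching the
    published per-region base percentages, and the four published
    control-region landmarks planted — an ATAGG(A) motif followed
    immediately by a 17 bp poly-T stretch near the 5' end, an (AT)14
    microsatellite mid-region, and a 10 bp poly-A stretch flush with the
    downstream trnM boundary."""
    from .reference import cydalima_annotation
    from .annotation_io import feature_length, intergenic_lengths

    ann = cydalima_annotation().sorted_by_start()
    spacer_of = dict(intergenic_lengths(ann))
    genes = tuple(
        GeneSpec(
            name=f.name,
            strand=f.strand,
            length=feature_length(f, ann.genome_length),
            anticodon=f.anticodon,
            start_codon=f.start_codon,
            stop_plan=f.stop_codon,
        )
        for f in ann.features
    )
    spacers = tuple(spacer_of[f.name] for f in ann.features)
    composition = {
        "full_genome": {"T": 0.410, "C": 0.114, "A": 0.399, "G": 0.077},
        "PCGs": {"T": 0.455, "C": 0.097, "A": 0.341, "G": 0.107},
        "tRNAs": {"T": 0.403, "C": 0.075, "A": 0.414, "G": 0.109},
        "rRNAs": {"T": 0.401, "C": 0.051, "A": 0.444, "G": 0.104},
        "control_region": {"T": 0.486, "C": 0.024, "A": 0.476, "G": 0.014},
    }
    cr_elements = (
        PlantedElement("motif", "ATAGGA", 1, 10),
        PlantedElement("homopolymer", "T", 17, 16),
        PlantedElement("microsatellite", "AT", 14, 120),
        PlantedElement("homopolymer", "A", 10, 278),
    )
    return GeneratorConfig(
        seed=seed,
        genes=genes,
        spacers=spacers,
        composition=composition,
        cr_elements=cr_elements,
    )
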