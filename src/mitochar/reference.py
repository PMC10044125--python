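"""Published reference data for the *Cydalima perspectalis* (box tree
moth) mitogenome, GenBank accession KY865331.

The 15,180 bp circular mitogenome carries the full metazoan complement of
13 protein-coding genes, 22 tRNAs, two rRNAs and one A+T-rich control
region.  The annotation table below (coordinates 1-based inclusive,
strands relative to the majority strand, tRNA anticodons in DNA spelling)
and the per-codon count table of its concatenated protein-coding genes are
the published desk-scale inputs against which this package's arithmetic is
validated; no sequence download is required to use them.
"""

from __future__ import annotations

from .annotation_io import FeatureRecord, MitoAnnotation, categorize_gene, normalize_gene_name
from .codon_usage import CodonCountTable

__all__ = [
    "GENOME_LENGTH",
    "cydalima_annotation",
    "cydalima_codon_counts",
]

GENOME_LENGTH = 15_180

# gene, strand, start, end, anticodon, start codon, stop codon
_FEATURES = (
    ("trnM", "F", 1, 68, "CAT", None, None),
    ("trnI", "F", 69, 134, "GAT", None, None),
    ("trnQ", "R", 132, 200, "TTG", None, None),
    ("nad2", "F", 244, 1257, None, "ATT", "TAA"),
    ("trnW", "F", 1259, 1325, "TCA", None, None),
    ("trnC", "R", 1318, 1383, "GCA", None, None),
    ("trnY", "R", 1387, 1451, "GTA", None, None),
    ("cox1", "F", 1461, 2996, None, "CGA", "TAA"),
    ("trnL2", "F", 2992, 3058, "TAA", None, None),
    ("cox2", "F", 3059, 3740, None, "ATG", "T"),
    ("trnK", "F", 3741, 3811, "CTT", None, None),
    ("trnD", "F", 3825, 3890, "GTC", None, None),
    ("atp8", "F", 3891, 4052, None, "ATC", "TAA"),
    ("atp6", "F", 4046, 4720, None, "ATG", "TAA"),
    ("cox3", "F", 4720, 5508, None, "ATG", "TAA"),
    ("trnG", "F", 5511, 5576, "TCC", None, None),
    ("nad3", "F", 5577, 5930, None, "ATT", "TAA"),
    ("trnA", "F", 5947, 6011, "TGC", None, None),
    ("trnR", "F", 6012, 6074, "TCG", None, None),
    ("trnN", "F", 6076, 6141, "GTT", None, None),
    ("trnS1", "F", 6148, 6213, "GCT", None, None),
    ("trnE", "F", 6214, 6280, "TTC", None, None),
    ("trnF", "R", 6283, 6349, "GAA", None, None),
    ("nad5", "R", 6362, 8098, None, "ATA", "T"),
    ("trnH", "R", 8099, 8164, "GTG", None, None),
    ("nad4", "R", 8166, 9506, None, "ATC", "T"),
    ("nad4L", "R", 9508, 9798, None, "ATA", "T"),
    ("trnT", "F", 9801, 9867, "TGT", None, None),
    ("trnP", "R", 9868, 9933, "TGG", None, None),
    ("nad6", "F", 9936, 10_472, None, "ATT", "TAA"),
    ("cob", "F", 10_479, 11_630, None, "ATG", "TAA"),
    ("trnS2", "F", 11_629, 11_693, "TGA", None, None),
    ("nad1", "R", 11_711, 12_649, None, "ATA", "T"),
    ("trnL1", "R", 12_651, 12_724, "TAG", None, None),
    ("rrnL", "R", 12_681, 14_050, None, None, None),
    ("trnV", "R", 14_055, 14_124, "TAC", None, None),
    ("rrnS", "R", 14_124, 14_892, None, None, None),
    ("control_region", "F", 14_893, 15_180, None, None, None),
)


def cydalima_annotation() -> MitoAnnotation:
    """The published 37-gene + control-region annotation of KY865331."""
    feats = [
        FeatureRecord(
            name=normalize_gene_name(name),
            category=categorize_gene(name),
            strand=strand,
            start=start,
            end=end,
            anticodon=anticodon,
            start_codon=start_codon,
            stop_codon=stop_codon,
        )
        for name, strand, start, end, anticodon, start_codon, stop_codon in _FEATURES
    ]
    return MitoAnnotation(genome_length=GENOME_LENGTH, features=feats)


# Published codon counts over the 13 concatenated protein-coding genes
# (DNA spelling; TAA/TAG rows are the termination-codon tally).
_CODON_COUNTS = {
    "TTT": 350, "TTC": 24, "TTA": 467, "TTG": 17,
    "TCT": 109, "TCC": 9, "TCA": 85, "TCG": 1,
    "TAT": 185, "TAC": 8, "TAA": 11, "TAG": 0,
    "TGT": 28, "TGC": 2, "TGA": 91, "TGG": 3,
    "CTT": 23, "CTC": 2, "CTA": 22, "CTG": 0,
    "CCT": 69, "CCC": 11, "CCA": 47, "CCG": 0,
    "CAT": 65, "CAC": 4, "CAA": 60, "CAG": 2,
    "CGT": 20, "CGC": 0, "CGA": 31, "CGG": 2,
    "ATT": 442, "ATC": 27, "ATA": 258, "ATG": 27,
    "ACT": 80, "ACC": 5, "ACA": 64, "ACG": 0,
    "AAT": 231, "AAC": 16, "AAA": 97, "AAG": 11,
    "AGT": 17, "AGC": 0, "AGA": 98, "AGG": 0,
    "GTT": 76, "GTC": 4, "GTA": 62, "GTG": 0,
    "GCT": 78, "GCC": 9, "GCA": 37, "GCG": 2,
    "GAT": 62, "GAC": 2, "GAA": 72, "GAG": 4,
    "GGT": 73, "GGC": 2, "GGA": 114, "GGG": 16,
}


def cydalima_codon_counts() -> CodonCountTable:
    """Published per-codon counts of the 13 concatenated PCGs (3723 sense
    codons plus the stop-codon tally)."""
    return CodonCountTable(_CODON_COUNTS)
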