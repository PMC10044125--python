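"""Annotation parsing, serialization and circular coordinate arithmetic."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitochar.annotation_io import (
    AnnotationError,
    FeatureRecord,
    FeatureTableParseError,
    GenomeRecord,
    MitoAnnotation,
    extract_feature_sequence,
    feature_length,
    intergenic_lengths,
    parse_feature_table,
    read_fasta,
    reverse_complement,
    strand_census,
    write_fasta,
    write_feature_table,
)


def _feat(name, start, end, strand="F", category=None):
    from mitochar.annotation_io import categorize_gene

    return FeatureRecord(
        name=name,
        category=category or categorize_gene(name),
        strand=strand,
        start=start,
        end=end,
        anticodon="CAT" if (category or categorize_gene(name)) == "tRNA" else None,
    )


class TestParseFeatureTable:
    def test_published_table_dialect_with_location_column(self):
        text = (
            "Gene\tStrand\tLocation\tSize (bp)\tAnticodon\n"
            "trnM\tF\t1–68\t68\tCAT\n"
            "16S\tR\t12,681–14,050\t1370\t\n"
        )
        ann = parse_feature_table(io.StringIO(text))
        trnM = ann.get("trnM")
        assert (trnM.name, trnM.category, trnM.strand) == ("trnM", "tRNA", "F")
        assert (trnM.start, trnM.end, trnM.anticodon) == (1, 68, "CAT")
        rrnL = ann.get("16S")  # alias-normalized lookup
        assert (rrnL.name, rrnL.start, rrnL.end) == ("rrnL", 12681, 14050)
        assert ann.genome_length == 14050  # inferred from max end

    def test_hyphen_range_and_rna_anticodon_normalized(self):
        text = "Gene\tStrand\tLocation\tAnticodon\ntrnN\tF\t6076-6141\tGUU\n"
        ann = parse_feature_table(io.StringIO(text))
        assert ann.get("trnN").anticodon == "GTT"

    @pytest.mark.parametrize(
        "row",
        [
            "trnM\tF\tone–68\t",  # malformed coordinate
            "trnM\tX\t1–68\t",  # unknown strand
        ],
    )
    def test_parse_errors_name_the_line(self, row):
        text = "Gene\tStrand\tLocation\tAnticodon\n" + row + "CAT\n"
        with pytest.raises(FeatureTableParseError, match="line 2"):
            parse_feature_table(io.StringIO(text))

    def test_duplicate_gene_name_rejected(self):
        text = "Gene\tStrand\tLocation\ncox1\tF\t1–30\ncox1\tF\t40–60\n"
        with pytest.raises(AnnotationError, match="duplicate"):
            parse_feature_table(io.StringIO(text))

    def test_declared_size_mismatch_warns_not_fails(self):
        text = "Gene\tStrand\tLocation\tSize (bp)\ncox1\tF\t1–30\t29\n"
        with pytest.warns(UserWarning, match="declared size 29 != computed 30"):
            ann = parse_feature_table(io.StringIO(text))
        assert feature_length(ann.get("cox1"), ann.genome_length) == 30


class TestWriteFeatureTable:
    def test_empty_annotation_is_header_only(self):
        out = write_feature_table(MitoAnnotation(genome_length=10, features=[]))
        assert out.strip().count("\n") == 0 and out.startswith("Gene\t")

    def test_reference_table_has_38_rows(self, ref_annotation):
        out = write_feature_table(ref_annotation)
        assert len(out.strip().splitlines()) == 1 + 38  # header + 37 genes + control

    def test_round_trip_identity(self, ref_annotation):
        text = write_feature_table(ref_annotation)
        back = parse_feature_table(
            io.StringIO(text), genome_length=ref_annotation.genome_length
        )
        assert back == ref_annotation

    @given(st.data())
    def test_round_trip_random_annotations(self, data):
        n = data.draw(st.integers(1, 8))
        starts = sorted(
            data.draw(
                st.lists(
                    st.integers(1, 500), min_size=n, max_size=n, unique=True
                )
            )
        )
        feats = []
        for i, s in enumerate(starts):
            length = data.draw(st.integers(1, 60))
            strand = data.draw(st.sampled_from(["F", "R"]))
            feats.append(_feat(f"trn{chr(65 + i)}x", s, s + length, strand))
        ann = MitoAnnotation(genome_length=1000, features=feats)
        assert parse_feature_table(
            io.StringIO(write_feature_table(ann)), genome_length=1000
        ) == ann


class TestFeatureLength:
    @pytest.mark.parametrize(
        "start,end,expected", [(1, 68, 68), (12681, 14050, 1370), (5, 5, 1)]
    )
    def test_non_wrapping(self, start, end, expected):
        f = _feat("cox1", start, end)
        assert feature_length(f, 15180) == expected

    def test_origin_wrapping(self):
        f = _feat("cox1", 5, 2)
        assert feature_length(f, 6) == 2 + 2  # 5,6 then 1,2

    def test_coordinates_beyond_genome_rejected(self):
        with pytest.raises(AnnotationError):
            feature_length(_feat("cox1", 1, 200), 100)


class TestIntergenicLengths:
    def test_published_overlaps(self, ref_annotation):
        spacers = dict(intergenic_lengths(ref_annotation))
        assert spacers["trnI"] == -3  # trnQ starts inside trnI
        assert spacers["trnQ"] == 43
        assert spacers["trnL1"] == -44  # rrnL nested under trnL1 end
        assert spacers["atp8"] == -7
        assert spacers["control_region"] == 0  # closes the circle to trnM

    def test_abutting_features_have_zero_spacer(self):
        ann = MitoAnnotation(
            genome_length=6, features=[_feat("cox1", 1, 3), _feat("cox2", 4, 6)]
        )
        assert intergenic_lengths(ann) == [("cox1", 0), ("cox2", 0)]

    def test_circle_closure_identity(self, ref_annotation):
        # sum(lengths) + sum(spacers) == genome length, overlaps negative
        total = sum(
            feature_length(f, ref_annotation.genome_length) for f in ref_annotation
        ) + sum(s for _, s in intergenic_lengths(ref_annotation))
        assert total == ref_annotation.genome_length

    def test_unsorted_annotation_rejected(self):
        ann = MitoAnnotation(
            genome_length=10, features=[_feat("cox2", 5, 7), _feat("cox1", 1, 3)]
        )
        with pytest.raises(AnnotationError, match="sort"):
            intergenic_lengths(ann)


class TestStrandCensus:
    def test_published_census(self, ref_annotation):
        assert strand_census(ref_annotation) == (23, 14)

    def test_control_region_excluded(self, ref_annotation):
        n_f, n_r = strand_census(ref_annotation)
        assert n_f + n_r == 37

    @given(st.lists(st.sampled_from(["F", "R"]), min_size=1, max_size=20))
    def test_matches_direct_tally(self, strands):
        feats = [
            _feat(f"trn{chr(65 + i)}q", 10 * i + 1, 10 * i + 5, s)
            for i, s in enumerate(strands)
        ]
        ann = MitoAnnotation(genome_length=500, features=feats)
        assert strand_census(ann) == (
            sum(1 for s in strands if s == "F"),
            sum(1 for s in strands if s == "R"),
        )


class TestExtractFeatureSequence:
    def test_forward(self):
        g = GenomeRecord("g", "ATGC")
        assert extract_feature_sequence(g, _feat("cox1", 1, 4)) == "ATGC"

    def test_reverse_is_reverse_complement(self):
        g = GenomeRecord("g", "ATGC")
        assert extract_feature_sequence(g, _feat("cox1", 1, 4, "R")) == "GCAT"

    def test_wrap_across_origin(self):
        # rotate "AAACCC" so position 5 leads: CC + AA
        g = GenomeRecord("g", "AAACCC", circular=True)
        assert extract_feature_sequence(g, _feat("cox1", 5, 2)) == "CCAA"

    def test_wrap_on_linear_genome_rejected(self):
        g = GenomeRecord("g", "AAACCC", circular=False)
        with pytest.raises(AnnotationError, match="circular"):
            extract_feature_sequence(g, _feat("cox1", 5, 2))

    @given(
        st.text(alphabet="ACGT", min_size=4, max_size=50),
        st.data(),
    )
    def test_strands_are_reverse_complements(self, seq, data):
        start = data.draw(st.integers(1, len(seq)))
        end = data.draw(st.integers(start, len(seq)))
        g = GenomeRecord("g", seq)
        fwd = extract_feature_sequence(g, _feat("cox1", start, end, "F"))
        rev = extract_feature_sequence(g, _feat("cox1", start, end, "R"))
        assert rev == reverse_complement(fwd)
        assert len(fwd) == feature_length(_feat("cox1", start, end), len(seq))


def test_fasta_round_trip(tmp_path):
    g = GenomeRecord("mito", "ACGT" * 60)
    path = tmp_path / "genome.fasta"
    write_fasta(g, str(path))
    lines = path.read_text().splitlines()
    assert lines[0] == ">mito"
    assert all(len(ln) <= 70 for ln in lines[1:])
    back = read_fasta(str(path))
    assert back.sequence == g.sequence and back.identifier == "mito"
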