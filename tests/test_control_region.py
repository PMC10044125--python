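"""Control-region scanners: motifs, homopolymers, microsatellites and
tandem repeats, cross-checked against naive brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitochar.control_region import (
    CRScanConfig,
    control_region_report,
    find_homopolymer_runs,
    find_microsatellites,
    find_motif,
    find_tandem_repeats,
)
from mitochar.annotation_io import FeatureRecord, GenomeRecord, MitoAnnotation

from _oracles import (
    as_tuples,
    homopolymer_oracle,
    microsat_oracle,
    motif_oracle,
    tandem_oracle,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=300)
# AT-rich text makes repeat structure likely, as in real control regions
at_rich = st.text(alphabet="AATTACGT", min_size=0, max_size=300)


class TestFindMotif:
    def test_single_occurrence(self):
        hits = find_motif("CCATAGGTT", "ATAGG")
        assert [(h.start, h.end) for h in hits] == [(3, 7)]

    def test_absent_motif(self):
        assert find_motif("CCCCC", "ATAGG") == []

    def test_motif_longer_than_sequence_is_empty(self):
        assert find_motif("AT", "ATAGG") == []

    def test_n_wildcard_and_overlaps(self):
        hits = find_motif("AAAA", "ANA")
        assert [(h.start, h.end) for h in hits] == [(1, 3), (2, 4)]

    @given(dna, st.sampled_from(["ATAGG", "ANT", "TTN", "A"]))
    def test_matches_naive_scan(self, seq, motif):
        assert as_tuples(find_motif(seq, motif)) == motif_oracle(seq, motif)


class TestHomopolymers:
    def test_run_below_threshold_ignored(self):
        assert find_homopolymer_runs("TTT", "T", 5) == []

    def test_exact_run_lengths(self):
        hits = find_homopolymer_runs("AA" + "T" * 17 + "GG", "T", 10)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].copies) == (3, 19, 17.0)

    def test_min_len_validated(self):
        with pytest.raises(ValueError):
            find_homopolymer_runs("AAAA", "A", 1)

    @given(at_rich, st.sampled_from("AT"), st.integers(2, 6))
    def test_matches_run_length_oracle(self, seq, base, min_len):
        assert as_tuples(find_homopolymer_runs(seq, base, min_len)) == (
            homopolymer_oracle(seq, base, min_len)
        )


class TestMicrosatellites:
    def test_minimum_copies(self):
        hits = find_microsatellites("ATATAT", "AT", 3)
        assert len(hits) == 1 and hits[0].copies == 3

    def test_trailing_partial_unit_extends_end_not_copies(self):
        hits = find_microsatellites("GATATATA" + "G", "AT", 3)
        assert (hits[0].start, hits[0].end, hits[0].copies) == (2, 8, 3.0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            find_microsatellites("ATAT", "AT", 2)
        with pytest.raises(ValueError):
            find_microsatellites("ATAT", "ATATATA", 3)

    @given(at_rich, st.sampled_from(["AT", "TA", "AAT"]), st.integers(3, 5))
    def test_matches_array_oracle(self, seq, unit, min_copies):
        got = [
            (h.start, h.end, int(h.copies))
            for h in find_microsatellites(seq, unit, min_copies)
        ]
        assert got == microsat_oracle(seq, unit, min_copies)


class TestTandemRepeats:
    def test_simple_array(self):
        hits = find_tandem_repeats("ACGACGACG", 3, 2)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.unit, h.copies) == (1, 9, "ACG", 3.0)

    def test_array_reported_at_smallest_period_only(self):
        # period 6 reading of an ACG array must not appear alongside period 3
        hits = find_tandem_repeats("ACGACGACGACG", 3, 2)
        assert [h.unit for h in hits] == ["ACG"]

    def test_homopolymer_not_a_tandem_repeat(self):
        assert find_tandem_repeats("A" * 30, 5, 2) == []

    def test_planted_10bp_unit(self):
        unit = "ATAGGATTTT"
        hits = find_tandem_repeats("CC" + unit * 2 + "GG", 5, 2)
        assert any(h.unit == unit and h.copies == 2.0 for h in hits)

    def test_microsat_hits_nest_inside_dinucleotide_tandem_hits(self):
        seq = "GGATATATATATGG"
        micro = find_microsatellites(seq, "AT", 3)
        tandem = find_tandem_repeats(seq, 2, 2)
        for m in micro:
            assert any(
                t.start <= m.start and m.end <= t.end and len(t.unit) == 2
                for t in tandem
            )

    @given(at_rich, st.integers(2, 5), st.integers(2, 3))
    @settings(max_examples=60)
    def test_matches_period_oracle(self, seq, min_unit, min_copies):
        got = [
            (h.start, h.end, h.unit, int(h.copies))
            for h in find_tandem_repeats(seq, min_unit, min_copies, max_unit=8)
        ]
        assert got == tandem_oracle(seq, min_unit, min_copies, 8)


class TestSelfConsistency:
    def test_every_hit_re_extracts_to_its_description(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            seq = "".join(rng.choice(list("AATTACGT"), size=400))
            for h in find_tandem_repeats(seq, 2, 2, max_unit=10):
                assert h.verify(seq)
            for h in find_microsatellites(seq, "AT", 3):
                assert h.verify(seq)
            for h in find_homopolymer_runs(seq, "T", 3):
                assert h.verify(seq)
            for h in find_motif(seq, "ATAGG"):
                assert h.verify(seq)


class TestControlRegionReport:
    def test_planted_elements_recovered_exactly(self, synthetic_mitogenome):
        genome, ann, manifest = synthetic_mitogenome
        hits = control_region_report(genome, ann)
        assert hits == manifest.cr_hits
        assert [h.kind for h in hits] == [
            "motif", "homopolymer", "microsatellite", "homopolymer"
        ]

    def test_featureless_cr_has_no_tandem_hits(self):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        genome = GenomeRecord("g", seq)
        ann = MitoAnnotation(
            genome_length=500,
            features=[FeatureRecord("control_region", "control", "F", 101, 200)],
        )
        hits = control_region_report(genome, ann)
        cr_seq = seq[100:200]
        expected = tandem_oracle(
            cr_seq,
            CRScanConfig().tandem_min_unit,
            CRScanConfig().tandem_min_copies,
            len(cr_seq) // 2,
        )
        got = [
            (h.start, h.end, h.unit, int(h.copies))
            for h in hits
            if h.kind == "tandem_repeat"
        ]
        assert got == expected

    def test_missing_control_region_rejected(self):
        genome = GenomeRecord("g", "ACGT" * 10)
        ann = MitoAnnotation(
            genome_length=40, features=[FeatureRecord("cox1", "PCG", "F", 1, 40)]
        )
        with pytest.raises(ValueError, match="control region"):
            control_region_report(genome, ann)
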