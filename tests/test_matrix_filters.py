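"""Demultiplexing, merging and the per-run filter cascade."""

import pandas as pd
import pytest
from Bio.Seq import Seq

from sparrowmhc.genotyping import (
    FilterReport,
    TagMap,
    call_genotypes,
    demultiplex,
    filter_length_and_frame,
    filter_low_abundance,
    filter_min_occurrence,
    filter_sample_coverage,
    filter_within_sample_frequency,
    merge_identical,
)
from sparrowmhc.simulate import FWD_PRIMER, REV_PRIMER

from conftest import make_matrix

REV_RC = str(Seq(REV_PRIMER).reverse_complement())


def _write_reads(tmp_path, reads):
    path = tmp_path / "reads.fasta"
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f">read{i}\n{seq}\n")
    return path


def _tag_map():
    return TagMap(pd.DataFrame({
        "tag": ["AAAAAAAA", "CCCCCCCC"],
        "sample": ["s1", "s2"],
        "run": ["R1", "R1"],
        "replicate_of": ["", ""],
    }))


class TestDemultiplex:
    def test_counts_valid_and_dropped(self, tmp_path):
        insert = "ACGT" * 10
        reads = [
            "AAAAAAAA" + FWD_PRIMER + insert + REV_RC,
            "CCCCCCCC" + FWD_PRIMER + insert + REV_RC,
            "GGGGGGGG" + FWD_PRIMER + insert + REV_RC,   # unknown tag
        ]
        mat = demultiplex(_write_reads(tmp_path, reads), _tag_map(), "R1",
                          FWD_PRIMER, REV_PRIMER)
        assert mat.total_reads == 2
        assert mat.dropped_reads == 1

    def test_primer_mismatch_dropped(self, tmp_path):
        bad_primer = "T" + FWD_PRIMER[1:]
        reads = ["AAAAAAAA" + bad_primer + "ACGT" * 10 + REV_RC]
        mat = demultiplex(_write_reads(tmp_path, reads), _tag_map(), "R1",
                          FWD_PRIMER, REV_PRIMER)
        assert mat.total_reads == 0
        assert mat.dropped_reads == 1

    def test_duplicate_tags_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TagMap(pd.DataFrame({
                "tag": ["AAAA", "AAAA"], "sample": ["a", "b"],
                "run": ["R1", "R1"], "replicate_of": ["", ""]}))


class TestMergeIdentical:
    def test_additivity(self):
        mat = make_matrix({"s1": {"v1": 5, "v2": 7}},
                          {"v1": "ACGT", "v2": "ACGT"})
        merged = merge_identical(mat)
        assert merged.n_variants == 1
        assert merged.counts.iloc[0, 0] == 12

    def test_distinct_unchanged(self):
        mat = make_matrix({"s1": {"v1": 5, "v2": 7}},
                          {"v1": "ACGT", "v2": "TGCA"})
        merged = merge_identical(mat)
        assert merged.n_variants == 2
        assert merged.total_reads == 12

    def test_idempotent(self):
        mat = make_matrix({"s1": {"v1": 5, "v2": 7}, "s2": {"v2": 3}},
                          {"v1": "ACGT", "v2": "ACGT"})
        once = merge_identical(mat)
        twice = merge_identical(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        assert once.sequences == twice.sequences


class TestLowAbundance:
    def test_boundary(self):
        mat = make_matrix({"s1": {"v1": 2, "v2": 3}},
                          {"v1": "AA", "v2": "CC"})
        out = filter_low_abundance(mat, min_reads=3)
        assert list(out.counts.columns) == ["v2"]

    def test_all_zero_gives_empty(self):
        mat = make_matrix({"s1": {"v1": 1, "v2": 2}}, {"v1": "AA", "v2": "CC"})
        out = filter_low_abundance(mat, min_reads=5)
        assert out.n_variants == 0

    def test_read_accounting(self):
        mat = make_matrix({"s1": {"v1": 2, "v2": 10}, "s2": {"v1": 4, "v2": 1}},
                          {"v1": "AA", "v2": "CC"})
        out = filter_low_abundance(mat, min_reads=3)
        removed = 2 + 1
        assert out.total_reads == mat.total_reads - removed

    def test_invalid_threshold(self):
        mat = make_matrix({"s1": {"v1": 1}}, {"v1": "AA"})
        with pytest.raises(ValueError):
            filter_low_abundance(mat, min_reads=0)


class TestSampleCoverage:
    def test_threshold_boundary(self):
        mat = make_matrix({"s1": {"v1": 103}, "s2": {"v1": 104}}, {"v1": "AA"})
        out, failed = filter_sample_coverage(mat, 104)
        assert failed == ["s1"]
        assert list(out.counts.index) == ["s2"]

    def test_zero_threshold_keeps_all(self):
        mat = make_matrix({"s1": {"v1": 1}, "s2": {"v1": 2}}, {"v1": "AA"})
        out, failed = filter_sample_coverage(mat, 0)
        assert failed == []
        assert len(out.counts) == 2


class TestWithinSampleFrequency:
    def test_two_percent_boundary(self):
        mat = make_matrix({"s1": {"v1": 5, "v2": 7, "v3": 288}},
                          {"v1": "AA", "v2": "CC", "v3": "GG"})
        out = filter_within_sample_frequency(mat, min_frac=0.02)
        # 5/300 = 1.67% removed; 7/300 = 2.33% kept
        assert "v1" not in out.counts.columns
        assert out.counts.loc["s1", "v2"] == 7

    def test_single_variant_always_kept(self):
        mat = make_matrix({"s1": {"v1": 4}}, {"v1": "AA"})
        out = filter_within_sample_frequency(mat, min_frac=0.02)
        assert out.counts.loc["s1", "v1"] == 4

    def test_single_pass_totals(self):
        """Removal uses entering totals, so decisions are order-independent:
        two 1.9% variants are both removed, not rescued by recomputation."""
        mat = make_matrix({"s1": {"v1": 19, "v2": 19, "v3": 962}},
                          {"v1": "AA", "v2": "CC", "v3": "GG"})
        out = filter_within_sample_frequency(mat, min_frac=0.02)
        assert set(out.counts.columns) == {"v3"}


class TestMinOccurrence:
    def test_occurrence_boundary(self):
        mat = make_matrix({"s1": {"v1": 5, "v2": 5}, "s2": {"v2": 5}},
                          {"v1": "AA", "v2": "CC"})
        out = filter_min_occurrence(mat, min_samples=2)
        assert set(out.counts.columns) == {"v2"}

    def test_replicate_counts_as_independent_pcr(self):
        mat = make_matrix({"s1": {"v1": 5}, "s1.rep": {"v1": 5}},
                          {"v1": "AA"},
                          replicate_links=[("s1", "s1.rep")])
        out = filter_min_occurrence(mat, min_samples=2)
        assert "v1" in out.counts.columns

    def test_dropping_never_resurrects(self):
        mat = make_matrix({"s1": {"v1": 5, "v2": 5}, "s2": {"v2": 5}},
                          {"v1": "AA", "v2": "CC"})
        before = set(filter_min_occurrence(mat, 2).counts.columns)
        after = set(filter_min_occurrence(filter_min_occurrence(mat, 2), 2).counts.columns)
        assert after <= before


class TestLengthAndFrame:
    @pytest.mark.parametrize("length,kept", [
        (222, True),    # reference length
        (225, True),    # +3: one extra codon
        (221, False),   # below range
        (226, False),   # above range
        (223, False),   # +1 shifts the frame
        (224, False),   # +2 shifts the frame
    ])
    def test_length_rules(self, length, kept):
        mat = make_matrix({"s1": {"v1": 9}}, {"v1": "A" * length})
        out = filter_length_and_frame(mat)
        assert ("v1" in out.counts.columns) == kept

    def test_empty_matrix(self):
        mat = make_matrix({}, {})
        out = filter_length_and_frame(mat)
        assert out.n_variants == 0


class TestCascade:
    def test_filter_report_monotone(self, default_pop):
        from sparrowmhc.simulate import simulate_reads

        mats, _ = simulate_reads(default_pop, default_pop.config)
        res = call_genotypes(mats[0])
        assert res.report.is_monotone()
        assert res.coverage_threshold == 104

    def test_low_coverage_sample_fails(self):
        seq = "A" * 222
        mat = make_matrix({"s1": {"v1": 50}, "s2": {"v1": 200}, "s3": {"v1": 200}},
                          {"v1": seq})
        res = call_genotypes(mat)
        assert res.calls["s1"].status == "failed_coverage"
        assert res.calls["s1"].accepted == set()
        assert res.calls["s2"].accepted == {seq}

    def test_report_roundtrip_tsv(self, tmp_path):
        report = FilterReport()
        mat = make_matrix({"s1": {"v1": 5}}, {"v1": "AA"})
        report.add("noop", mat, mat)
        path = tmp_path / "report.tsv"
        report.write_tsv(path)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(back, report.to_frame())
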