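"""Summary-statistics ingestion, harmonization and dimorphism scoring."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sexdim import (
    DEFAULT_REGIONS,
    GeneRegion,
    SummaryRecord,
    analyze_region,
    check_allele_consistency,
    classify,
    compute_z,
    extract_region,
    flag_palindromic,
    harmonize_effects,
    read_summary_stats,
    region_summary,
    z_to_p,
)
from sexdim.gwas import AlleleMismatchError, ColumnMapError

CMAP = {
    "chrom": "chr", "pos": "position", "rsid": "snp",
    "tested_allele": "ea", "other_allele": "oa", "freq": "eaf",
    "beta_female": "beta_f", "se_female": "se_f", "p_female": "p_f",
    "beta_male": "beta_m", "se_male": "se_m", "p_male": "p_m",
    "p_combined": "p_all",
}

HEADER = "chr\tposition\tsnp\tea\toa\teaf\tbeta_f\tse_f\tp_f\tbeta_m\tse_m\tp_m\tp_all\n"


def _row(rsid="rs1", pos=100, freq=0.3, se_f="0.01", chrom="14"):
    return (
        f"{chrom}\t{pos}\t{rsid}\tA\tG\t{freq}\t0.02\t{se_f}\t0.001\t"
        "0.01\t0.012\t0.2\t0.005\n"
    )


class TestReadSummaryStats:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text(HEADER + _row("rs1", 100) + _row("rs2", 200) + _row("rs3", 300))
        recs = read_summary_stats(path, CMAP)
        assert [r.rsid for r in recs] == ["rs1", "rs2", "rs3"]
        assert recs[0].pos == 100 and recs[0].freq_tested == 0.3
        assert recs[0].beta_female == 0.02 and recs[0].se_male == 0.012

    def test_unparseable_row_skipped(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text(HEADER + _row("rs1") + _row("rs2", se_f="NA"))
        recs = read_summary_stats(path, CMAP)
        assert [r.rsid for r in recs] == ["rs1"]
        assert read_summary_stats.last_skipped == 1

    def test_missing_mapped_column_names_it(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("chr\tposition\n14\t1\n")
        with pytest.raises(ColumnMapError, match="snp"):
            read_summary_stats(path, CMAP)

    def test_gzip_transparent(self, tmp_path):
        import gzip

        path = tmp_path / "ss.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(HEADER + _row("rs1"))
        assert len(read_summary_stats(path, CMAP)) == 1


class TestRegions:
    def test_default_regions_match_candidate_coordinates(self):
        ckb, merged = DEFAULT_REGIONS
        assert (ckb.region_start, ckb.region_end) == (103_486_004, 104_489_167)
        assert (merged.region_start, merged.region_end) == (43_385_055, 46_194_425)

    @pytest.mark.parametrize(
        "pos,included,core",
        [
            (103_486_004, True, False),   # region_start boundary
            (104_489_167, True, False),   # region_end boundary
            (103_986_004, True, True),    # core gene boundary
            (103_486_003, False, None),
            (104_489_168, False, None),
        ],
    )
    def test_closed_interval_membership(self, record, pos, included, core):
        region = DEFAULT_REGIONS[0]
        rec = replace(record, pos=pos)
        out = extract_region([rec], region)
        assert bool(out) is included
        if included:
            assert out[0].in_core_gene is core

    def test_other_chromosome_excluded(self, record):
        rec = replace(record, chrom="2")
        assert extract_region([rec], DEFAULT_REGIONS[0]) == []

    def test_merged_region_core_excludes_gap(self):
        merged = DEFAULT_REGIONS[1]
        assert merged.in_core("15", 43_885_055)
        assert merged.in_core("15", 45_694_425)
        assert not merged.in_core("15", 44_800_000)  # between the two genes

    def test_flank_clipped_at_one(self):
        r = GeneRegion("g", "1", 1000, 2000, flank=5000)
        assert r.region_start == 1


class TestPalindromicFilter:
    @pytest.mark.parametrize(
        "tested,other,freq,excluded",
        [
            ("A", "T", 0.50, True),
            ("C", "G", 0.48, True),   # closed lower bound
            ("G", "C", 0.52, True),   # closed upper bound (as 1-freq view)
            ("A", "G", 0.50, False),  # non-palindromic
            ("C", "G", 0.10, False),  # outside frequency window
            ("T", "A", 0.479, False),
        ],
    )
    def test_exclusion_rule(self, record, tested, other, freq, excluded):
        rec = replace(record, tested_allele=tested, other_allele=other,
                      freq_tested=freq)
        assert flag_palindromic(rec) is excluded

    def test_major_allele_frequency_uses_maf(self, record):
        rec = replace(record, tested_allele="A", other_allele="T",
                      freq_tested=0.51)
        assert flag_palindromic(rec)  # maf = 0.49 inside window

    def test_no_frequency_keeps_with_warning(self, record, caplog):
        rec = replace(record, tested_allele="A", other_allele="T",
                      freq_tested=None)
        with caplog.at_level("WARNING"):
            assert flag_palindromic(rec) is False
        assert "palindromic" in caplog.text


class TestHarmonize:
    def test_major_tested_flips_betas_and_alleles(self, record):
        rec = replace(record, freq_tested=0.61, beta_female=0.02,
                      beta_male=0.008)
        out = harmonize_effects(rec)
        assert out.freq_tested == pytest.approx(0.39)
        assert out.beta_female == -0.02 and out.beta_male == -0.008
        assert (out.tested_allele, out.other_allele) == (
            rec.other_allele, rec.tested_allele
        )
        assert out.harmonized

    def test_minor_tested_unchanged(self, record):
        assert harmonize_effects(record) is record

    def test_half_frequency_tie_is_no_action(self, record):
        rec = replace(record, freq_tested=0.5)
        assert harmonize_effects(rec) is rec

    def test_missing_frequency_unchanged(self, record):
        rec = replace(record, freq_tested=None)
        out = harmonize_effects(rec)
        assert out.harmonized is False and out.beta_female == rec.beta_female

    @given(freq=st.floats(0.0, 1.0), bf=st.floats(-1, 1), bm=st.floats(-1, 1))
    @settings(max_examples=100, derandomize=True)
    def test_idempotent(self, freq, bf, bm):
        rec = SummaryRecord(
            chrom="1", pos=1, rsid="rs", tested_allele="A", other_allele="G",
            freq_tested=freq, beta_female=bf, se_female=0.01, p_female=0.5,
            beta_male=bm, se_male=0.01, p_male=0.5,
        )
        once = harmonize_effects(rec)
        assert harmonize_effects(once) == once

    @given(freq=st.floats(0.501, 1.0), bf=st.floats(-1, 1), bm=st.floats(-1, 1))
    @settings(max_examples=100, derandomize=True)
    def test_preserves_absolute_z(self, freq, bf, bm):
        rec = SummaryRecord(
            chrom="1", pos=1, rsid="rs", tested_allele="A", other_allele="G",
            freq_tested=freq, beta_female=bf, se_female=0.01, p_female=0.5,
            beta_male=bm, se_male=0.01, p_male=0.5,
        )
        assert abs(compute_z(harmonize_effects(rec))) == pytest.approx(
            abs(compute_z(rec))
        )


class TestAlleleConsistency:
    def _single(self, tested, other, beta_m=0.01, rsid="rs9", freq=0.3):
        return SummaryRecord(
            chrom="1", pos=5, rsid=rsid, tested_allele=tested,
            other_allele=other, freq_tested=freq, beta_female=0.02,
            se_female=0.01, p_female=0.1, beta_male=beta_m, se_male=0.01,
            p_male=0.2,
        )

    def test_identical_assignment_merges_unchanged(self):
        f = self._single("A", "G")
        m = self._single("A", "G", beta_m=0.015)
        merged = check_allele_consistency(f, m)
        assert merged.beta_male == 0.015 and merged.beta_female == 0.02

    def test_swapped_assignment_negates_male_beta(self):
        f = self._single("A", "G")
        m = self._single("G", "A", beta_m=0.01)
        merged = check_allele_consistency(f, m)
        assert merged.beta_male == -0.01

    def test_irreconcilable_alleles_excluded(self):
        f = self._single("A", "G")
        m = self._single("C", "T")
        assert check_allele_consistency(f, m) is None

    def test_rsid_mismatch_is_usage_error(self):
        f = self._single("A", "G", rsid="rs1")
        m = self._single("A", "G", rsid="rs2")
        with pytest.raises(AlleleMismatchError):
            check_allele_consistency(f, m)


class TestZScore:
    def test_equal_betas_give_zero(self, record):
        rec = replace(record, beta_female=0.01, beta_male=0.01)
        assert compute_z(rec) == 0.0

    def test_closed_form_unit_case(self, record):
        rec = replace(record, beta_female=1.0, beta_male=0.0,
                      se_female=1.0, se_male=1.0)
        assert compute_z(rec) == pytest.approx(1 / math.sqrt(2))

    @given(
        bf=st.floats(-0.1, 0.1), bm=st.floats(-0.1, 0.1),
        sf=st.floats(1e-4, 0.1), sm=st.floats(1e-4, 0.1),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_direct_formula_and_antisymmetry(self, bf, bm, sf, sm):
        rec = SummaryRecord(
            chrom="1", pos=1, rsid="rs", tested_allele="A", other_allele="G",
            freq_tested=0.2, beta_female=bf, se_female=sf, p_female=0.5,
            beta_male=bm, se_male=sm, p_male=0.5,
        )
        swapped = replace(rec, beta_female=bm, se_female=sm,
                          beta_male=bf, se_male=sf)
        expected = (bf - bm) / math.sqrt(sf**2 + sm**2)
        assert compute_z(rec) == pytest.approx(expected, rel=1e-12)
        assert compute_z(swapped) == pytest.approx(-compute_z(rec), abs=1e-12)

    def test_missing_inputs_rejected(self, record):
        with pytest.raises(ValueError):
            compute_z(replace(record, beta_male=None))


class TestZToP:
    @pytest.mark.parametrize(
        "z,expected,tol",
        [
            (3.196, 0.00139, 1e-5),
            (4.27, 1.96e-5, 2e-7),
            (0.38, 0.7039, 1e-4),
            (0.0, 1.0, 0),
        ],
    )
    def test_reference_values(self, z, expected, tol):
        assert z_to_p(z) == pytest.approx(expected, abs=tol)

    @given(st.floats(0, 10), st.floats(0, 10))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_decreasing_in_magnitude(self, a, b):
        lo, hi = sorted((a, b))
        assert z_to_p(hi) <= z_to_p(lo)
        if hi - lo > 1e-6:  # strict once beyond float rounding of the tail
            assert z_to_p(hi) < z_to_p(lo)
        assert z_to_p(-a) == z_to_p(a)

    def test_infinite_z_rejected(self):
        with pytest.raises(ValueError):
            z_to_p(float("inf"))


class TestClassify:
    def test_z_threshold_inclusive(self, record):
        assert classify(record, 3.0).is_dimorphic
        assert not classify(record, 2.999999).is_dimorphic

    def test_gwas_threshold_strict(self, record):
        rec = replace(record, p_female=5e-8)
        assert not classify(rec, 1.0).is_trait_associated_female
        rec = replace(record, p_female=4.9e-8)
        assert classify(rec, 1.0).is_trait_associated_female

    def test_excluded_record_carries_no_z(self, record):
        res = classify(record, 5.0, excluded="palindromic-ambiguous")
        assert res.z is None and res.p_dimorphism is None
        assert not res.is_dimorphic

    def test_empty_region_summary(self):
        s = region_summary([], DEFAULT_REGIONS[0])
        assert s["total"]["n_snps"] == 0
        assert s["total"]["pct_dimorphic"] == 0.0


class TestAnalyzeRegion:
    def _records(self):
        base = dict(chrom="14", se_female=0.01, p_female=0.5,
                    se_male=0.01, p_male=0.5)
        return [
            SummaryRecord(pos=103_986_100, rsid="dimorphic", tested_allele="A",
                          other_allele="G", freq_tested=0.3, beta_female=0.10,
                          beta_male=0.0, **base),
            SummaryRecord(pos=103_986_200, rsid="palindrome", tested_allele="A",
                          other_allele="T", freq_tested=0.5, beta_female=0.10,
                          beta_male=0.0, **base),
            SummaryRecord(pos=103_986_300, rsid="majorflip", tested_allele="A",
                          other_allele="G", freq_tested=0.7, beta_female=0.10,
                          beta_male=0.0, **base),
            SummaryRecord(pos=103_986_400, rsid="incomplete", tested_allele="A",
                          other_allele="G", freq_tested=0.3, beta_female=None,
                          beta_male=0.0, **base),
        ]

    def test_pipeline_order_and_flags(self):
        results = {r.rsid: r for r in
                   analyze_region(self._records(), DEFAULT_REGIONS[0])}
        assert results["dimorphic"].is_dimorphic
        assert results["palindrome"].excluded == "palindromic-ambiguous"
        assert results["majorflip"].harmonized
        assert results["majorflip"].z == pytest.approx(
            -results["dimorphic"].z
        )
        assert results["incomplete"].excluded == "missing-fields"

    def test_frequency_free_mode_skips_scoring(self):
        recs = [replace(r, freq_tested=None) for r in self._records()
                if r.beta_female is not None]
        results = analyze_region(recs, DEFAULT_REGIONS[0])
        assert all(r.z is None for r in results)
        forced = analyze_region(recs, DEFAULT_REGIONS[0],
                                force_unharmonized=True)
        assert all(r.z is not None for r in forced)
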