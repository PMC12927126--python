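"""Tests for the SNP-index statistics, filtering, smoothing and localization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import emsmap
from emsmap.bsa import DEFAULT_MODEL
from emsmap.exceptions import NoSignalError
from emsmap.io import PoolObservation


def marker_row(chrom, pos, wp, mp, impact="", effect="", **extra):
    row = dict(
        chromosome=chrom, position=pos, ref="C", alt="T",
        ad_ref_wp=wp[0], ad_alt_wp=wp[1], ad_ref_mp=mp[0], ad_alt_mp=mp[1],
        effect=effect, impact=impact, gene_id="", hgvs_c="", hgvs_p="",
    )
    row.update(extra)
    return row


class TestSnpIndex:
    @pytest.mark.parametrize(
        "ad_ref,ad_alt,expected",
        [(10, 20, 20 / 30), (0, 28, 1.0), (28, 0, 0.0)],
    )
    def test_examples(self, ad_ref, ad_alt, expected):
        assert emsmap.snp_index(PoolObservation(ad_ref, ad_alt)) == pytest.approx(expected)

    def test_zero_depth_is_undefined(self):
        with pytest.raises(ValueError):
            emsmap.snp_index(PoolObservation(0, 0))

    @given(st.integers(0, 500), st.integers(0, 500))
    def test_bounded_in_unit_interval(self, ad_ref, ad_alt):
        if ad_ref + ad_alt == 0:
            return
        assert 0.0 <= emsmap.snp_index((ad_ref, ad_alt)) <= 1.0


class TestSnpIndexDiv:
    def test_zero_at_theoretical_indices(self):
        assert emsmap.snp_index_div(1 / 3, 1.0) == 0.0

    def test_unlinked_heterozygous_marker(self):
        assert emsmap.snp_index_div(0.5, 0.5) == pytest.approx(1 / 6 + 1 / 2)

    def test_fixed_marker(self):
        assert emsmap.snp_index_div(1.0, 1.0) == pytest.approx(2 / 3)

    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_bounds(self, idx_wp, idx_mp):
        value = emsmap.snp_index_div(idx_wp, idx_mp)
        assert 0.0 <= value <= 5 / 3 + 1e-12

    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_monotone_in_wp_deviation(self, idx_mp, wp_a, wp_b):
        # the closer the WP index is to its theoretical value, the smaller DIV
        theo = DEFAULT_MODEL.theo_wp
        near, far = sorted((wp_a, wp_b), key=lambda x: abs(x - theo))
        assert emsmap.snp_index_div(near, idx_mp) <= emsmap.snp_index_div(far, idx_mp) + 1e-12


class TestScoreMarkers:
    def test_filter_flags_use_strict_inequality(self):
        # DIV values 0, 0.3, exactly 1/3 (computed from 2/3 vs 1), and 0.5
        df = pd.DataFrame(
            [
                marker_row("chr1", 10, (20, 10), (0, 30)),
                marker_row("chr1", 20, (20, 10), (9, 21)),
                marker_row("chr1", 30, (20, 10), (10, 20)),
                marker_row("chr1", 40, (20, 10), (15, 15)),
            ]
        )
        scored = emsmap.score_markers(df)
        assert scored["snp_index_div"].tolist() == pytest.approx(
            [0.0, 0.3, 1 / 3, 0.5], abs=1e-12
        )
        assert scored["passes_filter"].tolist() == [True, True, False, False]

    def test_low_depth_markers_excluded_and_counted(self):
        df = pd.DataFrame(
            [
                marker_row("chr1", 10, (1, 1), (15, 15)),  # WP depth 2 < 5
                marker_row("chr1", 20, (0, 0), (15, 15)),  # zero depth
                marker_row("chr1", 30, (20, 10), (0, 30)),
            ]
        )
        scored = emsmap.score_markers(df)
        assert len(scored) == 1
        assert scored.attrs["n_input"] == 3
        assert scored.attrs["n_excluded"] == 2

    def test_min_depth_zero_still_excludes_zero_depth(self):
        df = pd.DataFrame([marker_row("chr1", 10, (0, 0), (1, 1))])
        with pytest.warns(UserWarning, match="no scorable markers"):
            scored = emsmap.score_markers(df, emsmap.TheoreticalModel(min_depth=0))
        assert len(scored) == 0

    def test_causal_like_marker_passes(self):
        df = pd.DataFrame([marker_row("chr5", 99, (20, 10), (0, 30))])
        scored = emsmap.score_markers(df)
        assert scored["snp_index_div"].iloc[0] == 0.0
        assert bool(scored["passes_filter"].iloc[0])

    def test_record_and_dataframe_routes_agree(self, tiny_dataset):
        records = tiny_dataset.variants[:100]
        from_records = emsmap.score_markers(records)
        from_frame = emsmap.score_markers(emsmap.io.variants_to_dataframe(records))
        pd.testing.assert_frame_equal(from_records, from_frame)

    def test_empty_input_warns(self):
        df = pd.DataFrame([marker_row("chr1", 10, (0, 0), (0, 0))])
        with pytest.warns(UserWarning, match="no scorable markers"):
            emsmap.score_markers(df)


class TestSelectCandidateChromosome:
    def test_argmax_of_filtered_counts(self):
        chromosomes = ["chr1"] * 2 + ["chr5"] * 40 + ["chr7"] * 3
        assert emsmap.select_candidate_chromosome(chromosomes) == "chr5"

    def test_single_marker(self):
        assert emsmap.select_candidate_chromosome(["chr3"]) == "chr3"

    def test_tie_broken_by_natural_order(self):
        assert emsmap.select_candidate_chromosome(["chr2", "chr1", "chr1", "chr2"]) == "chr1"
        assert emsmap.select_candidate_chromosome(["chr10", "chr2"] * 3) == "chr2"

    def test_empty_input_raises(self):
        with pytest.raises(NoSignalError):
            emsmap.select_candidate_chromosome([])


class TestSmoothTrack:
    def test_constant_values_unchanged(self):
        positions = np.arange(0, 10_000, 1000)
        smoothed = emsmap.smooth_track(positions, np.full(10, 0.7), 2000)
        np.testing.assert_allclose(smoothed, 0.7)

    def test_single_point_returns_itself(self):
        assert emsmap.smooth_track([5], [0.3], 1000)[0] == pytest.approx(0.3)

    def test_tent_profile_peaks_at_center(self):
        positions = np.arange(21) * 100.0
        values = 1.0 - np.abs(positions - 1000.0) / 1000.0
        smoothed = emsmap.smooth_track(positions, values, 500.0)
        assert int(np.argmax(smoothed)) == 10
        # oracle: direct evaluation of the tricube Nadaraya-Watson formula
        expected = []
        for p in positions:
            u = np.abs(positions - p) / 500.0
            w = np.where(u < 1, (1 - u**3) ** 3, 0.0)
            expected.append((w * values).sum() / w.sum())
        np.testing.assert_allclose(smoothed, expected, atol=1e-12)

    def test_output_bounded_by_observed_range(self, rng):
        positions = np.sort(rng.integers(0, 10**6, 200))
        values = rng.random(200)
        smoothed = emsmap.smooth_track(positions, values, 50_000)
        assert smoothed.min() >= values.min() - 1e-12
        assert smoothed.max() <= values.max() + 1e-12

    def test_unsorted_positions_raise(self):
        with pytest.raises(ValueError):
            emsmap.smooth_track([3, 1, 2], [0.1, 0.2, 0.3], 10)


class TestLocatePeak:
    def test_argmax_position(self):
        assert emsmap.locate_peak([10, 20, 30], [0.2, 0.9, 0.4]) == 20

    def test_tie_takes_smallest_position(self):
        assert emsmap.locate_peak([10, 20, 30], [0.5, 0.5, 0.5]) == 10


class TestRankCandidates:
    def test_rule_application(self):
        peak = 1_000_000
        df = pd.DataFrame(
            [
                marker_row("chr1", peak + 500_000, (20, 10), (0, 30), impact="HIGH",
                           effect="stop_gained", snp_index_mp=1.0, position=peak + 500_000),
                marker_row("chr1", peak + 100_000, (20, 10), (0, 30), impact="MODERATE",
                           effect="missense", snp_index_mp=1.0),
                marker_row("chr1", peak, (20, 10), (3, 27), impact="HIGH",
                           effect="stop_gained", snp_index_mp=0.9),
            ]
        )
        ranked = emsmap.rank_candidates(df, peak, homozygosity_tolerance=0.0)
        assert ranked["position"].tolist() == [peak + 100_000, peak + 500_000]

    def test_high_impact_breaks_distance_ties(self):
        peak = 100
        df = pd.DataFrame(
            [
                marker_row("chr1", 90, (20, 10), (0, 30), impact="MODERATE",
                           effect="missense", snp_index_mp=1.0),
                marker_row("chr1", 110, (20, 10), (0, 30), impact="HIGH",
                           effect="stop_gained", snp_index_mp=1.0),
            ]
        )
        ranked = emsmap.rank_candidates(df, peak)
        assert ranked["impact"].tolist() == ["HIGH", "MODERATE"]

    def test_tolerance_admits_near_homozygous(self):
        df = pd.DataFrame(
            [marker_row("chr1", 10, (20, 10), (1, 29), impact="HIGH",
                        effect="stop_gained", snp_index_mp=29 / 30)]
        )
        assert len(emsmap.rank_candidates(df, 10, homozygosity_tolerance=0.0)) == 0
        assert len(emsmap.rank_candidates(df, 10, homozygosity_tolerance=0.05)) == 1

    def test_two_surviving_candidates_both_reported(self):
        # mirrors the situation where two homozygous MODERATE/HIGH mutations
        # survive and the pipeline deliberately reports both
        df = pd.DataFrame(
            [
                marker_row("chr1", 200, (20, 10), (0, 30), impact="HIGH",
                           effect="start_lost", snp_index_mp=1.0),
                marker_row("chr1", 900, (20, 10), (0, 30), impact="MODERATE",
                           effect="missense", snp_index_mp=1.0),
            ]
        )
        assert len(emsmap.rank_candidates(df, 250)) == 2

    def test_modifier_and_unannotated_excluded(self):
        df = pd.DataFrame(
            [
                marker_row("chr1", 10, (20, 10), (0, 30), impact="MODIFIER",
                           effect="intergenic", snp_index_mp=1.0),
                marker_row("chr1", 20, (20, 10), (0, 30), impact="",
                           effect="", snp_index_mp=1.0),
            ]
        )
        assert len(emsmap.rank_candidates(df, 10)) == 0


class TestModelFit:
    def test_recovers_candidate_chromosome_and_gene(self, tiny_dataset):
        model = emsmap.BulkedSegregantAnalysis(tiny_dataset.variants)
        results = model.fit(bandwidth=40_000)
        assert results.candidate_chromosome == tiny_dataset.truth.chromosome
        assert abs(results.peak_position - tiny_dataset.truth.position) < 100_000
        assert results.n_detected == len(tiny_dataset.variants)
        lo, hi = results.candidate_interval
        assert lo <= results.peak_position <= hi

    def test_summary_mentions_key_quantities(self, tiny_dataset):
        results = emsmap.BulkedSegregantAnalysis(tiny_dataset.variants).fit(bandwidth=40_000)
        text = results.summary()
        assert "SNPs detected" in text
        assert results.candidate_chromosome in text

    def test_report_dict_is_json_safe(self, tiny_dataset):
        import json

        results = emsmap.BulkedSegregantAnalysis(tiny_dataset.variants).fit(bandwidth=40_000)
        payload = json.loads(json.dumps(results.to_dict()))
        assert payload["candidate_chromosome"] == results.candidate_chromosome
        assert payload["n_filtered"] == results.n_filtered

    def test_no_signal_produces_empty_results_with_warning(self):
        # unlinked-style markers only: DIV = 2/3 everywhere, nothing passes
        df = pd.DataFrame(
            [marker_row("chr1", p, (15, 15), (15, 15)) for p in range(10, 100, 10)]
        )
        model = emsmap.BulkedSegregantAnalysis(df)
        with pytest.warns(UserWarning, match="zero filtered markers"):
            results = model.fit()
        assert results.candidate_chromosome is None
        assert results.ranked_candidates.empty

    def test_vcf_and_table_constructors_agree(self, tmp_path, tiny_dataset):
        from emsmap.io import write_pooled_vcf, write_variants_table

        variants = tiny_dataset.variants
        vcf = write_pooled_vcf(variants, tmp_path / "p.vcf")
        tsv = write_variants_table(variants, tmp_path / "p.tsv")
        res_vcf = emsmap.BulkedSegregantAnalysis.from_vcf(vcf).fit(bandwidth=40_000)
        res_tsv = emsmap.BulkedSegregantAnalysis.from_table(tsv).fit(bandwidth=40_000)
        assert res_vcf.candidate_chromosome == res_tsv.candidate_chromosome
        assert res_vcf.peak_position == res_tsv.peak_position
        pd.testing.assert_series_equal(
            res_vcf.markers["snp_index_div"], res_tsv.markers["snp_index_div"]
        )
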