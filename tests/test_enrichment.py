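import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ipenrich import (
    AnalysisConfig,
    ProteinTable,
    assign_intensity_bins,
    bin_fences,
    call_significance,
    compute_log2_ratios,
    filter_identifications,
    impute_missing_controls,
    pooled_log10_quantile,
    run_pipeline,
    sample_imputed_log10,
)
from ipenrich.enrichment import LOG10_2, EnrichmentRecord

from conftest import classify_oracle, fences_oracle, make_record, quantile_oracle


def ratio_records(ratios, bin_index=0):
    return [
        EnrichmentRecord(
            protein_ids=f"P{i}", gene_names="", peptides_razor_unique=5,
            log10_bait=7.0, log10_control=7.0 - r * LOG10_2,
            control_imputed=False, log2_ratio=float(r), bin_index=bin_index,
        )
        for i, r in enumerate(ratios)
    ]


class TestFiltering:
    def test_peptide_threshold_keeps_two_and_above(self):
        table = ProteinTable(
            records=[make_record(f"P{n}", peptides=n) for n in (1, 2, 3)]
        )
        kept, dismissed = filter_identifications(table, AnalysisConfig())
        assert [r.protein_ids for r in kept] == ["P2", "P3"]
        assert [d.protein_ids for d in dismissed] == ["P1"]

    @pytest.mark.parametrize(
        "kwargs, reason_part",
        [
            ({"is_reverse": True}, "decoy"),
            ({"is_contaminant": True}, "contaminant"),
            ({"is_site_only": True}, "site"),
            ({"bait": None}, "bait"),
        ],
    )
    def test_flagged_or_bait_missing_records_removed(self, kwargs, reason_part):
        table = ProteinTable(records=[make_record("BAD", **kwargs), make_record("OK")])
        kept, dismissed = filter_identifications(table, AnalysisConfig())
        assert [r.protein_ids for r in kept] == ["OK"]
        assert dismissed[0].protein_ids == "BAD"
        assert reason_part in dismissed[0].reason

    def test_site_only_retained_when_toggled_off(self):
        table = ProteinTable(records=[make_record("SITE", is_site_only=True)])
        kept, _ = filter_identifications(table, AnalysisConfig(drop_site_only=False))
        assert len(kept) == 1

    def test_every_input_record_is_accounted_for(self, twelve_record_table):
        config = AnalysisConfig()
        kept, dismissed = filter_identifications(twelve_record_table, config)
        assert len(kept) + len(dismissed) == len(twelve_record_table)
        assert not any(
            r.is_contaminant or r.is_reverse or r.is_site_only
            or r.peptides_razor_unique < config.min_peptides_observed
            or r.lfq_bait is None
            for r in kept
        )


class TestPooledQuantile:
    def test_constant_distribution_returns_its_log10(self):
        table = ProteinTable(
            records=[make_record(f"P{i}", bait=1e6, control=1e6) for i in range(5)]
        )
        for level in (0.05, 0.5, 0.95):
            assert pooled_log10_quantile(table, level) == pytest.approx(6.0)

    def test_median_of_three_pooled_values(self):
        # one record contributes bait 10^1 and control 10^3, one bait 10^2 only
        table = ProteinTable(
            records=[
                make_record("P1", bait=10.0, control=1000.0),
                make_record("P2", bait=100.0, control=None),
            ]
        )
        assert pooled_log10_quantile(table, 0.5) == pytest.approx(2.0)

    def test_matches_brute_force_oracle_on_twenty_values(self):
        rng = np.random.default_rng(42)
        log10s = rng.uniform(4, 9, size=20)
        table = ProteinTable(
            records=[
                make_record(f"P{i}", bait=10.0 ** v, control=None)
                for i, v in enumerate(log10s)
            ]
        )
        assert pooled_log10_quantile(table, 0.05) == pytest.approx(
            quantile_oracle(log10s, 0.05), abs=1e-12
        )

    def test_no_observed_intensity_is_a_domain_error(self):
        with pytest.raises(ValueError, match="no observed"):
            pooled_log10_quantile(ProteinTable(records=[]), 0.05)


class TestImputation:
    def test_no_missing_controls_is_a_no_op(self):
        table = ProteinTable(records=[make_record(f"P{i}") for i in range(4)])
        result = impute_missing_controls(table, AnalysisConfig())
        assert result.table == table
        assert result.imputed_ids == set() and result.dismissals == []

    def test_missing_control_below_imputation_threshold_dismissed(self):
        table = ProteinTable(
            records=[
                make_record("TOOFEW", peptides=2, control=None),
                make_record("ENOUGH", peptides=3, control=None),
            ]
        )
        result = impute_missing_controls(table, AnalysisConfig(rng_seed=0))
        assert [r.protein_ids for r in result.table] == ["ENOUGH"]
        assert result.imputed_ids == {"ENOUGH"}
        assert result.dismissals[0].protein_ids == "TOOFEW"
        assert "3" in result.dismissals[0].reason

    def test_imputed_draws_follow_the_baseline_normal_law(self):
        # Monte-Carlo check: mean at the 5% pooled quantile, SD 0.1.
        rng_pool = np.random.default_rng(7)
        pooled = rng_pool.normal(6.5, 1.0, size=10_000)
        config = AnalysisConfig()
        draws = sample_imputed_log10(
            100_000, pooled, config, np.random.default_rng(11)
        )
        assert draws.mean() == pytest.approx(np.quantile(pooled, 0.05), abs=0.002)
        assert draws.std(ddof=1) == pytest.approx(0.1, abs=0.002)

    def test_identical_seed_identical_output_and_seed_touches_only_imputed(self):
        records = [make_record(f"P{i}") for i in range(6)] + [
            make_record(f"M{i}", control=None) for i in range(3)
        ]
        table = ProteinTable(records=records)
        first = impute_missing_controls(table, AnalysisConfig(rng_seed=5))
        again = impute_missing_controls(table, AnalysisConfig(rng_seed=5))
        other = impute_missing_controls(table, AnalysisConfig(rng_seed=6))
        assert first.table == again.table
        for a, b in zip(first.table, other.table):
            if a.protein_ids in first.imputed_ids:
                assert a.lfq_control != b.lfq_control
            else:
                assert a == b


class TestRatios:
    @pytest.mark.parametrize(
        "bait, control, expected",
        [(1e6, 1e6, 0.0), (4e5, 1e5, 2.0)],
    )
    def test_simple_ratios(self, bait, control, expected):
        table = ProteinTable(records=[make_record("P1", bait=bait, control=control)])
        (rec,) = compute_log2_ratios(table)
        assert rec.log2_ratio == pytest.approx(expected, abs=1e-12)

    def test_closed_form_log10_difference(self):
        table = ProteinTable(
            records=[make_record("P1", bait=10.0 ** 7.3, control=10.0 ** 6.1)]
        )
        (rec,) = compute_log2_ratios(table)
        assert rec.log2_ratio == pytest.approx(1.2 / math.log10(2), abs=1e-9)
        assert rec.log2_ratio == pytest.approx(
            (rec.log10_bait - rec.log10_control) / math.log10(2), abs=1e-12
        )

    def test_missing_value_here_is_a_contract_violation(self):
        table = ProteinTable(records=[make_record("P1", control=None)])
        with pytest.raises(ValueError, match="missing"):
            compute_log2_ratios(table)


class TestBinning:
    @pytest.mark.parametrize(
        "n, expected_sizes",
        [(250, [250]), (1000, [334, 333, 333]), (650, [325, 325])],
    )
    def test_partition_sizes(self, n, expected_sizes):
        rng = np.random.default_rng(0)
        records = ratio_records(rng.normal(0, 1, size=n))
        for rec, intensity in zip(records, rng.uniform(4, 9, size=n)):
            rec.log10_bait = float(intensity)
            rec.bin_index = -1
        assign_intensity_bins(records, AnalysisConfig())
        sizes = np.bincount([r.bin_index for r in records])
        assert sorted(sizes.tolist(), reverse=True) == expected_sizes

    def test_bins_are_contiguous_in_intensity_and_ordered(self):
        rng = np.random.default_rng(1)
        records = ratio_records(rng.normal(0, 1, size=700))
        for rec, intensity in zip(records, rng.uniform(4, 9, size=700)):
            rec.log10_bait = float(intensity)
        assign_intensity_bins(records, AnalysisConfig())
        by_intensity = sorted(records, key=lambda r: r.log10_bait)
        indices = [r.bin_index for r in by_intensity]
        assert indices == sorted(indices)  # bin 0 = lowest intensities

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(n=st.integers(1, 1500), min_bin_size=st.integers(1, 400))
    def test_partition_rule_property(self, n, min_bin_size):
        records = ratio_records(np.zeros(n))
        for i, rec in enumerate(records):
            rec.log10_bait = 5.0 + (i % 7) * 0.1
            rec.bin_index = -1
        config = AnalysisConfig(min_bin_size=min_bin_size)
        assign_intensity_bins(records, config)
        sizes = np.bincount([r.bin_index for r in records])
        assert len(sizes) == max(1, n // min_bin_size)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.min() >= min(n, min_bin_size)

    def test_ties_broken_by_stable_input_order(self):
        records = ratio_records(np.arange(4))
        for rec in records:
            rec.log10_bait = 6.0
            rec.bin_index = -1
        assign_intensity_bins(records, AnalysisConfig(min_bin_size=2))
        assert [r.bin_index for r in records] == [0, 0, 1, 1]


class TestFences:
    @pytest.mark.parametrize(
        "multiplier, expected",
        [(1.5, (-1.0, 7.0)), (3.0, (-4.0, 10.0))],
    )
    def test_worked_example(self, multiplier, expected):
        # Q1 = 2, Q3 = 4 under linear interpolation
        assert bin_fences([1, 2, 3, 4, 100], multiplier) == pytest.approx(expected)
        assert fences_oracle([1, 2, 3, 4, 100], multiplier) == pytest.approx(expected)

    def test_constant_bin_collapses_fences(self):
        assert bin_fences([3.3] * 10, 1.5) == pytest.approx((3.3, 3.3))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        ratios=st.lists(
            st.floats(-20, 20, allow_nan=False), min_size=2, max_size=40
        ),
        multiplier=st.floats(0.1, 5.0),
    )
    def test_matches_brute_force_oracle(self, ratios, multiplier):
        assert bin_fences(ratios, multiplier) == pytest.approx(
            fences_oracle(ratios, multiplier), abs=1e-9
        )


class TestSignificance:
    @pytest.mark.parametrize(
        "ratios, expected_classes",
        [
            ([1, 2, 3, 4, 100], [0, 0, 0, 0, 2]),  # 100 > 10 = Q3 + 3*IQR
            ([1, 2, 3, 4, 8], [0, 0, 0, 0, 1]),    # 7 < 8 <= 10
            ([0, 0, 0, 0, 5], [0, 0, 0, 0, 2]),    # IQR 0: any distinct value
        ],
    )
    def test_single_bin_worked_examples(self, ratios, expected_classes):
        records = call_significance(ratio_records(ratios), AnalysisConfig())
        assert [r.significance for r in records] == expected_classes
        assert records[-1].direction == "enriched"
        assert all(r.direction == "none" for r in records[:-1])

    def test_depleted_direction_on_low_outlier(self):
        records = call_significance(ratio_records([-100, 1, 2, 3, 4]), AnalysisConfig())
        assert records[0].significance == 2 and records[0].direction == "depleted"

    def test_unbinned_record_is_a_contract_violation(self):
        records = ratio_records([1, 2, 3])
        records[1].bin_index = -1
        with pytest.raises(ValueError, match="bin"):
            call_significance(records, AnalysisConfig())

    def test_matches_oracle_on_many_random_bins(self):
        # Full dual-route check on 1,000 random small bins.
        rng = np.random.default_rng(123)
        config = AnalysisConfig()
        for _ in range(1000):
            size = int(rng.integers(5, 50))
            ratios = rng.normal(0, 1, size=size) * rng.uniform(0.1, 3)
            records = call_significance(ratio_records(ratios), config)
            for rec in records:
                expected = classify_oracle(rec.log2_ratio, ratios)
                assert rec.significance == expected

    def test_raising_a_ratio_never_lowers_its_class(self):
        # Monotonicity, probe excluded from the fences as in the oracle.
        rng = np.random.default_rng(9)
        others = rng.normal(0, 1, size=60)
        classes = [
            classify_oracle(probe, others)
            for probe in np.linspace(0.0, 15.0, 400)
        ]
        assert classes == sorted(classes)


class TestPipeline:
    def test_twelve_record_fixture_keeps_eight(self, twelve_record_table):
        result = run_pipeline(twelve_record_table, AnalysisConfig(rng_seed=1))
        assert len(result.records) == 8
        assert len(result.dismissals) == 4
        stages = {d.protein_ids: d.stage for d in result.dismissals}
        assert stages["LOWEV_MISSING"] == "imputation"
        assert stages["CONTAM"] == stages["DECOY"] == stages["ONEPEP"] == "filter"

    def test_every_record_survives_or_is_logged(self, twelve_record_table):
        result = run_pipeline(twelve_record_table, AnalysisConfig(rng_seed=1))
        survivors = {r.protein_ids for r in result.records}
        logged = {d.protein_ids for d in result.dismissals}
        assert survivors | logged == {r.protein_ids for r in twelve_record_table}
        assert survivors & logged == set()

    def test_same_seed_gives_identical_results(self, twelve_record_table):
        config = AnalysisConfig(rng_seed=77)
        first = run_pipeline(twelve_record_table, config)
        second = run_pipeline(twelve_record_table, config)
        assert first.records == second.records
        assert first.dismissals == second.dismissals
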