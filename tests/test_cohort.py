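"""Cohort statistics: stage summaries, increments, folds, occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loricavol import (
    DivisionStage,
    LfmCategory,
    SpecimenRecord,
    ValidationError,
    category_table,
    elongation_percent,
    fold_range,
    occupancy,
    read_records_csv,
    stage_frequencies,
    stage_increments,
    stage_summary,
    swelling_factor,
    wall_summary,
    write_records_csv,
)

#: published per-stage means of total LFM with the ED baseline at 0 (µm³)
STAGE_MEANS = [0.0, 982.0, 3_212.0, 8_624.0, 12_679.0]


def rec(i, stage, **kwargs):
    return SpecimenRecord(id=str(i), stage=stage, **kwargs)


class TestStageSummary:
    def test_emd_mean_and_max(self):
        # two stand-in values completing the printed mean (982) and max (1,037)
        records = [
            rec(i, DivisionStage.EMD, lfm_total_um3=v)
            for i, v in enumerate([900.0, 1_009.0, 1_037.0])
        ]
        (s,) = stage_summary(records)
        assert (s.n, s.mean, s.max) == (3, pytest.approx(982.0), 1_037.0)

    def test_single_record_collapses(self):
        (s,) = stage_summary([rec(0, DivisionStage.VLD, lfm_total_um3=42.0)])
        assert s.mean == s.min == s.max == 42.0 and s.n == 1

    def test_missing_volumes_skipped_and_counted(self):
        records = [
            rec(0, DivisionStage.LMD, lfm_total_um3=100.0),
            rec(1, DivisionStage.LMD),
            rec(2, DivisionStage.ELD),
        ]
        (s,) = stage_summary(records)  # ELD has no data -> omitted
        assert s.stage is DivisionStage.LMD
        assert s.n == 1 and s.n_skipped == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            stage_summary([])


class TestStageIncrements:
    def test_published_means_give_published_increments(self):
        incs = stage_increments(STAGE_MEANS)
        assert [round(i["increment_um3"]) for i in incs] == \
            [982, 2_230, 5_412, 4_055]

    def test_percent_of_final(self):
        incs = stage_increments(STAGE_MEANS)
        percents = [i["percent_of_final"] for i in incs]
        assert percents == pytest.approx([7.745, 17.588, 42.685, 31.982],
                                         abs=0.001)
        assert [i["percent_of_final_rounded"] for i in incs] == [8, 18, 43, 32]

    def test_increments_sum_to_final_mean_exactly(self):
        incs = stage_increments(STAGE_MEANS)
        assert sum(i["increment_um3"] for i in incs) == STAGE_MEANS[-1]
        assert sum(i["percent_of_final"] for i in incs) == pytest.approx(100.0)

    def test_constant_means_give_zero_increments(self):
        incs = stage_increments([5.0, 5.0, 5.0])
        assert all(i["increment_um3"] == 0.0 for i in incs)

    def test_decreasing_means_warn_but_compute(self):
        with pytest.warns(UserWarning, match="not monotone"):
            incs = stage_increments([0.0, 10.0, 4.0, 8.0])
        assert incs[1]["increment_um3"] == -6.0

    @given(st.lists(st.floats(0.0, 1e5), min_size=2, max_size=8))
    @settings(derandomize=True, max_examples=100)
    def test_sums_are_invariant(self, means):
        means[-1] = max(means[-1], 1.0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            incs = stage_increments(means)
        total = sum(i["increment_um3"] for i in incs)
        assert total == pytest.approx(means[-1] - means[0],
                                      rel=1e-9, abs=1e-6)
        assert sum(i["percent_of_final"] for i in incs) == pytest.approx(
            100.0 * (means[-1] - means[0]) / means[-1], rel=1e-9, abs=1e-6
        )


class TestRatios:
    def test_occupancy_trivial_cases(self):
        assert occupancy(500.0, 500.0) == 100.0
        assert occupancy(0.0, 500.0) == 0.0

    def test_occupancy_summary_of_very_late_dividers(self):
        values = [2.3, 4.9, 7.2, 8.8, 10.3]
        assert np.mean(values) == pytest.approx(6.7, abs=0.05)

    def test_occupancy_requires_positive_cell_volume(self):
        with pytest.raises(ValidationError):
            occupancy(10.0, 0.0)

    def test_swelling_factor_conservative_bound(self):
        factor = swelling_factor(98_655.0, 21_860.0)
        assert factor == pytest.approx(4.513, abs=0.001)
        assert factor >= 4.5

    def test_swelling_trivial(self):
        assert swelling_factor(10.0, 10.0) == 1.0
        assert swelling_factor(20.0, 10.0) == 2.0
        with pytest.raises(ValidationError):
            swelling_factor(10.0, 0.0)

    @pytest.mark.parametrize(
        "values,expected",
        [
            ([4_806.0, 8_500.0, 9_547.0, 11_643.0], 2.4),  # early late dividers
            ([4_098.0, 7_000.0, 12_000.0, 18_437.0, 21_860.0], 5.3),  # VLD
            ([7.0, 7.0, 7.0], 1.0),
        ],
    )
    def test_fold_range(self, values, expected):
        assert fold_range(values)["fold_rounded"] == expected

    def test_fold_range_requires_positive_min(self):
        with pytest.raises(ValidationError):
            fold_range([0.0, 5.0])

    def test_scale_invariance_of_ratios(self):
        values = [4_098.0, 21_860.0]
        for s in (0.1, 3.7):
            assert fold_range([v * s for v in values])["fold"] == \
                pytest.approx(fold_range(values)["fold"])
            assert swelling_factor(98_655.0 * s, 21_860.0 * s) == \
                pytest.approx(swelling_factor(98_655.0, 21_860.0))
            assert occupancy(10.0 * s, 100.0 * s) == occupancy(10.0, 100.0)

    @pytest.mark.parametrize(
        "length,reference,expected",
        [
            (104.0, 72.0, 44),  # late dividers vs morphostatic specimens
            (97.0, 81.0, 20),   # middle vs early dividers
            (81.0, 72.0, 12),   # early dividers vs morphostatic specimens
        ],
    )
    def test_elongation_percent(self, length, reference, expected):
        assert round(elongation_percent(length, reference)) == expected


class TestStageFrequencies:
    def test_field_cohort_counts(self):
        out = stage_frequencies([210, 70, 43, 31, 13])
        assert list(out["percent_rounded"].values()) == [57, 19, 12, 8, 4]
        assert sum(out["percent"].values()) == pytest.approx(100.0)

    def test_trivial_splits(self):
        assert list(stage_frequencies([5, 0])["percent_rounded"].values()) == \
            [100, 0]
        assert list(stage_frequencies([3, 3])["percent_rounded"].values()) == \
            [50, 50]

    def test_invariant_under_uniform_scaling(self):
        a = stage_frequencies([210, 70, 43, 31, 13])["percent"]
        b = stage_frequencies([2100, 700, 430, 310, 130])["percent"]
        assert a == b

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            stage_frequencies([0, 0])


class TestWallSummary:
    def test_basic_statistics(self):
        out = wall_summary([1.0, 2.0, 3.0])
        assert out["mean"] == 2.0 and out["median"] == 2.0
        assert out["sd"] == pytest.approx(1.0)

    def test_sd_zero_iff_constant(self):
        assert wall_summary([4.0, 4.0, 4.0])["sd"] == 0.0
        assert wall_summary([4.0, 5.0])["sd"] > 0.0

    def test_single_value_omits_sd_with_notice(self):
        with pytest.warns(UserWarning, match="SD omitted"):
            assert wall_summary([9.0])["sd"] is None

    def test_negative_value_rejected(self):
        with pytest.raises(ValidationError):
            wall_summary([10.0, -1.0])


class TestRecordsRoundTrip:
    def test_csv_round_trip(self, tmp_path):
        records = [
            rec(0, DivisionStage.VLD, lfm_total_um3=21_860.0,
                lfm_anterior_um3=21_860.0, lfm_middle_um3=0.0,
                lfm_posterior_um3=0.0, category=LfmCategory.HIGH,
                cell_length_um=104.0, cell_width_um=73.0,
                wall_vol_um3=98_655.0),
            rec(1, DivisionStage.MORPHOSTATIC),
        ]
        path = tmp_path / "records.csv"
        write_records_csv(records, path)
        back = read_records_csv(path)
        assert [r.id for r in back] == ["0", "1"]
        assert back[0].lfm_total_um3 == 21_860.0
        assert back[0].category is LfmCategory.HIGH
        assert back[1].lfm_total_um3 is None

    def test_portion_sum_tolerance_enforced(self):
        with pytest.raises(ValidationError, match="portion sum"):
            rec(0, DivisionStage.VLD, lfm_total_um3=1_000.0,
                lfm_anterior_um3=500.0, lfm_middle_um3=100.0,
                lfm_posterior_um3=100.0)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValidationError):
            rec(0, DivisionStage.ED, lfm_total_um3=-5.0)

    def test_category_table_layout(self):
        records = [
            rec(0, DivisionStage.EMD, category=LfmCategory.LOW),
            rec(1, DivisionStage.EMD, category=LfmCategory.NONE),
            rec(2, DivisionStage.VLD, category=LfmCategory.HIGH),
        ]
        table = category_table(records)
        assert list(table.index) == ["ED", "EMD", "LMD", "ELD", "VLD"]
        assert table.loc["EMD", 1] == 1 and table.loc["VLD", 3] == 1
        assert table.to_numpy().sum() == 3
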