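"""First-crossing reduction, LOESS curves, bounded transition-day imputation."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenoqg as pq
from phenoqg.transitions import (
    TransitionError,
    _bracket,
    first_crossings,
    fit_curve,
    transition_day,
    validate_imputation,
)


class TestFirstCrossings:
    def test_keeps_first_day_of_each_attained_stage(self):
        d, s = first_crossings([100, 104, 106, 109], [1, 2, 2, 3])
        assert list(d) == [100, 104, 109]
        assert list(s) == [1, 2, 3]

    def test_single_observation_is_identity(self):
        d, s = first_crossings([100], [2])
        assert list(d) == [100] and list(s) == [2]

    def test_regressing_score_is_dropped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="phenoqg.transitions"):
            d, s = first_crossings([100, 104, 107], [3, 2, 4])
        assert list(d) == [100, 107]
        assert list(s) == [3, 4]
        assert any("regressing" in r.message for r in caplog.records)

    def test_empty_series_rejected(self):
        with pytest.raises(TransitionError, match="empty"):
            first_crossings([], [])

    def test_all_three_point_orderings_yield_monotone_output(self):
        # enumerate every score triple on a 3-point scale: the reduction must
        # always be strictly increasing and keep first occurrences
        for triple in itertools.product([1, 2, 3], repeat=3):
            d, s = first_crossings([10, 20, 30], list(triple))
            assert (np.diff(s) > 0).all()
            assert s[0] == triple[0]
            for day, stage in zip(d, s):
                assert triple[[10, 20, 30].index(day)] == stage

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=8), min_size=1, max_size=12))
    def test_output_is_subset_and_monotone(self, scores):
        days = np.arange(len(scores)) * 3 + 100
        d, s = first_crossings(days, scores)
        assert (np.diff(d) > 0).all() and (np.diff(s) > 0).all()
        assert set(zip(d, s)) <= set(zip(days, map(float, scores)))


class TestCurveAndTransitionDay:
    def test_two_points_degrade_to_linear_interpolation(self):
        curve = fit_curve([100, 110], [1, 5])
        day, source = transition_day(curve, 3)
        assert source == "imputed"
        assert day == pytest.approx(105, abs=0.02)

    def test_loess_reproduces_a_line_through_collinear_points(self):
        days = np.array([100.0, 105, 110, 115, 120])
        stages = 1 + (days - 100) / 5.0
        curve = fit_curve(days, stages)
        np.testing.assert_allclose(curve(days), stages, atol=1e-6)

    def test_sigmoid_series_fit_stays_within_quarter_stage(self):
        # sigmoid-like colouration series: slow-fast-slow progression
        days = np.array([100.0, 104, 107, 109, 111, 113, 116, 120])
        stages = np.arange(1.0, 9.0)
        curve = fit_curve(days, stages)
        assert np.abs(curve(days) - stages).max() <= 0.25

    def test_direct_observation_takes_precedence(self):
        curve = fit_curve([100, 107, 112], [1, 2, 3])
        day, source = transition_day(curve, 2)
        assert (day, source) == (107, "observed")

    def test_threshold_outside_observed_range_is_undefined(self):
        curve = fit_curve([100, 104, 108], [1, 2, 3])
        assert transition_day(curve, 4) == (None, "undefined")
        assert transition_day(curve, 0.5) == (None, "undefined")

    def test_crossing_matches_independent_bisection_oracle(self):
        # linear curve through (100,1),(104,3): root of curve(d)=2 by a
        # brute-force grid scan, vs the implementation
        curve = fit_curve([100, 104], [1, 3])
        grid = np.linspace(100, 104, 4001)
        oracle = grid[np.argmin(np.abs(curve(grid) - 2))]
        day, source = transition_day(curve, 2)
        assert source == "imputed"
        assert 100 < day < 104
        assert day == pytest.approx(oracle, abs=0.02)
        assert day == pytest.approx(102, abs=0.05)

    def test_fewer_than_two_points_is_rejected(self):
        with pytest.raises(TransitionError):
            fit_curve([100], [2])

    def test_bad_span_is_rejected(self):
        with pytest.raises(TransitionError, match="span"):
            fit_curve([100, 104], [1, 2], span=0.0)


class TestTransitionTable:
    def _survey(self, rows):
        return pd.DataFrame(
            rows, columns=["tree_id", "genotype_id", "year", "doy", "trait", "score"]
        )

    def test_fully_observed_tree_gives_ten_observed_rows(self):
        rows = []
        for year in (2017, 2018):
            for doy, score in [(100, 1), (105, 2), (110, 3), (115, 4), (120, 5)]:
                rows.append(("t1", "g1", year, doy, "bb", score))
            for doy, score in [(250, 1)] + [(250 + 4 * k, k) for k in range(2, 9)]:
                rows.append(("t1", "g1", year, doy, "col", score))
            for doy, score in [(280, 1), (290, 2), (300, 3)]:
                rows.append(("t1", "g1", year, doy, "ls", score))
        table = pq.build_transition_table(self._survey(rows))
        assert len(table) == 10  # 2 years x 5 milestone stages
        assert (table["source"] == "observed").all()

    def test_missing_trait_year_leaves_milestones_undefined(self):
        rows = [("t1", "g1", 2017, d, "bb", s) for d, s in [(100, 1), (104, 2), (110, 4)]]
        rows += [("t1", "g1", 2017, d, "col", s) for d, s in [(250, 2), (256, 3), (270, 8)]]
        rows += [("t1", "g1", 2018, d, "bb", s) for d, s in [(99, 1), (103, 2), (109, 4)]]
        table = pq.build_transition_table(self._survey(rows))
        t18 = table[(table.year == 2018) & (table.stage.isin(["co3", "co8", "ls3"]))]
        assert (t18["source"] == "undefined").all()
        assert t18["doy"].isna().all()

    def test_study_scale_row_count_matches_design(self, dataset, transition_table):
        n_trees = len(dataset.trial.tree_table)
        assert len(transition_table) == n_trees * 2 * 5
        assert set(transition_table["source"]) <= {"observed", "imputed", "undefined"}

    def test_imputed_days_lie_strictly_inside_raw_brackets(self, dataset, transition_table):
        """Bounded-interpolation rule: every imputed day sits strictly between
        the last visit below the threshold and the first visit at/above it."""
        stage_info = pq.DEFAULT_STAGES
        survey = dataset.survey
        imputed = transition_table[transition_table.source == "imputed"]
        grouped = survey.groupby(["tree_id", "year", "trait"])
        checked = 0
        for row in imputed.itertuples():
            trait, thr = stage_info[row.stage]
            grp = grouped.get_group((row.tree_id, row.year, trait))
            br = _bracket(grp["doy"].to_numpy(float), grp["score"].to_numpy(float), thr)
            assert br is not None
            d_lo, _, d_hi, _ = br
            assert d_lo < row.doy < d_hi
            checked += 1
        assert checked == len(imputed) > 0

    def test_imputation_error_bounded_by_survey_interval(self, dataset, transition_table):
        truth = dataset.trial.true_days.melt(
            id_vars=["tree_id", "genotype_id", "year"],
            value_vars=["bb2", "bb4", "co3", "co8", "ls3"],
            var_name="stage",
            value_name="true_doy",
        )
        merged = transition_table.merge(
            truth, on=["tree_id", "genotype_id", "year", "stage"]
        ).dropna(subset=["doy"])
        err = (merged["doy"] - merged["true_doy"]).abs()
        assert err.max() <= dataset.config.gap_max
        assert err.mean() <= 2.5


class TestCanopyDuration:
    def test_difference_of_milestones(self):
        table = pd.DataFrame(
            {
                "tree_id": ["t1"] * 5,
                "genotype_id": ["g1"] * 5,
                "year": [2017] * 5,
                "stage": ["bb2", "bb4", "co3", "co8", "ls3"],
                "doy": [120.0, 130.0, 270.0, 290.0, 300.0],
                "source": ["observed"] * 5,
            }
        )
        cd = pq.canopy_duration(table)
        assert cd["cd_days"].tolist() == [150.0]

    def test_undefined_endpoint_omits_record(self):
        table = pd.DataFrame(
            {
                "tree_id": ["t1", "t1"],
                "genotype_id": ["g1", "g1"],
                "year": [2017, 2017],
                "stage": ["bb2", "co3"],
                "doy": [np.nan, 270.0],
                "source": ["undefined", "observed"],
            }
        )
        assert pq.canopy_duration(table).empty

    def test_cohort_durations_all_positive(self, canopy):
        assert (canopy["cd_days"] > 0).all()
        assert len(canopy) > 1000


class TestValidation:
    def test_identical_vectors_give_unit_correlation(self):
        assert validate_imputation([1, 2, 3.0], [1, 2, 3.0]) == pytest.approx(1.0)

    def test_anticorrelated_pairs_give_minus_one(self):
        assert validate_imputation([1, 2, 3.0], [3, 2, 1.0]) == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(TransitionError, match="3"):
            validate_imputation([1, 2.0], [1, 2.0])

    def test_holdout_reports_pooled_and_per_stage_pairs(self, dataset):
        hv = pq.holdout_validation(dataset.survey)
        assert len(hv) >= 100
        pooled = validate_imputation(hv["imputed_doy"], hv["observed_doy"])
        assert pooled > 0.9
        for _, grp in hv.groupby("stage"):
            if len(grp) >= 3:
                assert validate_imputation(grp["imputed_doy"], grp["observed_doy"]) > 0.5
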