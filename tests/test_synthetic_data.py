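"""The synthetic clonal-trial generator: design counts, breeding-value
moments, latent phenotypes, surveys, reproducibility."""

import numpy as np
import pandas as pd
import pytest

import phenoqg as pq
from phenoqg.synthetic_data import (
    GeneratorError,
    _ramet_counts,
    simulate_survey,
)


class TestCrossingDesign:
    def test_default_counts_match_study_design(self, dataset):
        ped = dataset.trial.pedigree
        assert len(ped) == 139 and ped.founder_count == 19
        offspring = [r for r in ped.records if not r.is_founder]
        assert len(offspring) == 120
        families = {(r.sire_id, r.dam_id) for r in offspring}
        assert len(families) == 34
        assert len(dataset.trial.tree_table) == 564

    def test_same_seed_reproduces_design(self):
        cfg = pq.GeneratorConfig().with_overrides(seed=5)
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        p1, t1 = pq.simulate_crossing_design(cfg, rng1)
        p2, t2 = pq.simulate_crossing_design(cfg, rng2)
        assert p1.ids == p2.ids
        pd.testing.assert_frame_equal(t1, t2)

    def test_infeasible_family_count_rejected(self):
        cfg = pq.GeneratorConfig().with_overrides(n_females=3, n_males=3, n_families=100)
        with pytest.raises(GeneratorError, match="infeasible"):
            pq.simulate_crossing_design(cfg, np.random.default_rng(0))

    def test_ramet_counts_honor_range_median_and_total(self):
        counts = _ramet_counts(pq.GeneratorConfig(), np.random.default_rng(1))
        assert counts.min() >= 1 and counts.max() <= 20
        assert np.median(counts) == 6
        assert counts.sum() == 564


class TestBreedingValues:
    def test_identity_pedigree_sample_covariance_matches_g(self):
        G = np.array([[2.0, 0.6, 0.0], [0.6, 1.0, -0.3], [0.0, -0.3, 1.5]])
        u = pq.simulate_breeding_values(np.eye(5000), G, np.random.default_rng(2))
        emp = np.cov(u.T)
        assert np.abs(emp - G).max() / np.abs(G).max() < 0.05

    def test_full_sib_cross_covariance_is_half_g(self):
        """Monte-Carlo moment oracle: for full sibs with A(i,j) = 0.5 the
        cross-genotype covariance of breeding values is 0.5 * G."""
        ped = pq.build_pedigree(
            [("S", "", ""), ("D", "", ""), ("O1", "S", "D"), ("O2", "S", "D")]
        )
        A = pq.additive_relationship(ped).values
        g = 2.0
        # one scalar trait, 5000 independent replicates as columns
        u = pq.simulate_breeding_values(A, np.eye(5000) * g, np.random.default_rng(3))
        i1, i2 = ped.genotype_index["O1"], ped.genotype_index["O2"]
        cross = np.cov(u[i1], u[i2])[0, 1]
        assert cross == pytest.approx(0.5 * g, rel=0.1)

    def test_empirical_moments_are_exact(self):
        ped = pq.build_pedigree(
            [("S", "", ""), ("D", "", ""), ("O1", "S", "D"), ("O2", "S", "D")]
        )
        A = pq.additive_relationship(ped).values
        G = np.array([[2.0, 0.5], [0.5, 1.0]])
        u = pq.simulate_breeding_values(A, G, np.random.default_rng(4), empirical=True)
        realized = u.T @ np.linalg.inv(A) @ u / len(A)
        np.testing.assert_allclose(realized, G, atol=1e-10)

    def test_non_psd_inputs_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues -1, 3
        with pytest.raises(GeneratorError, match="positive semi-definite"):
            pq.simulate_breeding_values(np.eye(2), bad, np.random.default_rng(0))
        with pytest.raises(GeneratorError, match="symmetric"):
            pq.simulate_breeding_values(np.array([[1.0, 0.2], [0.0, 1.0]]), np.eye(2),
                                        np.random.default_rng(0))

    def test_degenerate_scale_gives_vanishing_values(self):
        u = pq.simulate_breeding_values(np.eye(10), np.eye(2) * 1e-12, np.random.default_rng(5))
        assert np.abs(u).max() < 1e-4


class TestPhenotypes:
    def test_milestones_ordered_within_every_tree_year(self, dataset):
        td = dataset.trial.true_days
        assert (td["bb2"] < td["bb4"]).all()
        assert (td["bb4"] < td["co3"]).all()
        assert (td["co3"] < td["co8"]).all()
        assert (td["co8"] < td["ls3"]).all()
        np.testing.assert_allclose(td["cd"], td["co3"] - td["bb2"])

    def test_zero_variance_config_puts_trees_at_trait_means(self):
        cfg = pq.GeneratorConfig().with_overrides(
            heritability={t: 0.5 for t in pq.FREE_TRAITS},
            phenotypic_sd={t: 1e-4 for t in pq.FREE_TRAITS},
        )
        ds = pq.generate_dataset(cfg)
        td = ds.trial.true_days
        y1 = td[td.year == 2017]
        for t in ("bb2", "co8", "ls3"):
            assert np.abs(y1[t] - cfg.trait_means[t]).max() < 0.01

    def test_year_shift_moves_second_year_mean(self, dataset):
        td = dataset.trial.true_days
        shift = dataset.config.year_shifts["bb2"]
        diff = td[td.year == 2018]["bb2"].mean() - td[td.year == 2017]["bb2"].mean()
        assert diff == pytest.approx(shift, abs=1.0)

    def test_between_genotype_variance_fraction_tracks_heritability(self, dataset):
        """ANOVA-style moment oracle on the latent DBH values: the one-way
        intraclass correlation over genotypes should match the fraction
        implied by the realized breeding values.  (Relatedness between
        genotypes makes the naive between-genotype variance smaller than
        Va, so the oracle is built from the latent truth, not from h2
        directly.)"""
        dbh = dataset.trial.dbh
        grp = dbh.groupby("genotype_id")["dbh_cm"]
        k = grp.size()
        n, q = len(dbh), len(k)
        grand = dbh["dbh_cm"].mean()
        ss_between = (k * (grp.mean() - grand) ** 2).sum()
        ss_within = ((dbh["dbh_cm"] - grp.transform("mean")) ** 2).sum()
        ms_between = ss_between / (q - 1)
        ms_within = ss_within / (n - q)
        k0 = (n - (k**2).sum() / n) / (q - 1)
        sigma_b = (ms_between - ms_within) / k0
        icc = sigma_b / (sigma_b + ms_within)
        # latent oracle: variance of the realized genotype effects over the
        # trait's residual variance
        ped = dataset.trial.pedigree
        rows = [ped.genotype_index[g] for g in sorted(k.index)]
        i_dbh = pq.FREE_TRAITS.index("dbh")
        u = dataset.trial.breeding_values[rows, i_dbh]
        ve = dataset.trial.truth["residual_covariance"][pq.TRAITS7.index("dbh")][
            pq.TRAITS7.index("dbh")
        ]
        expected = np.var(u, ddof=1) / (np.var(u, ddof=1) + ve)
        assert icc == pytest.approx(expected, rel=0.10)
        # and the fraction stays in the neighbourhood of the generative h2
        h2 = dataset.trial.truth["heritability"]["dbh"]
        assert abs(icc - h2) < 0.15


class TestSurvey:
    def test_scores_consistent_with_latent_days(self, dataset):
        td = dataset.trial.true_days.set_index(["tree_id", "year"])
        sample = dataset.survey.sample(500, random_state=0)
        thresholds = {
            "bb": ["bb2", "bb3", "bb4", "bb5"],
            "col": ["co2", "co3", "co4", "co5", "co6", "co7", "co8"],
            "ls": ["ls2", "ls3"],
        }
        for row in sample.itertuples():
            days = td.loc[(row.tree_id, row.year), thresholds[row.trait]]
            expected = 1 + int((days <= row.doy).sum())
            assert row.score == expected

    def test_visit_gaps_within_survey_interval(self, dataset):
        sp_lo, sp_hi = dataset.config.spring_window
        spring = dataset.survey[dataset.survey.trait == "bb"]
        for _, grp in spring.groupby(["tree_id", "year"]):
            gaps = np.diff(np.sort(grp["doy"].unique()))
            assert gaps.min() >= dataset.config.gap_min
            assert gaps.max() <= dataset.config.gap_max

    def test_window_too_short_is_rejected(self, dataset):
        bad = dataset.trial.true_days.copy()
        bad.loc[bad.index[0], "ls3"] = 400.0
        with pytest.raises(GeneratorError, match="window"):
            simulate_survey(bad, dataset.config, np.random.default_rng(0))

    def test_round_trip_imputation_error_small(self, dataset, transition_table):
        truth = dataset.trial.true_days.melt(
            id_vars=["tree_id", "year"],
            value_vars=["bb2", "bb4", "co3", "co8", "ls3"],
            var_name="stage",
            value_name="true_doy",
        )
        merged = transition_table.merge(truth, on=["tree_id", "year", "stage"]).dropna(
            subset=["doy"]
        )
        assert (merged["doy"] - merged["true_doy"]).abs().mean() <= 2.5


class TestReproducibility:
    def test_fixed_seed_outputs_byte_identical(self, tmp_path):
        cfg = pq.GeneratorConfig().with_overrides(seed=99)
        d1 = pq.generate_dataset(cfg)
        d2 = pq.generate_dataset(cfg)
        p1, p2 = tmp_path / "a", tmp_path / "b"
        f1 = d1.write(p1)
        f2 = d2.write(p2)
        for a, b in zip(f1, f2):
            assert a.read_bytes() == b.read_bytes()

    def test_truth_records_realized_parameters(self, dataset):
        truth = dataset.trial.truth
        corr = np.array(truth["genetic_correlations"])
        assert corr.shape == (7, 7)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-9)
        # induced canopy-duration correlations land near the free-trait targets
        ti = {t: i for i, t in enumerate(pq.TRAITS7)}
        assert corr[ti["cd"], ti["dbh"]] == pytest.approx(0.43, abs=0.02)
        assert corr[ti["cd"], ti["bb2"]] == pytest.approx(-0.66, abs=0.02)
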