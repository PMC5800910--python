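"""Harrell's C, jackknife inference and Cox risk scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gencorrect as gc
from oracles import brute_force_c


def _random_instance(rng, n):
    scores = np.round(rng.standard_normal(n), 1)  # rounding induces score ties
    time = np.ceil(rng.exponential(5.0, n) * 2) / 2  # induces time ties
    event = (rng.random(n) < 0.6).astype(int)
    return scores, time, event


class TestHarrellC:
    def test_worked_example_all_concordant(self):
        res = gc.harrell_c([0.9, 0.5, 0.8, 0.1], [2, 3, 5, 6], [1, 0, 1, 0])
        assert res.n_comparable_pairs == 4
        assert res.c_statistic == 1.0

    def test_worked_example_one_discordant(self):
        res = gc.harrell_c([0.9, 0.5, 0.95, 0.1], [2, 3, 5, 6], [1, 0, 1, 0])
        assert res.n_comparable_pairs == 4
        assert res.c_statistic == 0.75

    def test_identical_scores_give_half(self):
        res = gc.harrell_c(np.ones(30), np.arange(1, 31), np.ones(30, dtype=int))
        assert res.c_statistic == 0.5

    def test_matches_brute_force_on_random_censored_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(5, 201))
            scores, time, event = _random_instance(rng, n)
            if event[np.argsort(time)][:-1].sum() == 0:
                event[np.argmin(time)] = 1  # guarantee a comparable pair
            n_comp, n_conc, c = brute_force_c(scores, time, event)
            res = gc.harrell_c(scores, time, event)
            assert res.n_comparable_pairs == n_comp
            assert res.n_concordant == n_conc
            assert res.c_statistic == c

    def test_agrees_with_lifelines_concordance(self):
        # independent library cross-check (lifelines orients scores as
        # survival predictions, hence the sign flip)
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(66)
        for _ in range(20):
            scores, time, event = _random_instance(rng, 150)
            ours = gc.harrell_c(scores, time, event).c_statistic
            theirs = concordance_index(time, -scores, event)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(8)
        scores, time, event = _random_instance(rng, 150)
        base = gc.harrell_c(scores, time, event).c_statistic
        assert gc.harrell_c(np.exp(scores), time, event).c_statistic == base
        assert gc.harrell_c(3 * scores + 7, time, event).c_statistic == base

    def test_sign_reversal_maps_c_to_complement(self):
        rng = np.random.default_rng(9)
        scores, time, event = _random_instance(rng, 150)
        c = gc.harrell_c(scores, time, event).c_statistic
        assert gc.harrell_c(-scores, time, event).c_statistic == pytest.approx(1 - c, abs=1e-12)

    def test_uncensored_continuous_equals_kendall_type_statistic(self):
        rng = np.random.default_rng(10)
        n = 120
        scores = rng.standard_normal(n)
        time = rng.exponential(5.0, n)  # continuous: no ties
        event = np.ones(n, dtype=int)
        # direct rank statistic: fraction of pairs where the shorter survivor
        # has the higher score
        conc = sum(
            (scores[i] > scores[j]) == (time[i] < time[j])
            for i in range(n)
            for j in range(i + 1, n)
        )
        assert gc.harrell_c(scores, time, event).c_statistic == conc / (n * (n - 1) / 2)

    def test_ci_truncated_and_consistent(self):
        rng = np.random.default_rng(11)
        scores, time, event = _random_instance(rng, 200)
        res = gc.harrell_c(scores, time, event)
        assert 0.0 <= res.ci95[0] <= res.c_statistic <= res.ci95[1] <= 1.0
        assert res.se > 0
        assert res.c_statistic == res.n_concordant / res.n_comparable_pairs

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            gc.harrell_c([1.0, 2.0], [5.0, 5.0], [0, 0])
        with pytest.raises(ValueError, match="positive"):
            gc.harrell_c([1.0, 2.0], [0.0, 1.0], [1, 1])


class TestCompareC:
    def test_score_compared_with_itself(self):
        rng = np.random.default_rng(12)
        scores, time, event = _random_instance(rng, 100)
        res = gc.compare_c(scores, scores, time, event)
        assert res.delta == 0.0
        assert res.p_value == 1.0

    def test_delta_matches_separate_c_computations(self):
        rng = np.random.default_rng(13)
        s1, time, event = _random_instance(rng, 150)
        s2 = rng.standard_normal(150)
        res = gc.compare_c(s1, s2, time, event)
        c1 = gc.harrell_c(s1, time, event).c_statistic
        c2 = gc.harrell_c(s2, time, event).c_statistic
        assert res.delta == pytest.approx(c2 - c1, abs=1e-15)
        assert res.c_a == c1 and res.c_b == c2

    def test_strongly_informative_vs_noise_is_significant(self):
        rng = np.random.default_rng(14)
        n = 600
        risk = rng.standard_normal(n)
        time = np.where(risk > 0.8, rng.uniform(0.1, 2.5, n), 5.0)
        event = (time < 5.0).astype(int)
        noise = rng.standard_normal(n)
        res = gc.compare_c(noise, risk, time, event)
        assert res.delta > 0.2
        assert res.p_value < 1e-6

    def test_bootstrap_agrees_with_jackknife_direction(self):
        rng = np.random.default_rng(15)
        s1, time, event = _random_instance(rng, 120)
        s2 = s1 + 0.5 * rng.standard_normal(120)
        jk = gc.compare_c(s1, s2, time, event, method="jackknife")
        bs = gc.compare_c(s1, s2, time, event, method="bootstrap", n_boot=200, seed=1)
        assert jk.delta == bs.delta
        assert bs.se > 0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="same subjects"):
            gc.compare_c([1.0], [1.0, 2.0], [1.0, 2.0], [1, 0])


class TestFitCox:
    def test_recovers_binary_log_hazard_ratio(self):
        rng = np.random.default_rng(16)
        n, beta = 10_000, 0.7
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(beta * x))
        cens = np.minimum(t, 2.0)
        event = (t <= 2.0).astype(int)
        lp, cph = gc.fit_cox(np.maximum(cens, 1e-9), event, x)
        b = float(cph.params_["exposure"])
        se = float(cph.standard_errors_["exposure"])
        assert abs(b - beta) < 2 * se

    def test_null_covariate_recovered(self):
        rng = np.random.default_rng(17)
        n = 10_000
        x = rng.standard_normal(n)
        t = rng.exponential(1.0, n)
        event = np.ones(n, dtype=int)
        lp, cph = gc.fit_cox(t, event, x)
        assert abs(float(cph.params_["exposure"])) < 2 * float(cph.standard_errors_["exposure"])

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            gc.fit_cox([1.0, 2.0], [0, 0], [0.5, 0.6])

    def test_linear_predictor_monotone_in_univariate_exposure(self):
        rng = np.random.default_rng(18)
        n = 500
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.5 * x))
        event = np.ones(n, dtype=int)
        lp, _ = gc.fit_cox(t, event, x)
        order = np.argsort(x)
        assert (np.diff(lp[order]) >= 0).all() or (np.diff(lp[order]) <= 0).all()


class TestCSuite:
    def test_grid_complete(self, default_cohort, default_corrected):
        grid = gc.run_c_suite(default_cohort, default_corrected, cox_scores=False)
        assert list(grid["exposure"]) == ["AFP", "CA19-9", "CEA", "combination"]
        for col in ("c_raw", "c_corrected", "delta", "p_value"):
            assert grid[col].notna().all()
        assert ((grid["c_raw"] >= 0) & (grid["c_raw"] <= 1)).all()

    def test_cox_scores_leave_c_unchanged_for_univariate_exposures(
        self, default_cohort, default_corrected
    ):
        # the univariate Cox linear predictor is monotone in the exposure,
        # and C is invariant under monotone transforms
        direct = gc.run_c_suite(default_cohort, default_corrected, cox_scores=False)
        via_cox = gc.run_c_suite(default_cohort, default_corrected, cox_scores=True)
        assert np.allclose(direct["c_raw"], via_cox["c_raw"], atol=1e-12)
        assert np.allclose(direct["c_corrected"], via_cox["c_corrected"], atol=1e-12)

    def test_null_generative_model_gives_null_c(self):
        cohort = gc.simulate_cohort(
            gc.SimulationConfig(
                seed=34, disease_effect={"AFP": 1.0, "CA19-9": 1.0, "CEA": 1.0}
            )
        )
        corrected = gc.correct_levels(cohort)
        grid = gc.run_c_suite(cohort, corrected, cox_scores=False)
        # every 95% CI (~2 jackknife SE) should cover the null C of 0.5
        for _, row in grid.iterrows():
            assert row["c_raw_ci_lower"] <= 0.5 <= row["c_raw_ci_upper"]
            assert row["c_corrected_ci_lower"] <= 0.5 <= row["c_corrected_ci_upper"]
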