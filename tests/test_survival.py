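"""From-scratch survival statistics against hand computations, brute-force
oracles, and an independent library implementation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize

from silvarisk import (
    CoxPHModel,
    SurvivalSample,
    cox_fit,
    harrell_c,
    km_curve,
    logrank,
    survival_at,
    three_year_rate,
)
from silvarisk.survival import _concordance_counts, _cox_quantities


def sample(times, events, cov=None):
    return SurvivalSample(
        times=np.asarray(times, float),
        events=np.asarray(events, bool),
        covariates=None if cov is None else np.asarray(cov, float).reshape(len(times), -1),
    )


# ---------------------------------------------------------------------------
# Kaplan–Meier


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        c = km_curve(sample([1, 2, 3], [1, 1, 1]))
        assert np.allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_hand_example(self):
        c = km_curve(sample([1, 2, 2, 4], [1, 0, 1, 0]))
        assert np.allclose(c.event_times, [1, 2])
        assert np.allclose(c.survival, [3 / 4, 1 / 2])

    def test_all_censored_curve_is_one(self):
        c = km_curve(sample([5, 10, 15], [0, 0, 0]))
        assert c.event_times.size == 0
        assert survival_at(c, 100.0) == 1.0

    def test_step_function_evaluation(self):
        c = km_curve(sample([1, 2, 2, 4], [1, 0, 1, 0]))
        assert survival_at(c, 0.0) == 1.0
        assert survival_at(c, 2.0) == 0.5  # right-continuous: post-drop value
        assert survival_at(c, 3.0) == 0.5
        assert survival_at(c, 100.0) == 0.5

    def test_final_survival_matches_independent_product(self, rng):
        t = rng.exponential(10, 60) + 0.1
        e = rng.random(60) < 0.7
        c = km_curve(sample(t, e))
        prod = 1.0
        for tau in sorted(t[e]):
            n_i = np.sum(t >= tau)
            d_i = np.sum((t == tau) & e)
            prod *= 1 - d_i / n_i
        assert np.isclose(c.survival[-1], prod)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            km_curve(sample([], []))

    def test_three_year_rate(self):
        assert three_year_rate(sample([40, 50, 60, 70], [0, 0, 0, 0])) == 1.0
        assert three_year_rate(sample([12, 40, 50, 60], [1, 0, 0, 0])) == 0.75


# ---------------------------------------------------------------------------
# Log-rank


def logrank_oracle(t, e, g):
    """Independent O/E/V risk-table computation, straight from the formula."""
    o_minus_e, var = 0.0, 0.0
    for tau in sorted(set(t[e])):
        at = t >= tau
        n, n1 = at.sum(), (at & (g == 0)).sum()
        d = ((t == tau) & e).sum()
        d1 = ((t == tau) & e & (g == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_give_zero(self):
        a = sample([1, 2, 3, 4], [1, 0, 1, 0])
        r = logrank(a, a)
        assert r.chi_square == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        a = sample([1, 3, 5, 9], [1, 1, 0, 1])
        b = sample([2, 4, 8, 12], [0, 1, 1, 0])
        assert logrank(a, b).chi_square == pytest.approx(logrank(b, a).chi_square)

    def test_eight_subject_hand_oracle(self):
        t = np.array([2.0, 4.0, 5.0, 7.0, 3.0, 6.0, 8.0, 9.0])
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1], bool)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        r = logrank(sample(t[g == 0], e[g == 0]), sample(t[g == 1], e[g == 1]))
        assert r.chi_square == pytest.approx(logrank_oracle(t, e, g), abs=1e-10)

    def test_random_fixtures_match_oracle_and_squared_z_identity(self, rng):
        for _ in range(5):
            n = 40
            t = np.round(rng.exponential(20, n), 1) + 0.1
            e = rng.random(n) < 0.6
            g = (rng.random(n) < 0.5).astype(int)
            if not e.any() or len(set(g)) < 2:
                continue
            r = logrank(sample(t[g == 0], e[g == 0]), sample(t[g == 1], e[g == 1]))
            assert r.chi_square == pytest.approx(logrank_oracle(t, e, g), abs=1e-10)

    def test_zero_events_flagged_degenerate(self):
        r = logrank(sample([1, 2], [0, 0]), sample([3, 4], [0, 0]))
        assert r.degenerate and r.chi_square == 0.0 and r.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank(sample([], []), sample([1.0], [1]))


# ---------------------------------------------------------------------------
# Cox regression


def exact_partial_loglik(beta, x, t, e):
    """Brute-force exact partial likelihood for untied data."""
    ll = 0.0
    for i in np.nonzero(e)[0]:
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_six_subject_grid_oracle(self):
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 1, 1, 1], bool)
        res = cox_fit(sample(t, e, x))
        opt = optimize.minimize_scalar(
            lambda b: -exact_partial_loglik(b, x, t, e), bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.coef[0] == pytest.approx(opt.x, abs=1e-6)
        assert res.converged

    def test_score_vanishes_at_solution(self):
        rng = np.random.default_rng(3)
        n = 120
        x = rng.standard_normal((n, 2))
        t = rng.exponential(1 / np.exp(0.5 * x[:, 0]), n) + 0.01
        e = rng.random(n) < 0.8
        res = cox_fit(sample(t, e, x))
        order = np.argsort(t, kind="stable")
        _, start = np.unique(t[order], return_index=True)
        d = np.add.reduceat(e[order].astype(float), start)
        _, grad, _ = _cox_quantities(res.coef, x[order], start, d, e[order], "efron")
        assert np.max(np.abs(grad)) < 1e-8

    def test_matches_independent_library_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(8)
        n = 150
        x = (rng.random(n) < 0.4).astype(float)
        t = np.ceil(rng.exponential(30 / np.exp(0.8 * x), n))  # month ties
        e = rng.random(n) < 0.7
        res = cox_fit(sample(t, e, x))
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e.astype(int), "x": x}), "t", "e"
        )
        assert res.coef[0] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert res.se[0] == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-6)
        assert res.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(12)
        n = 80
        x = rng.standard_normal(n)
        t = rng.exponential(10, n) + 0.01  # continuous: no ties
        e = rng.random(n) < 0.7
        a = cox_fit(sample(t, e, x), ties="efron")
        b = cox_fit(sample(t, e, x), ties="breslow")
        assert a.coef[0] == pytest.approx(b.coef[0], abs=1e-12)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-10)

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(4)
        n = 1000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(50, n) + 0.01
        e = rng.random(n) < 0.5
        res = cox_fit(sample(t, e, x))
        assert 0.8 < res.hr[0] < 1.25

    def test_true_hr_two_recovered_at_large_n(self):
        rng = np.random.default_rng(15)
        n = 5000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.02 * np.exp(np.log(2) * x)), n)
        c = rng.uniform(10, 120, n)
        obs, e = np.minimum(t, c), t <= c
        res = cox_fit(sample(obs, e, x))
        assert 1.85 < res.hr[0] < 2.15

    def test_separation_flagged_and_capped(self):
        # positive group has no events: monotone likelihood
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        t = np.array([50.0, 60.0, 70.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([0, 0, 0, 1, 1, 1, 1, 0], bool)
        res = cox_fit(sample(t, e, x))
        assert res.degenerate
        assert np.abs(res.coef[0]) <= 15.0 + 1e-9

    def test_constant_covariate_degenerate_not_crash(self):
        res = cox_fit(sample([1, 2, 3, 4], [1, 1, 0, 1], np.ones(4)))
        assert res.degenerate and res.hr[0] == 1.0

    def test_hr_is_exp_coef_and_ci_brackets(self):
        rng = np.random.default_rng(5)
        n = 200
        x = rng.standard_normal(n)
        t = rng.exponential(1 / np.exp(0.4 * x), n) + 0.01
        e = np.ones(n, bool)
        res = cox_fit(sample(t, e, x))
        assert np.allclose(res.hr, np.exp(res.coef), atol=1e-12)
        assert res.ci_low[0] <= res.hr[0] <= res.ci_high[0]

    def test_sklearn_estimator_contract(self):
        from sklearn.base import clone

        m = CoxPHModel(ties="breslow", alpha=0.1)
        assert clone(m).get_params()["ties"] == "breslow"
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 1))
        t = rng.exponential(5, 50) + 0.01
        e = np.ones(50, bool)
        m.fit(x, (t, e))
        scores = m.predict(x)
        assert scores.shape == (50,)
        assert 0.0 <= m.score(x, (t, e)) <= 1.0


# ---------------------------------------------------------------------------
# Concordance


def brute_force_c(scores, t, e):
    conc = tied = comp = 0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if e[i] and t[i] < t[j]:
                comp += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    tied += 1
    return (conc + 0.5 * tied) / comp


class TestConcordance:
    def test_perfect_ordering_gives_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        s = np.array([4.0, 3.0, 2.0, 1.0])
        r = harrell_c(s, sample(t, [1, 1, 1, 1]), n_bootstrap=0)
        assert r.c_index == 1.0

    def test_all_tied_scores_give_half(self):
        r = harrell_c(np.ones(5), sample([1, 2, 3, 4, 5], [1, 1, 1, 0, 1]), n_bootstrap=0)
        assert r.c_index == 0.5

    def test_ten_subject_censored_fixture_matches_pair_enumeration(self):
        t = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8, 9.7, 2.0])
        e = np.array([1, 1, 0, 1, 0, 1, 1, 0, 1, 0], bool)
        s = np.array([0.9, 0.8, 0.3, 0.7, 0.1, 0.9, 0.4, 0.2, 0.05, 0.6])
        r = harrell_c(s, sample(t, e), n_bootstrap=0)
        assert r.c_index == pytest.approx(brute_force_c(s, t, e), abs=0)

    @pytest.mark.parametrize("binary", [True, False])
    def test_200_subject_fixture_matches_brute_force_exactly(self, binary, rng):
        n = 200
        t = np.round(rng.exponential(30, n), 0) + 1
        e = rng.random(n) < 0.4
        s = (rng.random(n) < 0.3).astype(float) if binary else rng.random(n)
        r = harrell_c(s, sample(t, e), n_bootstrap=0)
        assert r.c_index == pytest.approx(brute_force_c(s, t, e), abs=1e-14)

    def test_negating_scores_complements_c(self, rng):
        n = 60
        t = rng.exponential(10, n) + 0.1
        e = rng.random(n) < 0.6
        s = rng.random(n)  # continuous: no score ties
        c1 = harrell_c(s, sample(t, e), n_bootstrap=0).c_index
        c2 = harrell_c(-s, sample(t, e), n_bootstrap=0).c_index
        assert c1 + c2 == pytest.approx(1.0, abs=1e-12)

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self, rng):
        n = 100
        t = rng.exponential(10, n) + 0.1
        e = rng.random(n) < 0.6
        s = rng.random(n)
        a = harrell_c(s, sample(t, e), n_bootstrap=200, seed=42)
        b = harrell_c(s, sample(t, e), n_bootstrap=200, seed=42)
        assert a == b
        assert a.ci_low <= a.c_index <= a.ci_high

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c([1.0, 2.0], sample([5.0, 5.0], [0, 0]), n_bootstrap=0)

    def test_agrees_with_independent_library(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(33)
        n = 150
        t = rng.exponential(20, n) + 0.01  # continuous: no time ties
        e = rng.random(n) < 0.6
        s = rng.random(n)
        ours = harrell_c(s, sample(t, e), n_bootstrap=0).c_index
        theirs = 1 - lifelines.utils.concordance_index(t, s, e)
        assert ours == pytest.approx(theirs, abs=1e-12)
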