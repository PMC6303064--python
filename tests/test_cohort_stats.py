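"""Paired tests, rank correlation and PBVC regression."""

import math

import numpy as np
import pandas as pd
import pytest

from t1relax import (
    CohortEffects,
    paired_t_test,
    paired_volume_report,
    percent_change,
    regress_pbvc,
    simulate_cohort,
    spearman_rho,
)


# ---------------------------------------------------------------------------
# textbook-formula oracles, independent of scipy/statsmodels
# ---------------------------------------------------------------------------

def paired_t_oracle(b, f):
    d = np.asarray(f, float) - np.asarray(b, float)
    n = d.size
    sd = math.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
    return d.mean() / (sd / math.sqrt(n))


def average_ranks(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size)
    i = 0
    sorted_v = v[order]
    while i < v.size:
        j = i
        while j + 1 < v.size and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx, ry = average_ranks(x), average_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


def ols_oracle(y, X):
    """Normal-equations OLS with intercept: coefficients and R^2."""
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return beta, 1 - ss_res / ss_tot


class TestPercentChange:
    def test_no_change_is_zero(self):
        assert percent_change(100.0, 100.0) == 0.0

    def test_published_gm_volume_means_give_minus_2_24(self):
        assert percent_change(798024.63, 780135.80) == pytest.approx(-2.24, abs=0.005)

    def test_fifty_percent_increase(self):
        assert percent_change(50.0, 75.0) == 50.0

    def test_scale_invariance(self, rng):
        b, f = rng.uniform(1, 100, 20), rng.uniform(1, 100, 20)
        assert np.allclose(percent_change(3.7 * b, 3.7 * f), percent_change(b, f))

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)


class TestPairedT:
    def test_identical_vectors_flagged_degenerate(self):
        r = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_diff == 0.0 and r.degenerate
        assert r.t_statistic is None and r.p_value is None

    def test_three_pair_toy_set_matches_hand_formula(self):
        b, f = [10.0, 12.0, 9.0], [11.0, 15.0, 9.5]
        r = paired_t_test(b, f)
        assert r.t_statistic == pytest.approx(paired_t_oracle(b, f), abs=1e-12)
        assert r.direction == "increase"

    def test_matches_oracle_on_many_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            b = rng.normal(0, 1, n)
            f = b + rng.normal(0.2, 1, n)
            r = paired_t_test(b, f)
            assert r.t_statistic == pytest.approx(paired_t_oracle(b, f), abs=1e-8)

    def test_detects_simulated_gm_decline_with_high_power(self):
        eff = CohortEffects(gm_change_pct=-2.24, volume_noise_pct=0.5)
        hits = 0
        for seed in range(100):
            df = simulate_cohort(20, effects=eff, seed=seed)
            r = paired_t_test(df["gm_volume_baseline"], df["gm_volume_followup"])
            hits += (r.p_value is not None and r.p_value < 0.05
                     and r.direction == "decrease")
        assert hits >= 95

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0])


class TestSpearman:
    def test_monotone_sequences_give_plus_minus_one(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x**3)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_values_match_explicit_ranking_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0])
        rho, p = spearman_rho(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)
        assert 0 <= p <= 1

    def test_matches_oracle_on_many_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            x = np.round(rng.normal(0, 1, n), 1)  # rounding induces ties
            y = np.round(rng.normal(0, 1, n), 1)
            if np.allclose(x, x[0]) or np.allclose(y, y[0]):
                continue
            rho, _ = spearman_rho(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-8)

    def test_constant_vector_degenerate(self):
        rho, p = spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho) and p is None


class TestRegressPbvc:
    def test_outcome_identical_to_covariate_gives_unit_slope(self, rng):
        x = rng.normal(40, 8, 30)
        df = pd.DataFrame({"pbvc": x, "age": x})
        (res,) = regress_pbvc(df, ["age"])
        (term,) = res.terms
        assert term.coefficient == pytest.approx(1.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_univariate_r2_equals_squared_pearson(self, rng):
        age = rng.normal(40, 8, 50)
        pbvc = -0.05 * age + rng.normal(0, 0.5, 50)
        df = pd.DataFrame({"pbvc": pbvc, "age": age})
        (res,) = regress_pbvc(df, ["age"])
        r = np.corrcoef(age, pbvc)[0, 1]
        assert res.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 40))
            X = rng.normal(0, 1, (n, 3))
            y = X @ np.array([0.5, -1.0, 2.0]) + rng.normal(0, 1, n)
            df = pd.DataFrame({"pbvc": y, "a": X[:, 0], "b": X[:, 1], "c": X[:, 2]})
            (res,) = regress_pbvc(df, ["a", "b", "c"], multivariate=True)
            beta, r2 = ols_oracle(y, X)
            got = [t.coefficient for t in res.terms]
            assert got == pytest.approx(list(beta[1:]), abs=1e-8)
            assert res.r_squared == pytest.approx(r2, abs=1e-8)

    def test_null_covariate_ci_covers_zero_at_nominal_rate(self, rng):
        covered = 0
        n_seeds = 200
        for _ in range(n_seeds):
            x = rng.normal(0, 1, 200)
            y = rng.normal(0, 1, 200)
            df = pd.DataFrame({"pbvc": y, "x": x})
            (res,) = regress_pbvc(df, ["x"])
            (t,) = res.terms
            covered += t.ci_low <= 0.0 <= t.ci_high
        # binomial(200, 0.95): ~3 sigma band
        assert 0.90 <= covered / n_seeds <= 1.0

    def test_age_effect_recovered_from_simulated_cohort(self):
        eff = CohortEffects(age_effect_on_pbvc=-0.05, pbvc_noise_sd=0.3)
        df = simulate_cohort(200, effects=eff, seed=12)
        (res,) = regress_pbvc(df, ["age"])
        (t,) = res.terms
        assert t.ci_low <= -0.05 <= t.ci_high
        assert t.p_value < 0.05

    def test_race_encoded_as_indicator_contrasts(self):
        df = simulate_cohort(60, effects=CohortEffects(pbvc_noise_sd=0.5), seed=4)
        (res,) = regress_pbvc(df, ["race"])
        names = {t.name for t in res.terms}
        assert all(n.startswith("race[") for n in names)
        assert len(names) == df["race"].nunique() - 1

    def test_collinear_design_rejected(self, rng):
        x = rng.normal(0, 1, 30)
        df = pd.DataFrame({"pbvc": rng.normal(0, 1, 30), "a": x, "b": 2 * x})
        with pytest.raises(ValueError):
            regress_pbvc(df, ["a", "b"], multivariate=True)


class TestPairedVolumeReport:
    def test_report_structure_and_signs(self):
        df = simulate_cohort(20, effects=CohortEffects(gm_change_pct=-2.24,
                                                       wm_change_pct=0.0), seed=2)
        rep = paired_volume_report(df, ["gm_volume", "wm_volume"])
        gm = rep[rep.compartment == "gm_volume"].iloc[0]
        wm = rep[rep.compartment == "wm_volume"].iloc[0]
        assert gm.mean_pct_change == pytest.approx(-2.24, abs=1e-9)
        assert bool(wm.degenerate)
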