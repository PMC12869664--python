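"""Cox screening, aggregation, stratification and survival tests,
cross-checked against lifelines and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from clonerisk._stats import cox_univariate
from clonerisk.risk import (combine_strata, km_logrank, median_split,
                            multivariate_cox, nested_model_test,
                            screen_prognostic, total_abundance_T)
from clonerisk.simulate import SurvivalSimConfig, simulate_survival


def _cohort(rng, n=300, beta=0.0, x=None):
    x = rng.uniform(0, 1, n) if x is None else x
    cfg = SurvivalSimConfig(beta_T=beta, beta_mrd=0, beta_cyto=0,
                            baseline_hazard=0.3)
    df = simulate_survival(x, np.zeros(n), np.zeros(n), cfg, rng)
    return df, x


class TestCoxKernel:
    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter
        df, x = _cohort(rng, n=250, beta=0.8)
        fit = cox_univariate(df["os_time"], df["os_event"], x)
        ldf = pd.DataFrame({"t": df["os_time"], "e": df["os_event"], "x": x})
        cph = CoxPHFitter().fit(ldf, "t", "e")
        assert fit["coef"] == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit["se"] == pytest.approx(cph.standard_errors_["x"], rel=1e-4)
        assert fit["p"] == pytest.approx(cph.summary.loc["x", "p"], rel=1e-3)

    def test_heavy_ties_match_naive_breslow_likelihood(self, rng):
        # oracle: direct maximization of the loop-written Breslow partial
        # likelihood (risk sets recomputed from scratch per event)
        from scipy.optimize import minimize_scalar
        n = 200
        t = rng.integers(1, 6, n).astype(float)  # massive ties
        e = rng.integers(0, 2, n)
        x = rng.normal(0, 1, n)
        e[0] = 1

        def neg_ll(beta):
            ll = 0.0
            for i in range(n):
                if e[i]:
                    risk = np.exp(beta * x[t >= t[i]])
                    ll += beta * x[i] - np.log(risk.sum())
            return -ll

        ref = minimize_scalar(neg_ll, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        fit = cox_univariate(t, e, x)
        assert fit["coef"] == pytest.approx(ref.x, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate([1, 2, 3], [1, 1, 0], [2, 2, 2])
        with pytest.raises(ValueError, match="no events"):
            cox_univariate([1, 2, 3], [0, 0, 0], [1, 2, 3])


class TestScreen:
    def _inputs(self, rng, n=200, k=5, beta=None):
        ab = rng.dirichlet(np.ones(k), n)
        abundances = pd.DataFrame(ab, index=[f"B{i:04d}" for i in range(n)],
                                  columns=[f"M{j}" for j in range(k)])
        score = np.zeros(n) if beta is None else \
            beta * (ab[:, 0] - ab[:, 0].mean()) / ab[:, 0].std()
        cfg = SurvivalSimConfig(beta_T=1.0, beta_mrd=0, beta_cyto=0,
                                baseline_hazard=0.3)
        clin = simulate_survival(score, np.zeros(n), np.zeros(n), cfg, rng)
        clin["flt3_itd"] = 0
        return abundances, clin

    def test_planted_subclone_selected(self, rng):
        abundances, clin = self._inputs(rng, n=500, beta=np.log(3.0))
        res = screen_prognostic(abundances, clin)
        assert res.loc["M0", "selected"]
        assert res.loc["M0", "hr_os"] > 1

    def test_selection_monotone_in_alpha(self, rng):
        abundances, clin = self._inputs(rng, n=300, beta=np.log(2.0))
        loose = screen_prognostic(abundances, clin, alpha=0.05)
        tight = screen_prognostic(abundances, clin, alpha=0.001)
        assert set(tight.index[tight["selected"]]) <= \
            set(loose.index[loose["selected"]])

    def test_flt3_positive_patients_excluded(self, rng):
        abundances, clin = self._inputs(rng, n=300, beta=np.log(2.0))
        clin2 = clin.copy()
        flagged = clin2.index[:150]
        clin2.loc[flagged, "flt3_itd"] = 1
        r_all = screen_prognostic(abundances, clin, exclude_flt3=True)
        r_half = screen_prognostic(abundances, clin2, exclude_flt3=True)
        # excluding half the cohort must change the fitted p-values
        assert not np.allclose(r_all["p_os"], r_half["p_os"])

    def test_constant_column_skipped_with_warning(self, rng):
        abundances, clin = self._inputs(rng, n=120)
        abundances["M0"] = 0.2
        with pytest.warns(UserWarning, match="constant"):
            res = screen_prognostic(abundances, clin, min_patients=50)
        assert np.isnan(res.loc["M0", "p_os"])
        assert not res.loc["M0", "selected"]


class TestAggregation:
    def test_total_abundance_sums_selected(self):
        ab = pd.DataFrame({"a": [0.1, 0.2], "b": [0.2, 0.3], "c": [0.7, 0.5]})
        T = total_abundance_T(ab, ["a", "b"])
        np.testing.assert_allclose(T, [0.3, 0.5])

    def test_empty_selection_warns_zero(self):
        ab = pd.DataFrame({"a": [0.1, 0.9]})
        with pytest.warns(UserWarning, match="empty"):
            T = total_abundance_T(ab, [])
        assert (T == 0).all()

    def test_unknown_subclone_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            total_abundance_T(pd.DataFrame({"a": [1.0]}), ["zz"])

    def test_median_split_examples_and_tie_rule(self):
        np.testing.assert_array_equal(median_split([1, 2, 3, 4]), [0, 0, 1, 1])
        np.testing.assert_array_equal(median_split([1, 1, 2]), [0, 0, 1])
        v = np.random.default_rng(0).random(101)
        hi = median_split(v)
        order = np.argsort(v)
        np.testing.assert_array_equal(hi[order],
                                      np.r_[np.zeros(51), np.ones(50)])

    def test_median_split_degenerate(self):
        with pytest.raises(ValueError, match="identical"):
            median_split([2, 2, 2])

    def test_strata_encoding(self):
        T = [0, 1, 0, 1, 0, 1, 0, 1]
        m = [0, 0, 1, 1, 0, 0, 1, 1]
        c = [0, 0, 0, 0, 1, 1, 1, 1]
        out = combine_strata(T, m, c)
        np.testing.assert_array_equal(out["stratum"], np.arange(8))

    def test_missing_mrd_counts_as_positive_or_unknown(self):
        out = combine_strata([0, 0], [np.nan, 0.0], [0, 0])
        np.testing.assert_array_equal(out["mrd_bin"], [1, 0])


class TestKaplanMeierLogrank:
    def test_no_censoring_steps(self):
        res = km_logrank([1, 2, 3, 4, 5, 9, 9], [1] * 5 + [1, 1],
                         [0, 0, 0, 0, 0, 1, 1])
        surv = res["curves"][0]["survival"].to_numpy()
        np.testing.assert_allclose(surv, [1.0, 0.8, 0.6, 0.4, 0.2, 0.0])

    def test_km_matches_brute_force_product_limit(self, rng):
        n = 60
        t = rng.exponential(2, n).round(2) + 0.01
        e = rng.integers(0, 2, n)
        e[:5] = 1
        res = km_logrank(t, e, np.r_[np.zeros(30, int), np.ones(30, int)])
        for g in (0, 1):
            mask = (np.r_[np.zeros(30, int), np.ones(30, int)] == g)
            tg, eg = t[mask], e[mask]
            surv = 1.0
            expect = {}
            for u in np.unique(tg):
                d = ((tg == u) & (eg == 1)).sum()
                at_risk = (tg >= u).sum()
                if d:
                    surv *= 1 - d / at_risk
                expect[u] = surv
            curve = res["curves"][g].set_index("time")["survival"]
            for u, s in expect.items():
                assert curve.loc[u] == pytest.approx(s, abs=1e-12)

    def test_two_group_statistic_matches_hand_computation(self):
        # six subjects, no censoring: group A times 1,3,5; group B times 2,4,6
        t = np.array([1.0, 3, 5, 2, 4, 6])
        e = np.ones(6, int)
        g = np.array(list("AAABBB"))
        # O-E/V by hand over the six event times
        n_a, n_b, O_a, E_a, V = 3, 3, 0.0, 0.0, 0.0
        for time in sorted(t):
            at_a = ((t >= time) & (g == "A")).sum()
            at_b = ((t >= time) & (g == "B")).sum()
            n = at_a + at_b
            d = 1
            O_a += 1.0 if g[t == time][0] == "A" else 0.0
            E_a += d * at_a / n
            if n > 1:
                V += d * (at_a / n) * (at_b / n) * (n - d) / (n - 1)
        chi2 = (O_a - E_a) ** 2 / V
        res = km_logrank(t, e, g)
        assert res["statistic"] == pytest.approx(chi2, rel=1e-9)
        assert res["df"] == 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank([1, 2], [1, 1], [0, 0])


class TestModels:
    def _df(self, rng, n=800, betas=(0.5, 0.7), noise_cov=False):
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.integers(0, 2, n).astype(float)
        score = betas[0] * x1 + betas[1] * x2
        cfg = SurvivalSimConfig(beta_T=1.0, beta_mrd=0, beta_cyto=0,
                                baseline_hazard=0.2)
        df = simulate_survival(score, np.zeros(n), np.zeros(n), cfg, rng)
        df["x1"], df["x2"] = x1, x2
        if noise_cov:
            df["noise"] = rng.normal(0, 1, n)
        return df

    def test_equal_models_give_unit_p(self, rng):
        df = self._df(rng, n=200)
        res = nested_model_test(df, ["x1"], ["x1"])
        assert res["statistic"] == 0.0 and res["p"] == 1.0

    def test_informative_covariate_improves_fit(self, rng):
        df = self._df(rng, n=800)
        res = nested_model_test(df, ["x1"], ["x1", "x2"])
        assert res["p"] < 0.01 and res["df"] == 1

    def test_noise_covariate_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(20):
            df = self._df(rng, n=150, betas=(0.5, 0.0), noise_cov=True)
            ps.append(nested_model_test(df, ["x1"], ["x1", "noise"])["p"])
        assert 0.25 < np.mean(ps) < 0.75
        assert min(ps) > 1e-4  # no systematic inflation

    def test_non_nested_rejected(self, rng):
        df = self._df(rng, n=100)
        with pytest.raises(ValueError, match="nested"):
            nested_model_test(df, ["x2"], ["x1"])

    def test_multivariate_recovers_planted_betas(self, rng):
        n = 2000
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.integers(0, 2, n).astype(float)
        x3 = rng.integers(0, 2, n).astype(float)
        betas = (np.log(1.3), np.log(2.0), np.log(2.5))
        score = betas[0] * x1 + betas[1] * x2 + betas[2] * x3
        cfg = SurvivalSimConfig(beta_T=1.0, beta_mrd=0, beta_cyto=0,
                                baseline_hazard=0.15)
        df = simulate_survival(score, np.zeros(n), np.zeros(n), cfg, rng)
        df["T_bin"], df["mrd_bin"], df["cyto_bin"] = x1, x2, x3
        out = multivariate_cox(df, ["T_bin", "mrd_bin", "cyto_bin"])
        for cov, b in zip(["T_bin", "mrd_bin", "cyto_bin"], betas):
            assert out.loc[cov, "hr_ci_low"] < np.exp(b) < out.loc[cov, "hr_ci_high"]

    def test_univariate_multivariate_agree_for_independent_covariates(self, rng):
        df = self._df(rng, n=1500)
        multi = multivariate_cox(df, ["x1", "x2"])
        uni = cox_univariate(df["os_time"], df["os_event"], df["x1"])
        assert multi.loc["x1", "coef"] == pytest.approx(uni["coef"], abs=0.12)

    def test_constant_and_collinear_covariates_rejected(self, rng):
        df = self._df(rng, n=100)
        df["const"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            multivariate_cox(df, ["const", "x1"])
        df["dup"] = df["x1"]
        with pytest.raises(ValueError, match="collinear"):
            multivariate_cox(df, ["x1", "dup"])
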