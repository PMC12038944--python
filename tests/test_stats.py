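"""Statistical layer: Firth logistic, PheWAS scan, chi-square, Kaplan-Meier,
Cox (Efron), HWE carrier arithmetic -- each checked against an independent
oracle (hand computation, grid search, statsmodels or lifelines)."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import founderdel as fd
from founderdel.stats import StatsInputError, _firth_iterate


# ---------------------------------------------------------------------------
# case/control allele frequencies


class TestCaseControlAF:
    def test_all_cases_het(self):
        g = np.array([1, 1, 0, 0])
        y = np.array([1, 1, 0, 0])
        assert fd.case_control_af(g, y) == (0.5, 0.0)

    def test_no_carriers(self):
        assert fd.case_control_af(np.zeros(10), np.arange(10) < 3) == (0.0, 0.0)

    def test_empty_class_rejected(self):
        with pytest.raises(StatsInputError):
            fd.case_control_af(np.ones(4), np.ones(4))

    def test_recovers_generative_case_control_frequencies(self):
        """Cohort generated under the dementia-like structure (carrier AF
        about 0.0039 in cases vs 0.0025 in controls): recovered AFs sit
        within 3 binomial SD of their closed-form expectations."""
        N = 500_000
        rng = np.random.default_rng(17)
        maf = 0.0025
        g = rng.binomial(2, maf, N).astype(float)
        p0, or_ = 0.05, 2.14
        y = (rng.random(N) < expit(logit(p0) + np.log(or_) * g)).astype(int)
        af_case, af_ctrl = fd.case_control_af(g, y)
        # closed-form expected AF by class via Bayes over genotype
        pg = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        pcase_g = expit(logit(p0) + np.log(or_) * np.arange(3))
        p_case = (pg * pcase_g).sum()
        af_case_exp = (pg * pcase_g * np.arange(3)).sum() / (2 * p_case)
        af_ctrl_exp = (pg * (1 - pcase_g) * np.arange(3)).sum() / (2 * (1 - p_case))
        n_case = y.sum()
        for got, exp, n in [
            (af_case, af_case_exp, n_case),
            (af_ctrl, af_ctrl_exp, N - n_case),
        ]:
            sd = np.sqrt(exp * (1 - exp) / (2 * n))
            assert abs(got - exp) < 3 * sd


# ---------------------------------------------------------------------------
# Firth logistic


def _firth_grid_oracle(x, y, b0_range, b1_range, steps=61, refinements=4):
    """Coarse-to-fine grid maximization of the Jeffreys-penalized likelihood
    for an intercept + one covariate; independent of the Newton solver."""
    X = np.column_stack([np.ones_like(x), x])

    def pll(b0, b1):
        eta = b0 + b1 * x
        p = expit(eta)
        w = p * (1 - p)
        info = (X * w[:, None]).T @ X
        _, logdet = np.linalg.slogdet(info)
        return y @ eta - np.logaddexp(0, eta).sum() + 0.5 * logdet

    (b0_lo, b0_hi), (b1_lo, b1_hi) = b0_range, b1_range
    for _ in range(refinements):
        b0s = np.linspace(b0_lo, b0_hi, steps)
        b1s = np.linspace(b1_lo, b1_hi, steps)
        vals = np.array([[pll(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        db0, db1 = b0s[1] - b0s[0], b1s[1] - b1s[0]
        b0_lo, b0_hi = b0s[i] - db0, b0s[i] + db0
        b1_lo, b1_hi = b1s[j] - db1, b1s[j] + db1
    return b0s[i], b1s[j]


class TestFirthLogistic:
    def test_finite_estimate_under_complete_separation(self):
        g = np.array([1.0] * 5 + [0.0] * 20)
        y = np.array([1] * 5 + [0] * 20)  # all carriers are cases
        r = fd.firth_logistic(g, y)
        assert np.isfinite(r.beta) and r.converged
        assert r.or_ > 1

    def test_null_2x2(self):
        g = np.tile([1.0] * 10 + [0.0] * 40, 2)
        y = np.repeat([1, 0], 50)
        r = fd.firth_logistic(g, y)
        assert r.or_ == pytest.approx(1.0, abs=0.02)
        assert r.p > 0.9

    def test_matches_grid_search_oracle(self):
        # 10/90 carriers among cases vs 5/95 among controls
        g = np.array([1.0] * 10 + [0.0] * 90 + [1.0] * 5 + [0.0] * 95)
        y = np.repeat([1, 0], 100)
        r = fd.firth_logistic(g, y)
        b0, b1 = _firth_grid_oracle(g, y, (-3.0, 1.0), (-1.0, 2.5))
        assert r.beta == pytest.approx(b1, abs=1e-3)

    def test_approaches_mle_as_penalty_vanishes(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        y = (rng.random(400) < expit(0.3 + 0.5 * x)).astype(int)
        r = fd.firth_logistic(x, y, penalty_weight=1e-9)
        mle = sm.Logit(y, sm.add_constant(x)).fit(disp=0).params[1]
        assert r.beta == pytest.approx(mle, abs=1e-6)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(300):
            x = (rng.random(400) < 0.3).astype(float)
            y = (rng.random(400) < 0.2).astype(int)
            if y.sum() in (0, 400):
                continue
            pvals.append(fd.firth_logistic(x, y).p)
        from scipy import stats as sps

        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


@pytest.fixture(scope="module")
def scan():
    """A phenome-scan-sized null+causal endpoint battery at biobank scale
    across several seeds, reused by the ranking and calibration tests."""
    runs = []
    for seed in range(10):
        rng = np.random.default_rng(700 + seed)
        N = 200_000
        g = rng.binomial(2, 0.00214, N).astype(float)
        spec = fd.SurvivalSpec(
            or_map=fd.default_endpoint_map(30, {"dementia": 2.1, "alzheimer": 2.1})
        )
        ph = fd.simulate_phenotypes(g, spec, seed=800 + seed)
        res = fd.phewas(g, ph, list(spec.or_map), covariates=("sex", "apoe_e4"))
        runs.append(res)
    return runs


class TestPhewas:
    def test_causal_endpoints_rank_first(self, scan):
        hits = 0
        for res in scan:
            top2 = {r.endpoint for r in sorted(res, key=lambda r: r.p)[:2]}
            hits += top2 == {"dementia", "alzheimer"}
        assert hits >= 9  # >= 90% of seeds

    def test_null_p_values_uniform_pooled(self, scan):
        from scipy import stats as sps

        null_p = [
            r.p for res in scan for r in res if r.endpoint.startswith("null")
        ]
        assert sps.kstest(null_p, "uniform").pvalue > 0.01

    def test_duplicated_endpoint_identical(self):
        rng = np.random.default_rng(3)
        g = (rng.random(2_000) < 0.1).astype(float)
        ph = pd.DataFrame({"e1": (rng.random(2_000) < 0.1).astype(int)})
        ph["e2"] = ph["e1"]
        r1, r2 = fd.phewas(g, ph, ["e1", "e2"])
        assert (r1.beta, r1.p) == (r2.beta, r2.p)


# ---------------------------------------------------------------------------
# regional chi-square


class TestRegionalChi2:
    def test_toy_table_matches_textbook_formula(self):
        flags = np.concatenate([np.ones(10), np.zeros(990), np.ones(2), np.zeros(998)])
        labels = np.array(["a"] * 1000 + ["b"] * 1000)
        chi2, dof, p = fd.regional_freq_test(flags, labels)
        table = np.array([[10, 990], [2, 998]])
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_hand = ((table - exp) ** 2 / exp).sum()
        assert chi2 == pytest.approx(chi2_hand, abs=1e-6)
        assert dof == 1

    def test_null_regional_distribution_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            flags = rng.binomial(1, 0.01, 40_000)
            labels = fd.assign_regions(40_000, {"a": 0.3, "b": 0.3, "c": 0.4},
                                       seed=950 + seed)
            _, _, p = fd.regional_freq_test(flags, labels)
            hits += p <= 0.05
        assert hits <= 1  # null holds in >= 19/20 seeds

    def test_sparse_table_warns(self):
        flags = np.zeros(100)
        flags[0] = 1
        labels = np.array(["a"] * 50 + ["b"] * 50)
        with pytest.warns(UserWarning, match="expected counts"):
            fd.regional_freq_test(flags, labels)


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKaplanMeier:
    def test_no_events_flat_survival(self):
        c = fd.km_curve(np.array([1.0, 2.0, 3.0]), np.zeros(3, dtype=bool))
        assert c.survival_at(5.0) == 1.0 and len(c.times) == 0

    def test_all_events_product_limit_by_hand(self):
        c = fd.km_curve(np.array([1.0, 2.0, 3.0]), np.ones(3, dtype=bool))
        assert np.allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_by_hand(self):
        c = fd.km_curve(np.array([1.0, 2.0, 3.0]), np.array([False, True, True]))
        assert c.survival_at(2.0) == pytest.approx(0.5)
        assert c.survival_at(3.0) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(1.0, 200) + 1e-6
        c = fd.km_curve(t, np.ones(200, dtype=bool))
        for q in [0.1, 0.5, 1.0, 2.0]:
            assert c.survival_at(q) == pytest.approx((t > q).mean())

    def test_matches_lifelines(self):
        import lifelines

        rng = np.random.default_rng(14)
        t = rng.exponential(1.0, 300) + 1e-6
        e = rng.random(300) < 0.6
        c = fd.km_curve(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        sf = kmf.survival_function_.iloc[:, 0]
        for tt in c.times:
            assert c.survival_at(tt) == pytest.approx(sf.loc[tt], abs=1e-12)

    def test_grouped_curves(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=bool)
        curves = fd.km_curve(t, e, groups=np.array([0, 0, 1, 1]))
        assert set(curves) == {"0", "1"}
        assert curves["0"].survival_at(2.0) == 0.0

    def test_nonpositive_times_rejected(self):
        with pytest.raises(StatsInputError):
            fd.km_curve(np.array([0.0, 1.0]), np.array([True, True]))


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _efron_pll_oracle(beta, t, e, x):
    """Plain-python Efron partial log-likelihood for one covariate."""
    ll = 0.0
    for et in sorted(set(t[e])):
        tied = [i for i in range(len(t)) if t[i] == et and e[i]]
        risk = [i for i in range(len(t)) if t[i] >= et]
        d = len(tied)
        s0_risk = sum(np.exp(beta * x[i]) for i in risk)
        s0_tied = sum(np.exp(beta * x[i]) for i in tied)
        ll += beta * sum(x[i] for i in tied)
        for k in range(d):
            ll -= np.log(s0_risk - (k / d) * s0_tied)
    return ll


def _grid_maximize(fn, lo, hi, steps=201, refinements=5):
    for _ in range(refinements):
        grid = np.linspace(lo, hi, steps)
        vals = [fn(b) for b in grid]
        i = int(np.argmax(vals))
        step = grid[1] - grid[0]
        lo, hi = grid[i] - step, grid[i] + step
    return grid[i]


class TestCoxFit:
    def test_constant_covariate_rejected(self):
        with pytest.raises(StatsInputError):
            fd.cox_fit(np.arange(1, 7.0), np.ones(6, bool), np.zeros(6))
        with pytest.raises(StatsInputError):
            fd.cox_fit(np.arange(1, 7.0), np.zeros(6, bool), np.arange(6.0))

    def test_six_observation_grid_oracle(self):
        t = np.array([2.0, 3.0, 3.0, 5.0, 7.0, 8.0])  # includes a tie
        e = np.array([1, 1, 1, 0, 1, 0], dtype=bool)
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fit = fd.cox_fit(t, e, x)
        b_star = _grid_maximize(lambda b: _efron_pll_oracle(b, t, e, x), -3, 3)
        assert fit.beta[0] == pytest.approx(b_star, abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_sample_untied_grid_oracle(self, seed):
        rng = np.random.default_rng(400 + seed)
        n = rng.integers(5, 9)
        t = rng.exponential(1.0, n) + 0.01
        e = rng.random(n) < 0.8
        if e.sum() == 0:
            e[0] = True
        x = rng.normal(size=n)
        fit = fd.cox_fit(t, e, x)
        b_star = _grid_maximize(lambda b: _efron_pll_oracle(b, t, e, x), -5, 5)
        assert fit.beta[0] == pytest.approx(b_star, abs=1e-4)

    def test_matches_lifelines_with_ties(self):
        import lifelines

        rng = np.random.default_rng(21)
        n = 400
        X = np.column_stack([rng.binomial(1, 0.3, n), rng.normal(size=n)]).astype(float)
        t = np.ceil(rng.exponential(1 / np.exp(0.6 * X[:, 0] - 0.2 * X[:, 1])) * 4) / 4
        e = rng.random(n) < 0.7
        fit = fd.cox_fit(t, e, X)
        df = pd.DataFrame({"t": t, "e": e.astype(int), "a": X[:, 0], "b": X[:, 1]})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.beta, cph.params_.values, atol=1e-4)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-4)

    def test_null_p_values_uniform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(22)
        pvals = []
        for _ in range(200):
            n = 120
            t = rng.exponential(1.0, n) + 1e-9
            e = rng.random(n) < 0.6
            x = rng.normal(size=n)
            if e.sum() < 2:
                continue
            pvals.append(fd.cox_fit(t, e, x).p[0])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_separation_flagged_not_raised(self):
        # carrier dies first always -> monotone likelihood
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = fd.cox_fit(t, e, x)
        assert not fit.converged

    def test_recovery_unbiased_across_seeds(self):
        """Generator -> estimator loop: the mean recovered log-HR across
        seeds is within 2 Monte-Carlo SE of the generative value."""
        spec = fd.SurvivalSpec(hr_map={"carrier": 2.0}, or_map={})
        betas = []
        for seed in range(12):
            rng = np.random.default_rng(500 + seed)
            g = rng.binomial(1, 0.05, 8_000).astype(float)
            ph = fd.simulate_phenotypes(g, spec, seed=600 + seed)
            betas.append(
                fd.cox_fit(ph.age.to_numpy(), ph.event.to_numpy(),
                           ph.carrier.to_numpy().astype(float)).beta[0]
            )
        betas = np.array(betas)
        se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - np.log(2.0)) < 2 * se + 1e-9


# ---------------------------------------------------------------------------
# Hardy-Weinberg


class TestHWE:
    def test_one_in_a_million_approximate(self):
        est = fd.hwe_carrier_frequency(1e-6, approximate=True)
        assert est.het_freq == pytest.approx(0.002)
        assert est.reciprocal == pytest.approx(500)

    def test_one_in_half_million_exact(self):
        est = fd.hwe_carrier_frequency(1 / 500_000, approximate=False)
        assert est.het_freq == pytest.approx(0.0028245, abs=1e-6)
        assert round(est.reciprocal) == 354

    def test_degenerate_prevalence_one(self):
        est = fd.hwe_carrier_frequency(1.0, approximate=False)
        assert est.q == 1.0 and est.het_freq == 0.0

    def test_out_of_range(self):
        with pytest.raises(StatsInputError):
            fd.hwe_carrier_frequency(0.0)
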