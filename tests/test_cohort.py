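"""Cohort simulator: founder haplotype structure, imputation noise model,
phenotype generation, region assignment."""

import dataclasses

import numpy as np
import pytest

import founderdel as fd
from founderdel.cohort import CohortConfigError, DEFAULT_SITES, SurvivalSpec


class TestSimulatePanel:
    def test_zero_founder_frequency_means_no_carriers(self):
        panel = fd.simulate_panel(fd.PanelConfig(N=5_000, founder_freq=0.0), seed=1)
        assert panel.carrier_truth.sum() == 0
        assert panel.haplotypes[:, :, panel.site_index("proxy1")].sum() == 0

    def test_no_recombination_gives_perfect_proxy_ld(self, small_panel):
        # proxy alleles exist only on the founder haplotype (bg freq 0), so
        # without recombination r^2 with the deletion is exactly 1
        cfg = dataclasses.replace(small_panel.config, recomb_rate=0.0)
        panel = fd.simulate_panel(cfg, seed=2)
        hap_proxy = panel.haplotypes[:, :, panel.site_index("proxy1")].ravel()
        r = fd.ld_r2(hap_proxy, _deletion_haplotypes(panel).ravel())
        assert r.r2 == pytest.approx(1.0)

    def test_het_carrier_count_within_binomial_band(self):
        N = 500_000
        panel = fd.simulate_panel(fd.PanelConfig(N=N), seed=3)
        p = 0.00214
        expect = 2 * N * p * (1 - p)
        sd = np.sqrt(2 * N * p * (1 - p))
        n_het = int((panel.carrier_truth == 1).sum())
        assert abs(n_het - expect) < 4 * sd

    def test_bit_reproducible(self):
        cfg = fd.PanelConfig(N=3_000)
        a = fd.simulate_panel(cfg, seed=9)
        b = fd.simulate_panel(cfg, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.carrier_truth, b.carrier_truth)

    def test_invalid_config(self):
        with pytest.raises(CohortConfigError):
            fd.simulate_panel(fd.PanelConfig(founder_freq=0.7))
        with pytest.raises(CohortConfigError):
            fd.simulate_panel(fd.PanelConfig(sites=DEFAULT_SITES[:3]))

    def test_ld_decays_with_generations(self):
        # mean r^2 between the deletion and the farthest tag site is
        # non-increasing in the number of generations of recombination
        means = []
        for G in (0, 40, 160):
            vals = []
            for seed in range(4):
                cfg = fd.PanelConfig(N=30_000, generations=G, recomb_rate=1e-7)
                panel = fd.simulate_panel(cfg, seed=100 + seed)
                hap = panel.haplotypes[:, :, 0].ravel()
                vals.append(fd.ld_r2(hap, _deletion_haplotypes(panel).ravel()).r2)
            means.append(np.mean(vals))
        assert means[0] >= means[1] - 0.05
        assert means[1] >= means[2] - 0.05
        assert means[0] > means[2]  # actual decay at these distances


def _deletion_haplotypes(panel):
    """Phased deletion indicator: the founder haplotype carries the deletion."""
    return panel.founder_haplotypes.astype(np.int8)


class TestImputationNoise:
    def test_zero_error_is_identity_with_unit_gp(self, small_panel):
        imp = fd.add_imputation_noise(small_panel, 0.0, seed=5)
        assert np.array_equal(imp.haplotypes, small_panel.haplotypes)
        assert (imp.gp == 1.0).all() is not True  # GP ~ 1 - Beta(1,99), near 1
        assert (imp.gp > 0.9).mean() > 0.98

    def test_flip_fraction_binomial(self, small_panel):
        imp = fd.add_imputation_noise(small_panel, 0.05, seed=6)
        n_calls = small_panel.haplotypes.size
        flipped = int((imp.haplotypes != small_panel.haplotypes).sum())
        sd = np.sqrt(n_calls * 0.05 * 0.95)
        assert abs(flipped - 0.05 * n_calls) < 3 * sd

    def test_gp_separates_correct_from_flipped_calls(self, small_panel):
        imp = fd.add_imputation_noise(small_panel, 0.1, seed=7)
        correct = (imp.haplotypes == small_panel.haplotypes).all(axis=1)
        acc_high = correct[imp.gp >= 0.99].mean()
        acc_low = correct[imp.gp < 0.99].mean()
        assert acc_high > acc_low


class TestPhenotypes:
    def test_null_hazard_ratios_give_null_logrank(self):
        spec = SurvivalSpec(hr_map={"carrier": 1.0}, or_map={})
        pvals = []
        for seed in range(8):
            dosage = (np.random.default_rng(200 + seed).random(4_000) < 0.2).astype(float)
            ph = fd.simulate_phenotypes(dosage, spec, seed=300 + seed)
            chi2, p = fd.logrank_test(
                ph.age.to_numpy(), ph.event.to_numpy(), (ph.carrier > 0).to_numpy()
            )
            pvals.append(p)
        # under the null, small p-values should not be systematically produced
        assert np.mean(np.array(pvals) < 0.05) <= 0.25

    def test_zero_horizon_censors_everyone(self):
        spec = SurvivalSpec(censor_horizon=0.0, or_map={})
        ph = fd.simulate_phenotypes(np.zeros(100), spec, seed=1)
        assert ph.event.sum() == 0

    def test_endpoint_prevalence_responds_to_or(self):
        spec = SurvivalSpec(or_map={"dementia": 5.0, "null001": 1.0})
        dosage = np.repeat([0.0, 1.0], 20_000)
        ph = fd.simulate_phenotypes(dosage, spec, seed=2)
        prev_car = ph.dementia[ph.carrier == 1].mean()
        prev_non = ph.dementia[ph.carrier == 0].mean()
        assert prev_car > 2 * prev_non
        null_car = ph.null001[ph.carrier == 1].mean()
        null_non = ph.null001[ph.carrier == 0].mean()
        assert abs(null_car - null_non) < 0.02

    def test_cox_recovers_generative_hazard_ratio(self):
        # closed loop: generator -> estimator, single large cohort
        spec = SurvivalSpec(or_map={})
        dosage = np.random.default_rng(42).binomial(2, 0.00215, 400_000).astype(float)
        ph = fd.simulate_phenotypes(dosage, spec, seed=43)
        fit = fd.cox_fit(
            ph.age.to_numpy(),
            ph.event.to_numpy(),
            ph[["carrier", "apoe_e4", "sex"]].to_numpy(),
            terms=("carrier", "apoe_e4", "sex"),
        )
        lo, hi = fit.ci95[0]
        assert lo < 2.14 < hi
        assert fit.ci95[1][0] < 2.30 < fit.ci95[1][1]


class TestRegions:
    def test_single_region(self):
        labels = fd.assign_regions(500, {"all": 1.0}, seed=1)
        assert set(labels) == {"all"}

    def test_two_even_regions_within_band(self):
        labels = fd.assign_regions(10_000, {"a": 0.5, "b": 0.5}, seed=2)
        n_a = (labels == "a").sum()
        assert abs(n_a - 5_000) < 4 * np.sqrt(10_000 * 0.25)

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(CohortConfigError):
            fd.assign_regions(10, {"a": 0.5, "b": 0.4}, seed=1)

    def test_carrier_enrichment_reproduces_regional_maf_ratio(self):
        # regional allele-frequency contrast ~6.3x between the most and
        # least enriched regions
        N = 500_000
        rng = np.random.default_rng(8)
        flags = rng.binomial(2, 0.00214, N)
        freq_map = {"north": 0.12, "west": 0.05, "other": 0.83}
        maf_map = {"north": 0.0040, "west": 0.00063, "other": 0.0021}
        labels = fd.assign_regions(N, freq_map, seed=9, carrier_flags=flags,
                                   region_maf_map=maf_map)
        maf = {
            r: flags[labels == r].sum() / (2 * (labels == r).sum())
            for r in freq_map
        }
        ratio = maf["north"] / maf["west"]
        # Poisson sampling error on the sparse region dominates
        n_west = flags[labels == "west"].sum()
        log_sd = np.sqrt(1 / max(n_west, 1) + 1 / max(flags[labels == "north"].sum(), 1))
        assert abs(np.log(ratio) - np.log(6.3)) < 3 * log_sd


class TestCaseGenotypes:
    def test_cases_are_biallelic_at_proxies(self):
        G = fd.sample_case_genotypes(n_cases=3, seed=10)
        names = [s.name for s in fd.PanelConfig().sites]
        for proxy in ("proxy1", "proxy2"):
            assert (G[:, names.index(proxy)] == 2).all()
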