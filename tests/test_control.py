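"""Negative-control normalization: mode A, control-region EM, invariants."""

import numpy as np
import pytest

from cnvfactor import (
    SpikeInPlan,
    ValidationError,
    default_regions,
    fit_null,
    fit_mixture,
    generate_null,
    identify_control_regions,
    normalize_with_control_regions,
    normalize_with_control_samples,
    posterior_carriers,
    spike_in,
    zscores,
)
from cnvfactor.data import MixtureFit


@pytest.fixture(scope="module")
def spiked_case_control():
    """Cohort with 20 controls and a 50%-frequency deletion in the cases."""
    co = generate_null(n=600, m=60, K=2, seed=5, n_controls=20)
    plan = SpikeInPlan(
        regions=default_regions(600, 6, 10), cnv_type="het_del",
        frequency=0.5, seed=3,
    )
    spiked, truth = spike_in(co.counts, plan)
    return co, plan, spiked, truth


class TestControlSamples:
    def test_beta_unbiased_vs_pooled_fit_biased(self, spiked_case_control):
        co, plan, spiked, truth = spiked_case_control
        spk = np.concatenate([np.arange(s, s + w) for s, w in plan.regions])
        mA = normalize_with_control_samples(spiked, 2)
        mAll = fit_null(spiked, 2)
        rel_A = mA.beta / co.model.beta
        rel_A /= np.median(rel_A)
        rel_all = mAll.beta / co.model.beta
        rel_all /= np.median(rel_all)
        # controls-only estimate is unbiased in the CNV region; the pooled
        # fit absorbs the carriers' missing reads into beta
        assert abs(np.mean(rel_A[spk] - 1)) < 0.03
        assert np.mean(rel_all[spk] - 1) < -0.08

    def test_uniform_doubling_absorbed_by_library_size(self):
        co = generate_null(n=400, m=30, K=2, seed=8, n_controls=15)
        Y = co.counts.values.copy()
        j = 20  # a case sample
        rng = np.random.default_rng(0)
        Y[:, j] = rng.poisson(2.0 * co.lam[:, j])
        doubled = type(co.counts)(Y, co.counts.targets, co.counts.samples)
        model = normalize_with_control_samples(doubled, 2)
        assert model.library_size[j] == Y[:, j].sum()
        assert model.library_size[j] / co.model.library_size[j] == pytest.approx(
            2.0, rel=0.03
        )
        # the doubling is uniform across targets, so the fitted background
        # tracks 2*lam rather than pushing signal into the loadings
        ratio = np.log(model.fitted_mean()[:, j] / (2 * co.lam[:, j]))
        assert abs(ratio.mean()) < 0.05

    def test_null_cases_match_pooled_background(self):
        co = generate_null(n=400, m=40, K=2, seed=13, n_controls=20)
        mA = normalize_with_control_samples(co.counts, 2)
        pooled = fit_null(co.counts, 2)
        zA = zscores(co.counts, mA)
        zP = zscores(co.counts, pooled)
        cases = np.arange(20, 40)
        sd_ratio = zA[:, cases].std(axis=1) / zP[:, cases].std(axis=1)
        assert abs(np.mean(sd_ratio) - 1) < 0.1

    def test_too_few_controls_error_mentions_region_mode(self, small_cohort):
        with pytest.raises(ValidationError, match="control-region"):
            normalize_with_control_samples(small_cohort.counts, 2, controls=[0])


class TestIdentifyControlRegions:
    def test_null_simulation_few_flags(self):
        co = generate_null(n=800, m=60, K=2, seed=17)
        cr = identify_control_regions(co.counts, 2, min_control_targets=100)
        assert cr.istar.size / 800 <= 0.05

    def test_spiked_common_deletion_fully_flagged(self):
        co = generate_null(n=600, m=60, K=2, seed=19)
        plan = SpikeInPlan(regions=[(300, 10)], frequency=0.4, seed=2)
        spiked, _ = spike_in(co.counts, plan)
        cr = identify_control_regions(spiked, 2, min_control_targets=100)
        assert np.isin(np.arange(300, 310), cr.istar).all()

    def test_dispersion_free_matrix_flags_nothing(self, toy_targets, toy_samples):
        import pandas as pd

        from cnvfactor import CountMatrix, SampleTable, TargetSet

        n, m = 60, 10
        targets = TargetSet(
            pd.DataFrame(
                {
                    "chrom": ["chr1"] * n,
                    "start": np.arange(n) * 1000,
                    "end": np.arange(n) * 1000 + 500,
                    "gc": [50.0] * n,
                    "mappability": [0.99] * n,
                }
            )
        )
        samples = SampleTable(pd.DataFrame({"sample_id": [f"s{j}" for j in range(m)]}))
        cm = CountMatrix(np.full((n, m), 100), targets, samples)
        cr = identify_control_regions(cm, 0, min_control_targets=10)
        assert cr.istar.size == 0

    def test_floor_on_remaining_controls(self, small_cohort):
        with pytest.raises(ValidationError, match="negative-control"):
            identify_control_regions(
                small_cohort.counts, 2, istar=np.arange(250), min_control_targets=100
            )

    def test_user_supplied_istar_passthrough(self, small_cohort):
        cr = identify_control_regions(
            small_cohort.counts, 2, istar=[5, 6, 7], min_control_targets=100
        )
        np.testing.assert_array_equal(cr.istar, [5, 6, 7])


class TestMixtureEM:
    def _simulate_target(self, seed, pi=0.4, mu=np.log(0.5), m=200, exact=True):
        rng = np.random.default_rng(seed)
        off = np.log(rng.uniform(100, 300, m))
        h = rng.normal(0, 1, (m, 2))
        g = np.array([0.1, -0.15])
        lam = np.exp(off + 0.3 + h @ g)
        Z = np.zeros(m, dtype=bool)
        if exact:
            Z[rng.choice(m, int(round(pi * m)), replace=False)] = True
        else:
            Z = rng.random(m) < pi
        y = rng.poisson(lam * np.where(Z, np.exp(mu), 1.0))
        return y, off, h, Z

    def test_parameter_recovery(self):
        y, off, h, Z = self._simulate_target(0)
        _, _, fit = fit_mixture(y, off, h)
        assert fit.pi == pytest.approx(0.4, abs=0.05)
        assert fit.mu == pytest.approx(np.log(0.5), abs=0.05)
        # posteriors track the true carriers
        assert ((fit.z_posterior > 0.5) == Z).mean() > 0.95

    def test_em_loglik_monotone(self):
        y, off, h, _ = self._simulate_target(1)
        _, _, fit = fit_mixture(y, off, h)
        diffs = np.diff(fit.ll_trace)
        assert (diffs >= -1e-6 * np.abs(fit.ll_trace[:-1])).all()

    def test_free_mu_reports_minority_branch(self):
        y, off, h, _ = self._simulate_target(2, pi=0.7)
        _, _, fit = fit_mixture(y, off, h)
        assert fit.pi <= 0.5

    def test_null_target_collapses_to_single_component(self):
        rng = np.random.default_rng(3)
        m = 150
        off = np.log(rng.uniform(100, 300, m))
        h = rng.normal(0, 1, (m, 1))
        lam = np.exp(off + 0.2 + 0.1 * h[:, 0])
        y = rng.poisson(lam)
        blog, gv, fit = fit_mixture(y, off, h)
        assert fit.pi <= 0.05
        lam_hat = np.exp(off + blog + h @ gv)
        assert np.abs(np.log(lam_hat / lam)).mean() < 0.05

    def test_pi_zero_matches_plain_null_fit(self):
        co = generate_null(n=400, m=40, K=2, seed=23)
        model, fits = normalize_with_control_regions(
            co.counts, np.arange(50, 60), 2
        )
        plain = fit_null(co.counts, 2)
        lam_b = model.fitted_mean()[50:60]
        lam_p = plain.fitted_mean()[50:60]
        assert np.abs(np.log(lam_b / lam_p)).mean() < 0.05

    def test_mode_equivalence_with_true_regions(self, spiked_case_control):
        co, plan, spiked, truth = spiked_case_control
        spk = np.concatenate([np.arange(s, s + w) for s, w in plan.regions])
        mA = normalize_with_control_samples(spiked, 2)
        mB, _ = normalize_with_control_regions(spiked, spk, 2)
        rel = np.abs(np.log(mB.fitted_mean() / mA.fitted_mean()))
        assert rel.mean() < 0.05


class TestPosteriorCarriers:
    def test_threshold_is_strict(self):
        fits = [
            MixtureFit(0, 0.3, -0.6, np.array([0.9, 0.5, 0.0])),
        ]
        out = posterior_carriers(fits, cutoff=0.5)
        np.testing.assert_array_equal(out, [[True, False, False]])

    def test_empty_inputs(self):
        assert posterior_carriers([]).size == 0
        fits = [MixtureFit(0, 0.0, 0.0, np.zeros(4))]
        assert not posterior_carriers(fits).any()
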