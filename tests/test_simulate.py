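"""Synthetic-cohort generator, spike-ins, scoring, and the benchmark."""

import numpy as np
import pytest

from cnvfactor import (
    SegmentCall,
    SpikeInPlan,
    ValidationError,
    default_regions,
    generate_null,
    run_benchmark,
    score_calls,
    spike_in,
)


class TestGenerateNull:
    def test_seed_determinism_byte_identical(self):
        a = generate_null(n=200, m=20, K=2, seed=9)
        b = generate_null(n=200, m=20, K=2, seed=9)
        np.testing.assert_array_equal(a.counts.values, b.counts.values)
        assert a.counts.targets == b.counts.targets

    def test_counts_match_expectation(self, small_cohort):
        # pooled z-statistic over all cells: Y ~ Poisson(lam)
        resid = (small_cohort.counts.values - small_cohort.lam) / np.sqrt(
            small_cohort.lam
        )
        assert abs(resid.mean()) < 3 / np.sqrt(resid.size)

    def test_column_totals_near_library_size(self, small_cohort):
        rel = np.abs(
            small_cohort.counts.values.sum(0) / small_cohort.model.library_size - 1
        )
        assert (rel <= 0.02).all()

    def test_truth_model_reproduces_lam(self, small_cohort):
        np.testing.assert_allclose(
            small_cohort.model.fitted_mean(), small_cohort.lam, rtol=1e-8
        )

    def test_post_qc_background_coverage_floor(self, small_cohort):
        # the floor is enforced on the expected coverage; observed medians
        # fluctuate around it
        med = np.median(small_cohort.lam, axis=1)
        assert med.min() >= 44
        obs = np.median(small_cohort.counts.values, axis=1)
        assert obs.min() >= 30


class TestSpikeIn:
    def test_expected_depth_ratio_half(self, small_cohort):
        # fixed c=1 (sd 0): carrier depth expectation is exactly y/2
        plan = SpikeInPlan(
            regions=[(50, 100)], frequency=0.9, c_sd=0.0, seed=1
        )
        spiked, truth = spike_in(small_cohort.counts, plan)
        car = truth.carrier[0]
        ratio = (
            spiked.values[50:150][:, car].sum()
            / small_cohort.counts.values[50:150][:, car].sum()
        )
        assert ratio == pytest.approx(0.5, abs=0.01)

    def test_frequency_zero_is_identity(self, small_cohort):
        plan = SpikeInPlan(regions=[(10, 5)], frequency=0.0, seed=2)
        spiked, truth = spike_in(small_cohort.counts, plan)
        np.testing.assert_array_equal(spiked.values, small_cohort.counts.values)
        assert not truth.carrier.any()

    def test_clonal_mixture_fraction_one_identical(self, small_cohort):
        a, _ = spike_in(
            small_cohort.counts,
            SpikeInPlan(regions=[(10, 5)], cnv_type="het_del", frequency=0.3, seed=4),
        )
        b, _ = spike_in(
            small_cohort.counts,
            SpikeInPlan(
                regions=[(10, 5)], cnv_type="mixture", frequency=0.3,
                mixture_fraction=1.0, seed=4,
            ),
        )
        np.testing.assert_array_equal(a.values, b.values)

    def test_thinning_preserves_poisson_moments(self):
        rng = np.random.default_rng(6)
        lam, q = 200.0, 0.5
        y = rng.binomial(rng.poisson(lam, 50000), q)
        assert y.mean() == pytest.approx(lam * q, rel=0.02)
        assert y.var() == pytest.approx(lam * q, rel=0.05)  # still Poisson

    def test_gain_superposition_expectation(self, small_cohort):
        plan = SpikeInPlan(
            regions=[(50, 100)], cnv_type="dup", frequency=0.9, c_sd=0.0, seed=7
        )
        spiked, truth = spike_in(small_cohort.counts, plan)
        car = truth.carrier[0]
        ratio = (
            spiked.values[50:150][:, car].sum()
            / small_cohort.counts.values[50:150][:, car].sum()
        )
        assert ratio == pytest.approx(1.5, abs=0.01)  # c=3 -> y * 3/2

    def test_batch_correlation_achieved(self):
        co = generate_null(n=100, m=200, K=1, seed=10)
        plan = SpikeInPlan(
            regions=[(20, 10)], frequency=0.4, batch_corr=0.5, seed=11
        )
        _, truth = spike_in(co.counts, plan)
        x = truth.carrier[0].astype(float)
        b = (co.counts.samples.batch == co.counts.samples.batch[0]).astype(float)
        r = np.corrcoef(x, b)[0, 1]
        assert r == pytest.approx(0.5, abs=0.1)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            SpikeInPlan(regions=[(10, 10), (15, 10)], frequency=0.2)

    def test_region_outside_range_rejected(self, small_cohort):
        plan = SpikeInPlan(regions=[(295, 10)], frequency=0.2)
        with pytest.raises(ValidationError, match="range"):
            spike_in(small_cohort.counts, plan)

    def test_controls_never_carriers(self):
        co = generate_null(n=100, m=30, K=1, seed=12, n_controls=10)
        plan = SpikeInPlan(regions=[(10, 10)], frequency=0.9, seed=13)
        _, truth = spike_in(co.counts, plan)
        assert not truth.carrier[:, :10].any()


class TestScoreCalls:
    def _spiked(self, frequency=0.4, seed=20):
        co = generate_null(n=100, m=20, K=0, seed=seed)
        plan = SpikeInPlan(regions=[(40, 10)], frequency=frequency, seed=seed)
        return spike_in(co.counts, plan)

    def _perfect_calls(self, spiked, truth):
        calls = []
        for j in np.flatnonzero(truth.carrier[0]):
            calls.append(
                SegmentCall(
                    sample_id=spiked.samples.sample_id[j], chrom="chr16",
                    start=0, end=1, first_target=40, last_target=49,
                    copy_number=1.0, lratio=100.0, state="one_copy_del",
                )
            )
        return calls

    def test_perfect_calls_score_one(self):
        spiked, truth = self._spiked()
        sc = score_calls(self._perfect_calls(spiked, truth), truth, spiked)
        assert (sc["precision"], sc["recall"], sc["f1"]) == (1.0, 1.0, 1.0)

    def test_no_calls_precision_one_recall_zero(self):
        spiked, truth = self._spiked()
        sc = score_calls([], truth, spiked)
        assert sc["precision"] == 1.0
        assert sc["recall"] == 0.0

    def test_f_measure_harmonic_mean(self):
        # P=0.6, R=0.9 -> F = 2*0.54/1.5 = 0.72
        spiked, truth = self._spiked(seed=21)
        carriers = np.flatnonzero(truth.carrier[0])
        calls = []
        sid = spiked.samples.sample_id
        # cover 9 of each carrier's 10 truth targets
        for j in carriers:
            calls.append(
                SegmentCall(
                    sample_id=sid[j], chrom="chr16", start=0, end=1,
                    first_target=41, last_target=49, copy_number=1.0,
                    lratio=50.0, state="one_copy_del",
                )
            )
        # plus wrong calls: 6 cells per carrier outside the truth
        for j in carriers:
            calls.append(
                SegmentCall(
                    sample_id=sid[j], chrom="chr16", start=0, end=1,
                    first_target=60, last_target=65, copy_number=1.0,
                    lratio=50.0, state="one_copy_del",
                )
            )
        sc = score_calls(calls, truth, spiked)
        assert sc["precision"] == pytest.approx(0.6)
        assert sc["recall"] == pytest.approx(0.9)
        assert sc["f1"] == pytest.approx(0.72)

    def test_majority_event_scored_relative_to_population(self):
        # a 90%-frequency deletion may equivalently be recovered as
        # duplication calls in the non-carriers
        spiked, truth = self._spiked(frequency=0.9, seed=22)
        non_carriers = np.flatnonzero(truth.eligible & ~truth.carrier[0])
        calls = [
            SegmentCall(
                sample_id=spiked.samples.sample_id[j], chrom="chr16",
                start=0, end=1, first_target=40, last_target=49,
                copy_number=3.0, lratio=100.0, state="gain",
            )
            for j in non_carriers
        ]
        sc = score_calls(calls, truth, spiked)
        assert sc["recall"] == 1.0
        assert sc["precision"] == 1.0


class TestRunBenchmark:
    def test_single_cell_shape_and_determinism(self):
        kw = dict(
            frequencies=[0.3], lengths=[8], methods=["pooled_null"],
            reps=1, n=150, m=15, K=1, seed=5, n_regions=3,
        )
        a = run_benchmark(**kw)
        b = run_benchmark(**kw)
        assert len(a) == 1
        assert a.equals(b)
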