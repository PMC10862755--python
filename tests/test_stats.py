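import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsehmm.cloud_search import CloudScores
from sparsehmm.profile import AMINO, TargetSequence
from sparsehmm.reference_dp import (backward_full, forward_full, mea_full,
                                    posterior_full)
from sparsehmm.stats import (FilterThresholds, LAMBDA_PER_NAT, apply_filters,
                             bias_correct, calibrate, cloud_filter_estimate,
                             define_boundaries, evalue, fit_exponential_tail,
                             fit_gumbel_location, pvalue, pvalue_from_evalue)
from sparsehmm.synthetic import make_profile, random_background_sequence


class TestExponentialTailFit:
    def test_recovers_location_of_simulated_tail(self, rng):
        draws = rng.exponential(1.0 / LAMBDA_PER_NAT, size=10_000)
        tail = fit_exponential_tail(draws)
        assert abs(tail.tau) < 0.2

    def test_location_equivariance(self, rng):
        scores = rng.exponential(1.0, size=2000)
        a = fit_exponential_tail(scores)
        b = fit_exponential_tail(scores + 3.5)
        assert b.tau == pytest.approx(a.tau + 3.5, abs=1e-9)
        assert b.lam == a.lam

    def test_degenerate_sample_errors(self):
        with pytest.raises(ValueError, match="degenerate|equal"):
            fit_exponential_tail(np.ones(500))

    def test_pvalue_closed_form_and_boundaries(self, rng):
        tail = fit_exponential_tail(rng.exponential(1.0, size=5000))
        assert tail.pvalue(tail.tau) == pytest.approx(1.0)
        s = tail.tau + math.log(1e4) / tail.lam
        assert tail.pvalue(s) == pytest.approx(1e-4, rel=1e-9)
        grid = np.linspace(tail.tau - 2, tail.tau + 20, 100)
        p = tail.pvalue(grid)
        assert np.all(np.diff(p) <= 0)
        assert np.all((p > 0) & (p <= 1))


class TestGumbelFit:
    def test_anchored_quantile_is_calibrated(self, rng):
        draws = rng.gumbel(2.0, 1.0 / LAMBDA_PER_NAT, size=20_000)
        g = fit_gumbel_location(draws[:10_000])
        p = g.pvalue(draws[10_000:])
        # fresh-sample exceedance at the 5% point within binomial error
        rate = (p <= 0.05).mean()
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 10_000)

    def test_no_seed_trials_get_pvalue_one(self, rng):
        draws = np.concatenate([rng.gumbel(0, 1, size=900),
                                np.full(100, -np.inf)])
        g = fit_gumbel_location(draws)
        assert g.support == pytest.approx(0.9)
        assert g.pvalue(-np.inf) == 1.0


class TestCalibrate:
    def test_deterministic_given_seed(self, medium_profile):
        a = calibrate(medium_profile, n_samples=200, rng_seed=5)
        b = calibrate(medium_profile, n_samples=200, rng_seed=5)
        assert a.forward_tail.tau == b.forward_tail.tau

    def test_minimum_sample_size_enforced(self, medium_profile):
        with pytest.raises(ValueError):
            calibrate(medium_profile, n_samples=50)

    def test_empirical_exceedance_matches_fit(self, medium_profile, rng):
        """Fresh null scores exceed the fitted 1% point at ~1% rate."""
        from sparsehmm.reference_dp import forward_score_batch
        calib = calibrate(medium_profile, n_samples=1000, rng_seed=3)
        seqs = rng.choice(20, size=(8000, 100), p=AMINO.background)
        p = pvalue(forward_score_batch(medium_profile, seqs), calib)
        rate = (p <= 0.01).mean()
        assert abs(rate - 0.01) < 3 * math.sqrt(0.01 * 0.99 / 8000)

    def test_null_pvalues_uniform_at_filter_levels(self, medium_profile, rng):
        """Null P-values behave uniformly where the filters operate.

        With the tail rate fixed by convention, exact distributional
        uniformity of the shallow tail is not achievable; what matters for
        filter calibration is that P(P-value <= x) = x at the thresholds
        the pipeline uses, which is checked here at 10^4 fresh nulls
        within 3x binomial standard error per level.
        """
        from sparsehmm.reference_dp import forward_score_batch
        from sparsehmm.stats import FORWARD_TAIL_MASS
        calib = calibrate(medium_profile, n_samples=1000, rng_seed=3)
        seqs = rng.choice(20, size=(10_000, 100), p=AMINO.background)
        p = np.asarray(pvalue(forward_score_batch(medium_profile, seqs), calib))
        # two sampling layers: the fresh test sample, and the calibration
        # anchor (an order statistic of 1000 draws, ~1/sqrt(k) relative SE
        # on every tail rate)
        anchor_rel_se = 1.0 / math.sqrt(1000 * FORWARD_TAIL_MASS)
        for level in (0.04, 0.02, 0.01, 0.004, 0.001):
            rate = (p <= level).mean()
            se = math.sqrt(level * (1 - level) / 10_000
                           + (level * anchor_rel_se) ** 2)
            assert abs(rate - level) <= 3 * se, (level, rate)


class TestEvalues:
    def test_arithmetic(self):
        assert evalue(1e-4, 1000) == pytest.approx(0.1)
        assert pvalue_from_evalue(0.05, 5000) == pytest.approx(1e-5)

    def test_rank_preservation_under_db_size(self, rng):
        p = rng.uniform(size=50)
        small = np.argsort(evalue(p, 10))
        large = np.argsort(evalue(p, 100000))
        assert np.array_equal(small, large)


class TestCloudFilterEstimate:
    def test_printed_formula(self):
        est = cloud_filter_estimate(CloudScores(12.0, 9.0, 11.0, 8.5))
        assert est == pytest.approx(14.5)  # Z=3, A=2.5, max=9

    def test_zero_extension_identity(self):
        est = cloud_filter_estimate(CloudScores(7.0, 7.0, 6.0, 6.0))
        assert est == pytest.approx(7.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(st.floats(-50, 50), st.floats(0, 30),
                     st.floats(-50, 50), st.floats(0, 30)))
    def test_formula_contract_property(self, vals):
        infwd, z, inbkwd, a = vals
        cs = CloudScores(infwd + z, infwd, inbkwd + a, inbkwd)
        est = cloud_filter_estimate(cs)
        assert est == pytest.approx(a + max(infwd, inbkwd) + z, abs=1e-9)

    def test_bulk_random_scores(self, rng):
        z = rng.uniform(0, 30, size=10_000)
        a = rng.uniform(0, 30, size=10_000)
        infwd = rng.normal(size=10_000) * 10
        inbkwd = rng.normal(size=10_000) * 10
        for k in range(10_000):
            cs = CloudScores(infwd[k] + z[k], infwd[k],
                             inbkwd[k] + a[k], inbkwd[k])
            est = cloud_filter_estimate(cs)
            assert est == pytest.approx(
                a[k] + max(infwd[k], inbkwd[k]) + z[k], abs=1e-9)

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            cloud_filter_estimate(CloudScores(5.0, 6.0, 1.0, 0.0))


class _FakeHit:
    def __init__(self, seed_p, cloud_p=None, forward_p=None):
        self.seed_pvalue = seed_p
        self.cloud_pvalue = cloud_p
        self.forward_pvalue = forward_p
        self.stage = None


class TestApplyFilters:
    def test_survivor_passes_all_stages(self):
        h = _FakeHit(1e-3, 1e-4, 5e-5)
        assert apply_filters([h]) == [h]
        assert h.stage == "reported"

    def test_cloud_rejection_before_forward(self):
        h = _FakeHit(1e-3, 0.01, None)
        assert apply_filters([h]) == []
        assert h.stage == "cloud"

    def test_seed_rejection_at_threshold(self):
        h = _FakeHit(0.01)
        apply_filters([h])
        assert h.stage == "seed"

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            FilterThresholds(seed_p=1e-4, cloud_p=1e-3, forward_p=0.01)


class TestBiasCorrection:
    def _posterior(self, hmm, seq):
        fwd = forward_full(hmm, seq)
        bwd = backward_full(hmm, seq)
        post = posterior_full(fwd, bwd)
        return mea_full(post), post, fwd.score

    def test_background_like_alignment_gets_zero(self, rng):
        # decoy target: the weighted emission mix beats background nowhere
        hmm = make_profile(15, rng)
        seq = random_background_sequence(20, rng)
        aln, post, score = self._posterior(hmm, seq)
        corrected, corr = bias_correct(aln, post, hmm, seq, score)
        assert corr >= 0.0
        assert corrected <= score + 1e-12

    def test_exactly_zero_when_mix_equals_background(self, rng):
        # a profile whose every match row IS the background
        from sparsehmm.profile import ProfileHMM
        m = 10
        match = np.tile(AMINO.background, (m + 1, 1))
        ones = np.ones(m + 1)
        hmm = ProfileHMM("flat", m, match, AMINO.background.copy(),
                         ones * 0.9, ones * 0.05, ones * 0.05,
                         ones * 0.6, ones * 0.4, ones * 0.7, ones * 0.3)
        seq = random_background_sequence(12, np.random.default_rng(0))
        aln, post, score = self._posterior(hmm, seq)
        _, corr = bias_correct(aln, post, hmm, seq, score)
        assert corr == pytest.approx(0.0, abs=1e-6)

    def test_homopolymer_is_penalized(self, rng):
        hmm = make_profile(12, rng)
        # target = pure run of the profile's most common consensus residue
        res = AMINO.index(max(set(hmm.consensus), key=hmm.consensus.count))
        seq = TargetSequence("homo", np.full(15, res))
        aln, post, score = self._posterior(hmm, seq)
        corrected, corr = bias_correct(aln, post, hmm, seq, score)
        assert corr > 0.0
        assert corrected < score


class TestBoundaries:
    def test_sharp_diagonal_span(self, rng):
        from sparsehmm.profile import profile_from_sequence
        seq = TargetSequence.from_string("s", "WCWHMWYC")
        hmm = profile_from_sequence(seq)
        post = posterior_full(forward_full(hmm, seq), backward_full(hmm, seq))
        span = define_boundaries(post)
        assert span == (1, 8)

    def test_uniform_noise_yields_no_span(self):
        class P:
            pn = np.full(21, 0.5)
            pc = np.full(21, 0.5)
        assert define_boundaries(P()) is None
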