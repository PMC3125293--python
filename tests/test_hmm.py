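import numpy as np
import pytest

from updown import (DOWN, UP, GaussianHMM, HMMParams, ObservationSequence,
                    SegmentSet, hmm_forward_backward, hmm_viterbi)
from updown.hmm import emission_loglik, robustify_outliers, windowed_mean_update

from .conftest import make_feature_obs
from .oracles import hmm_enumerate

FS = 50.0


def random_params(rng, T):
    A = rng.dirichlet([3, 1], size=2)
    pi = rng.dirichlet([1, 1])
    means = np.tile(np.sort(rng.normal(size=2)), (T, 1)) + \
        rng.normal(0, 0.05, (T, 2))
    sds = rng.uniform(0.3, 1.2, 2)
    params = HMMParams(A, pi[None, :], means, sds ** 2, None)
    return params, A, pi, means, sds


class TestExactInference:
    def test_forward_backward_matches_enumeration(self):
        """Posterior marginals and log-likelihood equal brute-force
        enumeration over all 2^T paths (T <= 10), to 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            T = int(rng.integers(2, 11))
            y = rng.normal(size=T)
            params, A, pi, means, sds = random_params(rng, T)
            obs = ObservationSequence(y, FS)
            post = hmm_forward_backward(params, obs)
            ll_o, g_o, _ = hmm_enumerate(y, A, pi, means, sds)
            assert abs(post.loglik - ll_o) < 1e-10
            assert np.abs(post.gamma - g_o).max() < 1e-10
            np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_viterbi_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            T = int(rng.integers(2, 11))
            y = rng.normal(size=T)
            params, A, pi, means, sds = random_params(rng, T)
            seq = hmm_viterbi(params, ObservationSequence(y, FS))
            _, _, best = hmm_enumerate(y, A, pi, means, sds)
            assert np.array_equal(seq.labels[0], best)

    def test_symmetric_model_gives_uniform_posteriors(self):
        """Identical state-conditional distributions, symmetric A, uniform
        pi: gamma = (1/2, 1/2) everywhere."""
        rng = np.random.default_rng(2)
        T = 40
        params = HMMParams(np.array([[0.7, 0.3], [0.3, 0.7]]), [[0.5, 0.5]],
                           np.zeros((T, 2)), np.array([1.0, 1.0]), None)
        post = hmm_forward_backward(params, ObservationSequence(
            rng.normal(size=T), FS))
        np.testing.assert_allclose(post.gamma, 0.5, atol=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        T = 30
        y = rng.normal(size=T)
        params, *_ = random_params(rng, T)
        obs = ObservationSequence(y, FS)
        a = hmm_forward_backward(params, obs)
        b = hmm_forward_backward(params.swap_labels(), obs)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-10)
        np.testing.assert_allclose(a.gamma, b.gamma[:, ::-1], atol=1e-12)

    def test_segments_are_independent(self):
        """Per-segment log-likelihoods add; posteriors in one segment are
        untouched by edits in another."""
        rng = np.random.default_rng(4)
        y = rng.normal(size=40)
        params, *_ = random_params(rng, 40)
        seg = SegmentSet([(0, 25), (25, 40)], FS)
        joint = hmm_forward_backward(params, ObservationSequence(y, FS, seg))
        p1 = HMMParams(params.A, params.pi, params.mean_traj[:25],
                       params.covs, None)
        p2 = HMMParams(params.A, params.pi, params.mean_traj[25:],
                       params.covs, None)
        a = hmm_forward_backward(p1, ObservationSequence(y[:25], FS))
        b = hmm_forward_backward(p2, ObservationSequence(y[25:], FS))
        assert joint.loglik == pytest.approx(a.loglik + b.loglik, abs=1e-9)
        np.testing.assert_allclose(joint.gamma[:25], a.gamma, atol=1e-12)
        # edit second segment: first segment's posteriors unchanged
        y2 = y.copy()
        y2[30:] += 5.0
        joint2 = hmm_forward_backward(params,
                                      ObservationSequence(y2, FS, seg))
        np.testing.assert_allclose(joint2.gamma[:25], joint.gamma[:25],
                                   atol=1e-12)

    def test_near_zero_switching_locks_single_state(self):
        """Off-diagonal transition mass 1e-12: the MAP path is constant in
        the single most likely state."""
        rng = np.random.default_rng(5)
        T = 30
        y = rng.normal(0.8, 1.0, size=T)  # slightly UP-ish data
        A = np.array([[1 - 1e-12, 1e-12], [1e-12, 1 - 1e-12]])
        params = HMMParams(A, [[0.5, 0.5]], np.tile([-1.0, 1.0], (T, 1)),
                           np.array([1.0, 1.0]), None)
        seq = hmm_viterbi(params, ObservationSequence(y, FS))
        assert len(np.unique(seq.labels[0])) == 1

    def test_noiseless_two_level_signal_recovered(self):
        lab = (np.arange(100) // 10) % 2
        y = np.where(lab, 1.0, -1.0)
        params = HMMParams(np.array([[0.9, 0.1], [0.1, 0.9]]), [[0.5, 0.5]],
                           np.tile([-1.0, 1.0], (100, 1)),
                           np.array([0.04, 0.04]), None)
        seq = hmm_viterbi(params, ObservationSequence(y, FS))
        assert np.array_equal(seq.labels[0], lab)


class TestEMFit:
    def test_loglik_monotone_and_parameters_recovered(self):
        """EM on separable synthetic data: non-decreasing log-likelihood,
        means within 3 SE, SDs within 15%."""
        rng = np.random.default_rng(6)
        obs, labels = make_feature_obs(rng, n_seconds=60.0)
        model = GaussianHMM(obs, mean_window_s=None)
        params0 = HMMParams(np.array([[0.95, 0.05], [0.05, 0.95]]),
                            [[0.5, 0.5]],
                            np.tile([-0.8, 0.8], (obs.n_samples, 1)),
                            np.array([0.4, 0.4]), None)
        res = model.fit(init=params0, max_iter=50)
        d = np.diff(res.loglik_trace)
        assert np.all(d >= -1e-8 * np.abs(res.loglik_trace[:-1]))
        for k, mu_true, sd_true in ((DOWN, -1.0, 0.5), (UP, 1.0, 0.5)):
            n_k = np.sum(labels == k)
            mu_hat = res.params.mean_traj[0, k, 0]
            assert abs(mu_hat - mu_true) < 3 * sd_true / np.sqrt(n_k)
            sd_hat = np.sqrt(res.params.covs[k, 0, 0])
            assert abs(sd_hat - sd_true) / sd_true < 0.15

    def test_full_window_reduces_to_constant_mean_update(self):
        """A boxcar spanning the whole record makes the windowed mean update
        equal the classical constant-mean M step to 1e-10."""
        rng = np.random.default_rng(7)
        obs, _ = make_feature_obs(rng, n_seconds=30.0)
        gamma = rng.dirichlet([1, 1], size=obs.n_samples)
        wide = windowed_mean_update(obs, gamma, window_s=1e6)
        const = windowed_mean_update(obs, gamma, window_s=None)
        np.testing.assert_allclose(wide, const, atol=1e-10)

    def test_summary_mentions_fit_quality(self):
        rng = np.random.default_rng(8)
        obs, _ = make_feature_obs(rng, n_seconds=60.0)
        res = GaussianHMM(obs, mean_window_s=None).fit(max_iter=10)
        s = res.summary()
        assert "log-likelihood" in s and "iterations" in s


class TestRobustFallback:
    def _params(self, T):
        # UP variance four times DOWN's: heavy tail favours UP far out
        return HMMParams(np.array([[0.9, 0.1], [0.1, 0.9]]), [[0.5, 0.5]],
                         np.tile([-1.0, 1.0], (T, 1)),
                         np.array([0.25, 1.0]), None)

    def test_outlier_reassigned_to_nearer_mean(self):
        """A sample at DOWN_mean - 10 SD: the plain model prefers UP (wider
        variance); the pooled-variance fallback prefers DOWN (nearer mean)."""
        T = 3
        y = np.array([-1.0, -1.0 - 10 * 0.5, -1.0])
        obs = ObservationSequence(y, FS)
        params = self._params(T)
        plain = emission_loglik(params, obs)
        robust = emission_loglik(params, obs, robust_trigger_sd=4.0)
        assert plain[1, UP] > plain[1, DOWN]
        assert robust[1, DOWN] > robust[1, UP]
        mask = robustify_outliers(params, obs, 4.0)
        assert mask.tolist() == [False, True, False]

    def test_no_trigger_means_no_change(self):
        rng = np.random.default_rng(9)
        T = 50
        params = self._params(T)
        y = np.where(rng.random(T) < 0.5, -1.0, 1.0) + \
            0.3 * rng.standard_normal(T)
        obs = ObservationSequence(y, FS)
        assert not robustify_outliers(params, obs, 4.0).any()
        np.testing.assert_allclose(emission_loglik(params, obs),
                                   emission_loglik(params, obs, 4.0))

    def test_symmetric_outlier_decided_by_transitions(self):
        """Under the pooled equal-variance model, mirror-image outliers have
        mirror-image emission likelihoods, so with a symmetric transition
        structure the posteriors mirror exactly -- the wider-variance state
        no longer captures far-out samples."""
        params = HMMParams(np.array([[0.5, 0.5], [0.5, 0.5]]), [[0.5, 0.5]],
                           np.tile([-1.0, 1.0], (1, 1)),
                           np.array([0.04, 0.16]), None)
        obs_hi = ObservationSequence(np.array([30.0]), FS)
        obs_lo = ObservationSequence(np.array([-30.0]), FS)
        r_hi = emission_loglik(params, obs_hi, robust_trigger_sd=4.0)
        r_lo = emission_loglik(params, obs_lo, robust_trigger_sd=4.0)
        assert r_hi[0, UP] == pytest.approx(r_lo[0, DOWN], abs=1e-9)
        g_hi = hmm_forward_backward(params, obs_hi, 4.0).gamma
        g_lo = hmm_forward_backward(params, obs_lo, 4.0).gamma
        np.testing.assert_allclose(g_hi[0], g_lo[0, ::-1], atol=1e-9)
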