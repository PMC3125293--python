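import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from updown.durations import (DurationModel, fit_duration_family,
                              fit_durations_gamma, fit_durations_invgauss,
                              fit_expfam_duration, loglik_per_sample,
                              nonparametric_duration_mle)


def model(family, d_max=100, **params):
    return DurationModel(family, params, d_max)


class TestPmf:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.sampled_from(["geometric", "gamma", "invgauss"]),
           st.floats(0.5, 5.0), st.floats(0.05, 2.0),
           st.integers(5, 300))
    def test_normalization(self, family, p1, p2, d_max):
        """Censored pmfs sum to one on [1, d_max] for any parameters."""
        if family == "geometric":
            m = model("geometric", d_max, q=min(p2, 0.95))
        elif family == "gamma":
            m = model("gamma", d_max, alpha=p1, beta=p2)
        else:
            m = model("invgauss", d_max, mu=p1 * 10, lam=p2 * 20)
        assert m.pmf().sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(m.pmf() >= 0)

    def test_gamma_shape_one_has_constant_ratio(self):
        """alpha=1 makes the discretized gamma memoryless in ratio:
        pmf(d+1)/pmf(d) = exp(-beta) for all d."""
        m = model("gamma", 200, alpha=1.0, beta=0.07)
        r = m.pmf()[1:] / m.pmf()[:-1]
        np.testing.assert_allclose(r, np.exp(-0.07), rtol=1e-10)

    def test_geometric_truncated_mean_approaches_closed_form(self):
        q = 0.02
        m = model("geometric", 10_000, q=q)
        assert m.mean() == pytest.approx(1.0 / q, rel=1e-6)

    def test_domain_errors(self):
        m = model("geometric", 50, q=0.1)
        with pytest.raises(ValueError):
            m.log_pmf(0)
        with pytest.raises(ValueError):
            m.log_pmf(51)

    def test_censoring_noop_when_tail_negligible(self):
        """When the uncensored mass beyond d_max is < 1e-12 the censored pmf
        equals the (practically) uncensored one pointwise."""
        tight = model("invgauss", 400, mu=30.0, lam=300.0)
        loose = model("invgauss", 100_000, mu=30.0, lam=300.0)
        np.testing.assert_allclose(tight.pmf(), loose.pmf()[:400], atol=1e-10)

    def test_text_roundtrip(self):
        m = model("invgauss", 1500, mu=52.5, lam=210.0)
        back = DurationModel.from_text(m.to_text())
        assert back.family == "invgauss" and back.d_max == 1500
        np.testing.assert_allclose(back.pmf(), m.pmf())


class TestNonparametricMLE:
    def test_point_mass(self):
        m = nonparametric_duration_mle(np.eye(10)[2], d_max=10)
        assert m.pmf(3) == pytest.approx(1.0)

    def test_hard_posteriors_equal_histogram(self):
        """0/1 duration posteriors from a known label sequence give exactly
        the normalized dwell-length histogram."""
        durs = [3, 1, 4, 3, 2, 3]
        d_max = 6
        mass = np.zeros((len(durs), d_max))
        for i, d in enumerate(durs):
            mass[i, d - 1] = 1.0
        m = nonparametric_duration_mle(mass)
        hist = np.bincount(durs, minlength=d_max + 1)[1:]
        np.testing.assert_allclose(m.pmf(), hist / hist.sum())

    def test_all_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            nonparametric_duration_mle(np.zeros(5))


class TestMomentMatching:
    @pytest.mark.parametrize("family,params", [
        ("invgauss", {"mu": 40.0, "lam": 150.0}),
        ("gamma", {"alpha": 4.0, "beta": 0.1}),
    ])
    def test_fixed_point_on_exact_censored_pmf(self, family, params):
        """Fitting a family to its own censored pmf recovers the parameters
        to 1e-4 relative error (ML = moment matching is a fixed point)."""
        target = DurationModel(family, params, 1500)
        nonpar = DurationModel("nonparametric", {"pmf": target.pmf()}, 1500)
        fit = fit_expfam_duration(nonpar, family)
        for k, v in params.items():
            assert abs(fit.params[k] - v) / v < 1e-4

    def test_idempotent_on_fitted_family(self):
        target = DurationModel("gamma", {"alpha": 3.0, "beta": 0.2}, 500)
        once = fit_expfam_duration(
            DurationModel("nonparametric", {"pmf": target.pmf()}, 500), "gamma")
        twice = fit_expfam_duration(
            DurationModel("nonparametric", {"pmf": once.pmf()}, 500), "gamma")
        for k in ("alpha", "beta"):
            assert once.params[k] == pytest.approx(twice.params[k], rel=1e-6)

    def test_heavy_censoring_bias_direction(self):
        """With mean dwell near d_max, the fitted *uncensored* mean must
        exceed the truncated target mean (mass pushed past the cut)."""
        target = DurationModel("gamma", {"alpha": 4.0, "beta": 0.05}, 90)
        # mean 80 vs d_max 90: heavy censoring
        fit = fit_expfam_duration(
            DurationModel("nonparametric", {"pmf": target.pmf()}, 90), "gamma")
        uncensored_mean = fit.params["alpha"] / fit.params["beta"]
        assert uncensored_mean > target.mean()

    def test_raw_ml_agrees_with_moment_matching_when_uncensored(self):
        """Direct ML from durations and moment matching against their
        empirical pmf agree within 1% when censoring is negligible."""
        rng = np.random.default_rng(0)
        from scipy.stats import invgauss
        d = np.clip(np.round(invgauss.rvs(50 / 200, scale=200, size=20_000,
                                          random_state=rng)), 1, None).astype(int)
        d_max = 1500
        mu_raw, lam_raw = fit_durations_invgauss(d)
        mm = fit_duration_family(d, "invgauss", d_max)
        assert abs(mm.params["mu"] - mu_raw) / mu_raw < 0.01
        assert abs(mm.params["lam"] - lam_raw) / lam_raw < 0.01

    def test_gamma_raw_ml_agreement(self):
        rng = np.random.default_rng(1)
        from scipy.stats import gamma as gamma_dist
        d = np.clip(np.round(gamma_dist.rvs(4.0, scale=12.0, size=20_000,
                                            random_state=rng)), 1, None).astype(int)
        a_raw, b_raw = fit_durations_gamma(d)
        mm = fit_duration_family(d, "gamma", 1500)
        assert abs(mm.params["alpha"] - a_raw) / a_raw < 0.01
        assert abs(mm.params["beta"] - b_raw) / b_raw < 0.01


class TestLoglikPerSample:
    def test_invgauss_beats_geometric_on_ig_data(self):
        """5e3 censored-IG draws: L_n(invgauss) > L_n(geometric) and
        >= L_n(gamma) (the dwell-model comparison direction)."""
        rng = np.random.default_rng(2)
        from scipy.stats import invgauss
        d = np.clip(np.round(invgauss.rvs(60 / 240, scale=240, size=5000,
                                          random_state=rng)), 1, 1500).astype(int)
        L = {fam: loglik_per_sample(d, fam, 1500)
             for fam in ("invgauss", "gamma", "geometric")}
        assert L["invgauss"] > L["geometric"]
        assert L["invgauss"] >= L["gamma"]

    def test_geometric_loglik_near_negative_entropy(self):
        """On geometric data the per-sample log-likelihood approaches the
        distribution's negative entropy."""
        rng = np.random.default_rng(3)
        q = 0.05
        d = np.clip(rng.geometric(q, size=50_000), 1, 2000)
        L = loglik_per_sample(d, "geometric", 2000)
        H = -((1 - q) * np.log(1 - q) + q * np.log(q)) / q  # entropy, nats
        assert L == pytest.approx(-H, abs=3e-2)

    def test_saturated_model_dominates(self):
        rng = np.random.default_rng(4)
        d = np.clip(rng.poisson(20, 2000), 1, 200)
        L_np = loglik_per_sample(d, "nonparametric", 200)
        for fam in ("geometric", "gamma", "invgauss"):
            assert L_np >= loglik_per_sample(d, fam, 200) - 1e-12

    def test_empty_durations_rejected(self):
        with pytest.raises(ValueError):
            loglik_per_sample([], "gamma", 100)
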