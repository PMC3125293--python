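import numpy as np
import pytest

from updown import ObservationSequence, PipelineConfig, run_pipeline
from updown.simulate import SimConfig, downsample_labels, simulate_uds


@pytest.fixture(scope="session")
def uds_sim():
    """A 5-minute synthetic UDS recording with default study conditions."""
    return simulate_uds(SimConfig(duration_s=300.0, seed=7))


@pytest.fixture(scope="session")
def fitted_pipeline(uds_sim):
    """Full pipeline result on the 5-minute recording (shared: fitting is
    the expensive step)."""
    res = run_pipeline(uds_sim.lfp, PipelineConfig(seed=1))
    truth = downsample_labels(uds_sim.states, res.obs.fs, res.obs.n_samples,
                              res.obs.segment_map)
    return res, truth


def make_feature_obs(rng, n_seconds=120.0, fs=50.0, means=(-1.0, 1.0),
                     sds=(0.5, 0.5), dwell_mean_s=1.0, dwell_lambda_s=4.0,
                     drift_amplitude=0.0, drift_period_s=200.0):
    """Directly synthesized feature-level observation sequence with
    inverse-Gaussian dwells and Gaussian emissions (bypasses the raw-signal
    path; used where tests target the models, not the preprocessing)."""
    from scipy.stats import invgauss

    n = int(round(n_seconds * fs))
    labels = np.empty(n, dtype=int)
    state = int(rng.integers(2))
    pos = 0
    while pos < n:
        d = invgauss.rvs(dwell_mean_s / dwell_lambda_s, scale=dwell_lambda_s,
                         random_state=rng)
        d = max(1, int(round(d * fs)))
        labels[pos:pos + d] = state
        pos += d
        state = 1 - state
    drift = drift_amplitude * np.sin(2 * np.pi * np.arange(n) / fs
                                     / drift_period_s)
    y = (np.asarray(means)[labels] + drift
         + np.asarray(sds)[labels] * rng.standard_normal(n))
    return ObservationSequence(y, fs), labels
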