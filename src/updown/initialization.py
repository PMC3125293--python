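"""Initial EDHMM parameter estimates.

EM only finds the global optimum from a reasonable starting point, so the
model is seeded in stages: time-varying state means from a sliding-window
kernel density estimator (the two modes of a bimodal window are the DOWN and
UP means; unimodal windows are disambiguated by skewness), covariances from
Gaussian-mixture fits to mean-subtracted residuals, a transition matrix whose
implied geometric dwell is 1 s, and duration-model parameters from the dwell
times of an initial HMM Viterbi pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import find_peaks
from sklearn.mixture import GaussianMixture

from .containers import DOWN, UP, ObservationSequence
from .durations import fit_durations_gamma, fit_durations_invgauss

__all__ = [
    "MeanTrajectory",
    "InitReport",
    "terrell_bandwidth",
    "sliding_kde_state_means",
    "init_covariances",
    "init_transition_matrix",
    "init_duration_models",
]


@dataclass
class MeanTrajectory:
    """Per-state mean value for every feature time step (scalar feature).

    ``means`` has shape (T, 2); column 0 is the DOWN-state mean, column 1
    the UP-state mean, rows aligned with the observation sequence's
    concatenated feature rows.  The orientation convention (after LFP
    inversion) requires UP >= DOWN everywhere.
    """

    means: np.ndarray
    window_s: float
    fs: float

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.ndim != 2 or self.means.shape[1] != 2:
            raise ValueError("means must be (T, 2)")

    @property
    def down(self) -> np.ndarray:
        return self.means[:, DOWN]

    @property
    def up(self) -> np.ndarray:
        return self.means[:, UP]


@dataclass
class InitReport:
    """Window-level diagnostics from the sliding-window KDE initializer."""

    flags: list = field(default_factory=list)  # per-window classification
    bandwidths: list = field(default_factory=list)
    separations: list = field(default_factory=list)  # inter-mode, bimodal windows

    @property
    def fraction_bimodal(self) -> float:
        if not self.flags:
            return 0.0
        return sum(f == "bimodal" for f in self.flags) / len(self.flags)

    def summary(self) -> str:
        n = len(self.flags)
        counts = {f: self.flags.count(f) for f in
                  ("bimodal", "unimodal-skew-positive", "unimodal-skew-negative")}
        lines = [f"windows: {n}",
                 f"fraction bimodal: {self.fraction_bimodal:.3f}"]
        lines += [f"{k}: {v}" for k, v in counts.items()]
        if self.separations:
            lines.append(f"mean inter-mode separation: "
                         f"{np.mean(self.separations):.4g}")
        return "\n".join(lines)


def terrell_bandwidth(n: int) -> float:
    """Oversmoothing bandwidth factor (maximal-smoothing principle):
    ``h = 1.144 * sigma * n**(-1/5)``, returned as the factor on sigma."""
    return 1.144 * n ** (-0.2)


def _window_modes(data: np.ndarray, grid_n: int, prominence_frac: float):
    """KDE on a grid over the window's range; return mode locations sorted
    by descending prominence, and the bandwidth factor used."""
    bw = terrell_bandwidth(len(data))
    kde = stats.gaussian_kde(data, bw_method=bw)
    lo, hi = data.min(), data.max()
    if hi <= lo:
        return np.array([lo]), bw
    grid = np.linspace(lo, hi, grid_n)
    dens = kde(grid)
    peaks, props = find_peaks(dens, prominence=prominence_frac * dens.max())
    if len(peaks) == 0:
        return np.array([grid[np.argmax(dens)]]), bw
    order = np.argsort(props["prominences"])[::-1]
    return grid[peaks[order]], bw


def sliding_kde_state_means(obs: ObservationSequence, window_s: float = 50.0,
                            step_frac: float = 0.1, grid_n: int = 512,
                            prominence_frac: float = 0.05,
                            ) -> tuple[MeanTrajectory, InitReport]:
    """Sliding-window KDE estimate of the time-varying state means.

    Per window of length ``window_s`` (stepped by ``step_frac`` of the
    window), a Gaussian KDE with the oversmoothing bandwidth is evaluated on
    a ``grid_n``-point grid over the window's data range.  Windows with two
    modes (prominence >= ``prominence_frac`` of the density maximum) give the
    DOWN (lower) and UP (upper) means directly.  Unimodal windows assign
    their mode to DOWN when the window's skewness is >= 0 (a DOWN-dominated
    sample has a positive tail) and to UP when it is negative; the other
    state's mean is offset by the average inter-mode separation of the
    bimodal windows in the same segment.  Means are interpolated linearly
    between window centers.
    """
    if obs.n_features != 1:
        raise ValueError("sliding_kde_state_means expects the scalar primary feature")
    W = int(round(window_s * obs.fs))
    if W < 100:
        raise ValueError("window too short: need window_s * fs >= 100 samples")
    step = max(1, W // max(1, int(round(1 / step_frac))))
    x = obs.squeezed()
    report = InitReport()
    traj = np.empty((obs.n_samples, 2))

    per_segment = []  # (slice, centers, window records)
    for sl in obs.segment_slices():
        seg = x[sl]
        n = len(seg)
        if n <= W:
            starts = np.array([0])
            w_len = n
        else:
            starts = np.arange(0, n - W + 1, step)
            w_len = W
        centers, records = [], []
        for s in starts:
            data = seg[s:s + w_len]
            modes, bw = _window_modes(data, grid_n, prominence_frac)
            report.bandwidths.append(bw)
            if len(modes) >= 2:
                pair = np.sort(modes[:2])
                records.append(("bimodal", pair))
                report.flags.append("bimodal")
                report.separations.append(pair[1] - pair[0])
            else:
                skew = stats.skew(data)
                # skewness exactly 0 treated as positive: mode -> DOWN
                flag = ("unimodal-skew-negative" if skew < 0
                        else "unimodal-skew-positive")
                records.append((flag, modes[0]))
                report.flags.append(flag)
            centers.append(s + w_len / 2)
        per_segment.append((sl, np.asarray(centers, float), records))

    if not report.separations:
        raise ValueError("no bimodal windows; recording may lack UP-DOWN states")
    global_sep = float(np.mean(report.separations))

    for sl, centers, records in per_segment:
        seg_seps = [r[1][1] - r[1][0] for r in records if r[0] == "bimodal"]
        sep = float(np.mean(seg_seps)) if seg_seps else global_sep
        vals = np.empty((len(records), 2))
        for i, (flag, payload) in enumerate(records):
            if flag == "bimodal":
                vals[i] = payload
            elif flag == "unimodal-skew-positive":
                vals[i] = (payload, payload + sep)
            else:
                vals[i] = (payload - sep, payload)
        t_seg = np.arange(sl.stop - sl.start, dtype=float)
        for k in (DOWN, UP):
            traj[sl, k] = np.interp(t_seg, centers, vals[:, k])
    return MeanTrajectory(traj, window_s, obs.fs), report


def init_covariances(obs: ObservationSequence, means: MeanTrajectory | np.ndarray,
                     random_state: int = 0) -> np.ndarray:
    """Initial per-state covariances from mixture fits to residuals.

    For each state, the state's mean trajectory is subtracted from the
    observations and a two-component Gaussian mixture is fitted to the
    residuals; the covariance of the component centred nearest zero is
    taken as that state's covariance.  Returns an array (2, D, D).
    """
    mt = means.means if isinstance(means, MeanTrajectory) else np.asarray(means)
    if mt.shape[0] != obs.n_samples:
        raise ValueError("mean trajectory does not cover every feature sample")
    D = obs.n_features
    covs = np.empty((2, D, D))
    for k in (DOWN, UP):
        if mt.ndim == 2:
            resid = obs.features - mt[:, [k]]
        else:
            resid = obs.features - mt[:, k, :]
        gm = GaussianMixture(n_components=2, covariance_type="full",
                             n_init=2, random_state=random_state)
        gm.fit(resid)
        comp = int(np.argmin(np.linalg.norm(gm.means_, axis=1)))
        covs[k] = gm.covariances_[comp]
        covs[k] = _regularize_spd(covs[k])
    return covs


def _regularize_spd(S: np.ndarray) -> np.ndarray:
    S = 0.5 * (S + S.T)
    eig = np.linalg.eigvalsh(S)
    if eig.min() <= 0 or eig.min() / max(eig.max(), 1e-300) < 1e-12:
        warnings.warn("near-singular covariance; adding diagonal regularizer")
        S = S + np.eye(len(S)) * 1e-6 * np.trace(S) / len(S)
    return S


def init_transition_matrix(fs: float, expected_dur_s: float = 1.0) -> np.ndarray:
    """Initial HMM transition matrix with geometric mean dwell ``expected_dur_s``.

    Self-transition probability ``a_kk = 1 - 1/(fs * expected_dur_s)``, so
    the implied geometric expected dwell is exactly ``fs * expected_dur_s``
    samples for both states.
    """
    if fs * expected_dur_s <= 1:
        raise ValueError("need fs * expected_dur_s > 1")
    stay = 1.0 - 1.0 / (fs * expected_dur_s)
    return np.array([[stay, 1.0 - stay], [1.0 - stay, stay]])


def init_duration_models(durations_by_state) -> list[dict]:
    """Gamma and inverse-Gaussian ML parameters from per-state dwell samples.

    ``durations_by_state`` is a sequence (one entry per state) of dwell
    lengths in time steps, typically from the initial HMM Viterbi pass.
    Returns one dict per state with keys ``gamma`` -> (alpha, beta) and
    ``invgauss`` -> (mu, lam), all in time steps.
    """
    out = []
    for durs in durations_by_state:
        out.append({
            "gamma": fit_durations_gamma(durs),
            "invgauss": fit_durations_invgauss(durs),
        })
    return out
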