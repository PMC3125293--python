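"""Two-state Gaussian-observation hidden Markov model.

The standard HMM is both the initializer for the explicit-duration model and
a comparison method in its own right.  Emissions are Gaussian per state with
optionally *time-varying* means (a slowly drifting mean trajectory updated in
the M step as a windowed, posterior-weighted average of the observations --
the drift tracks amplifier AC-coupling artifacts and slow physiological
amplitude changes).  Covariances and the transition matrix are pooled across
discontinuous data segments; initial-state distributions are per segment.

A robust fallback guards against large artifacts: at samples far from both
state means (in Mahalanobis distance), emissions are re-evaluated under a
pooled equal-covariance model so the nearer-mean state wins rather than the
wider-variance one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import DOWN, UP, ObservationSequence, StateSequence

__all__ = [
    "HMMParams",
    "PosteriorMarginals",
    "emission_loglik",
    "robustify_outliers",
    "hmm_forward_backward",
    "hmm_viterbi",
    "GaussianHMM",
    "HMMResults",
]

_LOG2PI = np.log(2 * np.pi)


@dataclass
class HMMParams:
    """Parameters of the two-state Gaussian HMM.

    ``mean_traj`` has shape (T, 2, D) (rows aligned with the observation
    sequence); a constant-mean model simply stores a constant trajectory.
    ``pi`` holds one initial-state distribution per data segment.
    """

    A: np.ndarray
    pi: np.ndarray
    mean_traj: np.ndarray
    covs: np.ndarray
    mean_window_s: float | None = 50.0
    window_kind: str = "boxcar"

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.atleast_2d(np.asarray(self.pi, dtype=float))
        self.mean_traj = np.asarray(self.mean_traj, dtype=float)
        if self.mean_traj.ndim == 2:  # (T, 2) scalar feature
            self.mean_traj = self.mean_traj[:, :, None]
        self.covs = np.asarray(self.covs, dtype=float)
        if self.covs.ndim == 1:  # per-state variances, scalar feature
            self.covs = self.covs.reshape(2, 1, 1)
        self.validate()

    def validate(self) -> None:
        if self.A.shape != (2, 2) or np.any(self.A < 0):
            raise ValueError("A must be a non-negative 2x2 matrix")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of A must sum to 1")
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of pi must sum to 1")
        for S in self.covs:
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValueError("covariances must be symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError("covariances must be positive definite")

    @property
    def n_features(self) -> int:
        return self.mean_traj.shape[2]

    def pi_row(self, i: int) -> np.ndarray:
        """Initial distribution for segment ``i`` (a single stored row is
        shared across segments)."""
        return self.pi[i] if i < self.pi.shape[0] else self.pi[0]

    def swap_labels(self) -> "HMMParams":
        """Parameters with the two state labels exchanged."""
        return HMMParams(self.A[::-1, ::-1], self.pi[:, ::-1],
                         self.mean_traj[:, ::-1], self.covs[::-1],
                         self.mean_window_s, self.window_kind)


@dataclass
class PosteriorMarginals:
    """Per-sample state posteriors and the total data log-likelihood."""

    gamma: np.ndarray  # (T, 2)
    loglik: float


# ---------------------------------------------------------------------------
# emission likelihoods

def _gauss_loglik(diff: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log N(diff; 0, cov) for rows of diff (T, D)."""
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, diff.T)
    q = np.sum(sol ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (diff.shape[1] * _LOG2PI + logdet + q)


def emission_loglik(params: HMMParams, obs: ObservationSequence,
                    robust_trigger_sd: float | None = None) -> np.ndarray:
    """State-conditional emission log-likelihoods, shape (T, 2).

    With ``robust_trigger_sd`` set, samples whose Mahalanobis distance
    exceeds the trigger under *both* states are re-evaluated with the pooled
    (equal) covariance.
    """
    y = obs.features
    logb = np.empty((obs.n_samples, 2))
    for k in (DOWN, UP):
        logb[:, k] = _gauss_loglik(y - params.mean_traj[:, k, :], params.covs[k])
    if robust_trigger_sd is not None:
        mask = robustify_outliers(params, obs, robust_trigger_sd)
        if mask.any():
            pooled = params.covs.mean(axis=0)
            for k in (DOWN, UP):
                diff = y[mask] - params.mean_traj[mask, k, :]
                logb[mask, k] = _gauss_loglik(diff, pooled)
    return logb


def robustify_outliers(params: HMMParams, obs: ObservationSequence,
                       trigger_sd: float = 4.0) -> np.ndarray:
    """Mask of samples farther than ``trigger_sd`` (Mahalanobis) from *both*
    state means -- the samples where the equal-variance fallback applies."""
    y = obs.features
    far = np.ones(obs.n_samples, dtype=bool)
    for k in (DOWN, UP):
        diff = y - params.mean_traj[:, k, :]
        L = np.linalg.cholesky(params.covs[k])
        d2 = np.sum(np.linalg.solve(L, diff.T) ** 2, axis=0)
        far &= d2 > trigger_sd ** 2
    return far


# ---------------------------------------------------------------------------
# exact inference

def _forward_backward_segment(A, pi, logb):
    """Scaled forward-backward for one segment.

    Returns (gamma, xi_sum, loglik): posteriors (T, 2), summed two-slice
    expectations (2, 2), and log p(Y | params).
    """
    T = logb.shape[0]
    m = logb.max(axis=1)
    b = np.exp(logb - m[:, None])
    alpha = np.empty((T, 2))
    c = np.empty(T)
    a = pi * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        if not np.isfinite(c[t]) or c[t] <= 0:
            raise FloatingPointError(f"non-finite forward recursion at t={t}")
        alpha[t] = a / c[t]
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    xi_sum = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        beta[t] = (A @ bb) / c[t + 1]
        xi_sum += np.outer(alpha[t], bb) * A / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(c)) + np.sum(m))
    return gamma, xi_sum, loglik


def hmm_forward_backward(params: HMMParams, obs: ObservationSequence,
                         robust_trigger_sd: float | None = None,
                         ) -> PosteriorMarginals:
    """Exact posterior state marginals and data log-likelihood.

    Segments are treated as independent realizations: recursions restart at
    every segment boundary with that segment's initial distribution.
    """
    logb = emission_loglik(params, obs, robust_trigger_sd)
    gamma = np.empty((obs.n_samples, 2))
    total = 0.0
    for i, sl in enumerate(obs.segment_slices()):
        g, _, ll = _forward_backward_segment(params.A, params.pi_row(i),
                                             logb[sl])
        gamma[sl] = g
        total += ll
    return PosteriorMarginals(gamma, total)


def hmm_viterbi(params: HMMParams, obs: ObservationSequence,
                robust_trigger_sd: float | None = None) -> StateSequence:
    """Joint-MAP state path per segment (log-domain Viterbi).

    Ties are broken toward DOWN (the lower label).
    """
    logb = emission_loglik(params, obs, robust_trigger_sd)
    with np.errstate(divide="ignore"):
        logA = np.log(params.A)
    labels = []
    for i, sl in enumerate(obs.segment_slices()):
        lb = logb[sl]
        T = lb.shape[0]
        with np.errstate(divide="ignore"):
            delta = np.log(params.pi_row(i)) + lb[0]
        back = np.empty((T, 2), dtype=int)
        for t in range(1, T):
            cand = delta[:, None] + logA
            back[t] = np.argmax(cand, axis=0)  # first max -> DOWN on ties
            delta = cand[back[t], [0, 1]] + lb[t]
        path = np.empty(T, dtype=int)
        path[-1] = int(np.argmax(delta))
        for t in range(T - 2, -1, -1):
            path[t] = back[t + 1][path[t + 1]]
        labels.append(path)
    return StateSequence(labels, obs.fs, obs.segment_map)


# ---------------------------------------------------------------------------
# M-step helpers (shared with the explicit-duration model)

def windowed_mean_update(obs: ObservationSequence, gamma: np.ndarray,
                         window_s: float | None, window_kind: str = "boxcar",
                         min_mass: float = 1e-12) -> np.ndarray:
    """Posterior-weighted mean trajectories, shape (T, 2, D).

    Per segment and state, the mean at time t is the gamma-weighted average
    of the observations inside a symmetric window centred on t (boxcar of
    length ``window_s`` by default, truncated at segment edges; Gaussian
    window with SD ``window_s/4`` as an option).  ``window_s=None`` gives the
    classical constant-mean update (per segment's pooled weighted mean over
    the *whole record*, i.e. a global constant per state).
    """
    y = obs.features
    T, D = y.shape
    out = np.empty((T, 2, D))
    if window_s is None:
        for k in (DOWN, UP):
            w = gamma[:, k]
            out[:, k, :] = (w @ y) / max(w.sum(), min_mass)
        return out
    for sl in (obs.segment_slices()):
        yseg = y[sl]
        n = yseg.shape[0]
        for k in (DOWN, UP):
            w = gamma[sl, k]
            wy = w[:, None] * yseg
            if window_kind == "gaussian":
                sigma = window_s * obs.fs / 4.0
                num = gaussian_filter1d(wy, sigma, axis=0, mode="constant")
                den = gaussian_filter1d(w, sigma, mode="constant")
            else:
                h = int(round(window_s * obs.fs / 2))
                cs_wy = np.vstack([np.zeros((1, D)), np.cumsum(wy, axis=0)])
                cs_w = np.concatenate([[0.0], np.cumsum(w)])
                t = np.arange(n)
                lo = np.clip(t - h, 0, n)
                hi = np.clip(t + h + 1, 0, n)
                num = cs_wy[hi] - cs_wy[lo]
                den = cs_w[hi] - cs_w[lo]
            out[sl, k, :] = num / np.maximum(den, min_mass)[:, None]
    return out


def pooled_covariance_update(obs: ObservationSequence, gamma: np.ndarray,
                             mean_traj: np.ndarray,
                             prev_covs: np.ndarray | None = None,
                             min_mass: float = 10.0) -> np.ndarray:
    """Posterior-weighted covariances pooled across segments, shape (2, D, D).

    A state whose total posterior mass falls below ``min_mass`` samples keeps
    its previous covariance (with a warning): its second moment is not
    identifiable from the data.
    """
    y = obs.features
    D = y.shape[1]
    covs = np.empty((2, D, D))
    for k in (DOWN, UP):
        w = gamma[:, k]
        mass = w.sum()
        if mass < min_mass:
            if prev_covs is None:
                raise ValueError(f"state {k} has negligible posterior mass")
            warnings.warn(f"state {k} posterior mass {mass:.2f} < {min_mass}; "
                          "freezing its covariance")
            covs[k] = prev_covs[k]
            continue
        diff = y - mean_traj[:, k, :]
        covs[k] = (diff * w[:, None]).T @ diff / mass
        covs[k] = 0.5 * (covs[k] + covs[k].T)
        eig = np.linalg.eigvalsh(covs[k])
        if eig.min() <= 0:
            covs[k] += np.eye(D) * 1e-6 * max(np.trace(covs[k]), 1e-12) / D
    return covs


# ---------------------------------------------------------------------------
# Model / Results

class GaussianHMM:
    """Two-state Gaussian HMM built from an observation sequence.

    Parameters
    ----------
    obs : ObservationSequence
        Feature matrix with its segment structure.
    mean_window_s : float or None
        Time scale of the boxcar window for the time-varying-mean update;
        ``None`` fits constant means.
    window_kind : {"boxcar", "gaussian"}
    robust_trigger_sd : float or None
        Enable the equal-variance outlier fallback at this Mahalanobis
        trigger (typical value 4); ``None`` disables it.
    """

    def __init__(self, obs: ObservationSequence, mean_window_s: float | None = 50.0,
                 window_kind: str = "boxcar",
                 robust_trigger_sd: float | None = None,
                 random_state: int = 0):
        self.obs = obs
        self.mean_window_s = mean_window_s
        self.window_kind = window_kind
        self.robust_trigger_sd = robust_trigger_sd
        self.random_state = random_state

    def initialize(self, expected_dur_s: float = 1.0,
                   kde_window_s: float = 50.0) -> HMMParams:
        """Initial parameters from the sliding-window KDE procedure."""
        from .initialization import (init_covariances, init_transition_matrix,
                                     sliding_kde_state_means)

        if self.obs.n_features == 1:
            traj, _ = sliding_kde_state_means(self.obs, kde_window_s)
            mean_traj = traj.means[:, :, None]
            covs = init_covariances(self.obs, traj,
                                    random_state=self.random_state)
        else:
            # KDE init on the primary (first) feature; remaining features
            # start at their global mean for both states
            primary = ObservationSequence(self.obs.features[:, :1], self.obs.fs,
                                          self.obs.segment_map)
            traj, _ = sliding_kde_state_means(primary, kde_window_s)
            D = self.obs.n_features
            mean_traj = np.tile(self.obs.features.mean(axis=0),
                                (self.obs.n_samples, 2, 1))
            mean_traj[:, :, 0] = traj.means
            covs = init_covariances(self.obs, mean_traj,
                                    random_state=self.random_state)
        A = init_transition_matrix(self.obs.fs, expected_dur_s)
        pi = np.full((self.obs.n_segments, 2), 0.5)
        return HMMParams(A, pi, mean_traj, covs,
                         self.mean_window_s, self.window_kind)

    def fit(self, init: HMMParams | None = None, tol: float = 1e-5,
            max_iter: int = 100) -> "HMMResults":
        """EM fit; the log-likelihood trace is non-decreasing and iteration
        stops when the relative improvement drops below ``tol``."""
        params = init if init is not None else self.initialize()
        trace = []
        converged = False
        prev_params = params
        for _ in range(max_iter):
            logb = emission_loglik(params, self.obs, self.robust_trigger_sd)
            gamma = np.empty((self.obs.n_samples, 2))
            xi_total = np.zeros((2, 2))
            pi = np.empty((self.obs.n_segments, 2))
            total = 0.0
            for i, sl in enumerate(self.obs.segment_slices()):
                g, xi, ll = _forward_backward_segment(params.A,
                                                      params.pi_row(i),
                                                      logb[sl])
                gamma[sl] = g
                xi_total += xi
                pi[i] = g[0]
                total += ll
            if trace and total < trace[-1] - 1e-8 * abs(trace[-1]):
                # windowed-mean update is not an exact M-step; keep the
                # previous (better) parameters and stop
                params = prev_params
                converged = True
                break
            trace.append(total)
            if len(trace) > 1 and (trace[-1] - trace[-2]) < tol * abs(trace[-2]):
                converged = True
                break
            prev_params = params
            A = xi_total / np.maximum(xi_total.sum(axis=1, keepdims=True), 1e-300)
            mean_traj = windowed_mean_update(self.obs, gamma,
                                             params.mean_window_s,
                                             params.window_kind)
            covs = pooled_covariance_update(self.obs, gamma, mean_traj,
                                            prev_covs=params.covs)
            params = HMMParams(A, pi, mean_traj, covs,
                               params.mean_window_s, params.window_kind)
        return HMMResults(self, params, np.asarray(trace), converged)


class HMMResults:
    """Fitted HMM: final parameters, log-likelihood trace, decoders."""

    def __init__(self, model: GaussianHMM, params: HMMParams,
                 loglik_trace: np.ndarray, converged: bool):
        self.model = model
        self.params = params
        self.loglik_trace = loglik_trace
        self.converged = converged
        self._posterior: PosteriorMarginals | None = None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace)

    def posterior(self) -> PosteriorMarginals:
        if self._posterior is None:
            self._posterior = hmm_forward_backward(
                self.params, self.model.obs, self.model.robust_trigger_sd)
        return self._posterior

    def decode(self) -> StateSequence:
        return hmm_viterbi(self.params, self.model.obs,
                           self.model.robust_trigger_sd)

    def summary(self) -> str:
        p = self.params
        T = self.model.obs.n_samples
        lines = [
            "Two-state Gaussian HMM",
            "=" * 46,
            f"samples: {T}  segments: {self.model.obs.n_segments}  "
            f"features: {p.n_features}",
            f"EM iterations: {self.n_iter}  converged: {self.converged}",
            f"log-likelihood: {self.loglik:.4f} "
            f"({self.loglik / T:.4f} per sample)",
            f"transition matrix: [[{p.A[0, 0]:.4f}, {p.A[0, 1]:.4f}], "
            f"[{p.A[1, 0]:.4f}, {p.A[1, 1]:.4f}]]",
        ]
        for k, name in ((DOWN, "DOWN"), (UP, "UP")):
            mu = p.mean_traj[:, k, :].mean(axis=0)
            sd = np.sqrt(np.diag(p.covs[k]))
            lines.append(f"{name}: mean(t) avg {np.array2string(mu, precision=3)} "
                         f"sd {np.array2string(sd, precision=3)}")
        return "\n".join(lines)
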