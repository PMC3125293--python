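"""Explicit-duration HMM (hidden semi-Markov model) for UP-DOWN states.

The standard HMM forces geometric dwell times; cortical UP/DOWN dwell times
are far from geometric.  The explicit-duration HMM instead draws each run
length from a per-state duration pmf on ``[1, d_max]`` (self-transitions are
prohibited, so in the two-state case the transition matrix is fixed to
swap).  Exact inference sums over all legal segmentations of each data
segment under the boundary convention that the first run starts at the
segment start and the last run ends at the segment end.

Implementation notes: recursions run in the log domain over run *end*
positions, with cumulative emission sums so each step is a vectorized
reduction over durations; cost is O(T * d_max) per state and pass.  Viterbi
replaces the sums by maxima -- equivalently, the longest path in the DAG
whose nodes are (state, run span) with emission + duration log-probability
weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import DOWN, UP, ObservationSequence, StateSequence
from .durations import DurationModel, fit_expfam_duration, nonparametric_duration_mle
from .hmm import (GaussianHMM, HMMParams, PosteriorMarginals, emission_loglik,
                  pooled_covariance_update, windowed_mean_update)

__all__ = [
    "EDHMMParams",
    "DurationPosteriors",
    "edhmm_forward_backward",
    "edhmm_viterbi",
    "ExplicitDurationHMM",
    "EDHMMResults",
]

# fixed two-state transition structure: self-transitions prohibited
A_SWAP = np.array([[0.0, 1.0], [1.0, 0.0]])


@dataclass
class EDHMMParams:
    """Parameters of the two-state explicit-duration HMM.

    Observation side is shared with :class:`~updown.hmm.HMMParams`
    (time-varying Gaussian means, per-state covariances); the duration side
    is one :class:`~updown.durations.DurationModel` per state.
    """

    pi: np.ndarray
    mean_traj: np.ndarray
    covs: np.ndarray
    duration_models: list
    mean_window_s: float | None = 50.0
    window_kind: str = "boxcar"

    def __post_init__(self) -> None:
        self.pi = np.atleast_2d(np.asarray(self.pi, dtype=float))
        self.mean_traj = np.asarray(self.mean_traj, dtype=float)
        if self.mean_traj.ndim == 2:
            self.mean_traj = self.mean_traj[:, :, None]
        self.covs = np.asarray(self.covs, dtype=float)
        if self.covs.ndim == 1:
            self.covs = self.covs.reshape(2, 1, 1)
        if len(self.duration_models) != 2:
            raise ValueError("need one duration model per state")
        if self.duration_models[0].d_max != self.duration_models[1].d_max:
            raise ValueError("duration models must share d_max")

    @property
    def A(self) -> np.ndarray:
        return A_SWAP

    def pi_row(self, i: int) -> np.ndarray:
        return self.pi[i] if i < self.pi.shape[0] else self.pi[0]

    @property
    def d_max(self) -> int:
        return self.duration_models[0].d_max

    def as_hmm_params(self, fs: float) -> HMMParams:
        """Matched standard-HMM parameters (geometric dwell at the same mean)."""
        stay = [1.0 - 1.0 / m.mean() for m in self.duration_models]
        A = np.array([[stay[0], 1 - stay[0]], [1 - stay[1], stay[1]]])
        return HMMParams(A, self.pi, self.mean_traj, self.covs,
                         self.mean_window_s, self.window_kind)


@dataclass
class DurationPosteriors:
    """Posterior run-occupancy statistics from the EDHMM E step.

    ``mass`` (2, d_max) is the total posterior probability, summed over run
    end positions and segments, of a run of each state having duration d --
    the sufficient statistic for the duration M step.  ``cells`` optionally
    stores the individual (segment, state, end, duration) -> probability
    entries above a floor, for diagnostics on short sequences.
    """

    mass: np.ndarray
    cells: list | None = field(default=None, repr=False)


def _lse(v: np.ndarray) -> float:
    m = v.max()
    if m == -np.inf:
        return -np.inf
    return m + np.log(np.sum(np.exp(v - m)))


def _segment_log_quantities(logb: np.ndarray, logp: np.ndarray,
                            logpi: np.ndarray, d_max: int):
    """Forward/backward log variables over run-end positions for one segment.

    Returns (F, G, loglik): F[t, k] = log P(y_0..t, a run of k ends at t);
    G[t, k] = log P(y_{t+1}..y_{T-1} | a run of k ended at t).
    """
    T = logb.shape[0]
    if T < 2:
        raise ValueError("segment too short for explicit-duration inference")
    cum = np.vstack([np.zeros(2), np.cumsum(logb, axis=0)])  # (T+1, 2)
    F = np.full((T, 2), -np.inf)
    for t in range(T):
        dm = min(d_max, t + 1)
        d = np.arange(1, dm + 1)
        for k in (DOWN, UP):
            emis = cum[t + 1, k] - cum[t + 1 - d, k]
            vals = emis + logp[k][:dm]
            if dm == t + 1:
                if t > 0:
                    vals[:t] += F[t - 1::-1, 1 - k]
                vals[t] += logpi[k]
            else:
                vals += F[t - dm:t, 1 - k][::-1]
            F[t, k] = _lse(vals)
    G = np.full((T, 2), -np.inf)
    G[T - 1] = 0.0
    for t in range(T - 2, -1, -1):
        for k in (DOWN, UP):
            k2 = 1 - k
            dm = min(d_max, T - 1 - t)
            d = np.arange(1, dm + 1)
            emis = cum[t + 1 + d, k2] - cum[t + 1, k2]
            G[t, k] = _lse(emis + logp[k2][:dm] + G[t + 1:t + 1 + dm, k2])
    loglik = _lse(F[T - 1])
    return cum, F, G, loglik


def edhmm_forward_backward(params: EDHMMParams, obs: ObservationSequence,
                           robust_trigger_sd: float | None = None,
                           store_cells: bool = False, cell_floor: float = 1e-12,
                           ) -> tuple[PosteriorMarginals, DurationPosteriors]:
    """Exact state marginals and duration posteriors under the EDHMM.

    Segments are independent; within each, the first run starts at the
    segment start and the last run ends at the segment end.
    """
    logb = emission_loglik(params.as_hmm_params(obs.fs), obs, robust_trigger_sd)
    d_max = params.d_max
    with np.errstate(divide="ignore"):
        logp = [m.log_pmf() for m in params.duration_models]
    gamma = np.empty((obs.n_samples, 2))
    mass = np.zeros((2, d_max))
    cells = [] if store_cells else None
    total = 0.0
    for si, sl in enumerate(obs.segment_slices()):
        lb = logb[sl]
        T = lb.shape[0]
        with np.errstate(divide="ignore"):
            logpi = np.log(params.pi_row(si))
        cum, F, G, ll = _segment_log_quantities(lb, logp, logpi, d_max)
        total += ll
        diff = np.zeros((T + 1, 2))
        for t in range(T):
            dm = min(d_max, t + 1)
            d = np.arange(1, dm + 1)
            for k in (DOWN, UP):
                emis = cum[t + 1, k] - cum[t + 1 - d, k]
                logD = emis + logp[k][:dm] + G[t, k] - ll
                if dm == t + 1:
                    if t > 0:
                        logD[:t] += F[t - 1::-1, 1 - k]
                    logD[t] += logpi[k]
                else:
                    logD += F[t - dm:t, 1 - k][::-1]
                m = np.exp(logD)
                mass[k, :dm] += m
                # run of duration d ends at t: covers samples [t-d+1, t]
                diff[t - dm + 1:t + 1, k] += m[::-1]
                diff[t + 1, k] -= m.sum()
                if store_cells:
                    for j in np.flatnonzero(m > cell_floor):
                        cells.append((si, k, t, int(d[j]), float(m[j])))
        gamma[sl] = np.cumsum(diff[:-1], axis=0)
    gamma = np.clip(gamma, 0.0, None)
    gamma /= gamma.sum(axis=1, keepdims=True)
    return PosteriorMarginals(gamma, total), DurationPosteriors(mass, cells)


def edhmm_viterbi(params: EDHMMParams, obs: ObservationSequence,
                  robust_trigger_sd: float | None = None) -> StateSequence:
    """Joint-MAP segmentation: DAG longest path over (state, run span) nodes.

    Node weight = summed state-conditional log emissions over the span plus
    the log duration pmf.  Labels strictly alternate; every dwell is in
    ``[1, d_max]``.  Ties resolve toward DOWN and shorter final durations.
    """
    logb = emission_loglik(params.as_hmm_params(obs.fs), obs, robust_trigger_sd)
    d_max = params.d_max
    with np.errstate(divide="ignore"):
        logp = [m.log_pmf() for m in params.duration_models]
    labels = []
    for si, sl in enumerate(obs.segment_slices()):
        lb = logb[sl]
        T = lb.shape[0]
        with np.errstate(divide="ignore"):
            logpi = np.log(params.pi_row(si))
        cum = np.vstack([np.zeros(2), np.cumsum(lb, axis=0)])
        V = np.full((T, 2), -np.inf)
        best_d = np.zeros((T, 2), dtype=int)
        for t in range(T):
            dm = min(d_max, t + 1)
            d = np.arange(1, dm + 1)
            for k in (DOWN, UP):
                emis = cum[t + 1, k] - cum[t + 1 - d, k]
                vals = emis + logp[k][:dm]
                if dm == t + 1:
                    if t > 0:
                        vals[:t] += V[t - 1::-1, 1 - k]
                    vals[t] += logpi[k]
                else:
                    vals += V[t - dm:t, 1 - k][::-1]
                j = int(np.argmax(vals))
                V[t, k] = vals[j]
                best_d[t, k] = j + 1
        lab = np.empty(T, dtype=int)
        k = int(np.argmax(V[T - 1]))  # first max -> DOWN on ties
        t = T - 1
        while t >= 0:
            dstar = best_d[t, k]
            lab[t - dstar + 1:t + 1] = k
            t -= dstar
            k = 1 - k
        labels.append(lab)
    return StateSequence(labels, obs.fs, obs.segment_map)


class ExplicitDurationHMM:
    """Explicit-duration HMM built from an observation sequence.

    Parameters
    ----------
    obs : ObservationSequence
    duration_family : {"invgauss", "gamma", "geometric", "nonparametric"}
        Parametric family refitted in each EM duration M step (inverse
        Gaussian by default -- the better dwell model for cortical UDS).
    d_max_s : float
        Maximum state duration in seconds (support of the censored pmf).
    mean_window_s : float or None
        Boxcar window of the time-varying-mean update; ``None`` = constant.
    robust_trigger_sd : float or None
        Mahalanobis trigger for the equal-variance outlier fallback.
    """

    def __init__(self, obs: ObservationSequence, duration_family: str = "invgauss",
                 d_max_s: float = 30.0, mean_window_s: float | None = 50.0,
                 window_kind: str = "boxcar",
                 robust_trigger_sd: float | None = None,
                 random_state: int = 0):
        self.obs = obs
        self.duration_family = duration_family
        self.d_max = max(2, int(round(d_max_s * obs.fs)))
        self.mean_window_s = mean_window_s
        self.window_kind = window_kind
        self.robust_trigger_sd = robust_trigger_sd
        self.random_state = random_state

    def initialize(self, hmm_results=None, tol: float = 1e-5,
                   max_iter: int = 100) -> EDHMMParams:
        """Initial EDHMM parameters from a standard-HMM fit.

        Fits (or reuses) a :class:`~updown.hmm.GaussianHMM`, decodes its
        Viterbi path, and estimates duration-model parameters from the
        decoded dwell lengths; observation parameters carry over.
        """
        from .initialization import init_duration_models

        if hmm_results is None:
            hmm = GaussianHMM(self.obs, self.mean_window_s, self.window_kind,
                              self.robust_trigger_sd, self.random_state)
            hmm_results = hmm.fit(tol=tol, max_iter=max_iter)
        p = hmm_results.params
        seq = hmm_results.decode()
        durs = [np.clip(seq.durations(k), 1, self.d_max) for k in (DOWN, UP)]
        models = []
        if self.duration_family in ("gamma", "invgauss"):
            ests = init_duration_models(durs)
            names = {"gamma": ("alpha", "beta"), "invgauss": ("mu", "lam")}
            for k in (DOWN, UP):
                pars = dict(zip(names[self.duration_family],
                                ests[k][self.duration_family]))
                models.append(DurationModel(self.duration_family, pars,
                                            self.d_max, self.obs.fs))
        elif self.duration_family == "geometric":
            for k in (DOWN, UP):
                q = 1.0 / max(np.mean(durs[k]), 1.0 + 1e-9)
                models.append(DurationModel("geometric", {"q": q},
                                            self.d_max, self.obs.fs))
        else:  # nonparametric: smoothed histogram of Viterbi dwell lengths
            for k in (DOWN, UP):
                hist = np.bincount(durs[k], minlength=self.d_max + 1)[1:]
                models.append(DurationModel(
                    "nonparametric", {"pmf": (hist + 1e-6) / (hist + 1e-6).sum()},
                    self.d_max, self.obs.fs))
        return EDHMMParams(p.pi, p.mean_traj, p.covs, models,
                           self.mean_window_s, self.window_kind)

    def fit(self, init: EDHMMParams | None = None, tol: float = 1e-5,
            max_iter: int = 30, verbose: bool = False) -> "EDHMMResults":
        """EM fit.  The duration M step forms the nonparametric posterior
        dwell pmf and moment-matches the parametric family to it (exact
        censored ML); convergence at relative tolerance ``tol``."""
        params = init if init is not None else self.initialize()
        trace: list[float] = []
        duration_history = []
        converged = False
        prev_params = params
        for _ in range(max_iter):
            gamma = np.empty((self.obs.n_samples, 2))
            post, dpost = edhmm_forward_backward(params, self.obs,
                                                 self.robust_trigger_sd)
            gamma = post.gamma
            total = post.loglik
            if verbose:
                print(f"EDHMM EM iter {len(trace)}: loglik {total:.6f}")
            if trace and total < trace[-1] - 1e-8 * abs(trace[-1]):
                params = prev_params
                converged = True
                break
            trace.append(total)
            if len(trace) > 1 and (trace[-1] - trace[-2]) < tol * abs(trace[-2]):
                converged = True
                break
            prev_params = params
            pi = np.vstack([gamma[sl][0] for sl in self.obs.segment_slices()])
            mean_traj = windowed_mean_update(self.obs, gamma,
                                             params.mean_window_s,
                                             params.window_kind)
            covs = pooled_covariance_update(self.obs, gamma, mean_traj,
                                            prev_covs=params.covs)
            models = []
            for k in (DOWN, UP):
                if dpost.mass[k].sum() <= 0:
                    warnings.warn(f"state {k} has no posterior run mass; "
                                  "keeping its duration model")
                    models.append(params.duration_models[k])
                    continue
                nonpar = nonparametric_duration_mle(dpost.mass[k], self.d_max,
                                                    self.obs.fs)
                if self.duration_family == "nonparametric":
                    models.append(nonpar)
                else:
                    old = np.array(list(params.duration_models[k].params.values()))
                    models.append(fit_expfam_duration(
                        nonpar, self.duration_family, init=old))
            duration_history.append(models)
            params = EDHMMParams(pi, mean_traj, covs, models,
                                 params.mean_window_s, params.window_kind)
        return EDHMMResults(self, params, np.asarray(trace), converged,
                            duration_history)


class EDHMMResults:
    """Fitted EDHMM: parameters, log-likelihood trace, decoders, summary."""

    def __init__(self, model: ExplicitDurationHMM, params: EDHMMParams,
                 loglik_trace: np.ndarray, converged: bool,
                 duration_history: list | None = None):
        self.model = model
        self.params = params
        self.loglik_trace = loglik_trace
        self.converged = converged
        self.duration_history = duration_history or []
        self._posterior = None
        self._dpost = None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace)

    def posterior(self) -> PosteriorMarginals:
        if self._posterior is None:
            self._posterior, self._dpost = edhmm_forward_backward(
                self.params, self.model.obs, self.model.robust_trigger_sd)
        return self._posterior

    def duration_posteriors(self) -> DurationPosteriors:
        self.posterior()
        return self._dpost

    def decode(self) -> StateSequence:
        return edhmm_viterbi(self.params, self.model.obs,
                             self.model.robust_trigger_sd)

    def align(self, target_obs: ObservationSequence, max_pert_s: float = 0.15):
        """Realign the decoded transition times to a higher-rate sequence."""
        from .alignment import align_state_sequence

        return align_state_sequence(self.decode(), self.posterior().gamma,
                                    self.model.obs, target_obs, max_pert_s)

    def summary(self) -> str:
        p = self.params
        T = self.model.obs.n_samples
        fs = self.model.obs.fs
        lines = [
            "Two-state explicit-duration HMM",
            "=" * 52,
            f"samples: {T}  segments: {self.model.obs.n_segments}  "
            f"features: {p.mean_traj.shape[2]}  fs: {fs:g} Hz",
            f"duration family: {self.model.duration_family}  "
            f"d_max: {p.d_max} steps ({p.d_max / fs:.1f} s)",
            f"EM iterations: {self.n_iter}  converged: {self.converged}",
            f"log-likelihood: {self.loglik:.4f} "
            f"({self.loglik / T:.4f} per sample)",
        ]
        for k, name in ((DOWN, "DOWN"), (UP, "UP")):
            mu = p.mean_traj[:, k, :].mean(axis=0)
            sd = np.sqrt(np.diag(p.covs[k]))
            dm = p.duration_models[k]
            pars = ", ".join(f"{a}={float(v):.4g}" for a, v in dm.params.items()
                             if a != "pmf")
            lines.append(
                f"{name}: mean(t) avg {np.array2string(mu, precision=3)} "
                f"sd {np.array2string(sd, precision=3)}  "
                f"dwell {dm.family}({pars}) mean {dm.mean() / fs:.3f} s")
        return "\n".join(lines)
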