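"""Evaluation machinery: feature separability, threshold-crossing baselines,
and agreement between state sequences from paired signals.

Separability of a candidate signal feature is the Bhattacharyya distance
between its two state-conditional Gaussians (closed form; time-varying means
enter through the time-averaged Mahalanobis term).  Threshold-crossing (TC)
baselines classify UP wherever a scalar feature exceeds a fixed threshold
chosen either from a static two-component Gaussian mixture (SMM) or from the
lowest local minimum of a kernel density estimate (Np).  Agreement between
state sequences decoded from paired recordings (e.g. LFP vs membrane
potential) is scored by an instantaneous error probability ``e_i`` (false-UP
plus false-DOWN time fraction) and a state error probability ``e_s`` (state
additions plus deletions after a greedy transition correspondence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import find_peaks
from sklearn.mixture import GaussianMixture

from .containers import DOWN, UP, ObservationSequence, StateSequence
from .initialization import terrell_bandwidth

__all__ = [
    "SeparabilityResult",
    "bhattacharyya_gaussian",
    "bhattacharyya_time_varying",
    "feature_separability",
    "tc_threshold",
    "tc_classify",
    "CorrespondenceResult",
    "match_states",
    "ErrorMetrics",
    "error_metrics",
]


# ---------------------------------------------------------------------------
# Bhattacharyya separability

@dataclass
class SeparabilityResult:
    """Bhattacharyya distance between state-conditional distributions."""

    D_B: float
    label: str = ""


def bhattacharyya_gaussian(m1, S1, m2, S2, label: str = "") -> SeparabilityResult:
    """Closed-form Bhattacharyya distance between two multivariate normals:

    ``D_B = (1/8) dm' Sbar^-1 dm + (1/2) ln(det Sbar / sqrt(det S1 det S2))``
    with ``Sbar = (S1 + S2)/2`` and ``dm = m1 - m2``.
    """
    m1 = np.atleast_1d(np.asarray(m1, float))
    m2 = np.atleast_1d(np.asarray(m2, float))
    S1 = np.atleast_2d(np.asarray(S1, float))
    S2 = np.atleast_2d(np.asarray(S2, float))
    Sbar = 0.5 * (S1 + S2)
    sign, logdet_bar = np.linalg.slogdet(Sbar)
    if sign <= 0:
        raise ValueError("pooled covariance is singular")
    dm = m1 - m2
    term_m = 0.125 * dm @ np.linalg.solve(Sbar, dm)
    term_c = 0.5 * (logdet_bar - 0.5 * (np.linalg.slogdet(S1)[1]
                                        + np.linalg.slogdet(S2)[1]))
    return SeparabilityResult(float(term_m + term_c), label)


def bhattacharyya_time_varying(mean_traj: np.ndarray, S1, S2,
                               label: str = "") -> SeparabilityResult:
    """Separability with time-varying means: the Mahalanobis term is the
    time average over the mean trajectories (shape (T, 2, D) or (T, 2))."""
    mt = np.asarray(mean_traj, dtype=float)
    if mt.ndim == 2:
        mt = mt[:, :, None]
    S1 = np.atleast_2d(np.asarray(S1, float))
    S2 = np.atleast_2d(np.asarray(S2, float))
    Sbar = 0.5 * (S1 + S2)
    sign, logdet_bar = np.linalg.slogdet(Sbar)
    if sign <= 0:
        raise ValueError("pooled covariance is singular")
    dm = mt[:, DOWN, :] - mt[:, UP, :]
    term_m = 0.125 * np.mean(np.einsum("td,td->t", dm,
                                       np.linalg.solve(Sbar, dm.T).T))
    term_c = 0.5 * (logdet_bar - 0.5 * (np.linalg.slogdet(S1)[1]
                                        + np.linalg.slogdet(S2)[1]))
    return SeparabilityResult(float(term_m + term_c), label)


def feature_separability(params, label: str = "") -> SeparabilityResult:
    """Separability of a fitted model's state-conditional observation
    distributions (HMM or EDHMM parameter object)."""
    return bhattacharyya_time_varying(params.mean_traj, params.covs[DOWN],
                                      params.covs[UP], label)


# ---------------------------------------------------------------------------
# threshold-crossing baselines

def tc_threshold(feature, method: str = "smm",
                 random_state: int = 0) -> float:
    """Fixed classification threshold for a scalar feature.

    ``smm``: fit a two-component Gaussian mixture; the threshold is the point
    between the component means where the two components have equal
    responsibility.  ``np``: the lowest-valued local minimum of a Gaussian
    KDE (oversmoothing bandwidth) between the mixture-component means; falls
    back to the SMM threshold when no interior minimum exists.
    """
    x = np.asarray(feature, dtype=float).squeeze()
    if x.ndim != 1:
        raise ValueError("tc_threshold expects a scalar (1-D) feature")
    gm = GaussianMixture(n_components=2, n_init=2, random_state=random_state)
    gm.fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    mlo, mhi = gm.means_.ravel()[order]
    wlo, whi = gm.weights_[order]
    vlo, vhi = gm.covariances_.ravel()[order]

    def resp_diff(v):
        return (np.log(wlo) + stats.norm.logpdf(v, mlo, np.sqrt(vlo))
                - np.log(whi) - stats.norm.logpdf(v, mhi, np.sqrt(vhi)))

    if method == "smm":
        if mhi - mlo < 1e-12:
            return float(mlo)
        from scipy.optimize import brentq
        a, b = mlo + 1e-9 * (mhi - mlo), mhi - 1e-9 * (mhi - mlo)
        if resp_diff(a) * resp_diff(b) < 0:
            return float(brentq(resp_diff, a, b))
        grid = np.linspace(a, b, 1001)
        return float(grid[np.argmin(np.abs(resp_diff(grid)))])
    if method == "np":
        kde = stats.gaussian_kde(x, bw_method=terrell_bandwidth(len(x)))
        grid = np.linspace(mlo, mhi, 512)[1:-1]
        dens = kde(grid)
        minima, _ = find_peaks(-dens)
        if len(minima) == 0:
            warnings.warn("no interior KDE minimum between component means; "
                          "falling back to the SMM threshold")
            return tc_threshold(x, "smm", random_state)
        return float(grid[minima[np.argmin(dens[minima])]])
    raise ValueError("method must be 'smm' or 'np'")


def tc_classify(obs, threshold: float, fs: float | None = None) -> StateSequence:
    """Threshold-crossing classification: UP where the feature exceeds the
    threshold, DOWN otherwise; transitions at the crossings, no minimum-
    duration rule."""
    if isinstance(obs, ObservationSequence):
        x = obs.squeezed()
        labels = [(x[sl] > threshold).astype(int) for sl in obs.segment_slices()]
        return StateSequence(labels, obs.fs, obs.segment_map)
    x = np.asarray(obs, dtype=float)
    if fs is None:
        raise ValueError("fs required when passing a bare array")
    return StateSequence([(x > threshold).astype(int)], fs)


# ---------------------------------------------------------------------------
# correspondence between paired state sequences

@dataclass
class CorrespondenceResult:
    """Greedy transition links between two state sequences (e.g. LFP vs MP)."""

    up_links: list = field(default_factory=list)      # (lfp_idx, mp_idx)
    down_links: list = field(default_factory=list)
    extra_states: int = 0    # LFP states with no linked bounding transition
    missed_states: int = 0   # MP states with no linked bounding transition
    n_lfp_states: int = 0
    n_mp_states: int = 0


def _transition_times(seq: StateSequence, into_state: int) -> np.ndarray:
    """Times (s) of transitions into ``into_state``, across segments."""
    times = []
    for si in range(seq.n_segments):
        off = (seq.segment_map.intervals[si, 0]
               if seq.segment_map is not None else 0)
        idx, entered = seq.transitions(si)
        times.extend((idx[entered == into_state] + off) / seq.fs)
    return np.asarray(times, dtype=float)


def _greedy_link(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """Iteratively link the closest-in-time (a, b) pair until one side is
    exhausted; ties link the earlier ``a`` transition first (argmin is
    row-major, so the smaller index wins on exact ties)."""
    if len(a) == 0 or len(b) == 0:
        return []
    d = np.abs(a[:, None] - b[None, :])
    links = []
    for _ in range(min(len(a), len(b))):
        i, j = np.unravel_index(np.argmin(d), d.shape)
        links.append((int(i), int(j)))
        d[i, :] = np.inf
        d[:, j] = np.inf
    return links


def _remove_crossings(links: list[tuple[int, int]], a: np.ndarray,
                      b: np.ndarray) -> list[tuple[int, int]]:
    """Drop, from any crossed pair of links, the more separated link, until
    the remaining links preserve temporal order on both sides."""
    links = sorted(links)
    while True:
        crossing = None
        for x in range(len(links)):
            for y in range(x + 1, len(links)):
                (i1, j1), (i2, j2) = links[x], links[y]
                if (i1 < i2) != (j1 < j2) or j1 == j2:
                    crossing = (x, y)
                    break
            if crossing:
                break
        if crossing is None:
            return links
        x, y = crossing
        dx = abs(a[links[x][0]] - b[links[x][1]])
        dy = abs(a[links[y][0]] - b[links[y][1]])
        links.pop(x if dx > dy else y)


def _unmatched_states(seq: StateSequence, linked_up: set, linked_down: set) -> int:
    """Count states none of whose bounding transitions are linked."""
    n_unmatched = 0
    up_times = _transition_times(seq, UP)
    down_times = _transition_times(seq, DOWN)
    up_linked_t = {round(up_times[i], 9) for i in linked_up if i < len(up_times)}
    down_linked_t = {round(down_times[i], 9) for i in linked_down
                     if i < len(down_times)}
    for si in range(seq.n_segments):
        off = (seq.segment_map.intervals[si, 0]
               if seq.segment_map is not None else 0)
        idx, entered = seq.transitions(si)
        t = (idx + off) / seq.fs
        runs = seq.intervals(si)
        for r, (k, s, e) in enumerate(runs):
            bounds = []
            if r > 0:  # onset transition exists
                bounds.append((t[r - 1], entered[r - 1]))
            if r < len(idx):  # offset transition exists
                bounds.append((t[r], entered[r]))
            if not bounds:
                continue  # constant segment: no transitions to link
            hit = False
            for tt, ent in bounds:
                ref = up_linked_t if ent == UP else down_linked_t
                if round(tt, 9) in ref:
                    hit = True
                    break
            if not hit:
                n_unmatched += 1
    return n_unmatched


def _count_states(seq: StateSequence) -> int:
    return sum(len(seq.intervals(si)) for si in range(seq.n_segments))


def match_states(lfp: StateSequence, mp: StateSequence) -> CorrespondenceResult:
    """Best correspondence between two decoded state sequences.

    UP transitions are linked greedily nearest-in-time until one side is
    exhausted, crossed links removed (dropping the more separated one), then
    the same for DOWN transitions.  States on either side none of whose
    bounding transitions ended up linked are counted as extra (first
    sequence) or missed (second sequence) states.
    """
    res = CorrespondenceResult()
    for into, attr in ((UP, "up_links"), (DOWN, "down_links")):
        a = _transition_times(lfp, into)
        b = _transition_times(mp, into)
        links = _remove_crossings(_greedy_link(a, b), a, b)
        setattr(res, attr, links)
    lfp_up = {i for i, _ in res.up_links}
    lfp_down = {i for i, _ in res.down_links}
    mp_up = {j for _, j in res.up_links}
    mp_down = {j for _, j in res.down_links}
    res.extra_states = _unmatched_states(lfp, lfp_up, lfp_down)
    res.missed_states = _unmatched_states(mp, mp_up, mp_down)
    res.n_lfp_states = _count_states(lfp)
    res.n_mp_states = _count_states(mp)
    return res


# ---------------------------------------------------------------------------
# error metrics

@dataclass
class ErrorMetrics:
    """Instantaneous and state error probabilities between paired sequences."""

    false_up: float     # P(first = UP, second = DOWN)
    false_down: float   # P(first = DOWN, second = UP)
    additions: float    # extra states / n reference states
    deletions: float    # missed states / n reference states

    @property
    def e_i(self) -> float:
        return self.false_up + self.false_down

    @property
    def e_s(self) -> float:
        return self.additions + self.deletions


def error_metrics(lfp: StateSequence, mp: StateSequence,
                  corr: CorrespondenceResult | None = None) -> ErrorMetrics:
    """Error of the first sequence relative to the second (reference).

    ``e_i`` is the time fraction of disagreement split into false-UP and
    false-DOWN components; ``e_s`` is (extra + missed states) divided by the
    number of reference (second-sequence) states, using the greedy
    correspondence (computed here if not supplied).
    """
    a, b = lfp.concatenated(), mp.concatenated()
    if a.size != b.size or a.size == 0:
        raise ValueError("sequences must share a common, non-empty time axis")
    if corr is None:
        corr = match_states(lfp, mp)
    false_up = float(np.mean((a == UP) & (b == DOWN)))
    false_down = float(np.mean((a == DOWN) & (b == UP)))
    n_ref = max(corr.n_mp_states, 1)
    return ErrorMetrics(false_up, false_down,
                        corr.extra_states / n_ref, corr.missed_states / n_ref)
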