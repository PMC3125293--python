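"""Maximum-likelihood realignment of decoded transition times.

Decoding runs on band-limited features at a low rate (default 50 Hz), which
blurs transition times.  Alignment recovers temporal precision: per-state
Gaussians are estimated on a higher-rate, less-filtered target sequence
(default the broadband signal at 252 Hz) using the posteriors from the fit,
and a dynamic program finds the per-transition perturbations (default up to
+-150 ms) that maximize the target-sequence likelihood of the perturbed
segmentation.  The DP is exact: it equals exhaustive search over all
admissible perturbation combinations, with ordering of transitions enforced
inside the recursion.
"""

from __future__ import annotations

import numpy as np

from .containers import DOWN, UP, ObservationSequence, StateSequence

__all__ = ["estimate_target_models", "align_transitions", "align_state_sequence"]

_LOG2PI = np.log(2 * np.pi)


def transfer_gamma(gamma_seg: np.ndarray, base_fs: float, n_target: int,
                   target_fs: float) -> np.ndarray:
    """Nearest-neighbour-in-time transfer of posteriors to the target grid."""
    j = np.arange(n_target)
    i = np.clip(np.round(j * base_fs / target_fs).astype(int), 0,
                len(gamma_seg) - 1)
    return gamma_seg[i]


def estimate_target_models(target: np.ndarray, gamma: np.ndarray,
                           min_mass: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-weighted per-state mean and variance on the target sequence.

    ``target`` is the scalar target signal (length T'), ``gamma`` the state
    posteriors already transferred to the target grid (T', 2).
    """
    y = np.asarray(target, dtype=float).squeeze()
    if y.ndim != 1:
        raise ValueError("alignment target must be a scalar sequence")
    means = np.empty(2)
    variances = np.empty(2)
    for k in (DOWN, UP):
        w = gamma[:, k]
        mass = w.sum()
        if mass < min_mass:
            raise ValueError(f"state {k} has negligible posterior mass on the "
                             "target sequence")
        means[k] = np.dot(w, y) / mass
        variances[k] = np.dot(w, (y - means[k]) ** 2) / mass
        if variances[k] <= 0:
            variances[k] = 1e-12
    return means, variances


def _preference_order(max_pert: int) -> np.ndarray:
    """Candidate perturbations ordered smallest |delta| first, negative
    before positive -- the documented deterministic tie-break."""
    out = [0]
    for a in range(1, max_pert + 1):
        out.extend((-a, a))
    return np.asarray(out, dtype=int)


def align_transitions(transitions: np.ndarray, entered: np.ndarray,
                      first_state: int, target: np.ndarray,
                      means: np.ndarray, variances: np.ndarray,
                      max_pert: int) -> np.ndarray:
    """Optimal integer perturbations of the transition times, one per transition.

    ``transitions`` are sample indices on the target grid (transition i means
    the entered state starts at that sample); ``entered`` are the states
    entered; ``first_state`` is the state before the first transition.
    Perturbed transitions are constrained to remain strictly increasing and
    inside the open segment interval.  Returns the perturbation vector
    ``delta*`` maximizing the total Gaussian log-likelihood of the target
    sequence under the perturbed segmentation.
    """
    y = np.asarray(target, dtype=float).squeeze()
    T = len(y)
    M = len(transitions)
    if M == 0:
        return np.zeros(0, dtype=int)
    # per-state cumulative log-likelihoods; interval [a, b) = cum[b] - cum[a]
    cum = np.zeros((T + 1, 2))
    for k in (DOWN, UP):
        ll = -0.5 * (_LOG2PI + np.log(variances[k])
                     + (y - means[k]) ** 2 / variances[k])
        cum[1:, k] = np.cumsum(ll)

    deltas = _preference_order(max_pert)
    nd = len(deltas)
    states_before = np.empty(M, dtype=int)
    states_before[0] = first_state
    states_before[1:] = entered[:-1]

    V = np.full((M, nd), -np.inf)
    back = np.zeros((M, nd), dtype=int)
    pos0 = transitions[0] + deltas
    ok = (pos0 >= 1) & (pos0 <= T - 1)
    V[0, ok] = cum[pos0[ok], states_before[0]] - cum[0, states_before[0]]
    for i in range(1, M):
        kprev = states_before[i]
        pos_prev = transitions[i - 1] + deltas
        prev_score = V[i - 1] - np.where(
            (pos_prev >= 1) & (pos_prev <= T - 1),
            cum[np.clip(pos_prev, 0, T), kprev], np.inf)
        pos = transitions[i] + deltas
        for j in range(nd):
            p = pos[j]
            if p < 1 or p > T - 1:
                continue
            best, arg = -np.inf, 0
            for jp in range(nd):
                if pos_prev[jp] >= p:
                    continue
                s = prev_score[jp]
                if s > best:
                    best, arg = s, jp
            if best > -np.inf:
                V[i, j] = best + cum[p, kprev]
                back[i, j] = arg
    # closing term: last state runs to the segment end
    klast = entered[-1]
    pos_last = transitions[-1] + deltas
    final = V[-1] + np.where((pos_last >= 1) & (pos_last <= T - 1),
                             cum[T, klast] - cum[np.clip(pos_last, 0, T), klast],
                             -np.inf)
    j = int(np.argmax(final))  # deltas are in preference order
    if not np.isfinite(final[j]):
        raise ValueError("no admissible perturbation assignment; transitions "
                         "too dense for this max_pert")
    out = np.empty(M, dtype=int)
    for i in range(M - 1, -1, -1):
        out[i] = deltas[j]
        j = back[i, j]
    return out


def align_state_sequence(seq: StateSequence, gamma: np.ndarray,
                         base_obs: ObservationSequence,
                         target_obs: ObservationSequence,
                         max_pert_s: float = 0.15) -> StateSequence:
    """Realign a decoded state sequence to a higher-rate observation sequence.

    ``gamma`` are the decode-grid posteriors (rows aligned with
    ``base_obs``); target per-state Gaussians are estimated from the
    posteriors transferred to the target grid, then each segment's
    transition times are perturbed by up to ``max_pert_s`` seconds.
    """
    if target_obs.n_segments != base_obs.n_segments:
        raise ValueError("base and target sequences must share segment structure")
    if max_pert_s < 0:
        raise ValueError("max_pert_s must be non-negative")
    scale = target_obs.fs / base_obs.fs
    tslices = target_obs.segment_slices()
    bslices = base_obs.segment_slices()
    # pooled target models over all segments
    g_t = np.vstack([
        transfer_gamma(gamma[bsl], base_obs.fs, tsl.stop - tsl.start,
                       target_obs.fs)
        for bsl, tsl in zip(bslices, tslices)])
    means, variances = estimate_target_models(target_obs.squeezed(), g_t)
    max_pert = int(round(max_pert_s * target_obs.fs))

    labels = []
    for si, (bsl, tsl) in enumerate(zip(bslices, tslices)):
        yt = target_obs.squeezed()[tsl]
        Tt = len(yt)
        trans, entered = seq.transitions(si)
        lab0 = seq.labels[si]
        if len(trans) == 0:
            labels.append(np.full(Tt, lab0[0] if len(lab0) else DOWN, dtype=int))
            continue
        pos = np.round(trans * scale).astype(int)
        pos = np.clip(pos, 1, Tt - 1)
        # up-scaling can collide transition indices; keep them strictly increasing
        for i in range(1, len(pos)):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        pos = np.clip(pos, 1, Tt - 1)
        delta = align_transitions(pos, entered, int(lab0[0]), yt,
                                  means, variances, max_pert)
        new_pos = pos + delta
        lab = np.empty(Tt, dtype=int)
        lab[:new_pos[0]] = lab0[0]
        bounds = np.append(new_pos, Tt)
        for i in range(len(new_pos)):
            lab[bounds[i]:bounds[i + 1]] = entered[i]
        labels.append(lab)
    return StateSequence(labels, target_obs.fs, target_obs.segment_map)
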