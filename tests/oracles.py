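"""Independent brute-force oracles used by the test suite.

Everything here enumerates explicitly (paths, segmentations, perturbation
combinations) and is kept free of the library's recursion code so it can
serve as an independent check of exact inference on small instances.
"""

from itertools import product

import numpy as np
from scipy.stats import norm


def hmm_enumerate(y, A, pi, means, sds):
    """Sum/argmax over all 2^T state paths of a scalar-emission HMM.

    Returns (loglik, gamma, best_path)."""
    T = len(y)
    tot = 0.0
    gamma = np.zeros((T, 2))
    best_lp, best_path = -np.inf, None
    for path in product((0, 1), repeat=T):
        lp = np.log(pi[path[0]])
        for t in range(1, T):
            lp += np.log(A[path[t - 1], path[t]])
        for t in range(T):
            lp += norm.logpdf(y[t], means[t, path[t]], sds[path[t]])
        pr = np.exp(lp)
        tot += pr
        for t in range(T):
            gamma[t, path[t]] += pr
        if lp > best_lp:
            best_lp, best_path = lp, np.asarray(path)
    return np.log(tot), gamma / tot, best_path


def _compositions(T, d_max):
    """All ordered part lists in [1, d_max] summing to T."""
    if T == 0:
        yield []
        return
    for d in range(1, min(d_max, T) + 1):
        for rest in _compositions(T - d, d_max):
            yield [d] + rest


def edhmm_enumerate(y, pi, means, sds, duration_models, d_max):
    """Sum/argmax over all legal alternating segmentations of a scalar EDHMM.

    First run starts at 0, last run ends at T-1, run lengths in [1, d_max].
    Returns (loglik, gamma, duration_mass, best_labels)."""
    T = len(y)
    tot = 0.0
    gamma = np.zeros((T, 2))
    mass = np.zeros((2, d_max))
    best_lp, best_lab = -np.inf, None
    for k0 in (0, 1):
        for comp in _compositions(T, d_max):
            lp = np.log(pi[k0])
            k, t = k0, 0
            lab = np.empty(T, dtype=int)
            for d in comp:
                lp += duration_models[k].log_pmf(d)
                lp += norm.logpdf(y[t:t + d], means[t:t + d, k], sds[k]).sum()
                lab[t:t + d] = k
                t += d
                k = 1 - k
            pr = np.exp(lp)
            tot += pr
            for t2 in range(T):
                gamma[t2, lab[t2]] += pr
            k, t = k0, 0
            for d in comp:
                mass[k, d - 1] += pr
                t += d
                k = 1 - k
            if lp > best_lp:
                best_lp, best_lab = lp, lab.copy()
    return np.log(tot), gamma / tot, mass / tot, best_lab


def alignment_enumerate(y, transitions, entered, first_state, means,
                        variances, max_pert):
    """Exhaustive search over all perturbation combinations.

    Returns (best_deltas, best_loglik)."""
    T = len(y)

    def total(ds):
        pos = np.asarray(transitions) + np.asarray(ds)
        if np.any(pos < 1) or np.any(pos > T - 1) or np.any(np.diff(pos) <= 0):
            return -np.inf
        lab = np.empty(T, dtype=int)
        lab[:pos[0]] = first_state
        bounds = np.append(pos, T)
        for i in range(len(pos)):
            lab[bounds[i]:bounds[i + 1]] = entered[i]
        return float(np.sum(norm.logpdf(y, means[lab],
                                        np.sqrt(variances[lab]))))

    best, best_ds = -np.inf, None
    for ds in product(range(-max_pert, max_pert + 1), repeat=len(transitions)):
        lp = total(ds)
        if lp > best:
            best, best_ds = lp, ds
    return np.asarray(best_ds), best


def random_edhmm_instance(rng, T_max=10, d_max_max=5):
    """A random small EDHMM instance (scalar emissions, mixed families)."""
    from updown.durations import DurationModel

    T = int(rng.integers(4, T_max + 1))
    d_max = int(rng.integers(2, d_max_max + 1))
    y = rng.normal(size=T)
    means = np.tile(np.sort(rng.normal(size=2)), (T, 1))
    # mild time variation so the time-varying path is exercised
    means = means + rng.normal(0, 0.05, size=(T, 2))
    sds = rng.uniform(0.3, 1.2, size=2)
    pi = rng.dirichlet([1.0, 1.0])
    models = []
    for _ in range(2):
        fam = ["gamma", "invgauss", "geometric", "nonparametric"][
            int(rng.integers(4))]
        if fam == "gamma":
            m = DurationModel("gamma", {"alpha": rng.uniform(0.5, 5),
                                        "beta": rng.uniform(0.1, 2)}, d_max)
        elif fam == "invgauss":
            m = DurationModel("invgauss", {"mu": rng.uniform(1, 6),
                                           "lam": rng.uniform(1, 10)}, d_max)
        elif fam == "geometric":
            m = DurationModel("geometric", {"q": rng.uniform(0.1, 0.9)}, d_max)
        else:
            m = DurationModel("nonparametric",
                              {"pmf": rng.dirichlet(np.ones(d_max))}, d_max)
        models.append(m)
    return y, pi, means, sds, models, d_max
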