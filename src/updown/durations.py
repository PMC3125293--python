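"""Dwell-time (state-duration) distributions on integer support [1, d_max].

UP and DOWN state dwell times are modelled with censored discrete
distributions: a continuous density (gamma or inverse Gaussian) evaluated at
integer step counts and renormalized over ``[1, d_max]``, a truncated
geometric (the implicit choice of a standard HMM), or a nonparametric pmf.

Fitting uses the exponential-family structure: on a fixed finite support the
censored ML estimate for a family with natural statistics ``T(d)`` is the
parameter vector whose model expectations ``E[T(d)]`` match the empirical
(or posterior-weighted nonparametric) expectations -- a small root-finding
problem.  Natural statistics are ``(log d, d)`` for the gamma family and
``(d, 1/d)`` for the inverse Gaussian.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, special

__all__ = [
    "DurationModel",
    "fit_durations_gamma",
    "fit_durations_invgauss",
    "nonparametric_duration_mle",
    "fit_expfam_duration",
    "fit_duration_family",
    "loglik_per_sample",
]

_FAMILIES = ("geometric", "gamma", "invgauss", "nonparametric")


class DurationModel:
    """A dwell-time pmf on integer support ``[1, d_max]`` (in time steps).

    Parameters
    ----------
    family : {"geometric", "gamma", "invgauss", "nonparametric"}
    params : dict
        ``{"q": ...}`` for geometric; ``{"alpha": ..., "beta": ...}`` for
        gamma; ``{"mu": ..., "lam": ...}`` for inverse Gaussian (both in
        time steps); ``{"pmf": array}`` for nonparametric.
    d_max : int
        Maximum allowed duration in time steps; the pmf is renormalized
        (censored) over ``[1, d_max]``.
    fs : float, optional
        Feature sampling rate, only used to report parameters in seconds.
    """

    def __init__(self, family: str, params: dict, d_max: int,
                 fs: float | None = None):
        if family not in _FAMILIES:
            raise ValueError(f"unknown duration family {family!r}")
        if d_max < 1:
            raise ValueError("d_max must be >= 1")
        self.family = family
        self.params = dict(params)
        self.d_max = int(d_max)
        self.fs = fs
        self._log_pmf = self._build_log_pmf()

    # -- construction -----------------------------------------------------
    def _build_log_pmf(self) -> np.ndarray:
        d = np.arange(1, self.d_max + 1, dtype=float)
        if self.family == "geometric":
            q = self.params["q"]
            if not 0 < q < 1:
                raise ValueError("geometric success probability must be in (0,1)")
            logw = np.log(q) + (d - 1) * np.log1p(-q)
        elif self.family == "gamma":
            a, b = self.params["alpha"], self.params["beta"]
            if a <= 0 or b <= 0:
                raise ValueError("gamma parameters must be positive")
            logw = (a - 1) * np.log(d) - b * d
        elif self.family == "invgauss":
            mu, lam = self.params["mu"], self.params["lam"]
            if mu <= 0 or lam <= 0:
                raise ValueError("inverse Gaussian parameters must be positive")
            logw = -1.5 * np.log(d) - lam * (d - mu) ** 2 / (2 * mu ** 2 * d)
        else:  # nonparametric
            p = np.asarray(self.params["pmf"], dtype=float)
            if p.shape != (self.d_max,):
                raise ValueError("nonparametric pmf must have length d_max")
            if np.any(p < 0) or p.sum() <= 0:
                raise ValueError("nonparametric pmf must be non-negative, not all zero")
            with np.errstate(divide="ignore"):
                logw = np.log(p)
        return logw - special.logsumexp(logw)

    # -- evaluation -------------------------------------------------------
    def log_pmf(self, d=None):
        """Log pmf at integer duration(s) ``d`` (default: the full support)."""
        if d is None:
            return self._log_pmf
        d = np.asarray(d)
        if np.any(d < 1) or np.any(d > self.d_max):
            raise ValueError(f"duration outside support [1, {self.d_max}]")
        return self._log_pmf[d - 1]

    def pmf(self, d=None):
        return np.exp(self.log_pmf(d))

    @property
    def support(self) -> np.ndarray:
        return np.arange(1, self.d_max + 1)

    def mean(self) -> float:
        """Expected dwell in time steps (under censoring)."""
        return float(np.sum(self.support * self.pmf()))

    def natural_stats(self, family: str | None = None) -> np.ndarray:
        """Natural-statistic matrix T(d), shape (P, d_max)."""
        fam = family or self.family
        d = self.support.astype(float)
        if fam == "gamma":
            return np.vstack([np.log(d), d])
        if fam == "invgauss":
            return np.vstack([d, 1.0 / d])
        if fam == "geometric":
            return d[None, :]
        raise ValueError(f"no natural statistics for family {fam!r}")

    def expected_stats(self, family: str | None = None) -> np.ndarray:
        """E[T_p(d)] under this (censored) pmf, for the given family's T."""
        return self.natural_stats(family) @ self.pmf()

    # -- serialization ----------------------------------------------------
    def to_text(self) -> str:
        lines = [f"family = {self.family}", f"d_max = {self.d_max}"]
        if self.fs is not None:
            lines.append(f"fs = {self.fs}")
        for k, v in self.params.items():
            if k == "pmf":
                lines.append("pmf = " + " ".join(f"{x:.10g}" for x in v))
            else:
                lines.append(f"{k} = {v:.10g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "DurationModel":
        kv = {}
        for line in text.strip().splitlines():
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
        family = kv.pop("family")
        d_max = int(kv.pop("d_max"))
        fs = float(kv.pop("fs")) if "fs" in kv else None
        params = {k: (np.array([float(x) for x in v.split()]) if k == "pmf"
                      else float(v)) for k, v in kv.items()}
        return cls(family, params, d_max, fs)

    def __repr__(self) -> str:
        p = {k: (f"<{len(v)} bins>" if k == "pmf" else round(float(v), 4))
             for k, v in self.params.items()}
        return f"DurationModel({self.family}, {p}, d_max={self.d_max})"


# -- direct ML from duration samples (used at initialization) --------------

def fit_durations_gamma(durations, tol: float = 1e-12,
                        max_iter: int = 200) -> tuple[float, float]:
    """Uncensored gamma ML: shape by Newton-Raphson, rate analytically.

    Solves ``log(alpha) - psi(alpha) = log(mean d) - mean(log d)`` for the
    shape and sets ``beta = alpha / mean(d)``.
    """
    d = np.asarray(durations, dtype=float)
    _check_durations(d)
    c = np.log(d.mean()) - np.mean(np.log(d))
    if c <= 0:
        raise ValueError("degenerate durations (all equal); gamma ML diverges")
    # standard closed-form starting point
    a = (3.0 - c + np.sqrt((c - 3.0) ** 2 + 24.0 * c)) / (12.0 * c)
    for _ in range(max_iter):
        f = np.log(a) - special.digamma(a) - c
        fp = 1.0 / a - special.polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < tol * max(1.0, a):
            a = a_new
            break
        a = a_new
    return float(a), float(a / d.mean())


def fit_durations_invgauss(durations) -> tuple[float, float]:
    """Uncensored inverse Gaussian ML: ``mu = mean``, ``lam = N / sum(1/d - 1/mu)``."""
    d = np.asarray(durations, dtype=float)
    _check_durations(d)
    mu = d.mean()
    denom = np.sum(1.0 / d - 1.0 / mu)
    if denom <= 0:
        raise ValueError("degenerate durations (all equal); inverse Gaussian "
                         "lambda estimate diverges")
    return float(mu), float(len(d) / denom)


def _check_durations(d: np.ndarray) -> None:
    if d.size < 5:
        raise ValueError("need at least 5 duration samples per state")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    if np.allclose(d, d[0]):
        raise ValueError("durations are all equal; duration model degenerate")


# -- nonparametric ML from duration posteriors -----------------------------

def nonparametric_duration_mle(duration_posteriors, d_max: int | None = None,
                               fs: float | None = None) -> DurationModel:
    """Nonparametric dwell pmf proportional to total posterior mass per duration.

    ``duration_posteriors`` is either a (T, d_max) matrix of per-(t, d)
    posterior mass for one state, or an already-summed length-``d_max``
    vector.  The result is normalized over ``[1, d_max]``.
    """
    m = np.asarray(duration_posteriors, dtype=float)
    if m.ndim == 2:
        m = m.sum(axis=0)
    if np.any(m < 0):
        raise ValueError("posterior masses must be non-negative")
    if m.sum() <= 0:
        raise ValueError("all-zero posterior mass")
    if d_max is None:
        d_max = len(m)
    return DurationModel("nonparametric", {"pmf": m / m.sum()}, d_max, fs)


# -- exponential-family fits ----------------------------------------------

def _init_from_target(target: DurationModel, family: str) -> np.ndarray:
    """Moment-based starting parameters from the target pmf's expectations."""
    if family == "gamma":
        Elogd, Ed = target.expected_stats("gamma")
        c = np.log(Ed) - Elogd
        if c <= 0:
            a = 100.0
        else:
            a = (3.0 - c + np.sqrt((c - 3.0) ** 2 + 24.0 * c)) / (12.0 * c)
        return np.array([a, a / Ed])
    if family == "invgauss":
        Ed, Einv = target.expected_stats("invgauss")
        mu = Ed
        denom = Einv - 1.0 / mu
        lam = 1.0 / denom if denom > 0 else 100.0 * mu
        return np.array([mu, lam])
    if family == "geometric":
        Ed = float(target.expected_stats("geometric")[0])
        return np.array([min(1.0 / Ed, 1.0 - 1e-9)])
    raise ValueError(family)


_PARAM_NAMES = {"gamma": ("alpha", "beta"), "invgauss": ("mu", "lam"),
                "geometric": ("q",)}


def _make(family: str, theta: np.ndarray, d_max: int, fs) -> DurationModel:
    return DurationModel(family, dict(zip(_PARAM_NAMES[family], theta)),
                         d_max, fs)


def fit_expfam_duration(target: DurationModel, family: str,
                        init: np.ndarray | None = None,
                        tol: float = 1e-10) -> DurationModel:
    """Censored ML fit of a parametric family to a target pmf.

    Solves the moment-matching conditions ``E_family[T_p(d)] =
    E_target[T_p(d)]`` over the censored support -- the exact ML conditions
    for an exponential family on ``[1, d_max]``.  Parameters are searched in
    log space (positivity).  On root-finder failure, falls back to the
    moment-based direct estimate with a warning.
    """
    if family not in ("gamma", "invgauss", "geometric"):
        raise ValueError("family must be gamma, invgauss or geometric")
    d_max, fs = target.d_max, target.fs
    target_stats = target.expected_stats(family)
    theta0 = np.asarray(init, float) if init is not None else \
        _init_from_target(target, family)

    if family == "geometric":
        # one natural statistic: solve the truncated-geometric mean equation
        def resid_q(logit):
            q = special.expit(logit)
            return _make("geometric", [q], d_max, fs).mean() - target_stats[0]

        lo, hi = -30.0, 30.0
        if resid_q(lo) * resid_q(hi) > 0:  # mean at/beyond attainable range
            q = np.clip(theta0[0], 1e-12, 1 - 1e-12)
            return _make("geometric", [q], d_max, fs)
        logit = optimize.brentq(resid_q, lo, hi, xtol=1e-14)
        return _make("geometric", [special.expit(logit)], d_max, fs)

    def resid(log_theta):
        model = _make(family, np.exp(log_theta), d_max, fs)
        return model.expected_stats(family) - target_stats

    sol = optimize.root(resid, np.log(theta0), method="hybr",
                        options={"xtol": tol})
    if not sol.success or not np.all(np.isfinite(sol.x)):
        warnings.warn(f"moment matching for {family} did not converge "
                      f"({sol.message}); using moment-based direct estimate")
        return _make(family, theta0, d_max, fs)
    return _make(family, np.exp(sol.x), d_max, fs)


def fit_duration_family(durations, family: str, d_max: int,
                        fs: float | None = None) -> DurationModel:
    """Censored ML fit of ``family`` to observed integer durations.

    Builds the empirical pmf on ``[1, d_max]`` and moment-matches against it
    (exact censored ML for these families); ``nonparametric`` returns the
    empirical pmf itself.
    """
    d = np.asarray(durations, dtype=int)
    if d.size == 0:
        raise ValueError("empty duration list")
    if np.any(d < 1) or np.any(d > d_max):
        raise ValueError(f"durations outside [1, {d_max}]")
    hist = np.bincount(d, minlength=d_max + 1)[1:].astype(float)
    empirical = DurationModel("nonparametric", {"pmf": hist / hist.sum()},
                              d_max, fs)
    if family == "nonparametric":
        return empirical
    return fit_expfam_duration(empirical, family)


def loglik_per_sample(durations, model_or_family, d_max: int | None = None,
                      fs: float | None = None) -> float:
    """Mean log pmf of the durations: ``L_n``, the model-comparison score.

    Pass a fitted :class:`DurationModel`, or a family name (then the
    ML model of that family is fitted to the durations first).
    """
    d = np.asarray(durations, dtype=int)
    if d.size == 0:
        raise ValueError("empty duration list")
    if isinstance(model_or_family, DurationModel):
        model = model_or_family
    else:
        if d_max is None:
            raise ValueError("d_max required when passing a family name")
        model = fit_duration_family(d, model_or_family, d_max, fs)
    return float(np.mean(model.log_pmf(d)))
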