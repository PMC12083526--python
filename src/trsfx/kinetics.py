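"""Kinetic models and fitting for log-spaced time traces.

Two model families: a first-order accumulation A_inf*(1 - exp(-t/tau)) and a
sequential two-step (rise-then-decay) intermediate population
baseline + A * tau2/(tau2-tau1) * (exp(-t/tau2) - exp(-t/tau1)).
Fits are unweighted (or 1/sigma^2-weighted) least squares in linear value
space with deterministic multi-start initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TimeTrace",
    "KineticFit",
    "eval_first_order",
    "eval_two_step",
    "fit_trace",
    "FitFailureError",
]


class FitFailureError(RuntimeError):
    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


@dataclass
class TimeTrace:
    """Values over strictly increasing positive times (seconds)."""

    times: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.times):
                raise ValueError("sigma length mismatch")
        if len(self.times) != len(self.values):
            raise ValueError("times/values length mismatch")
        if np.any(self.times <= 0):
            raise ValueError("times must be positive")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def averaged(self) -> "TimeTrace":
        """Average repeated time points (propagating sigma when present)."""
        ut, inv = np.unique(self.times, return_inverse=True)
        if len(ut) == len(self.times):
            return self
        vals = np.zeros(len(ut))
        sig = np.zeros(len(ut)) if self.sigma is not None else None
        for i in range(len(ut)):
            sel = inv == i
            vals[i] = self.values[sel].mean()
            if sig is not None:
                sig[i] = np.sqrt(np.sum(self.sigma[sel] ** 2)) / sel.sum()
        return TimeTrace(ut, vals, sig, self.label)


@dataclass
class KineticFit:
    model: str                      # "first_order" | "two_step"
    params: dict[str, float]
    uncertainties: dict[str, float]
    rss: float
    fitted: np.ndarray
    times: np.ndarray
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def tau(self) -> float:
        return self.params.get("tau", np.nan)

    @property
    def tau1(self) -> float:
        return self.params.get("tau1", np.nan)

    @property
    def tau2(self) -> float:
        return self.params.get("tau2", np.nan)


def eval_first_order(t, a_inf: float, tau: float):
    """First-order accumulation a_inf * (1 - exp(-t/tau))."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    return a_inf * (1.0 - np.exp(-t / tau))


def eval_two_step(t, a: float, tau1: float, tau2: float, baseline: float = 0.0,
                  allow_degenerate: bool = False):
    """Sequential-intermediate population: rise with tau1, decay with tau2.

    baseline + a * tau2/(tau2 - tau1) * (exp(-t/tau2) - exp(-t/tau1)).
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("time constants must be positive")
    t = np.asarray(t, dtype=float)
    if tau1 == tau2:
        if not allow_degenerate:
            raise ValueError("tau1 == tau2 is degenerate; pass allow_degenerate=True "
                             "for the limiting (t/tau) exp(-t/tau) form")
        return baseline + a * (t / tau1) * np.exp(-t / tau1)
    return baseline + a * (tau2 / (tau2 - tau1)) * (np.exp(-t / tau2) - np.exp(-t / tau1))


def two_step_peak_time(tau1: float, tau2: float) -> float:
    """Closed-form argmax of the two-step curve."""
    return tau1 * tau2 / (tau2 - tau1) * np.log(tau2 / tau1)


def _canonical_two_step(a, tau1, tau2, baseline):
    # swapping (tau1, tau2) with a -> a*tau2/tau1 leaves the curve unchanged;
    # enforce tau1 < tau2
    if tau1 > tau2:
        a = a * tau2 / tau1
        tau1, tau2 = tau2, tau1
    return a, tau1, tau2, baseline


def _uncertainties_from_jac(sol, n_obs):
    # covariance from J^T J, scaled by residual variance
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(n_obs - len(sol.x), 1)
        s2 = 2.0 * sol.cost / dof
        cov = np.linalg.inv(jtj) * s2
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(len(sol.x), np.nan)


def fit_trace(trace: TimeTrace, model: str, init: dict | None = None,
              seed: int | None = None) -> KineticFit:
    """Least-squares fit of a kinetic model to a time trace.

    Repeated time points are averaged first.  Without an explicit `init`,
    a deterministic multi-start over log-spaced tau grids spanning the time
    range picks the best converged solution.  Parameters are fitted in log
    space for the time constants to keep them positive.
    """
    if model not in ("first_order", "two_step"):
        raise ValueError(f"unknown model {model!r}")
    trace = trace.averaged()
    t, y = trace.times, trace.values
    n_min = 4 if model == "first_order" else 6
    if len(t) < n_min:
        raise ValueError(f"{model} fit needs >= {n_min} distinct time points")
    w = np.ones_like(y) if trace.sigma is None else 1.0 / np.where(
        trace.sigma > 0, trace.sigma, np.inf)

    span = np.abs(y).max()
    degenerate = False
    notes: list[str] = []
    if span == 0 or np.ptp(y) == 0:
        degenerate = True
        notes.append("constant trace: amplitude parameters degenerate")

    tau_grid = np.geomspace(t.min(), t.max(), 5)

    if model == "first_order":
        def unpack(p):
            return p[0], np.exp(p[1])

        def resid(p):
            a_inf, tau = unpack(p)
            return w * (eval_first_order(t, a_inf, tau) - y)

        if init is not None:
            starts = [[init.get("a_inf", y[-1]), np.log(init["tau"])]]
        else:
            a0 = y[-1] if y[-1] != 0 else (span if span else 1.0)
            starts = [[a0, np.log(tau)] for tau in tau_grid]
        names = ["a_inf", "tau"]
    elif model == "two_step":
        def unpack(p):
            return p[0], np.exp(p[1]), np.exp(p[1]) + np.exp(p[2]), p[3]

        def resid(p):
            a, tau1, tau2, base = unpack(p)
            return w * (eval_two_step(t, a, tau1, tau2, base) - y)

        if init is not None:
            t1, t2 = init["tau1"], init["tau2"]
            starts = [[init.get("a", np.ptp(y) or 1.0), np.log(t1),
                       np.log(max(t2 - t1, 1e-12 * t1)), init.get("baseline", 0.0)]]
        else:
            a0 = (y[np.argmax(np.abs(y))] or span or 1.0)
            starts = []
            for t1 in tau_grid:
                for t2 in tau_grid:
                    if t2 > t1:
                        starts.append([a0, np.log(t1), np.log(t2 - t1), 0.0])
        names = ["a", "tau1", "tau2", "baseline"]
    else:
        raise ValueError(f"unknown model {model!r}")

    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0=np.asarray(x0, float), method="lm",
                                xtol=1e-14, ftol=1e-14, max_nfev=5000)
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("no start converged", best_attempt=best)

    errs = _uncertainties_from_jac(best, len(t))
    if model == "first_order":
        a_inf, tau = unpack(best.x)
        if tau < t.min() * 1e-3 or tau <= t.min() * (1 + 1e-9) and degenerate:
            degenerate = True
            notes.append("tau at/below the resolvable lower bound")
        params = {"a_inf": float(a_inf), "tau": float(tau)}
        unc = {"a_inf": float(errs[0]), "tau": float(tau * errs[1])}
        fitted = eval_first_order(t, a_inf, tau)
    else:
        a, tau1, tau2, base = _canonical_two_step(*unpack(best.x))
        params = {"a": float(a), "tau1": float(tau1), "tau2": float(tau2),
                  "baseline": float(base)}
        unc = {"a": float(errs[0]), "tau1": float(tau1 * errs[1]),
               "tau2": float(tau2 * np.hypot(errs[1], errs[2])),
               "baseline": float(errs[3])}
        fitted = eval_two_step(t, a, tau1, tau2, base)

    rss = float(np.sum((w * (fitted - y)) ** 2))
    if degenerate:
        warnings.warn("degenerate trace: fit parameters weakly constrained",
                      UserWarning, stacklevel=2)
    return KineticFit(model=model, params=params, uncertainties=unc, rss=rss,
                      fitted=fitted, times=t, degenerate=degenerate, notes=notes)
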