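"""Specific growth rate estimation from density time series.

Each monoculture time series is fit with the Buchanan three-phase linear
model of log density — a flat lag phase, a linear exponential phase with
slope mu, and a flat stationary phase — by multi-start nonlinear least
squares with the lowest-AICc parameter set retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "GrowthCurve",
    "BuchananFit",
    "buchanan_model",
    "aicc",
    "fit_buchanan",
    "fit_growth_table",
]

#: Named parameters of the three-phase model (t_lag, t_max, N0, Nmax, mu);
#: continuity at t_max ties Nmax to the other four during fitting, but the
#: AICc complexity penalty counts the five named parameters.
N_PARAMS = 5

_RSS_FLOOR = 1e-30  # guards AICc's log for numerically perfect fits


@dataclass
class GrowthCurve:
    """One monoculture density time series at a fixed condition."""

    species: str
    temperature_C: float
    phosphate_umol_L: float
    replicate: int
    days: np.ndarray
    density: np.ndarray
    no_growth: bool = False  # set by the generator when the realised rate is <= 0

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.days.shape != self.density.shape:
            raise ValueError("days and density must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.density <= 0):
            raise ValueError("densities must be strictly positive")


@dataclass
class BuchananFit:
    """Three-phase model parameters and diagnostics for one growth curve.

    Log densities are natural log by default (``scale='ln'``), so ``mu`` is
    the specific growth rate in d^-1; with ``scale='log10'`` the intercepts
    are log10 but ``mu`` is still reported as a natural-log rate.
    """

    t_lag: float = math.nan
    t_max: float = math.nan
    N0_log: float = math.nan
    Nmax_log: float = math.nan
    mu: float = math.nan
    rss: float = math.nan
    n_obs: int = 0
    aicc: float = math.nan
    converged: bool = False
    failed_growth: bool = False
    scale: str = "ln"
    status: str = ""


def buchanan_model(t, t_lag, t_max, N0_log, Nmax_log, mu):
    """Piecewise-linear log density: lag, exponential and stationary phase.

    Returns ``N0_log`` for t <= t_lag, ``N0_log + mu*(t - t_lag)`` for
    t_lag < t < t_max and ``Nmax_log`` for t >= t_max.  With consistent
    parameters (Nmax_log = N0_log + mu*(t_max - t_lag)) the function is
    continuous.
    """
    if t_lag > t_max:
        raise ValueError("t_lag must not exceed t_max")
    t = np.asarray(t, dtype=float)
    out = np.where(
        t <= t_lag,
        N0_log,
        np.where(t >= t_max, Nmax_log, N0_log + mu * (t - t_lag)),
    )
    return float(out) if out.ndim == 0 else out


def aicc(rss: float, n: int, p: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = n ln(rss/n) + 2p + 2p(p+1)/(n - p - 1); lower is better.
    Undefined for n <= p + 1 or non-positive rss.
    """
    if n <= p + 1:
        raise ValueError("AICc undefined: need n > p + 1 observations")
    if rss <= 0:
        raise ValueError("AICc undefined for non-positive rss")
    return n * math.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def _screen_starts(t, y, t_lag, t_max, N0, Nmax, mu):
    """Vectorised RSS of raw candidate parameter sets (no continuity imposed)."""
    tt = t[None, :]
    pred = np.where(
        tt <= t_lag[:, None],
        N0[:, None],
        np.where(tt >= t_max[:, None], Nmax[:, None],
                 N0[:, None] + mu[:, None] * (tt - t_lag[:, None])),
    )
    return np.sum((pred - y[None, :]) ** 2, axis=1)


def _data_driven_start(t, y):
    """Heuristic start: steepest two-point slope, flanking flat phases."""
    dy = np.diff(y) / np.diff(t)
    i = int(np.argmax(dy))
    mu0 = max(float(dy[i]), 1e-3)
    n0 = float(np.min(y))
    nmax = float(np.max(y))
    t_lag0 = max(float(t[i]) - max(float(y[i]) - n0, 0.0) / mu0, 0.0)
    dt0 = max((nmax - n0) / mu0, 1e-6)
    return np.array([t_lag0, dt0, n0, mu0])


def fit_buchanan(
    curve: GrowthCurve,
    n_starts: int = 1000,
    seed: int | None = None,
    scale: str = "ln",
    n_polish: int = 5,
    mu_start_max: float = 3.0,
    failed_growth_decades: float = 1.0,
) -> BuchananFit:
    """Multi-start least-squares fit of the three-phase model to one curve.

    ``n_starts`` random parameter combinations are drawn from uniform
    distributions (t_lag and t_max over the sampling window with t_lag <=
    t_max, mu over [0, ``mu_start_max``], intercepts within one log unit of
    the observed extremes), ranked by their residual sum of squares, and the
    best ``n_polish`` plus one data-driven start are refined with bounded
    Levenberg-Marquardt-type optimisation; the refined fit with the lowest
    AICc is returned.  Continuity at t_max is enforced during refinement by
    parameterising t_max = t_lag + dt and Nmax = N0 + mu*dt.

    Curves whose fitted rise is below ``failed_growth_decades`` decades are
    flagged ``failed_growth`` (the culture never grew properly) and should
    be excluded from downstream Monod fitting.
    """
    if scale not in ("ln", "log10"):
        raise ValueError(f"unknown scale {scale!r}")
    t = curve.days
    y = np.log(curve.density) if scale == "ln" else np.log10(curve.density)
    n = len(t)
    fit = BuchananFit(n_obs=n, scale=scale)
    if n < N_PARAMS:
        fit.status = "fewer observations than model parameters"
        return fit
    decade = math.log(10.0) if scale == "ln" else 1.0

    if np.ptp(y) == 0:
        # all-identical densities: exact flat fit
        fit.t_lag = float(t[0])
        fit.t_max = float(t[-1])
        fit.N0_log = fit.Nmax_log = float(y[0])
        fit.mu = 0.0
        fit.rss = 0.0
        fit.aicc = aicc(_RSS_FLOOR, n, N_PARAMS) if n > N_PARAMS + 1 else math.nan
        fit.converged = True
        fit.failed_growth = True
        fit.status = "flat curve"
        return fit

    rng = np.random.default_rng(seed)
    t_hi = float(t[-1])
    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    # draw t_lag/t_max uniformly, rejecting t_lag > t_max by sorting the pair
    knots = np.sort(rng.uniform(0.0, t_hi, size=(n_starts, 2)), axis=1)
    mu_s = rng.uniform(0.0, mu_start_max / (1.0 if scale == "ln" else math.log(10)),
                       n_starts)
    N0_s = rng.uniform(y_lo - 1.0, y_lo + 1.0, n_starts)
    Nmax_s = rng.uniform(y_hi - 1.0, y_hi + 1.0, n_starts)
    rss0 = _screen_starts(t, y, knots[:, 0], knots[:, 1], N0_s, Nmax_s, mu_s)
    order = np.argsort(rss0)[: max(n_polish, 1)]

    def resid(theta):
        t_lag, dt, n0, mu = theta
        g = np.clip(t - t_lag, 0.0, dt)
        return n0 + mu * g - y

    cand = [
        np.array([knots[i, 0], max(knots[i, 1] - knots[i, 0], 1e-6), N0_s[i], mu_s[i]])
        for i in order
    ]
    cand.append(_data_driven_start(t, y))

    lower = np.array([0.0, 1e-9, -np.inf, 0.0])
    upper = np.array([t_hi, np.inf, np.inf, np.inf])
    # with n and p fixed across starts, lowest AICc == lowest rss
    best = None
    for theta0 in cand:
        theta0 = np.clip(theta0, lower + 1e-12, None)
        theta0[0] = min(theta0[0], t_hi)
        res = least_squares(resid, theta0, bounds=(lower, upper),
                            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    rss, res = best
    score = (aicc(max(rss, _RSS_FLOOR), n, N_PARAMS)
             if n > N_PARAMS + 1 else math.nan)
    t_lag, dt, n0, mu = (float(v) for v in res.x)
    fit.t_lag, fit.t_max = t_lag, t_lag + dt
    fit.N0_log, fit.Nmax_log = n0, n0 + mu * dt
    fit.mu = mu if scale == "ln" else mu * math.log(10.0)
    fit.rss = rss
    fit.aicc = score
    fit.converged = bool(res.success)
    fit.failed_growth = (fit.Nmax_log - fit.N0_log) < failed_growth_decades * decade
    return fit


def fit_growth_table(
    curves: Sequence[GrowthCurve],
    n_starts: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Fit every curve and return one tidy row per curve.

    Seeds are spawned per curve from ``seed`` so the result does not depend
    on the order in which curves are fitted being stable across runs.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(curves))
    rows = []
    for curve, child in zip(curves, children):
        f = fit_buchanan(curve, n_starts=n_starts,
                         seed=child.generate_state(1)[0], **kwargs)
        rows.append(
            {
                "species": curve.species,
                "temperature_C": curve.temperature_C,
                "phosphate_umol_L": curve.phosphate_umol_L,
                "replicate": curve.replicate,
                "t_lag": f.t_lag,
                "t_max": f.t_max,
                "N0_log": f.N0_log,
                "Nmax_log": f.Nmax_log,
                "mu": f.mu,
                "rss": f.rss,
                "n_obs": f.n_obs,
                "aicc": f.aicc,
                "converged": f.converged,
                "failed_growth": f.failed_growth,
                "status": f.status,
            }
        )
    return pd.DataFrame(rows)
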