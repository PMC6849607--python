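"""Nutrient- and temperature-dependence of growth: Monod and Boltzmann-Arrhenius fits.

Per-condition specific growth rates are converted into Monod parameters
(``mu_max``, ``K_S``) at each temperature, and those in turn into the four
metabolic traits of a species — the normalisation constants and activation
energies of ``mu_max`` and ``K_S`` — by fitting the Boltzmann-Arrhenius model
within the operational temperature range (OTR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ._constants import BOLTZMANN_EV_K, celsius_to_kelvin

__all__ = [
    "MonodFit",
    "ArrheniusFit",
    "monod_mu",
    "fit_monod",
    "arrhenius_value",
    "fit_arrhenius",
]


@dataclass
class MonodFit:
    """Monod parameters for one species at one temperature and replicate.

    ``mu_max`` is the nutrient-saturated specific growth rate (d^-1) and
    ``K_S`` the half-saturation constant (umol L^-1): the nutrient
    concentration at which growth is half of ``mu_max``.
    """

    species: str
    temperature_C: float
    replicate: int
    mu_max: float
    K_S: float
    se_mu_max: float = math.nan
    se_K_S: float = math.nan
    rss: float = math.nan
    n_obs: int = 0
    converged: bool = False
    status: str = ""


@dataclass
class ArrheniusFit:
    """Boltzmann-Arrhenius fit of one trait (mu_max or K_S) for one species.

    ``normalisation`` is the trait value at the reference temperature
    (B0 for mu_max, K0 for K_S); ``activation_energy`` (eV) is the thermal
    sensitivity of the trait within the OTR.
    """

    species: str
    trait_name: str
    normalisation: float
    activation_energy: float
    T_ref_K: float
    OTR_C: tuple[float, float] = (15.0, 25.0)
    se_normalisation: float = math.nan
    se_activation: float = math.nan
    n_points: int = 0
    converged: bool = False
    status: str = ""


def monod_mu(S, mu_max, K_S):
    """Monod growth rate mu = mu_max * S / (K_S + S).

    Parameters
    ----------
    S : float or array
        Nutrient concentration (umol L^-1), must be >= 0.
    mu_max : float
        Nutrient-saturated growth rate (d^-1), > 0.
    K_S : float
        Half-saturation constant (umol L^-1), > 0.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("nutrient concentration S must be non-negative")
    if mu_max <= 0 or K_S <= 0:
        raise ValueError("mu_max and K_S must be positive")
    out = mu_max * S / (K_S + S)
    return float(out) if out.ndim == 0 else out


def arrhenius_value(normalisation, activation_energy, T_K, T_ref_K):
    """Boltzmann-Arrhenius trait value at temperature ``T_K``.

    value = normalisation * exp(-E/k * (1/T - 1/T_ref)) with k the Boltzmann
    constant in eV K^-1.  At ``T_K == T_ref_K`` the value equals the
    normalisation constant; positive E means the trait increases with
    temperature.
    """
    T_K = np.asarray(T_K, dtype=float)
    if np.any(T_K <= 0) or T_ref_K <= 0:
        raise ValueError("temperatures must be positive Kelvin")
    out = normalisation * np.exp(
        -activation_energy / BOLTZMANN_EV_K * (1.0 / T_K - 1.0 / T_ref_K)
    )
    return float(out) if out.ndim == 0 else out


def fit_monod(
    points: Sequence[tuple[float, float]],
    species: str = "",
    temperature_C: float = math.nan,
    replicate: int = 0,
    n_starts: int = 100,
    seed: int | None = None,
) -> MonodFit:
    """Fit the Monod model to (S, mu) pairs by multi-start least squares.

    Starts are drawn uniformly for ``mu_max`` around the largest observed
    rate and log-uniformly for ``K_S`` across the observed S range; the
    lowest-RSS converged start wins.  Standard errors come from the Jacobian
    at the optimum; a K_S standard error exceeding the estimate flags an
    unidentifiable half-saturation constant (e.g. all S saturating).
    """
    pts = np.asarray(points, dtype=float)
    fit = MonodFit(species, temperature_C, replicate, math.nan, math.nan)
    if pts.ndim != 2 or pts.shape[0] < 3:
        fit.status = "fewer than 3 (S, mu) points"
        return fit
    S, mu = pts[:, 0], pts[:, 1]
    if np.any(S < 0):
        raise ValueError("nutrient concentrations must be non-negative")
    fit.n_obs = int(len(S))
    mu_top = float(np.max(mu))
    if mu_top <= 1e-12:
        fit.status = "non-growing: all growth rates ~ 0"
        return fit

    rng = np.random.default_rng(seed)
    s_pos = S[S > 0]
    lo, hi = float(np.min(s_pos)), float(np.max(s_pos))

    def resid(theta):
        m, k = np.exp(theta)
        return m * S / (k + S) - mu

    best = None
    starts = np.column_stack(
        [
            np.log(rng.uniform(0.5 * mu_top, 3.0 * mu_top, n_starts)),
            np.log(np.exp(rng.uniform(np.log(lo / 10), np.log(hi * 10), n_starts))),
        ]
    )
    for theta0 in starts:
        res = least_squares(resid, theta0, method="lm", xtol=1e-12, ftol=1e-12)
        if not np.all(np.isfinite(res.x)):
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        fit.status = "no start converged"
        return fit
    rss, res = best
    fit.mu_max, fit.K_S = (float(v) for v in np.exp(res.x))
    fit.rss = rss
    fit.converged = True
    # delta-method SEs from the log-scale Jacobian
    n, p = len(S), 2
    if n > p and rss > 0:
        jtj = res.jac.T @ res.jac
        if np.linalg.cond(jtj) < 1e12:
            cov = np.linalg.inv(jtj) * rss / (n - p)
            se_log = np.sqrt(np.diag(cov))
            fit.se_mu_max = float(fit.mu_max * se_log[0])
            fit.se_K_S = float(fit.K_S * se_log[1])
        else:
            fit.status = "K_S poorly identified (singular information matrix)"
    if math.isfinite(fit.se_K_S) and fit.se_K_S > fit.K_S:
        fit.status = "K_S poorly identified (se exceeds estimate)"
    return fit


def _boltzmann_x(T_C, T_ref_C):
    """Regressor 1/(kT) - 1/(kT_ref) so that slope of ln(value) equals -E."""
    T_K = celsius_to_kelvin(np.asarray(T_C, dtype=float))
    T_ref_K = celsius_to_kelvin(T_ref_C)
    return (1.0 / T_K - 1.0 / T_ref_K) / BOLTZMANN_EV_K


def fit_arrhenius(
    estimates: Sequence[tuple[float, float]],
    T_ref_C: float = 15.0,
    species: str = "",
    trait_name: str = "",
    OTR_C: tuple[float, float] = (15.0, 25.0),
    method: str = "linear",
) -> ArrheniusFit:
    """Fit ln(trait) against the Boltzmann factor within the OTR.

    ``estimates`` are (temperature_C, trait value) pairs, values > 0. The
    default is ordinary least squares of ln(value) on
    x = 1/(kT) - 1/(kT_ref): the slope is -E (activation energy, eV) and the
    back-transformed intercept is the normalisation constant at ``T_ref_C``.
    ``method='nonlinear'`` instead minimises squared residuals of ln(value)
    against the exponential form directly; the two coincide at the optimum.
    """
    pts = np.asarray(estimates, dtype=float)
    T_ref_K = celsius_to_kelvin(T_ref_C)
    fit = ArrheniusFit(species, trait_name, math.nan, math.nan, T_ref_K, OTR_C)
    if pts.ndim != 2 or pts.shape[0] < 4:
        fit.status = "fewer than 4 (temperature, value) points"
        return fit
    T_C, vals = pts[:, 0], pts[:, 1]
    if np.any(vals <= 0):
        raise ValueError("trait values must be positive for a log-scale fit")
    inside = (T_C >= OTR_C[0] - 1e-9) & (T_C <= OTR_C[1] + 1e-9)
    T_C, vals = T_C[inside], vals[inside]
    fit.n_points = int(len(vals))
    if fit.n_points < 4:
        fit.status = "fewer than 4 points inside the OTR"
        return fit
    if np.ptp(T_C) == 0:
        fit.status = "all temperatures identical: slope undefined"
        return fit

    x = _boltzmann_x(T_C, T_ref_C)
    y = np.log(vals)
    if method == "linear":
        X = np.column_stack([np.ones_like(x), x])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    elif method == "nonlinear":
        def f(theta):
            return theta[0] + theta[1] * x - y

        res = least_squares(f, np.array([np.mean(y), 0.0]), method="lm",
                            xtol=1e-14, ftol=1e-14)
        beta, resid = res.x, res.fun
    else:
        raise ValueError(f"unknown method {method!r}")

    intercept, slope = float(beta[0]), float(beta[1])
    fit.normalisation = math.exp(intercept)
    fit.activation_energy = -slope
    fit.converged = True
    n = len(y)
    dof = n - 2
    if dof > 0:
        s2 = float(resid @ resid) / dof
        sxx = float(np.sum((x - x.mean()) ** 2))
        if sxx > 0:
            fit.se_activation = math.sqrt(s2 / sxx)
            se_int = math.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
            fit.se_normalisation = fit.normalisation * se_int
    return fit
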