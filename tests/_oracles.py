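"""Independent reference implementations used only as test oracles.

These deliberately re-derive each quantity step by step from the model
definitions (Monod saturation, Boltzmann-Arrhenius temperature scaling,
log-ratio competitive advantage) without importing the package's composed
functions, so that agreement is a genuine cross-check rather than a
tautology.
"""

import math

import numpy as np

K_EV = 8.617333e-5  # Boltzmann constant, eV/K


def ba(value_at_ref, activation_eV, T_K, T_ref_K):
    """Boltzmann-Arrhenius scaling, written out longhand."""
    exponent = -(activation_eV / K_EV) * (1.0 / T_K - 1.0 / T_ref_K)
    return value_at_ref * math.exp(exponent)


def stepwise_mu(B0, E_mu, K0, E_K, T_ref_K, T_K, S):
    """Realised growth rate: Arrhenius-shift both Monod parameters, then saturate."""
    mu_max_T = ba(B0, E_mu, T_K, T_ref_K)
    K_S_T = ba(K0, E_K, T_K, T_ref_K)
    return mu_max_T * (S / (K_S_T + S))

def stepwise_R(traits_a, traits_b, T_K, S, t):
    mu_a = stepwise_mu(traits_a.B0, traits_a.E_mu, traits_a.K0, traits_a.E_K,
                       traits_a.T_ref_K, T_K, S)
    mu_b = stepwise_mu(traits_b.B0, traits_b.E_mu, traits_b.K0, traits_b.E_K,
                       traits_b.T_ref_K, T_K, S)
    return (mu_a - mu_b) * t


def stepwise_Rinf(traits_a, traits_b, T_K, t):
    return (ba(traits_a.B0, traits_a.E_mu, T_K, traits_a.T_ref_K)
            - ba(traits_b.B0, traits_b.E_mu, T_K, traits_b.T_ref_K)) * t


def grid_search_buchanan(t, y, n_knots=40, n_mu=60, mu_hi=3.0):
    """Coarse exhaustive search over (t_lag, t_max, mu) with the intercept
    profiled analytically.

    For fixed knots and slope the three-phase prediction is N0 + mu * g(t)
    with g = clip(t - t_lag, 0, t_max - t_lag), linear in N0, so the
    optimal intercept is the mean residual.  Returns the best RSS found.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    lags = np.linspace(0.0, t[-1], n_knots)
    best = np.inf
    for t_lag in lags:
        for t_max in lags:
            if t_max < t_lag:
                continue
            g = np.clip(t - t_lag, 0.0, t_max - t_lag)
            for mu in np.linspace(0.0, mu_hi, n_mu):
                resid = y - mu * g
                n0 = resid.mean()
                rss = float(np.sum((resid - n0) ** 2))
                if rss < best:
                    best = rss
    return best
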