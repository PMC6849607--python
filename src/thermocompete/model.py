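"""Theory core: pairwise competitive advantage from metabolic traits.

Two species co-invading a fresh batch of medium at equal, low inoculum both
grow exponentially at the Monod rate set by their temperature-dependent
kinetics, so the log ratio of their abundances at time t,

    R = ln(N_a(t) / N_b(t)) = (mu_a(T, S) - mu_b(T, S)) * t,

is the competitive advantage of species a over species b.  Its nutrient-
saturated limit R_inf depends only on the normalisation constants (B0) and
activation energies (E_mu) of maximum growth rate, which makes the
trade-off between performance at the reference temperature and thermal
sensitivity explicit: at T = T_ref the larger B0 wins, far above T_ref the
larger E_mu wins, and in between the winner can reverse at a crossing
temperature T* where the two thermal performance curves intersect.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._constants import BOLTZMANN_EV_K, celsius_to_kelvin, kelvin_to_celsius
from .traits import arrhenius_value, monod_mu

__all__ = [
    "MetabolicTraits",
    "CompetitionPrediction",
    "TIE_TOLERANCE",
    "realised_growth_rate",
    "competitive_advantage_R",
    "competitive_advantage_Rinf",
    "crossing_temperature",
    "predict_reversal",
    "prediction_grid",
]

#: |R| below this is declared a tie; real ties only arise from identical traits.
TIE_TOLERANCE = 1e-12


@dataclass(frozen=True)
class MetabolicTraits:
    """The four metabolic traits of a species plus its reference temperature.

    B0 (d^-1) and K0 (umol L^-1) are the values of mu_max and K_S at
    ``T_ref_K``; E_mu and E_K (eV) are their activation energies within the
    operational temperature range.
    """

    B0: float
    E_mu: float
    K0: float
    E_K: float
    T_ref_K: float = celsius_to_kelvin(15.0)

    def __post_init__(self):
        if self.B0 <= 0 or self.K0 <= 0 or self.T_ref_K <= 0:
            raise ValueError("B0, K0 and T_ref_K must be positive")
        if not (math.isfinite(self.E_mu) and math.isfinite(self.E_K)):
            raise ValueError("activation energies must be finite")

    def mu_max(self, T_K: float) -> float:
        """Nutrient-saturated growth rate (d^-1) at temperature ``T_K``."""
        return arrhenius_value(self.B0, self.E_mu, T_K, self.T_ref_K)

    def K_S(self, T_K: float) -> float:
        """Half-saturation constant (umol L^-1) at temperature ``T_K``."""
        return arrhenius_value(self.K0, self.E_K, T_K, self.T_ref_K)


@dataclass(frozen=True)
class CompetitionPrediction:
    """Predicted outcome of one pairwise contest at one condition."""

    pair: tuple[str, str]
    temperature_C: float
    phosphate_umol_L: float | None  # None for the nutrient-saturated variant
    t_days: float
    R: float
    winner: str  # 'a', 'b' or 'tie'


def realised_growth_rate(traits: MetabolicTraits, T_K: float, S: float) -> float:
    """Monod growth rate at temperature ``T_K`` and nutrient level ``S``.

    Composes the Boltzmann-Arrhenius temperature dependence of mu_max and
    K_S with the Monod saturation curve.
    """
    if S < 0:
        raise ValueError("nutrient concentration S must be non-negative")
    if S == 0:
        return 0.0
    return monod_mu(S, traits.mu_max(T_K), traits.K_S(T_K))


def _winner(R: float) -> str:
    if abs(R) < TIE_TOLERANCE:
        return "tie"
    return "a" if R > 0 else "b"


def competitive_advantage_R(
    a: MetabolicTraits,
    b: MetabolicTraits,
    T_K: float,
    S: float,
    t_days: float = 14.0,
    pair: tuple[str, str] = ("a", "b"),
) -> CompetitionPrediction:
    """Competitive advantage R = (mu_a - mu_b) * t under constant nutrients.

    Assumes equal initial densities and exponential growth over the horizon
    ``t_days``; positive R means species a is predicted to outnumber b.
    """
    if t_days <= 0:
        raise ValueError("prediction horizon t_days must be positive")
    R = (realised_growth_rate(a, T_K, S) - realised_growth_rate(b, T_K, S)) * t_days
    return CompetitionPrediction(pair, kelvin_to_celsius(T_K), S, t_days, R, _winner(R))


def competitive_advantage_Rinf(
    a: MetabolicTraits,
    b: MetabolicTraits,
    T_K: float,
    t_days: float = 14.0,
    pair: tuple[str, str] = ("a", "b"),
) -> CompetitionPrediction:
    """Nutrient-saturated competitive advantage R_inf = (mu_max,a - mu_max,b) * t.

    The half-saturation traits drop out entirely: only (B0, E_mu) of each
    species matter.
    """
    if t_days <= 0:
        raise ValueError("prediction horizon t_days must be positive")
    R = (a.mu_max(T_K) - b.mu_max(T_K)) * t_days
    return CompetitionPrediction(pair, kelvin_to_celsius(T_K), None, t_days, R, _winner(R))


def crossing_temperature(a: MetabolicTraits, b: MetabolicTraits):
    """Temperature (Kelvin) at which the mu_max curves of a and b cross.

    Solves ln(B0_a/B0_b) = (E_mu,a - E_mu,b)/k * (1/T* - 1/T_ref), i.e.
    1/T* = 1/T_ref + k ln(B0_a/B0_b) / (E_mu,a - E_mu,b).

    Returns
    -------
    float or None or 'degenerate'
        The crossing temperature in Kelvin; ``None`` when no physical
        crossing exists (equal activation energies with unequal B0, or the
        solution falls at non-positive temperature); the string
        ``'degenerate'`` when both trait pairs are identical and every
        temperature is a crossing.
    """
    if a.T_ref_K != b.T_ref_K:
        raise ValueError("species must share a reference temperature")
    dE = a.E_mu - b.E_mu
    lnB = math.log(a.B0 / b.B0)
    if dE == 0:
        return "degenerate" if lnB == 0 else None
    inv = 1.0 / a.T_ref_K + BOLTZMANN_EV_K * lnB / dE
    if inv <= 0:
        return None
    return 1.0 / inv


def predict_reversal(
    a: MetabolicTraits,
    b: MetabolicTraits,
    T1_K: float,
    T2_K: float,
    S: float | None = None,
    t_days: float = 14.0,
):
    """Does the predicted winner flip between temperatures T1 and T2?

    ``S=None`` uses the nutrient-saturated advantage R_inf.  Returns True /
    False, or ``None`` (indeterminate) when either advantage is a tie.
    """
    if T1_K == T2_K:
        raise ValueError("reversal requires two distinct temperatures")
    if S is None:
        R1 = competitive_advantage_Rinf(a, b, T1_K, t_days).R
        R2 = competitive_advantage_Rinf(a, b, T2_K, t_days).R
    else:
        R1 = competitive_advantage_R(a, b, T1_K, S, t_days).R
        R2 = competitive_advantage_R(a, b, T2_K, S, t_days).R
    if abs(R1) < TIE_TOLERANCE or abs(R2) < TIE_TOLERANCE:
        return None
    return (R1 > 0) != (R2 > 0)


def prediction_grid(
    panel: Mapping[str, MetabolicTraits],
    temperatures_C: Sequence[float],
    phosphates_umol_L: Iterable[float] | None,
    t_days: float = 14.0,
    mode: str = "R",
) -> pd.DataFrame:
    """Predictions for every unordered species pair across a condition grid.

    ``mode='R'`` evaluates the nutrient-explicit advantage at each phosphate
    level; ``mode='Rinf'`` the saturated limit (phosphate column left NaN).
    Pairs are ordered by panel insertion order, so antisymmetry holds by
    construction: each unordered pair appears once.
    """
    if not panel:
        raise ValueError("empty species panel")
    if mode not in ("R", "Rinf"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    names = list(panel)
    for name_a, name_b in itertools.combinations(names, 2):
        a, b = panel[name_a], panel[name_b]
        for T_C in temperatures_C:
            T_K = celsius_to_kelvin(T_C)
            if mode == "Rinf":
                p = competitive_advantage_Rinf(a, b, T_K, t_days, (name_a, name_b))
                rows.append(
                    (name_a, name_b, T_C, np.nan, t_days, mode, p.R, p.winner)
                )
            else:
                for S in phosphates_umol_L:
                    p = competitive_advantage_R(a, b, T_K, S, t_days, (name_a, name_b))
                    rows.append(
                        (name_a, name_b, T_C, S, t_days, mode, p.R, p.winner)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "species_a", "species_b", "temperature_C", "phosphate_umol_L",
            "t_days", "mode", "R", "winner",
        ],
    )
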