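"""Synthetic monoculture and competition experiments with known ground truth.

Emulates a factorial design in which six freshwater green algae are grown
in monoculture across temperature x phosphate grids to estimate their
metabolic traits, and then competed pairwise at two temperatures and three
phosphate levels.  Because every species' generating traits are known, the
whole downstream pipeline (growth-curve fitting, Monod and Arrhenius fits,
competition prediction, evaluation) can be validated without any external
dataset.

Monoculture curves follow the three-phase model in log space (lag,
exponential at the realised Monod rate, stationary at a carrying capacity);
competition trials grow each species exponentially from equal inocula,
optionally with explicit phosphate drawdown.  Noise sources: multiplicative
log-normal density error, and binomial misclassification of counted cells
between the two competitors (mimicking an imperfect flow-cytometric
discriminator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._constants import celsius_to_kelvin
from .growth import GrowthCurve
from .model import MetabolicTraits, realised_growth_rate

__all__ = [
    "ExperimentDesign",
    "TrueSpecies",
    "NoiseModel",
    "MONOCULTURE_DESIGN",
    "COMPETITION_DESIGN",
    "DEFAULT_TRAIT_RANGES",
    "default_panel",
    "sample_species_panel",
    "simulate_growth_curve",
    "simulate_monoculture_dataset",
    "simulate_competition_trial",
    "simulate_competition_dataset",
    "write_dataset",
    "growth_curves_to_frame",
    "frame_to_growth_curves",
    "panel_to_frame",
    "frame_to_panel",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of one experiment (who is grown where, sampled when)."""

    temperatures_C: tuple[float, ...]
    phosphate_umol_L: tuple[float, ...]
    n_replicates: int
    sampling_days: tuple[float, ...]
    inoculum_cells_per_mL: float = 100.0
    volume_mL: float = 40.0  # documentation only

    def __post_init__(self):
        if len(self.temperatures_C) == 0 or not np.all(np.isfinite(self.temperatures_C)):
            raise ValueError("temperatures must be nonempty and finite")
        if np.any(np.asarray(self.phosphate_umol_L) <= 0):
            raise ValueError("all phosphate concentrations must be positive")
        d = np.asarray(self.sampling_days)
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("sampling days must be >= 0 and strictly increasing")
        if self.inoculum_cells_per_mL <= 0:
            raise ValueError("inoculum must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class TrueSpecies:
    """Generating parameters of one synthetic species.

    ``traits`` drive the realised growth rate; ``t_lag_days`` and
    ``Nmax_log10`` shape the monoculture growth curve; ``quota_umolP_per_cell``
    is the phosphorus bound per cell, used only by the drawdown simulator.
    """

    name: str
    traits: MetabolicTraits
    t_lag_days: float = 1.0
    Nmax_log10: float = 7.0
    quota_umolP_per_cell: float = 1e-9

    def __post_init__(self):
        if self.t_lag_days < 0:
            raise ValueError("lag duration must be non-negative")
        if self.quota_umolP_per_cell <= 0:
            raise ValueError("phosphorus quota must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise for simulated densities.

    ``sigma_log10`` is additive Gaussian noise on log10 density
    (multiplicative on density); ``misclassification_rate`` is the
    probability that a counted cell in a two-species trial is assigned to
    the wrong species, applied as a binomial swap over the cells counted in
    a ``counted_volume_mL`` aliquot.
    """

    sigma_log10: float = 0.05
    misclassification_rate: float = 0.0
    seed: int = 0
    counted_volume_mL: float = 0.01

    def __post_init__(self):
        if self.sigma_log10 < 0:
            raise ValueError("sigma_log10 must be non-negative")
        if not 0.0 <= self.misclassification_rate < 0.5:
            raise ValueError("misclassification rate must be in [0, 0.5)")
        if self.counted_volume_mL <= 0:
            raise ValueError("counted volume must be positive")


#: Monoculture trait experiment: 5 temperatures x 13 phosphate levels x 3
#: replicates, densities sampled every other day for four weeks.
MONOCULTURE_DESIGN = ExperimentDesign(
    temperatures_C=(15.0, 20.0, 25.0, 30.0, 35.0),
    phosphate_umol_L=tuple(np.geomspace(0.01, 50.0, 13)),
    n_replicates=3,
    sampling_days=tuple(float(d) for d in range(0, 29, 2)),
    inoculum_cells_per_mL=100.0,
    volume_mL=40.0,
)

#: Pairwise competition experiment: 2 temperatures x 3 phosphate levels x 6
#: replicates, sampled at days 5, 14 and 23 from 100 cells/mL inocula each.
COMPETITION_DESIGN = ExperimentDesign(
    temperatures_C=(15.0, 25.0),
    phosphate_umol_L=(0.1, 1.0, 30.0),
    n_replicates=6,
    sampling_days=(5.0, 14.0, 23.0),
    inoculum_cells_per_mL=100.0,
    volume_mL=2.0,
)

#: Uniform sampling ranges for random species panels, spanning trait
#: magnitudes typical of small freshwater chlorophytes.
DEFAULT_TRAIT_RANGES: dict[str, tuple[float, float]] = {
    "B0": (0.4, 0.9),            # d^-1 at 15 C
    "E_mu": (0.3, 0.9),          # eV
    "K0": (0.05, 0.6),           # umol L^-1 at 15 C
    "E_K": (0.2, 0.8),           # eV
    "t_lag_days": (0.0, 2.0),
    "Nmax_log10": (7.0, 7.0),    # common carrying capacity by default
    "quota_umolP_per_cell": (5e-10, 2e-9),
}

_T_REF_K = celsius_to_kelvin(15.0)

# Curated panel: B0 and E_mu trade off so that several pairs have crossing
# temperatures inside the 15-25 C range; half-saturation traits follow a
# mild gleaner-opportunist pattern (K_S,i proportional to mu_max,i^0.6 at
# every temperature) so that the species ranking by growth rate is the same
# at saturating and at scarce phosphate.
_DEFAULT_PANEL_TABLE = [
    # name        B0     E_mu   K0       E_K    t_lag  Nmax  quota
    ("sp01",      0.85,  0.35,  0.31748, 0.36,  0.5,   7.0,  1.0e-9),
    ("sp02",      0.60,  0.75,  0.25761, 0.60,  1.2,   7.0,  1.0e-9),
    ("sp03",      0.70,  0.55,  0.28257, 0.48,  0.8,   7.0,  1.0e-9),
    ("sp04",      0.50,  0.65,  0.23091, 0.54,  1.5,   7.0,  1.0e-9),
    ("sp05",      0.78,  0.60,  0.30152, 0.51,  1.0,   7.0,  1.0e-9),
    ("sp06",      0.45,  0.50,  0.21677, 0.45,  0.7,   7.0,  1.0e-9),
]


def default_panel() -> list[TrueSpecies]:
    """The curated six-species reference panel used by the default pipeline."""
    return [
        TrueSpecies(
            name=name,
            traits=MetabolicTraits(B0=b0, E_mu=emu, K0=k0, E_K=ek, T_ref_K=_T_REF_K),
            t_lag_days=lag,
            Nmax_log10=nmax,
            quota_umolP_per_cell=quota,
        )
        for name, b0, emu, k0, ek, lag, nmax, quota in _DEFAULT_PANEL_TABLE
    ]


def sample_species_panel(
    n_species: int,
    trait_ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int | None = None,
) -> list[TrueSpecies]:
    """Draw a random species panel with traits uniform within ranges.

    Deterministic for a fixed seed.  Degenerate ranges (low == high) are
    allowed and yield identical values.
    """
    if n_species < 2:
        raise ValueError("a competition panel needs at least 2 species")
    ranges = dict(DEFAULT_TRAIT_RANGES)
    if trait_ranges:
        ranges.update(trait_ranges)
    for key, (lo, hi) in ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
            raise ValueError(f"invalid range for trait {key!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n_species):
        draw = {key: rng.uniform(lo, hi) if hi > lo else float(lo)
                for key, (lo, hi) in ranges.items()}
        panel.append(
            TrueSpecies(
                name=f"sp{i + 1:02d}",
                traits=MetabolicTraits(
                    B0=draw["B0"], E_mu=draw["E_mu"],
                    K0=draw["K0"], E_K=draw["E_K"], T_ref_K=_T_REF_K,
                ),
                t_lag_days=draw["t_lag_days"],
                Nmax_log10=draw["Nmax_log10"],
                quota_umolP_per_cell=draw["quota_umolP_per_cell"],
            )
        )
    return panel


def _log10_trajectory(sp: TrueSpecies, mu: float, days: np.ndarray,
                      inoculum: float) -> np.ndarray:
    """Noiseless log10 density along the three-phase curve."""
    n0_ln = math.log(inoculum)
    nmax_ln = sp.Nmax_log10 * math.log(10.0)
    if mu <= 0:
        return np.full_like(days, n0_ln) / math.log(10.0)
    dt_cap = max((nmax_ln - n0_ln) / mu, 0.0)
    ln_n = n0_ln + mu * np.clip(days - sp.t_lag_days, 0.0, dt_cap)
    return ln_n / math.log(10.0)


def simulate_growth_curve(
    sp: TrueSpecies,
    T_C: float,
    S: float,
    design: ExperimentDesign = MONOCULTURE_DESIGN,
    noise: NoiseModel = NoiseModel(sigma_log10=0.0),
    replicate: int = 1,
    rng: np.random.Generator | None = None,
) -> GrowthCurve:
    """Simulate one monoculture growth curve at (temperature, phosphate).

    Log density stays at the inoculum through the lag phase, rises linearly
    (in ln space) at the realised Monod rate mu(T, S), and plateaus at the
    species' carrying capacity.  Gaussian noise of sd ``sigma_log10`` is
    added on the log10 scale.  If mu(T, S) <= 0 the curve is flat at the
    inoculum and flagged ``no_growth``.
    """
    if S <= 0:
        raise ValueError("phosphate concentration must be positive")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    mu = realised_growth_rate(sp.traits, celsius_to_kelvin(T_C), S)
    days = np.asarray(design.sampling_days, dtype=float)
    log10_n = _log10_trajectory(sp, mu, days, design.inoculum_cells_per_mL)
    if noise.sigma_log10 > 0:
        log10_n = log10_n + rng.normal(0.0, noise.sigma_log10, size=days.shape)
    return GrowthCurve(
        species=sp.name,
        temperature_C=T_C,
        phosphate_umol_L=S,
        replicate=replicate,
        days=days,
        density=10.0 ** log10_n,
        no_growth=mu <= 0,
    )


def simulate_monoculture_dataset(
    panel: Sequence[TrueSpecies],
    design: ExperimentDesign = MONOCULTURE_DESIGN,
    noise: NoiseModel = NoiseModel(sigma_log10=0.0),
    seed: int | None = None,
) -> list[GrowthCurve]:
    """All species x temperature x phosphate x replicate growth curves.

    ``seed`` overrides ``noise.seed``; every curve gets an independent
    substream so the dataset is reproducible regardless of iteration order.
    """
    root = np.random.default_rng(noise.seed if seed is None else seed)
    curves = []
    for sp in panel:
        for T_C in design.temperatures_C:
            for S in design.phosphate_umol_L:
                for rep in range(1, design.n_replicates + 1):
                    curves.append(
                        simulate_growth_curve(sp, T_C, S, design, noise,
                                              replicate=rep, rng=root)
                    )
    return curves


def _competition_trajectories(
    a: TrueSpecies,
    b: TrueSpecies,
    T_C: float,
    S0: float,
    days: np.ndarray,
    inoculum: float,
    depletion: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Noiseless trajectories (N_a, N_b, S) at the sampling days.

    Inocula are acclimated, exponentially growing cells, so no lag phase is
    applied in competition.  Without depletion each species grows at its
    constant realised rate mu_i(T, S0), capped at its own carrying capacity
    (nutrient trajectory returned as None); with depletion the pair's
    growth and the shared phosphate pool are integrated jointly.
    """
    T_K = celsius_to_kelvin(T_C)
    mu_a = realised_growth_rate(a.traits, T_K, S0)
    mu_b = realised_growth_rate(b.traits, T_K, S0)
    cap_a, cap_b = 10.0 ** a.Nmax_log10, 10.0 ** b.Nmax_log10
    if not depletion:
        na = np.minimum(inoculum * np.exp(mu_a * days), cap_a)
        nb = np.minimum(inoculum * np.exp(mu_b * days), cap_b)
        return na, nb, None

    # dN_i/dt = mu_i(S) N_i while below the cap; dS/dt = -sum quota_i mu_i N_i.
    # N in cells/mL, S in umol/L, quota in umol/cell -> factor 1000 mL/L.
    ta, tb = a.traits, b.traits

    def rhs(_t, y):
        na_, nb_, s = y
        s = max(s, 0.0)
        ra = realised_growth_rate(ta, T_K, s) if na_ < cap_a else 0.0
        rb = realised_growth_rate(tb, T_K, s) if nb_ < cap_b else 0.0
        return [
            ra * na_,
            rb * nb_,
            -(a.quota_umolP_per_cell * ra * na_ + b.quota_umolP_per_cell * rb * nb_)
            * 1000.0,
        ]

    sol = solve_ivp(
        rhs, (0.0, float(days[-1])), [inoculum, inoculum, S0],
        t_eval=days, method="LSODA", rtol=1e-8, atol=1e-8,
    )
    if not sol.success:
        raise RuntimeError(f"drawdown integration failed: {sol.message}")
    return sol.y[0], sol.y[1], sol.y[2]


def simulate_competition_trial(
    a: TrueSpecies,
    b: TrueSpecies,
    T_C: float,
    S0: float,
    design: ExperimentDesign = COMPETITION_DESIGN,
    noise: NoiseModel = NoiseModel(sigma_log10=0.0),
    depletion: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one pairwise trial: all replicates x sampling days.

    Both species start at the design inoculum.  Log-normal density noise is
    applied per species and observation; misclassification then swaps each
    cell counted in the aliquot to the other species with the stated
    probability.  Returns observed densities only (one row per replicate
    and day).
    """
    if S0 <= 0:
        raise ValueError("initial phosphate concentration must be positive")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    days = np.asarray(design.sampling_days, dtype=float)
    na, nb, _ = _competition_trajectories(
        a, b, T_C, S0, days, design.inoculum_cells_per_mL, depletion
    )
    rows = []
    m = noise.misclassification_rate
    v = noise.counted_volume_mL
    for rep in range(1, design.n_replicates + 1):
        oa, ob = na.copy(), nb.copy()
        if noise.sigma_log10 > 0:
            oa = oa * 10.0 ** rng.normal(0.0, noise.sigma_log10, size=days.shape)
            ob = ob * 10.0 ** rng.normal(0.0, noise.sigma_log10, size=days.shape)
        if m > 0:
            ca = np.round(oa * v).astype(np.int64)
            cb = np.round(ob * v).astype(np.int64)
            a_as_b = rng.binomial(ca, m)
            b_as_a = rng.binomial(cb, m)
            oa = (ca - a_as_b + b_as_a) / v
            ob = (cb - b_as_a + a_as_b) / v
        for j, day in enumerate(days):
            rows.append((a.name, b.name, T_C, S0, rep, day, oa[j], ob[j]))
    return pd.DataFrame(
        rows,
        columns=["species_a", "species_b", "temperature_C", "phosphate_umol_L",
                 "replicate", "day", "density_a", "density_b"],
    )


def simulate_competition_dataset(
    panel: Sequence[TrueSpecies],
    design: ExperimentDesign = COMPETITION_DESIGN,
    noise: NoiseModel = NoiseModel(sigma_log10=0.0),
    depletion: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """All pairwise trials across the competition design grid."""
    root = np.random.default_rng(noise.seed if seed is None else seed)
    frames = []
    for i in range(len(panel)):
        for j in range(i + 1, len(panel)):
            for T_C in design.temperatures_C:
                for S0 in design.phosphate_umol_L:
                    frames.append(
                        simulate_competition_trial(
                            panel[i], panel[j], T_C, S0, design, noise,
                            depletion=depletion, rng=root,
                        )
                    )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# CSV round-tripping


def growth_curves_to_frame(curves: Sequence[GrowthCurve]) -> pd.DataFrame:
    """Tidy long format: one row per density observation."""
    rows = []
    for c in curves:
        for day, dens in zip(c.days, c.density):
            rows.append((c.species, c.temperature_C, c.phosphate_umol_L,
                         c.replicate, day, dens))
    return pd.DataFrame(
        rows,
        columns=["species", "temperature_C", "phosphate_umol_L", "replicate",
                 "day", "density_cells_per_mL"],
    )


def frame_to_growth_curves(df: pd.DataFrame) -> list[GrowthCurve]:
    """Rebuild GrowthCurve objects from the tidy long format."""
    required = {"species", "temperature_C", "phosphate_umol_L", "replicate",
                "day", "density_cells_per_mL"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth_curves table missing columns: {sorted(missing)}")
    curves = []
    keys = ["species", "temperature_C", "phosphate_umol_L", "replicate"]
    for (sp, t, s, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("day")
        curves.append(GrowthCurve(sp, float(t), float(s), int(rep),
                                  grp["day"].to_numpy(),
                                  grp["density_cells_per_mL"].to_numpy()))
    return curves


def panel_to_frame(panel: Sequence[TrueSpecies]) -> pd.DataFrame:
    """True generating traits, one row per species."""
    return pd.DataFrame(
        [
            {
                "species": sp.name,
                "B0_per_day": sp.traits.B0,
                "E_mu_eV": sp.traits.E_mu,
                "K0_umol_L": sp.traits.K0,
                "E_K_eV": sp.traits.E_K,
                "T_ref_C": sp.traits.T_ref_K - 273.15,
                "t_lag_days": sp.t_lag_days,
                "Nmax_log10": sp.Nmax_log10,
                "quota_umolP_per_cell": sp.quota_umolP_per_cell,
            }
            for sp in panel
        ]
    )


def frame_to_panel(df: pd.DataFrame) -> list[TrueSpecies]:
    """Rebuild a species panel from a true_traits table."""
    return [
        TrueSpecies(
            name=row["species"],
            traits=MetabolicTraits(
                B0=row["B0_per_day"], E_mu=row["E_mu_eV"],
                K0=row["K0_umol_L"], E_K=row["E_K_eV"],
                T_ref_K=celsius_to_kelvin(row["T_ref_C"]),
            ),
            t_lag_days=row["t_lag_days"],
            Nmax_log10=row["Nmax_log10"],
            quota_umolP_per_cell=row["quota_umolP_per_cell"],
        )
        for _, row in df.iterrows()
    ]


def write_dataset(
    path: str | Path,
    curves: Sequence[GrowthCurve] | None = None,
    competition: pd.DataFrame | None = None,
    panel: Sequence[TrueSpecies] | None = None,
) -> dict[str, Path]:
    """Write whichever artifacts are provided as CSVs under ``path``.

    Produces ``growth_curves.csv``, ``competition_counts.csv`` and/or
    ``true_traits.csv``; returns the paths written.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if curves is not None:
        p = path / "growth_curves.csv"
        growth_curves_to_frame(curves).to_csv(p, index=False)
        written["growth_curves"] = p
    if competition is not None:
        p = path / "competition_counts.csv"
        competition.to_csv(p, index=False)
        written["competition_counts"] = p
    if panel is not None:
        p = path / "true_traits.csv"
        panel_to_frame(panel).to_csv(p, index=False)
        written["true_traits"] = p
    return written
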