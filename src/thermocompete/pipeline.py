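"""End-to-end orchestration: simulate, fit, predict, evaluate.

A single :class:`PipelineConfig` (optionally loaded from YAML) drives the
five stages; a global seed is expanded into independent per-stage
substreams so any stage can be rerun without perturbing the others, and a
run manifest records seeds and row counts for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._constants import celsius_to_kelvin
from . import __version__
from .evaluate import (
    attach_observed_R,
    count_reversals,
    correlate_pred_obs,
    day_persistence,
    drop_low_density,
    evaluation_table,
    join_predictions,
    reversal_summary,
)
from .growth import fit_growth_table
from .model import MetabolicTraits, prediction_grid
from .synthetic import (
    COMPETITION_DESIGN,
    MONOCULTURE_DESIGN,
    ExperimentDesign,
    NoiseModel,
    default_panel,
    frame_to_growth_curves,
    frame_to_panel,
    sample_species_panel,
    simulate_competition_dataset,
    simulate_monoculture_dataset,
    write_dataset,
)
from .traits import fit_arrhenius, fit_monod

logger = logging.getLogger("thermocompete")

__all__ = [
    "PipelineConfig",
    "run_all",
    "stage_simulate",
    "stage_fit_growth",
    "stage_fit_monod",
    "stage_fit_arrhenius",
    "stage_predict",
    "stage_evaluate",
    "monod_fits_table",
    "traits_from_monod",
]

_STAGES = ("panel", "monoculture", "competition", "fit_growth", "fit_monod",
           "bootstrap")


@dataclass
class PipelineConfig:
    """Every knob of the synthetic replication in one place."""

    seed: int = 0
    outdir: str = "pipeline_out"
    # panel
    n_species: int = 6
    use_default_panel: bool = True
    # designs
    monoculture: ExperimentDesign = field(default_factory=lambda: MONOCULTURE_DESIGN)
    competition: ExperimentDesign = field(default_factory=lambda: COMPETITION_DESIGN)
    # noise / simulator
    sigma_log10: float = 0.05
    misclassification_rate: float = 0.0
    depletion: bool = False
    # fitting
    n_starts: int = 1000
    n_polish: int = 5
    otr_C: tuple[float, float] = (15.0, 25.0)
    t_ref_C: float = 15.0
    failed_growth_decades: float = 1.0
    # evaluation
    evaluation_day: float = 14.0
    drop_threshold: float = 500.0
    bootstrap_B: int = 10000
    t_days: float = 14.0

    def __post_init__(self):
        if self.otr_C[0] >= self.otr_C[1]:
            raise ValueError("OTR lower bound must be below upper bound")
        if not self.otr_C[0] <= self.t_ref_C <= self.otr_C[1]:
            raise ValueError("reference temperature must lie inside the OTR")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("monoculture", "competition"):
            if key in raw and isinstance(raw[key], dict):
                d = raw[key]
                for f in ("temperatures_C", "phosphate_umol_L", "sampling_days"):
                    if f in d:
                        d[f] = tuple(d[f])
                raw[key] = ExperimentDesign(**d)
        if "otr_C" in raw:
            raw["otr_C"] = tuple(raw["otr_C"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        d = _plain(dataclasses.asdict(self))
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_STAGES))
        return {name: int(c.generate_state(1)[0]) % (2**31)
                for name, c in zip(_STAGES, children)}


def stage_simulate(config: PipelineConfig):
    """Draw the panel and simulate monoculture + competition datasets."""
    seeds = config.stage_seeds()
    if config.use_default_panel:
        panel = default_panel()
        if config.n_species != len(panel):
            panel = panel[: config.n_species]
    else:
        panel = sample_species_panel(config.n_species, seed=seeds["panel"])
    noise = NoiseModel(sigma_log10=config.sigma_log10,
                       misclassification_rate=config.misclassification_rate)
    curves = simulate_monoculture_dataset(panel, config.monoculture, noise,
                                          seed=seeds["monoculture"])
    competition = simulate_competition_dataset(
        panel, config.competition, noise, depletion=config.depletion,
        seed=seeds["competition"],
    )
    logger.info("simulate: %d species, %d growth curves, %d competition rows",
                len(panel), len(curves), len(competition))
    return panel, curves, competition


def stage_fit_growth(config: PipelineConfig, curves) -> pd.DataFrame:
    """Buchanan fits for every monoculture curve."""
    seeds = config.stage_seeds()
    fits = fit_growth_table(curves, n_starts=config.n_starts,
                            seed=seeds["fit_growth"],
                            n_polish=config.n_polish,
                            failed_growth_decades=config.failed_growth_decades)
    n_failed = int(fits["failed_growth"].sum())
    logger.info("fit-growth: %d curves, %d flagged failed growth",
                len(fits), n_failed)
    return fits


def monod_fits_table(
    growth_fits: pd.DataFrame,
    n_starts: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Monod fit per species x temperature x replicate from growth-rate fits.

    Curves flagged as failed growth or non-converged contribute mu = 0 only
    if they converged; failed curves are excluded, mirroring the removal of
    cultures that never grew.
    """
    usable = growth_fits[growth_fits["converged"] & ~growth_fits["failed_growth"]]
    ss = np.random.SeedSequence(seed)
    rows = []
    groups = list(usable.groupby(["species", "temperature_C", "replicate"], sort=True))
    children = ss.spawn(len(groups))
    for ((sp, T, rep), grp), child in zip(groups, children):
        pts = list(zip(grp["phosphate_umol_L"], grp["mu"]))
        f = fit_monod(pts, species=sp, temperature_C=float(T), replicate=int(rep),
                      n_starts=n_starts, seed=child.generate_state(1)[0])
        rows.append(dataclasses.asdict(f))
    return pd.DataFrame(rows)


def stage_fit_monod(config: PipelineConfig, growth_fits: pd.DataFrame) -> pd.DataFrame:
    seeds = config.stage_seeds()
    fits = monod_fits_table(growth_fits, seed=seeds["fit_monod"])
    logger.info("fit-monod: %d fits, %d converged", len(fits),
                int(fits["converged"].sum()))
    return fits


def traits_from_monod(
    monod_fits: pd.DataFrame,
    t_ref_C: float = 15.0,
    otr_C: tuple[float, float] = (15.0, 25.0),
    replicate_mean: bool = False,
) -> tuple[dict[str, MetabolicTraits], pd.DataFrame]:
    """Boltzmann-Arrhenius fits of mu_max and K_S per species within the OTR.

    By default per-replicate Monod estimates are pooled into one regression
    per species and trait; ``replicate_mean=True`` averages replicates per
    temperature first.
    """
    usable = monod_fits[monod_fits["converged"]]
    panel: dict[str, MetabolicTraits] = {}
    rows = []
    for sp, grp in usable.groupby("species", sort=True):
        fits = {}
        for trait in ("mu_max", "K_S"):
            sub = grp[["temperature_C", trait]].dropna()
            if replicate_mean:
                sub = sub.groupby("temperature_C", as_index=False).mean()
            f = fit_arrhenius(list(sub.itertuples(index=False)), T_ref_C=t_ref_C,
                              species=sp, trait_name=trait, OTR_C=otr_C)
            fits[trait] = f
            rows.append(dataclasses.asdict(f))
        if fits["mu_max"].converged and fits["K_S"].converged:
            panel[sp] = MetabolicTraits(
                B0=fits["mu_max"].normalisation,
                E_mu=fits["mu_max"].activation_energy,
                K0=fits["K_S"].normalisation,
                E_K=fits["K_S"].activation_energy,
                T_ref_K=celsius_to_kelvin(t_ref_C),
            )
    return panel, pd.DataFrame(rows)


def stage_fit_arrhenius(config: PipelineConfig, monod_fits: pd.DataFrame):
    panel, table = traits_from_monod(monod_fits, t_ref_C=config.t_ref_C,
                                     otr_C=config.otr_C)
    logger.info("fit-arrhenius: traits for %d species", len(panel))
    return panel, table


def stage_predict(config: PipelineConfig, traits: dict[str, MetabolicTraits]):
    """Predictions for both the nutrient-explicit and saturated models."""
    temps = config.competition.temperatures_C
    phos = config.competition.phosphate_umol_L
    pred_R = prediction_grid(traits, temps, phos, t_days=config.t_days, mode="R")
    pred_Rinf = prediction_grid(traits, temps, None, t_days=config.t_days,
                                mode="Rinf")
    logger.info("predict: %d R rows, %d Rinf rows", len(pred_R), len(pred_Rinf))
    return pred_R, pred_Rinf


def stage_evaluate(
    config: PipelineConfig,
    competition: pd.DataFrame,
    pred_R: pd.DataFrame,
    pred_Rinf: pd.DataFrame,
) -> dict:
    """Score both prediction modes against the observed trials."""
    seeds = config.stage_seeds()
    obs = attach_observed_R(drop_low_density(competition, config.drop_threshold))
    results = {}
    for mode, pred in (("R", pred_R), ("Rinf", pred_Rinf)):
        comparison = join_predictions(obs, pred, day=config.evaluation_day)
        table = evaluation_table(comparison, B=config.bootstrap_B,
                                 seed=seeds["bootstrap"])
        rev = count_reversals(obs, pred, day=config.evaluation_day)
        results[mode] = {
            "comparison": comparison,
            "summary": table,
            "reversals": rev,
            "reversal_summary": reversal_summary(rev),
            "correlation": correlate_pred_obs(comparison),
        }
    days = sorted(set(obs["day"]))
    persistence = {}
    for d1, d2 in zip(days[:-1], days[1:]):
        try:
            persistence[f"day{d1:g}_day{d2:g}"] = day_persistence(obs, d1, d2)
        except ValueError:
            pass
    results["persistence"] = persistence
    results["n_dropped"] = int(obs["dropped"].sum())
    logger.info("evaluate: %d replicates dropped; R proportion=%.3f, "
                "Rinf proportion=%.3f", results["n_dropped"],
                results["R"]["summary"]["proportion_correct"].iloc[0],
                results["Rinf"]["summary"]["proportion_correct"].iloc[0])
    return results


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline and write every stage artifact under outdir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    panel, curves, competition = stage_simulate(config)
    write_dataset(out, curves=curves, competition=competition, panel=panel)

    growth_fits = stage_fit_growth(config, curves)
    growth_fits.to_csv(out / "growth_fits.csv", index=False)

    monod_fits = stage_fit_monod(config, growth_fits)
    monod_fits.to_csv(out / "monod_fits.csv", index=False)

    traits, trait_table = stage_fit_arrhenius(config, monod_fits)
    trait_table.to_csv(out / "arrhenius_fits.csv", index=False)
    _traits_frame(traits, config.t_ref_C).to_csv(out / "metabolic_traits.csv",
                                                 index=False)

    pred_R, pred_Rinf = stage_predict(config, traits)
    pd.concat([pred_R, pred_Rinf], ignore_index=True).to_csv(
        out / "predictions.csv", index=False)

    results = stage_evaluate(config, competition, pred_R, pred_Rinf)
    for mode in ("R", "Rinf"):
        results[mode]["summary"].to_csv(out / f"evaluation_summary_{mode}.csv",
                                        index=False)
        results[mode]["reversals"].to_csv(out / f"reversals_{mode}.csv",
                                          index=False)
        results[mode]["comparison"].to_csv(out / f"comparison_{mode}.csv",
                                           index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": config.stage_seeds(),
        "n_species": len(panel),
        "n_growth_curves": len(curves),
        "n_competition_rows": len(competition),
        "n_dropped": results["n_dropped"],
        "proportion_correct_R": float(
            results["R"]["summary"]["proportion_correct"].iloc[0]),
        "proportion_correct_Rinf": float(
            results["Rinf"]["summary"]["proportion_correct"].iloc[0]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    results["traits"] = traits
    results["panel"] = panel
    return results


def _traits_frame(traits: dict[str, MetabolicTraits], t_ref_C: float) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"species": sp, "B0_per_day": t.B0, "E_mu_eV": t.E_mu,
             "K0_umol_L": t.K0, "E_K_eV": t.E_K, "T_ref_C": t_ref_C}
            for sp, t in traits.items()
        ]
    )
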