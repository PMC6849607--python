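"""Scoring of competition predictions against observed trial outcomes.

The observed competitive advantage of species a over b in one replicate is
R_obs = ln((N_a + 1)/(N_b + 1)), the +1 guarding against local extinction.
Replicates with too few cells to call a winner are dropped; the remainder
are compared to the model's predicted winner, summarised as proportions
correctly predicted with bootstrap p-values against chance, reversal counts
across temperatures, and predicted-observed correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationSummary",
    "observed_R",
    "binary_winner",
    "drop_low_density",
    "attach_observed_R",
    "join_predictions",
    "bootstrap_p_correct",
    "proportion_correct",
    "evaluation_table",
    "count_reversals",
    "reversal_summary",
    "correlate_pred_obs",
    "day_persistence",
]

PAIR_KEYS = ["species_a", "species_b", "temperature_C", "phosphate_umol_L"]


@dataclass
class EvaluationSummary:
    """Proportion of replicates whose winner the model called correctly."""

    label: str
    proportion_correct: float
    n: int
    p_value: float
    mode: str = "R"


def observed_R(density_a, density_b):
    """Observed competitive advantage ln((N_a + 1)/(N_b + 1)).

    The +1 correction keeps the ratio finite when one (or both) species has
    gone locally extinct; double extinction scores an exact tie.
    """
    density_a = np.asarray(density_a, dtype=float)
    density_b = np.asarray(density_b, dtype=float)
    if np.any(density_a < 0) or np.any(density_b < 0):
        raise ValueError("densities must be non-negative")
    out = np.log(density_a + 1.0) - np.log(density_b + 1.0)
    return float(out) if out.ndim == 0 else out


def binary_winner(R_obs: float) -> str | None:
    """Sign classification of an advantage: 'a', 'b', or None for an exact tie."""
    if R_obs > 0:
        return "a"
    if R_obs < 0:
        return "b"
    return None


def drop_low_density(
    obs: pd.DataFrame, threshold_cells_per_mL: float = 500.0
) -> pd.DataFrame:
    """Flag replicates whose combined density is below the threshold.

    Returns a copy with boolean ``dropped`` and string ``drop_reason``
    columns; downstream summaries exclude dropped rows but keep them for
    accounting.
    """
    if threshold_cells_per_mL < 0:
        raise ValueError("threshold must be non-negative")
    out = obs.copy()
    total = out["density_a"] + out["density_b"]
    out["dropped"] = total < threshold_cells_per_mL
    out["drop_reason"] = np.where(
        out["dropped"], f"total density below {threshold_cells_per_mL:g} cells/mL", ""
    )
    return out


def attach_observed_R(obs: pd.DataFrame) -> pd.DataFrame:
    """Add ``R_obs`` and ``winner_obs`` columns to an observation table."""
    out = obs.copy()
    out["R_obs"] = observed_R(out["density_a"].to_numpy(),
                              out["density_b"].to_numpy())
    out["winner_obs"] = [binary_winner(r) for r in out["R_obs"]]
    return out


def join_predictions(
    obs: pd.DataFrame, predictions: pd.DataFrame, day: float | None = 14.0
) -> pd.DataFrame:
    """Replicate-level comparison table: observations joined to predictions.

    Predictions are matched on (pair, temperature, phosphate); for the
    nutrient-saturated mode (NaN phosphate in the prediction table) the
    match ignores phosphate.  ``day=None`` keeps all sampling days.
    """
    out = obs if "R_obs" in obs.columns else attach_observed_R(obs)
    if day is not None:
        out = out[out["day"] == day].copy()
    pred = predictions.rename(columns={"R": "R_pred", "winner": "winner_pred"})
    keys = PAIR_KEYS if pred["phosphate_umol_L"].notna().all() else [
        c for c in PAIR_KEYS if c != "phosphate_umol_L"
    ]
    cols = keys + ["R_pred", "winner_pred", "mode"]
    merged = out.merge(pred[cols], on=keys, how="left", validate="many_to_one")
    if merged["R_pred"].isna().any():
        missing = merged.loc[merged["R_pred"].isna(), PAIR_KEYS].drop_duplicates()
        raise ValueError(f"no prediction for conditions:\n{missing}")
    merged["correct"] = [
        (wo is not None and wp in ("a", "b") and wo == wp) if wo is not None and wp != "tie"
        else None
        for wo, wp in zip(merged["winner_obs"], merged["winner_pred"])
    ]
    return merged


def bootstrap_p_correct(
    k: int, n: int, B: int = 10000, rng: np.random.Generator | None = None
) -> float:
    """One-sided bootstrap p-value for H0: true proportion correct <= 0.5.

    Resamples the n replicate-level correct/incorrect indicators with
    replacement B times (equivalently, draws Binomial(n, k/n) counts) and
    reports the fraction of bootstrap proportions <= 0.5.
    """
    if n <= 0:
        raise ValueError("cannot bootstrap an empty subset")
    if not 0 <= k <= n:
        raise ValueError("k must be between 0 and n")
    if rng is None:
        rng = np.random.default_rng()
    boot = rng.binomial(n, k / n, size=B) / n
    return float(np.mean(boot <= 0.5))


def _valid(comparison: pd.DataFrame) -> pd.DataFrame:
    out = comparison
    if "dropped" in out.columns:
        out = out[~out["dropped"]]
    return out[out["correct"].notna()]


def proportion_correct(
    comparison: pd.DataFrame,
    label: str = "full",
    B: int = 10000,
    seed: int | None = None,
) -> EvaluationSummary:
    """Fraction of non-dropped, determinate replicates predicted correctly.

    The point estimate is bootstrap-free (a plain proportion); the p-value
    tests the proportion against chance (0.5) by resampling replicates.
    """
    valid = _valid(comparison)
    n = int(len(valid))
    if n == 0:
        raise ValueError(f"subset {label!r}: no scorable replicates after drops")
    k = int(valid["correct"].sum())
    mode = valid["mode"].iloc[0] if "mode" in valid.columns else "R"
    p = bootstrap_p_correct(k, n, B=B, rng=np.random.default_rng(seed))
    return EvaluationSummary(label, k / n, n, p, mode)


def evaluation_table(
    comparison: pd.DataFrame, B: int = 10000, seed: int | None = None
) -> pd.DataFrame:
    """Headline summary: full dataset, by temperature, by nutrient, by species.

    The per-species slices keep every competition involving that species.
    """
    ss = np.random.SeedSequence(seed)

    def _seed():
        return ss.spawn(1)[0].generate_state(1)[0]

    summaries = [proportion_correct(comparison, "full", B, _seed())]
    for T in sorted(comparison["temperature_C"].unique()):
        summaries.append(proportion_correct(
            comparison[comparison["temperature_C"] == T],
            f"T={T:g}C", B, _seed()))
    for S in sorted(comparison["phosphate_umol_L"].unique()):
        summaries.append(proportion_correct(
            comparison[comparison["phosphate_umol_L"] == S],
            f"P={S:g}umol/L", B, _seed()))
    species = sorted(set(comparison["species_a"]) | set(comparison["species_b"]))
    for sp in species:
        mask = (comparison["species_a"] == sp) | (comparison["species_b"] == sp)
        summaries.append(proportion_correct(comparison[mask], f"species:{sp}",
                                            B, _seed()))
    return pd.DataFrame(
        [
            {"subset": s.label, "proportion_correct": s.proportion_correct,
             "n": s.n, "p_value": s.p_value, "mode": s.mode}
            for s in summaries
        ]
    )


def count_reversals(
    observations: pd.DataFrame,
    predictions: pd.DataFrame,
    day: float | None = 14.0,
) -> pd.DataFrame:
    """Observed and predicted sign reversals of R between two temperatures.

    An observed reversal for a (pair, nutrient) cell requires the median
    R_obs across non-dropped replicates to change sign between the two
    temperatures; a median of exactly zero makes the cell indeterminate
    (``observed`` is NA).  Predicted reversals come from the sign of the
    predicted R at the two temperatures.
    """
    obs = observations if "R_obs" in observations.columns else attach_observed_R(observations)
    if day is not None:
        obs = obs[obs["day"] == day]
    if "dropped" in obs.columns:
        obs = obs[~obs["dropped"]]
    temps = sorted(obs["temperature_C"].unique())
    if len(temps) != 2:
        raise ValueError("reversal counting needs exactly two temperatures")
    t1, t2 = temps

    pred = predictions.rename(columns={"R": "R_pred"})
    sat_mode = pred["phosphate_umol_L"].isna().all()

    rows = []
    for (sa, sb, S), grp in obs.groupby(
        ["species_a", "species_b", "phosphate_umol_L"], sort=True
    ):
        med1 = grp.loc[grp["temperature_C"] == t1, "R_obs"].median()
        med2 = grp.loc[grp["temperature_C"] == t2, "R_obs"].median()
        if pd.isna(med1) or pd.isna(med2):
            continue  # one temperature entirely dropped: untestable
        observed = None if (med1 == 0 or med2 == 0) else (med1 > 0) != (med2 > 0)

        sel = (pred["species_a"] == sa) & (pred["species_b"] == sb)
        if not sat_mode:
            sel &= pred["phosphate_umol_L"] == S
        p1 = pred.loc[sel & (pred["temperature_C"] == t1), "R_pred"]
        p2 = pred.loc[sel & (pred["temperature_C"] == t2), "R_pred"]
        if len(p1) != 1 or len(p2) != 1:
            raise ValueError(f"need one prediction per temperature for pair "
                             f"({sa}, {sb}) at P={S}")
        r1, r2 = float(p1.iloc[0]), float(p2.iloc[0])
        predicted = None if (abs(r1) < 1e-12 or abs(r2) < 1e-12) else (r1 > 0) != (r2 > 0)
        rows.append(
            {"species_a": sa, "species_b": sb, "phosphate_umol_L": S,
             "median_R_obs_low_T": med1, "median_R_obs_high_T": med2,
             "observed": observed, "predicted": predicted}
        )
    return pd.DataFrame(rows)


def reversal_summary(reversals: pd.DataFrame, by: str | None = "phosphate_umol_L") -> pd.DataFrame:
    """Aggregate reversal counts and the share of observed ones predicted."""

    def _agg(grp, label):
        det = grp[grp["observed"].notna()]
        obs_yes = det[det["observed"] == True]  # noqa: E712
        n_pred = int((obs_yes["predicted"] == True).sum())  # noqa: E712
        return {
            "subset": label,
            "observed_yes": int(len(obs_yes)),
            "observed_no": int((det["observed"] == False).sum()),  # noqa: E712
            "predicted_among_observed": n_pred,
            "proportion_predicted": n_pred / len(obs_yes) if len(obs_yes) else math.nan,
        }

    rows = [_agg(reversals, "full")]
    if by is not None:
        for val, grp in reversals.groupby(by, sort=True):
            rows.append(_agg(grp, f"{by}={val:g}"))
    return pd.DataFrame(rows)


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n < 4 or abs(r) >= 1.0:
        return (math.nan, math.nan)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + level / 2)
    return (math.tanh(z - crit * se), math.tanh(z + crit * se))


def correlate_pred_obs(comparison: pd.DataFrame) -> dict:
    """Pearson correlation between predicted and observed R with Fisher CI."""
    valid = comparison
    if "dropped" in valid.columns:
        valid = valid[~valid["dropped"]]
    x = valid["R_pred"].to_numpy(dtype=float)
    y = valid["R_obs"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    lo, hi = _fisher_ci(r, len(x))
    return {"r": r, "ci95": (lo, hi), "n": int(len(x))}


def day_persistence(
    observations: pd.DataFrame, day1: float, day2: float
) -> dict:
    """Pearson correlation of R_obs between two sampling days.

    Pairs replicates of the same (pair, condition, replicate) across days —
    the check that an early exponential-phase advantage persists once
    growth has saturated.
    """
    obs = observations if "R_obs" in observations.columns else attach_observed_R(observations)
    if "dropped" in obs.columns:
        obs = obs[~obs["dropped"]]
    keys = PAIR_KEYS + ["replicate"]
    a = obs[obs["day"] == day1].set_index(keys)["R_obs"]
    b = obs[obs["day"] == day2].set_index(keys)["R_obs"]
    joined = pd.concat([a, b], axis=1, join="inner", keys=["d1", "d2"]).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired replicates across days")
    r = float(stats.pearsonr(joined["d1"], joined["d2"]).statistic)
    lo, hi = _fisher_ci(r, len(joined))
    return {"r": r, "ci95": (lo, hi), "n": int(len(joined))}
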