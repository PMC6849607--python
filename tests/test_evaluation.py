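"""Scoring logic: observed advantage, drops, proportions, reversals, correlations."""

import math

import numpy as np
import pandas as pd
import pytest

from thermocompete.evaluate import (
    attach_observed_R,
    binary_winner,
    bootstrap_p_correct,
    correlate_pred_obs,
    count_reversals,
    day_persistence,
    drop_low_density,
    evaluation_table,
    join_predictions,
    observed_R,
    proportion_correct,
    reversal_summary,
)


def make_obs(rows):
    return pd.DataFrame(
        rows,
        columns=["species_a", "species_b", "temperature_C", "phosphate_umol_L",
                 "replicate", "day", "density_a", "density_b"],
    )


def make_pred(rows, mode="R"):
    df = pd.DataFrame(
        rows,
        columns=["species_a", "species_b", "temperature_C", "phosphate_umol_L",
                 "R", "winner"],
    )
    df["mode"] = mode
    return df


class TestObservedR:
    @pytest.mark.parametrize(
        "da, db, expected",
        [(100.0, 100.0, 0.0), (0.0, 0.0, 0.0), (math.e**2 - 1.0, 0.0, 2.0)],
    )
    def test_closed_forms(self, da, db, expected):
        assert observed_R(da, db) == pytest.approx(expected, abs=1e-12)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            observed_R(-1.0, 5.0)

    def test_label_swap_negates(self):
        rng = np.random.default_rng(0)
        da, db = rng.uniform(0, 1e5, 20), rng.uniform(0, 1e5, 20)
        np.testing.assert_allclose(observed_R(da, db), -observed_R(db, da))


class TestBinaryWinner:
    def test_sign_classification(self):
        assert binary_winner(0.3) == "a"
        assert binary_winner(-0.3) == "b"
        assert binary_winner(0.0) is None


class TestDropLowDensity:
    def test_zero_threshold_drops_nothing(self):
        obs = make_obs([("x", "y", 15, 1.0, 1, 14, 10.0, 5.0)])
        assert not drop_low_density(obs, 0.0)["dropped"].any()

    def test_threshold_on_total_density(self):
        obs = make_obs([
            ("x", "y", 15, 1.0, 1, 14, 300.0, 100.0),   # total 400 -> dropped
            ("x", "y", 15, 1.0, 2, 14, 450.0, 100.0),   # total 550 -> kept
        ])
        flagged = drop_low_density(obs, 500.0)
        assert list(flagged["dropped"]) == [True, False]
        assert "below 500" in flagged.loc[0, "drop_reason"]


class TestProportionCorrect:
    def _comparison(self, n_correct, n_wrong):
        rows = []
        for i in range(n_correct + n_wrong):
            correct = i < n_correct
            rows.append(("x", "y", 15.0, 1.0, i, 14.0,
                         200.0 if correct else 50.0, 100.0))
        obs = attach_observed_R(make_obs(rows))
        pred = make_pred([("x", "y", 15.0, 1.0, 0.5, "a")])
        return join_predictions(obs, pred, day=14.0)

    def test_exact_arithmetic(self):
        s = proportion_correct(self._comparison(7, 3), B=100, seed=0)
        assert s.proportion_correct == pytest.approx(0.7)
        assert s.n == 10

    def test_point_estimate_independent_of_seed_and_order(self):
        cmp_ = self._comparison(7, 3)
        a = proportion_correct(cmp_, B=100, seed=1)
        b = proportion_correct(cmp_.sample(frac=1, random_state=5), B=100, seed=2)
        assert a.proportion_correct == b.proportion_correct

    def test_perfect_predictions_reject_chance(self):
        s = proportion_correct(self._comparison(40, 0), B=10000, seed=0)
        assert s.proportion_correct == 1.0
        assert s.p_value < 1e-3

    def test_empty_subset_flagged(self):
        cmp_ = self._comparison(2, 2)
        with pytest.raises(ValueError):
            proportion_correct(cmp_[cmp_["temperature_C"] == 99.0])

    def test_bootstrap_p_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_p_correct(1, 0)
        with pytest.raises(ValueError):
            bootstrap_p_correct(5, 3)


class TestJoinAndTable:
    def _dataset(self):
        rows, preds = [], []
        for t in (15.0, 25.0):
            for sp_pair in (("x", "y"), ("x", "z"), ("y", "z")):
                for s in (0.1, 1.0, 30.0):
                    for rep in range(1, 4):
                        rows.append((*sp_pair, t, s, rep, 14.0, 2000.0, 1000.0))
                    preds.append((*sp_pair, t, s, 0.2, "a"))
        return attach_observed_R(make_obs(rows)), make_pred(preds)

    def test_table_has_expected_subsets(self):
        obs, pred = self._dataset()
        table = evaluation_table(join_predictions(obs, pred), B=100, seed=0)
        subsets = set(table["subset"])
        assert {"full", "T=15C", "T=25C", "P=0.1umol/L", "P=1umol/L",
                "P=30umol/L", "species:x", "species:y", "species:z"} == subsets
        assert (table["proportion_correct"] == 1.0).all()

    def test_species_slices_count_all_their_competitions(self):
        obs, pred = self._dataset()
        table = evaluation_table(join_predictions(obs, pred), B=100, seed=0)
        full_n = int(table.loc[table["subset"] == "full", "n"].iloc[0])
        x_n = int(table.loc[table["subset"] == "species:x", "n"].iloc[0])
        assert x_n == full_n * 2 // 3  # x appears in 2 of the 3 pairs

    def test_missing_prediction_raises(self):
        obs, pred = self._dataset()
        with pytest.raises(ValueError):
            join_predictions(obs, pred[pred["temperature_C"] == 15.0])

    def test_label_swap_leaves_proportions_unchanged(self):
        obs, pred = self._dataset()
        base = evaluation_table(join_predictions(obs, pred), B=100, seed=0)
        obs_sw = obs.rename(columns={"species_a": "species_b",
                                     "species_b": "species_a",
                                     "density_a": "density_b",
                                     "density_b": "density_a"})
        obs_sw = attach_observed_R(obs_sw.drop(columns=["R_obs", "winner_obs"]))
        pred_sw = pred.rename(columns={"species_a": "species_b",
                                       "species_b": "species_a"})
        pred_sw["R"] = -pred_sw["R"]
        pred_sw["winner"] = pred_sw["winner"].map({"a": "b", "b": "a", "tie": "tie"})
        swapped = evaluation_table(join_predictions(obs_sw, pred_sw), B=100, seed=0)
        pd.testing.assert_series_equal(base["proportion_correct"],
                                       swapped["proportion_correct"])


class TestReversals:
    def _obs(self, med15, med25):
        # densities built so that R_obs = ln((da+1)/(db+1)) equals the
        # requested median exactly in every replicate
        rows = []
        for t, med in ((15.0, med15), (25.0, med25)):
            for rep in (1, 2, 3):
                da = 1000.0 * math.exp(med) - 1.0
                rows.append(("x", "y", t, 30.0, rep, 14.0, da, 999.0))
        return make_obs(rows)

    def test_sign_change_is_reversal(self):
        pred = make_pred([("x", "y", 15.0, 30.0, 0.4, "a"),
                          ("x", "y", 25.0, 30.0, -0.2, "b")])
        rev = count_reversals(self._obs(0.4, -0.2), pred)
        assert rev.loc[0, "observed"] == True  # noqa: E712
        assert rev.loc[0, "predicted"] == True  # noqa: E712

    def test_same_sign_is_not_reversal(self):
        pred = make_pred([("x", "y", 15.0, 30.0, 0.4, "a"),
                          ("x", "y", 25.0, 30.0, 0.1, "a")])
        rev = count_reversals(self._obs(0.4, 0.1), pred)
        assert rev.loc[0, "observed"] == False  # noqa: E712

    def test_zero_median_indeterminate(self):
        pred = make_pred([("x", "y", 15.0, 30.0, 0.4, "a"),
                          ("x", "y", 25.0, 30.0, -0.2, "b")])
        rev = count_reversals(self._obs(0.0, -0.2), pred)
        assert pd.isna(rev.loc[0, "observed"])
        summary = reversal_summary(rev)
        assert summary.loc[0, "observed_yes"] == 0

    def test_summary_proportion(self):
        rev = pd.DataFrame({
            "species_a": list("abcd"), "species_b": list("wxyz"),
            "phosphate_umol_L": [30.0] * 4,
            "median_R_obs_low_T": [1, 1, 1, 1.0],
            "median_R_obs_high_T": [-1, -1, 1, 1.0],
            "observed": [True, True, False, None],
            "predicted": [True, False, False, True],
        })
        s = reversal_summary(rev)
        assert s.loc[0, "observed_yes"] == 2
        assert s.loc[0, "proportion_predicted"] == pytest.approx(0.5)


class TestCorrelations:
    def _comparison(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        R_pred = rng.normal(0, 1, 60)
        rows = []
        for i, r in enumerate(R_pred):
            da = 1000.0 * math.exp(r + rng.normal(0, noise))
            rows.append(("x", "y", 15.0, 1.0, i, 14.0, da - 1.0, 999.0))
        obs = attach_observed_R(make_obs(rows))
        obs["R_pred"] = R_pred
        return obs

    def test_identity_gives_unit_correlation(self):
        out = correlate_pred_obs(self._comparison())
        assert out["r"] == pytest.approx(1.0, abs=1e-9)

    def test_permuted_observations_decorrelate(self):
        cmp_ = self._comparison()
        rng = np.random.default_rng(1)
        cmp_["R_obs"] = rng.permutation(cmp_["R_obs"].to_numpy())
        out = correlate_pred_obs(cmp_)
        assert abs(out["r"]) < 0.35

    def test_zero_variance_flagged(self):
        cmp_ = self._comparison()
        cmp_["R_pred"] = 1.0
        with pytest.raises(ValueError):
            correlate_pred_obs(cmp_)

    def test_fisher_interval_brackets_estimate(self):
        out = correlate_pred_obs(self._comparison(noise=0.5))
        lo, hi = out["ci95"]
        assert lo < out["r"] < hi

    def test_day_persistence_pairs_replicates(self):
        rng = np.random.default_rng(2)
        rows = []
        for rep in range(30):
            r = rng.normal(0, 1)
            for day in (5.0, 14.0):
                da = 1000.0 * math.exp(r + rng.normal(0, 0.2))
                rows.append(("x", "y", 15.0, 1.0, rep, day, da - 1.0, 999.0))
        out = day_persistence(make_obs(rows), 5.0, 14.0)
        assert out["n"] == 30
        assert out["r"] > 0.8
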