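"""Metrics, protocols, baselines and Parkes error-grid tests."""

import numpy as np
import pandas as pd
import pytest

from glucast.evaluation import (
    EvaluationProtocol,
    EvaluationReport,
    baseline_identity,
    evaluate,
    mape,
    r2,
    rmse,
)
from glucast.models import RecurrentConfig, build_model
from glucast.parkes import (
    MGDL_PER_MMOLL,
    ZONES,
    _TYPE1_LOWER,
    _TYPE1_UPPER,
    _extend,
    parkes_report,
    parkes_zone,
    parkes_zones,
)
from glucast.preprocessing import split_train_val_test
from glucast.types import FEATURES, RegularSeries


def _oracle_metrics(y, y_hat):
    """Naive loop implementations, independent of the vectorised path."""
    T = len(y)
    se = sum((y[t] - y_hat[t]) ** 2 for t in range(T))
    rm = (se / T) ** 0.5
    mp = 100.0 * sum(abs(y[t] - y_hat[t]) / y[t] for t in range(T)) / T
    ybar = sum(y) / T
    r = 1.0 - se / sum((y[t] - ybar) ** 2 for t in range(T))
    return rm, mp, r


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([5.0, 6.0, 7.0])
        assert rmse(y, y) == 0.0
        assert mape(y, y) == 0.0
        assert r2(y, y) == 1.0

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([5.0, 6.0, 7.0])
        y_hat = np.full(3, y.mean())
        assert r2(y, y_hat) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        y = np.array([5.0, 6.0, 7.0])
        y_hat = np.array([6.0, 6.0, 6.0])
        assert rmse(y, y_hat) == pytest.approx(np.sqrt(2.0 / 3.0))
        assert mape(y, y_hat) == pytest.approx(100 * (1 / 5 + 0 + 1 / 7) / 3)

    def test_r2_can_be_negative(self):
        y = np.array([5.0, 6.0, 7.0])
        assert r2(y, np.array([9.0, 9.0, 9.0])) < 0

    def test_oracle_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.uniform(2, 20, size=50)
            y_hat = y + rng.normal(0, 2, size=50)
            rm, mp, r = _oracle_metrics(list(y), list(y_hat))
            assert abs(rmse(y, y_hat) - rm) < 1e-12
            assert abs(mape(y, y_hat) - mp) < 1e-12
            assert abs(r2(y, y_hat) - r) < 1e-12

    def test_error_conditions(self):
        with pytest.raises(ValueError):
            rmse(np.array([1.0, 2.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            mape(np.array([0.0, 1.0]), np.array([1.0, 1.0]))


def _flat_day(value=6.0, n=288):
    idx = pd.date_range("2022-06-11 07:00", periods=n, freq="5min")
    frame = pd.DataFrame({f: np.zeros(n) for f in FEATURES}, index=idx)
    frame["glucose"] = value
    return RegularSeries("P0", frame)


class TestProtocols:
    def test_warmup_steps(self):
        assert EvaluationProtocol(30, "full_day").warmup_steps == 24
        assert EvaluationProtocol(30, "night").warmup_steps == 144
        assert EvaluationProtocol(120, "full_day").horizon_steps == 24

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            EvaluationProtocol(45, "full_day")
        with pytest.raises(ValueError):
            EvaluationProtocol(30, "evening")

    def test_scored_count_night(self):
        entry = baseline_identity(_flat_day(), EvaluationProtocol(30, "night"))
        assert len(entry.references) == 288 - 144 - 6 == 138

    def test_night_scores_are_subset_of_full_day(self):
        """The night-scored target timestamps are contained in the
        full-day-scored ones."""
        day = _flat_day()
        full = baseline_identity(day, EvaluationProtocol(30, "full_day"))
        night = baseline_identity(day, EvaluationProtocol(30, "night"))
        # same alignment rule, longer warm-up: suffix relation on targets
        assert len(night.references) < len(full.references)
        assert np.array_equal(
            full.references[-len(night.references):], night.references
        )

    def test_too_short_test_day_rejected(self):
        short = _flat_day(n=25)
        with pytest.raises(ValueError, match="too short"):
            baseline_identity(short, EvaluationProtocol(30, "full_day"))


class TestBaselines:
    def test_identity_on_constant_series_is_exact(self):
        entry = baseline_identity(_flat_day(), EvaluationProtocol(30, "full_day"))
        assert entry.rmse == 0.0

    def test_identity_lagged_rmse_on_linear_ramp(self):
        day = _flat_day()
        day.frame["glucose"] = 6.0 + 0.01 * np.arange(288)
        entry = baseline_identity(day, EvaluationProtocol(30, "full_day"))
        # y_t vs y_{t+6}: constant gap of 6 * 0.01
        assert entry.rmse == pytest.approx(0.06)

    def test_identity_matches_lag_difference_definition(self):
        rng = np.random.default_rng(1)
        day = _flat_day()
        g = 8.0 + np.cumsum(rng.normal(0, 0.1, 288))
        day.frame["glucose"] = g
        proto = EvaluationProtocol(30, "full_day")
        entry = baseline_identity(day, proto)
        manual = np.sqrt(np.mean((g[30:282 + 6] - g[24:282]) ** 2))
        assert entry.rmse == pytest.approx(manual)

    def test_linear_model_with_oracle_weights_is_exact(self):
        """On a noiseless series where glucose at t+h is an affine map of
        the features at t, the linear baseline with oracle weights scores
        zero RMSE."""
        from glucast.evaluation import LinearForecaster
        from glucast.models import RecurrentConfig
        from glucast.preprocessing import split_train_val_test
        from glucast.types import Standardizer

        rng = np.random.default_rng(6)
        n = 1728
        idx = pd.date_range("2022-06-06 07:00", periods=n, freq="5min")
        frame = pd.DataFrame({f: np.zeros(n) for f in FEATURES}, index=idx)
        x = rng.normal(size=n) ** 2
        frame["carbs_fast"] = x
        g = np.full(n, 7.0)
        g[6:] = 7.0 + 0.3 * x[:-6]
        frame["glucose"] = g
        split = split_train_val_test(RegularSeries("P0", frame))
        model = LinearForecaster(RecurrentConfig("rnn", 1, 1, horizon=6))
        # oracle weights in standardized space
        st = split.standardizer
        gi = FEATURES.index("glucose")
        ci = FEATURES.index("carbs_fast")
        model.head.W.value[...] = 0.0
        model.head.W.value[ci, 0] = 0.3 * st.std[ci] / st.std[gi]
        model.head.b.value[...] = (7.0 + 0.3 * st.mean[ci] - st.mean[gi]) / st.std[gi]
        entry = evaluate(model, split, EvaluationProtocol(30, "full_day"))
        assert entry.rmse < 1e-9

    def test_linear_baseline_trains_below_identity(self, tiny_cohort):
        from glucast.evaluation import baseline_linear
        from glucast.training import TrainingPlan

        proto = EvaluationProtocol(30, "full_day")
        # the affine map has few parameters but few gradient steps per
        # epoch on a 3-child cohort; 300 epochs reach the least-squares fit
        plan = TrainingPlan(epochs=300, seeds=(0,))
        entries = baseline_linear(tiny_cohort, plan, proto, seed=0)
        lin = np.mean([e.rmse for e in entries.values()])
        ident = np.mean(
            [
                baseline_identity(s.test, proto).rmse
                for s in tiny_cohort.splits.values()
            ]
        )
        assert lin < ident

    def test_evaluate_constant_night_is_exact(self, tiny_cohort):
        model = build_model(RecurrentConfig("rnn", 1, 4, horizon=6))
        split = next(iter(tiny_cohort.splits.values()))
        flat = _flat_day()
        import dataclasses

        flat_split = dataclasses.replace(split, test=flat)
        entry = evaluate(
            model, flat_split, EvaluationProtocol(30, "night"),
            standardizer=tiny_cohort.standardizer_for(split.participant_id),
        )
        # a constant series has rmse equal to the model's constant offset;
        # the identity baseline is exactly zero
        ident = baseline_identity(flat, EvaluationProtocol(30, "night"))
        assert ident.rmse == 0.0


def _oracle_zone(ref_mgdl: float, pred_mgdl: float) -> str:
    """Independent piecewise-linear classifier over the vertex table, using
    np.interp along each boundary polyline (no polygon machinery)."""

    def above_upper(key):
        xs, ys = _extend(_TYPE1_UPPER[key])
        return pred_mgdl > np.interp(ref_mgdl, xs, ys)

    def right_of_lower(key):
        xs, ys = _extend(_TYPE1_LOWER[key])
        return ref_mgdl > np.interp(pred_mgdl, ys, xs)

    if not above_upper("B") and not right_of_lower("B"):
        return "A"
    if not above_upper("C") and not right_of_lower("C"):
        return "B"
    if not above_upper("D") and not right_of_lower("D"):
        return "C"
    return "E" if above_upper("E") else "D"


class TestParkes:
    def test_diagonal_is_zone_a(self):
        assert parkes_zone(5.55, 5.55) == "A"
        assert parkes_zone(10.0, 10.0) == "A"

    def test_severe_overestimation_is_dangerous(self):
        """Low reference, very high prediction lands beyond zone B."""
        zone = parkes_zone(2.78, 22.2)
        assert zone in ("C", "D", "E")
        assert zone == _oracle_zone(2.78 * MGDL_PER_MMOLL, 22.2 * MGDL_PER_MMOLL)

    def test_matches_independent_piecewise_oracle(self):
        rng = np.random.default_rng(3)
        refs = rng.uniform(1.2, 33.0, size=400)
        preds = rng.uniform(1.2, 33.0, size=400)
        zones = parkes_zones(refs, preds)
        mismatches = 0
        for r, p, z in zip(refs, preds, zones):
            oz = _oracle_zone(r * MGDL_PER_MMOLL, p * MGDL_PER_MMOLL)
            if z != oz:
                mismatches += 1
        assert mismatches == 0

    def test_zone_monotone_along_prediction_ray(self):
        """For fixed reference, widening the prediction error never makes
        the zone safer."""
        order = {z: i for i, z in enumerate(ZONES)}
        for ref in (2.5, 5.0, 10.0, 20.0):
            ups = [parkes_zone(ref, min(ref + d, 33.3)) for d in np.linspace(0, 25, 40)]
            downs = [parkes_zone(ref, max(ref - d, 0.5)) for d in np.linspace(0, 18, 40)]
            for seq in (ups, downs):
                ranks = [order[z] for z in seq]
                assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            parkes_zone(0.0, 5.0)

    def test_report_fractions(self, tmp_path):
        refs = np.full(50, 8.0)
        fractions = parkes_report(refs, refs, plot_path=tmp_path / "grid.png")
        assert fractions["A"] == 100.0
        assert sum(fractions.values()) == pytest.approx(100.0, abs=1e-6)
        assert (tmp_path / "grid.png").exists()

    def test_fractions_invariant_under_duplication(self):
        rng = np.random.default_rng(4)
        refs = rng.uniform(3, 20, 60)
        preds = refs + rng.normal(0, 1.5, 60)
        preds = np.clip(preds, 0.5, 33.0)
        once = parkes_report(refs, preds)
        twice = parkes_report(np.tile(refs, 2), np.tile(preds, 2))
        assert once == twice

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            parkes_report(np.array([]), np.array([]))


class TestAggregation:
    def _report(self):
        proto = EvaluationProtocol(30, "full_day")
        rng = np.random.default_rng(5)
        report = EvaluationReport(protocol=proto)
        for seed in (0, 1):
            for pid in ("P0", "P1"):
                refs = rng.uniform(5, 10, 30)
                from glucast.evaluation import EvalEntry

                report.entries.append(
                    EvalEntry(pid, seed, proto, refs, refs + rng.normal(0, 1, 30))
                )
        return report

    def test_pooled_versus_participant_average(self):
        report = self._report()
        pooled = report.pooled()
        avg = report.participant_average()
        assert pooled["rmse"][0] > 0
        # two-stage aggregation: mean over per-participant seed-means
        frame = report.per_participant_frame()
        manual = frame.groupby("participant_id")["rmse"].mean().mean()
        assert avg["rmse"][0] == pytest.approx(manual)

    def test_standard_error_uses_sqrt_seed_count(self):
        report = self._report()
        frame = report.per_participant_frame()
        # recompute pooled per-seed metrics by hand
        per_seed = []
        for s in (0, 1):
            sel = [e for e in report.entries if e.seed == s]
            refs = np.concatenate([e.references for e in sel])
            preds = np.concatenate([e.predictions for e in sel])
            per_seed.append(rmse(refs, preds))
        per_seed = np.array(per_seed)
        expected_se = per_seed.std(ddof=0) / np.sqrt(2)
        assert report.pooled()["rmse"][1] == pytest.approx(expected_se)
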