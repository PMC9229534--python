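"""Dataset assembly, splits, R², Model/Results API, search and evaluation."""

import numpy as np
import pandas as pd
import pytest

from gaitmyo.emg import BodyMetrics
from gaitmyo.errors import DataError, NumericalError
from gaitmyo.model import (
    FEATURES,
    Hyperparams,
    ANNResults,
    MuscleActivityANN,
    assemble_dataset,
    evaluate_repeated,
    grid_search,
    r_squared,
    split_dataset,
)
from gaitmyo.simulate import simulate_feature_dataset


def _stride_records(n=10):
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "cycle_index": np.arange(n),
            "l_stride": rng.normal(1.2, 0.1, n),
            "a_peak": rng.normal(2.0, 0.2, n),
            "omega_peak": rng.normal(300, 20, n),
            "v_peak": rng.normal(3.0, 0.3, n),
            "stance_time": rng.normal(0.3, 0.02, n),
            "swing_time": rng.normal(0.2, 0.02, n),
        }
    )


def _targets(n=10):
    rows = []
    for muscle in ("RFM", "OGM"):
        for i in range(n):
            rows.append((i, 10.0 + i, 20.0 + i, muscle))
    return pd.DataFrame(rows, columns=["cycle_index", "mvc_avg", "mvc_peak", "muscle"])


class TestAssemble:
    def test_ten_paired_cycles(self):
        df = assemble_dataset(_stride_records(), _targets(), BodyMetrics(21.5, 0.43))
        assert len(df) == 10
        assert [c for c in FEATURES if c in df.columns] == FEATURES
        assert set(df["bmi"]) == {21.5}  # body metrics broadcast

    def test_missing_target_drops_row(self):
        tg = _targets()
        tg = tg[~((tg["cycle_index"] == 3) & (tg["muscle"] == "OGM"))]
        df = assemble_dataset(_stride_records(), tg, BodyMetrics(21.5, 0.43))
        assert len(df) == 9
        assert df.attrs["n_dropped"] == 1

    def test_no_overlap_is_error(self):
        tg = _targets()
        tg["cycle_index"] += 100
        with pytest.raises(DataError):
            assemble_dataset(_stride_records(), tg, BodyMetrics(21.5, 0.43))


class TestSplit:
    def test_eighty_twenty(self, feature_df):
        tr, val = split_dataset(feature_df.head(100), ratio=0.8, seed=0)
        assert (len(tr), len(val)) == (80, 20)

    def test_deterministic_disjoint_exhaustive(self, feature_df):
        df = feature_df.head(97)
        tr1, v1 = split_dataset(df, seed=5)
        tr2, v2 = split_dataset(df, seed=5)
        assert tr1.index.tolist() == tr2.index.tolist()
        assert set(tr1.index).isdisjoint(v1.index)
        assert set(tr1.index) | set(v1.index) == set(df.index)

    def test_too_few_rows(self, feature_df):
        with pytest.raises(DataError):
            split_dataset(feature_df.head(4))


class TestRSquared:
    def test_perfect_fit_in_both_modes(self, rng):
        y = rng.normal(size=30)
        assert r_squared(y, y, "standard") == pytest.approx(1.0)
        assert r_squared(y, y, "as-printed") == pytest.approx(1.0)

    def test_null_model_scores_zero(self, rng):
        obs = rng.normal(size=50)
        est = np.full(50, obs.mean())
        assert r_squared(est, obs, "standard") == pytest.approx(0.0)

    def test_direct_evaluation(self):
        obs = [1.0, 2.0, 3.0]
        est = [1.1, 1.9, 3.2]
        assert r_squared(est, obs) == pytest.approx(1 - 0.06 / 2)

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(NumericalError):
            r_squared([1.0, 2.0], [5.0, 5.0], "standard")

    def test_joint_permutation_invariance(self, rng):
        est, obs = rng.normal(size=40), rng.normal(size=40)
        perm = rng.permutation(40)
        assert r_squared(est, obs) == pytest.approx(r_squared(est[perm], obs[perm]), rel=1e-12)


class TestModelAPI:
    def test_fit_predict_and_summary(self, feature_df):
        tr = feature_df.head(400)
        hp = Hyperparams(n_hidden_layers=2, n_units=16, epochs=150, seed=1)
        res = MuscleActivityANN.from_dataframe(tr, "mvc_avg_ogm", hyperparams=hp).fit()
        assert res.rsquared > 0.5
        text = res.summary()
        assert "mvc_avg_ogm" in text and "Parameters:" in text
        # permuting rows permutes predictions identically
        pred = res.predict(tr)
        perm = np.random.default_rng(0).permutation(len(tr))
        np.testing.assert_allclose(res.predict(tr.iloc[perm]), pred[perm], rtol=1e-12)
        # single-row prediction works
        assert res.predict(tr.head(1)).shape == (1,)

    def test_missing_feature_column_raises(self, feature_df):
        res = MuscleActivityANN.from_dataframe(
            feature_df.head(100), "mvc_avg_rfm",
            hyperparams=Hyperparams(n_hidden_layers=1, n_units=4, epochs=5, seed=0),
        ).fit()
        with pytest.raises(DataError, match="missing columns"):
            res.predict(feature_df.head(5).drop(columns=["a_peak"]))

    def test_plot_fit_returns_axes(self, feature_df):
        import matplotlib

        matplotlib.use("Agg")
        res = MuscleActivityANN.from_dataframe(
            feature_df.head(120), "mvc_avg_rfm",
            hyperparams=Hyperparams(n_hidden_layers=1, n_units=4, epochs=10, seed=0),
        ).fit()
        ax = res.plot_fit()
        assert ax.get_xlabel().startswith("observed")

    def test_save_load_roundtrip(self, feature_df, tmp_path):
        tr = feature_df.head(200)
        hp = Hyperparams(n_hidden_layers=2, n_units=8, epochs=40, seed=3)
        res = MuscleActivityANN.from_dataframe(tr, "mvc_peak_ogm", hyperparams=hp).fit()
        res.save(tmp_path / "m.json")
        back = ANNResults.load(tmp_path / "m.json")
        np.testing.assert_allclose(back.predict(tr), res.predict(tr), rtol=1e-12)


class TestSearchAndEvaluation:
    def test_single_point_grid_returns_that_point(self, feature_df):
        hp = Hyperparams(n_hidden_layers=1, n_units=6, epochs=30, seed=0)
        best, table = grid_search(
            {"n_units": [6]}, feature_df.head(200), "mvc_avg_ogm", n_repeats=2, base=hp
        )
        assert best.n_units == 6
        assert len(table) == 1

    def test_capacity_recovery_on_nonlinear_toy(self, feature_df):
        """A grid containing an adequate and a crippled architecture picks
        the adequate one on a nonlinear target."""
        hp = Hyperparams(n_hidden_layers=2, epochs=120, seed=0, dropout_rate=0.0)
        best, table = grid_search(
            {"n_units": [1, 16]}, feature_df.head(500), "mvc_peak_rfm",
            n_repeats=2, base=hp,
        )
        assert best.n_units == 16
        assert len(table) == 2

    def test_empty_grid_rejected(self, feature_df):
        with pytest.raises(DataError):
            grid_search({}, feature_df, "mvc_avg_rfm")

    def test_repeated_evaluation_shape_and_variance(self, feature_df):
        hp = Hyperparams(n_hidden_layers=2, n_units=16, epochs=120, seed=0)
        rep = evaluate_repeated(
            feature_df.head(600), hp, n_repeats=4, targets=["mvc_avg_ogm"]
        )
        assert len(rep.per_repeat) == 4
        assert set(rep.table.columns) >= {"target", "r2_mean", "r2_std"}
        assert rep.table["r2_std"].iloc[0] >= 0

    def test_r2_degrades_with_target_noise(self):
        """More target noise, lower attainable validation R² (checked at the
        extremes; adjacent levels can swap within Monte-Carlo error)."""
        hp = Hyperparams(n_hidden_layers=2, n_units=16, epochs=150, seed=0)
        scores = {}
        for frac in (0.05, 0.20, 0.50):
            df = simulate_feature_dataset(800, noise_frac=frac, seed=21)
            tr, val = split_dataset(df, seed=1)
            res = MuscleActivityANN.from_dataframe(tr, "mvc_avg_ogm", hyperparams=hp).fit()
            scores[frac] = res.rsquared_on(val)
        assert scores[0.05] > scores[0.20] + 0.02
        assert scores[0.20] > scores[0.50] + 0.02

    def test_dropout_helps_under_label_noise(self):
        """With 10% of training labels corrupted, the 20%-dropout model's
        validation R² stays within 0.05 of (or above) the no-dropout model."""
        df = simulate_feature_dataset(800, noise_frac=0.05, seed=31)
        tr, val = split_dataset(df, seed=2)
        tr = tr.copy()
        rng = np.random.default_rng(3)
        bad = rng.choice(len(tr), size=len(tr) // 10, replace=False)
        col = tr.columns.get_loc("mvc_avg_ogm")
        spread = tr["mvc_avg_ogm"].std() * 4
        tr.iloc[bad, col] += rng.normal(0, spread, bad.size)
        scores = {}
        for rate in (0.2, 0.0):
            hp = Hyperparams(dropout_rate=rate, epochs=300, seed=5)
            res = MuscleActivityANN.from_dataframe(tr, "mvc_avg_ogm", hyperparams=hp).fit()
            scores[rate] = res.rsquared_on(val)
        assert scores[0.2] >= scores[0.0] - 0.05
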