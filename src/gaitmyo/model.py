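"""Per-cycle muscle-activity regression.

The estimation problem: map eight per-cycle predictors — swing-phase peak
acceleration ‖a‖ (G), peak angular velocity ‖ω‖ (deg/s), peak horizontal
velocity (m/s), stride length (m), stance and swing durations (s), BMI
(kg/m²) and the lower-limb length ratio — to a %MVC activity target (cycle
average or cycle peak, for the rectus femoris or the lateral
gastrocnemius).  One single-output network is fitted per target so the four
reported accuracies stay independent.

The API follows the Model/Results convention: construct
:class:`MuscleActivityANN` from arrays or a dataframe, call :meth:`fit`, and
read estimates, R² and diagnostics off the returned :class:`ANNResults`.
Features (and, internally, the target) are z-scored with statistics from
the fitting data only; predictions are returned on the original %MVC scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, NumericalError
from .nn import MLP, Hyperparams, build_network, train_network
from .simulate import FEATURES, TARGETS

__all__ = [
    "FEATURES",
    "TARGETS",
    "Hyperparams",
    "MuscleActivityANN",
    "ANNResults",
    "EvalReport",
    "assemble_dataset",
    "split_dataset",
    "r_squared",
    "grid_search",
    "evaluate_repeated",
]


def assemble_dataset(
    stride_records: pd.DataFrame,
    activity_targets: pd.DataFrame,
    body: "BodyMetrics | None" = None,
) -> pd.DataFrame:
    """Join kinematic records with %MVC targets into one row per cycle.

    ``stride_records`` comes from the gait chain (one row per retained
    stride, keyed by ``cycle_index``); ``activity_targets`` from the EMG
    chain (rows per cycle and muscle, columns mvc_avg/mvc_peak/muscle).
    Body metrics broadcast to every row.  Rows with any missing value are
    dropped (their count is recorded in ``df.attrs['n_dropped']``); an
    empty result is an error.
    """
    wide = activity_targets.pivot_table(
        index="cycle_index", columns="muscle", values=["mvc_avg", "mvc_peak"]
    )
    wide.columns = [f"{stat}_{muscle.lower()}" for stat, muscle in wide.columns]
    df = stride_records.merge(wide.reset_index(), on="cycle_index", how="inner")
    if body is not None:
        df["bmi"] = body.bmi
        df["lower_limb_ratio"] = body.lower_limb_ratio
    cols = ["cycle_index"] + [c for c in FEATURES if c in df.columns] + [
        c for c in TARGETS if c in df.columns
    ]
    df = df[cols]
    n_before = len(df)
    df = df.dropna().reset_index(drop=True)
    df.attrs["n_dropped"] = n_before - len(df)
    if df.empty:
        raise DataError("no usable cycles after joining features with targets")
    return df


def split_dataset(
    table: pd.DataFrame, ratio: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded 8:2 (by default) row split into training and validation sets.

    Rows are sampled uniformly without replacement; the two parts are
    disjoint and exhaustive, and a fixed seed reproduces the same split.
    """
    if not 0.0 < ratio < 1.0:
        raise DataError(f"split ratio must lie in (0, 1), got {ratio}")
    if len(table) < 5:
        raise DataError(f"need at least 5 rows to split, got {len(table)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    n_train = int(round(ratio * len(table)))
    return (
        table.iloc[np.sort(perm[:n_train])].copy(),
        table.iloc[np.sort(perm[n_train:])].copy(),
    )


def r_squared(estimates: np.ndarray, observed: np.ndarray, mode: str = "standard") -> float:
    """Coefficient of determination.

    ``standard``: 1 − Σ(est−obs)² / Σ(obs−mean(obs))².  ``as-printed``
    follows the variant definition that normalizes by the spread of the
    *estimates*, 1 − Σ(est−obs)² / Σ(est−mean(est))² — almost certainly a
    typographical slip in its source, but kept selectable; both agree at a
    perfect fit.  A zero denominator (constant reference series) makes the
    statistic undefined and raises :class:`NumericalError`.
    """
    est = np.asarray(estimates, dtype=float).reshape(-1)
    obs = np.asarray(observed, dtype=float).reshape(-1)
    if est.shape != obs.shape or est.size == 0:
        raise DataError(f"estimates/observed must be equal non-empty lengths, got {est.size}/{obs.size}")
    if mode == "standard":
        denom = float(np.sum((obs - obs.mean()) ** 2))
    elif mode == "as-printed":
        denom = float(np.sum((est - est.mean()) ** 2))
    else:
        raise DataError(f"mode must be 'standard' or 'as-printed', got {mode!r}")
    if denom == 0.0:
        raise NumericalError("R² undefined: zero variance in the reference series")
    return 1.0 - float(np.sum((est - obs) ** 2)) / denom


class MuscleActivityANN:
    """Feed-forward regression of one per-cycle %MVC target.

    Parameters
    ----------
    endog : (n,) target values (%MVC)
    exog : (n, k) feature matrix
    hyperparams : network/training configuration (defaults to the tuned
        7×12 relu / Adam / log-cosh / 20%-dropout combination)
    feature_names, target_name : labels for summaries and dataframe predict
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        hyperparams: Hyperparams | None = None,
        feature_names: list[str] | None = None,
        target_name: str = "target",
    ) -> None:
        self.endog = np.asarray(endog, dtype=float).reshape(-1)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise DataError("endog and exog row counts differ")
        if not (np.all(np.isfinite(self.endog)) and np.all(np.isfinite(self.exog))):
            raise DataError("model inputs must be finite")
        self.hyperparams = hyperparams or Hyperparams()
        self.feature_names = feature_names or [f"x{i}" for i in range(self.exog.shape[1])]
        self.target_name = target_name

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        target: str,
        features: list[str] | None = None,
        hyperparams: Hyperparams | None = None,
    ) -> "MuscleActivityANN":
        features = features or [c for c in FEATURES if c in df.columns]
        missing = [c for c in features + [target] if c not in df.columns]
        if missing:
            raise DataError(f"dataframe is missing columns {missing}")
        return cls(
            endog=df[target].to_numpy(float),
            exog=df[features].to_numpy(float),
            hyperparams=hyperparams,
            feature_names=list(features),
            target_name=target,
        )

    def fit(self, seed: int | None = None, verbose: bool = False) -> "ANNResults":
        """Standardize on the fitting data, train, return results."""
        hp = self.hyperparams if seed is None else self.hyperparams.replace(seed=seed)
        x_mean = self.exog.mean(axis=0)
        x_scale = self.exog.std(axis=0)
        x_scale[x_scale == 0.0] = 1.0
        y_mean = float(self.endog.mean())
        y_scale = float(self.endog.std()) or 1.0
        Xs = (self.exog - x_mean) / x_scale
        ys = (self.endog - y_mean) / y_scale
        net = build_network(hp, n_features=self.exog.shape[1])
        net = train_network(net, Xs, ys, verbose=verbose)
        return ANNResults(
            model=self,
            net=net,
            x_mean=x_mean,
            x_scale=x_scale,
            y_mean=y_mean,
            y_scale=y_scale,
        )


@dataclass
class ANNResults:
    """Fitted network plus the normalization frozen at fit time."""

    model: MuscleActivityANN
    net: MLP
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float

    def predict(self, exog: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Estimates on the original %MVC scale; deterministic (no dropout)."""
        if isinstance(exog, pd.DataFrame):
            missing = [c for c in self.model.feature_names if c not in exog.columns]
            if missing:
                raise DataError(f"prediction input is missing columns {missing}")
            X = exog[self.model.feature_names].to_numpy(float)
        else:
            X = np.atleast_2d(np.asarray(exog, dtype=float))
        Xs = (X - self.x_mean) / self.x_scale
        return self.net.predict(Xs) * self.y_scale + self.y_mean

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def rsquared(self) -> float:
        """In-sample R² (standard definition)."""
        return r_squared(self.fittedvalues, self.model.endog)

    def rsquared_on(self, df: pd.DataFrame, mode: str = "standard") -> float:
        """Out-of-sample R² on a held-out dataframe carrying the target column."""
        return r_squared(
            self.predict(df), df[self.model.target_name].to_numpy(float), mode=mode
        )

    @property
    def n_epochs(self) -> int:
        return len(self.net.history.get("loss", []))

    def summary(self) -> str:
        hp = self.net.hyperparams
        lines = [
            "Muscle Activity ANN Results",
            "=" * 46,
            f"{'Target:':<22}{self.model.target_name}",
            f"{'Observations:':<22}{self.model.endog.size}",
            f"{'Features:':<22}{len(self.model.feature_names)}",
            f"{'Hidden layers:':<22}{hp.n_hidden_layers} x {hp.n_units} ({hp.activation})",
            f"{'Dropout:':<22}{hp.dropout_rate:.0%}",
            f"{'Optimizer / loss:':<22}{hp.optimizer} / {hp.loss}",
            f"{'Parameters:':<22}{self.net.n_parameters}",
            f"{'Epochs run:':<22}{self.n_epochs}",
            f"{'R² (fit data):':<22}{self.rsquared:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_fit(self, df: pd.DataFrame | None = None, ax=None):
        """Observed-vs-estimated scatter with the identity line.

        Plots the fitting data by default; pass a held-out dataframe (with
        the target column) to inspect validation behavior.
        """
        import matplotlib.pyplot as plt

        if df is None:
            obs, est = self.model.endog, self.fittedvalues
            label = "fit data"
        else:
            obs = df[self.model.target_name].to_numpy(float)
            est = self.predict(df)
            label = "held-out data"
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(obs, est, s=12, alpha=0.6, label=label)
        lims = [min(obs.min(), est.min()), max(obs.max(), est.max())]
        ax.plot(lims, lims, "k--", lw=1, label="identity")
        ax.set_xlabel(f"observed {self.model.target_name} (%MVC)")
        ax.set_ylabel("estimated (%MVC)")
        ax.set_title(f"R² = {r_squared(est, obs):.3f}")
        ax.legend(frameon=False)
        return ax

    # -- persistence (plain JSON so artifacts stay human-inspectable) -------
    def save(self, path: str | Path) -> None:
        hp = self.net.hyperparams
        payload = {
            "schema": "gaitmyo-ann-v1",
            "target": self.model.target_name,
            "features": self.model.feature_names,
            "hyperparams": hp.__dict__,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "weights": [w.tolist() for w in self.net.weights],
            "biases": [b.tolist() for b in self.net.biases],
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def load(path: str | Path) -> "ANNResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != "gaitmyo-ann-v1":
            raise DataError(f"{path}: not a gaitmyo model file")
        hp = Hyperparams(**payload["hyperparams"])
        weights = [np.array(w) for w in payload["weights"]]
        biases = [np.array(b) for b in payload["biases"]]
        net = MLP(
            weights=weights, biases=biases, hyperparams=hp,
            n_features=weights[0].shape[0],
        )
        stub = MuscleActivityANN(
            endog=np.zeros(2),
            exog=np.zeros((2, net.n_features)),
            hyperparams=hp,
            feature_names=payload["features"],
            target_name=payload["target"],
        )
        return ANNResults(
            model=stub,
            net=net,
            x_mean=np.array(payload["x_mean"]),
            x_scale=np.array(payload["x_scale"]),
            y_mean=payload["y_mean"],
            y_scale=payload["y_scale"],
        )


def train_model(
    train_table: pd.DataFrame,
    target: str,
    hyperparams: Hyperparams | None = None,
    features: list[str] | None = None,
) -> ANNResults:
    """Fit one target on a training table (thin wrapper over the Model API)."""
    if train_table.empty:
        raise DataError("training table is empty")
    return MuscleActivityANN.from_dataframe(
        train_table, target=target, features=features, hyperparams=hyperparams
    ).fit()


@dataclass
class EvalReport:
    """Repeated-split evaluation: per-target mean/std of validation R²."""

    table: pd.DataFrame  # columns: target, r2_mean, r2_std, gap_mean
    per_repeat: pd.DataFrame  # columns: target, repeat, seed, r2_train, r2_val

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:.3f}")


def evaluate_repeated(
    dataset: pd.DataFrame,
    hyperparams: Hyperparams | None = None,
    n_repeats: int = 20,
    targets: list[str] | None = None,
    features: list[str] | None = None,
    ratio: float = 0.8,
    seed: int = 0,
) -> EvalReport:
    """Repeat (seeded split → train → validate) and report R² mean ± std.

    Every repeat draws a fresh 8:2 split and fresh initial weights from its
    own derived seed; the report also carries the train-vs-validation gap,
    the overfitting diagnostic the dropout structure is meant to control.
    """
    if n_repeats < 2:
        raise DataError("n_repeats must be >= 2")
    hp = hyperparams or Hyperparams()
    targets = targets or [t for t in TARGETS if t in dataset.columns]
    if not targets:
        raise DataError("no target columns present in the dataset")
    rows = []
    for target in targets:
        for rep in range(n_repeats):
            rep_seed = (seed * 1000 + rep * 13 + 7) % (2**31)
            train, val = split_dataset(dataset, ratio=ratio, seed=rep_seed)
            res = MuscleActivityANN.from_dataframe(
                train, target=target, features=features, hyperparams=hp.replace(seed=rep_seed)
            ).fit()
            rows.append(
                {
                    "target": target,
                    "repeat": rep,
                    "seed": rep_seed,
                    "r2_train": res.rsquared,
                    "r2_val": res.rsquared_on(val),
                }
            )
    per = pd.DataFrame(rows)
    per["gap"] = (per["r2_train"] - per["r2_val"]).abs()
    table = (
        per.groupby("target", sort=False)
        .agg(
            r2_mean=("r2_val", "mean"),
            r2_std=("r2_val", lambda s: s.std(ddof=1)),
            gap_mean=("gap", "mean"),
        )
        .reset_index()
    )
    return EvalReport(table=table, per_repeat=per)


def grid_search(
    param_grid: dict[str, list],
    dataset: pd.DataFrame,
    target: str,
    n_repeats: int = 3,
    base: Hyperparams | None = None,
    features: list[str] | None = None,
    seed: int = 0,
) -> tuple[Hyperparams, pd.DataFrame]:
    """Exhaustive hyperparameter search scored by mean validation R².

    Every grid point is trained ``n_repeats`` times (distinct derived seeds,
    distinct splits) and scored by the mean validation R²; the full score
    table is returned alongside the winning configuration.
    """
    if not param_grid or any(len(v) == 0 for v in param_grid.values()):
        raise DataError("param_grid must map hyperparameter names to non-empty lists")
    base = base or Hyperparams()
    keys = list(param_grid)
    records = []
    best_score, best_hp = -np.inf, None
    for combo in product(*(param_grid[k] for k in keys)):
        hp = base.replace(**dict(zip(keys, combo)))
        scores = []
        for rep in range(n_repeats):
            rep_seed = (seed * 1000 + rep * 13 + 7) % (2**31)
            train, val = split_dataset(dataset, seed=rep_seed)
            res = MuscleActivityANN.from_dataframe(
                train, target=target, features=features, hyperparams=hp.replace(seed=rep_seed)
            ).fit()
            scores.append(res.rsquared_on(val))
        mean_score = float(np.mean(scores))
        records.append({**dict(zip(keys, combo)), "r2_mean": mean_score,
                        "r2_std": float(np.std(scores, ddof=1)) if n_repeats > 1 else 0.0})
        if mean_score > best_score:
            best_score, best_hp = mean_score, hp
    return best_hp, pd.DataFrame(records)
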