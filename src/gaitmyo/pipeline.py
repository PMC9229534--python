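"""End-to-end orchestration: session directory in, artifacts + report out.

Stage order mirrors the measurement chain: read session → per-stride
kinematic features → per-cycle %MVC targets → joined dataset → one trained
network per target → repeated-split evaluation.  Any stage failure aborts
with the stage name; re-running with identical inputs, configuration and
seed reproduces identical artifacts (all stochastic stages consume the
global seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .emg import body_metrics, emg_targets_for_session
from .errors import DataError
from .gait import detect_gait_events, extract_gait_features, stride_lengths
from .io import Session, read_session, write_session
from .model import TARGETS, MuscleActivityANN, evaluate_repeated, split_dataset, assemble_dataset
from .simulate import GaitSimParams, simulate_session


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)  # name, wall_ms, n_in, n_out
    config_hash: str = ""
    version: str = ""
    metrics: dict = field(default_factory=dict)

    def add(self, name: str, wall_ms: float, n_in: int, n_out: int) -> None:
        self.stages.append(
            {"stage": name, "wall_ms": round(wall_ms, 2), "n_in": n_in, "n_out": n_out}
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "stages": self.stages,
                "metrics": self.metrics,
            },
            indent=1,
        )


def _config_hash(cfg: PipelineConfig) -> str:
    blob = repr(cfg).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def simulate_to_dir(params: GaitSimParams, directory: str | Path) -> Path:
    """Write a simulated session plus its ground truth in the CSV dialect."""
    directory = Path(directory)
    session, truth = simulate_session(params)
    write_session(session, directory)
    n = truth.to_times.size
    gt = pd.DataFrame(
        {
            "cycle": np.arange(n),
            "hs": truth.hs_times[:-1],
            "ff": truth.ff_times,
            "to": truth.to_times,
            "ms": truth.ms_times,
            "next_hs": truth.hs_times[1:],
            "stride_length": truth.stride_lengths,
        }
    )
    gt.to_csv(directory / "ground_truth.csv", index=False)
    act = pd.DataFrame({"t": truth.emg_timestamps, **truth.activation})
    act.to_csv(directory / "activation.csv", index=False, float_format="%.6g")
    return directory


def compute_emg_targets(
    session: Session, cfg: PipelineConfig, features: pd.DataFrame
) -> pd.DataFrame:
    """Per-cycle %MVC targets for both muscles, paired to retained strides."""
    stream = session.imu("ankle")
    events = detect_gait_events(stream, cfg.gait)
    retained = features["cycle_index"].to_numpy()
    frames = []
    for muscle in ("RFM", "OGM"):
        walking = session.emg(muscle, mvc=False)
        mvc = session.emg(muscle, mvc=True)
        frames.append(
            emg_targets_for_session(
                walking, mvc, events.hs_times, retained_cycles=retained,
                window_ms=cfg.emg_window_ms,
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_pipeline(
    session_dir: str | Path,
    output_dir: str | Path,
    cfg: PipelineConfig | None = None,
    train_models: bool = True,
) -> RunReport:
    cfg = cfg or PipelineConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=_config_hash(cfg), version=__version__)

    t0 = time.perf_counter()
    session = read_session(session_dir)
    report.add("read_session", (time.perf_counter() - t0) * 1e3,
               0, len(session.imu_streams) + len(session.emg_streams))

    t0 = time.perf_counter()
    features = extract_gait_features(session, cfg.gait)
    features.to_csv(out / "features.csv", index=False)
    report.add("gait_features", (time.perf_counter() - t0) * 1e3,
               session.imu("ankle").n, len(features))

    t0 = time.perf_counter()
    targets = compute_emg_targets(session, cfg, features)
    targets.to_csv(out / "targets.csv", index=False)
    report.add("emg_targets", (time.perf_counter() - t0) * 1e3, len(features), len(targets))

    t0 = time.perf_counter()
    if session.body is None:
        raise DataError("session has no body measurements; cannot assemble model dataset")
    dataset = assemble_dataset(features, targets, body_metrics(session.body))
    dataset.to_csv(out / "dataset.csv", index=False)
    report.add("assemble", (time.perf_counter() - t0) * 1e3,
               len(features), len(dataset))

    if train_models:
        t0 = time.perf_counter()
        train, val = split_dataset(dataset, ratio=cfg.split_ratio, seed=cfg.seed)
        metrics = {}
        for target in [t for t in TARGETS if t in dataset.columns]:
            res = MuscleActivityANN.from_dataframe(
                train, target=target, hyperparams=cfg.model.replace(seed=cfg.seed)
            ).fit()
            res.save(out / f"model_{target}.json")
            metrics[target] = {
                "r2_train": res.rsquared,
                "r2_val": res.rsquared_on(val) if len(val) > 1 else None,
                "n_train": len(train),
                "n_val": len(val),
            }
        report.metrics = metrics
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
        report.add("train", (time.perf_counter() - t0) * 1e3, len(dataset), len(metrics))

    (out / "run_report.json").write_text(report.to_json())
    return report


def evaluate_dataset(
    dataset: pd.DataFrame, cfg: PipelineConfig, output_dir: str | Path | None = None
):
    """Repeated-split evaluation; optionally writes the report CSV."""
    rep = evaluate_repeated(
        dataset, hyperparams=cfg.model, n_repeats=cfg.eval_repeats,
        ratio=cfg.split_ratio, seed=cfg.seed,
    )
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        rep.table.to_csv(out / "evaluation.csv", index=False)
        rep.per_repeat.to_csv(out / "evaluation_repeats.csv", index=False)
    return rep
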