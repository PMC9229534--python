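"""Declarative pipeline configuration.

One YAML file configures every stage, with sections mirroring the module
boundaries::

    seed: 1
    gait:
      min_swing_peak: 80.0
      zero_interval: stance-only
      ekf:
        window_N: 40
        gyro_noise_var: 1.0
    emg:
      window_ms: 100.0
    model:
      n_hidden_layers: 7
      n_units: 12
      dropout_rate: 0.2

Unknown keys are rejected (a typo silently falling back to a default is the
worst failure mode for a measurement pipeline).  Precedence is CLI flag >
config file > built-in default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .gait import GaitConfig
from .nn import Hyperparams
from .orientation import EKFConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    gait: GaitConfig = field(default_factory=GaitConfig)
    emg_window_ms: float = 100.0
    model: Hyperparams = field(default_factory=Hyperparams)
    eval_repeats: int = 20
    split_ratio: float = 0.8


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}")
    return data


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` gives the built-in defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    allowed_top = {"seed", "gait", "emg", "model", "eval_repeats", "split_ratio"}
    unknown = set(raw) - allowed_top
    if unknown:
        raise ConfigError(f"{path}: unknown sections {sorted(unknown)}")

    gait_raw = dict(raw.get("gait", {}))
    ekf_raw = gait_raw.pop("ekf", {})
    try:
        ekf = EKFConfig(**_build(EKFConfig, ekf_raw, f"{path}:gait.ekf"))
        gait = GaitConfig(**_build(GaitConfig, gait_raw, f"{path}:gait"), ekf=ekf)
    except TypeError as exc:
        raise ConfigError(f"{path}: bad gait section ({exc})") from exc

    emg_raw = dict(raw.get("emg", {}))
    unknown = set(emg_raw) - {"window_ms"}
    if unknown:
        raise ConfigError(f"{path}: unknown emg keys {sorted(unknown)}")

    try:
        model = Hyperparams(**_build(Hyperparams, dict(raw.get("model", {})), f"{path}:model"))
    except TypeError as exc:
        raise ConfigError(f"{path}: bad model section ({exc})") from exc

    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        gait=gait,
        emg_window_ms=float(emg_raw.get("window_ms", 100.0)),
        model=model,
        eval_repeats=int(raw.get("eval_repeats", 20)),
        split_ratio=float(raw.get("split_ratio", 0.8)),
    )
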