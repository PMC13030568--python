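"""Run configuration: one YAML-backed object covering every pipeline stage.

Every preprocessing constant defaults to the framework's canonical value:
30 deg/s I-VT velocity threshold, 75-500 ms blink bounds, 150 ms
moving-window integration, sym8 wavelet at 8 levels, SMOTE k = 5, 60-s
windows, seed 42.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .model import BoostParams, ImbalanceConfig
from .synthetic import CohortConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    imbalance: ImbalanceConfig = field(default_factory=ImbalanceConfig)
    boost: BoostParams = field(default_factory=BoostParams)
    grid_rows: int = 4
    grid_cols: int = 8
    velocity_threshold: float = 30.0
    min_fix_dur_ms: float = 100.0
    window_s: float = 60.0
    n_cal: int = 30
    inner_folds: int = 5
    loso_inner_folds: int = 3
    test_size: float = 0.2
    seed: int = 42

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    for key, cls in (("cohort", CohortConfig), ("imbalance", ImbalanceConfig), ("boost", BoostParams)):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = cls(**kwargs[key])
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ValueError(f"{path}: invalid configuration ({exc})") from exc


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
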