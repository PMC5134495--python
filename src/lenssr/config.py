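"""Run configuration: YAML file handling with CLI-flag override precedence.

A single flat mapping of knobs shared by the command-line tools.  Unknown
keys are rejected so typos fail loudly, and the effective configuration is
echoed into every JSON report an invocation writes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # resampling
    t: int = 4
    kernel_a: float = -0.5
    antialias: bool = True
    # ELM engine
    elm_L: int = 20
    elm_C: float = 512.0
    # CNN engine
    cnn_n1: int = 64
    cnn_n2: int = 32
    cnn_f1: int = 5
    cnn_f2: int = 1
    cnn_f3: int = 3
    cnn_eta: float = 0.1
    cnn_iters: int = 2000
    cnn_momentum: float = 0.9
    cnn_init_sigma: float = 0.05
    # detection / counting
    detect_k: float = 4.0
    min_area: int = 4
    max_area: int = 400
    crop_size: int = 12
    velocity: float = 6.0
    gate_fraction: float = 0.5
    background: str = "first"
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def merged(self, overrides: Mapping[str, Any]) -> "RunConfig":
        """Return a copy with non-None overrides applied; reject unknown keys."""
        known = {f.name for f in fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: Optional[str | Path] = None, **overrides: Any) -> RunConfig:
    """Build the effective config: defaults < YAML file < explicit overrides."""
    cfg = RunConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = cfg.merged(data)
    return cfg.merged(overrides)
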