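"""YAML configuration loading for reproducible runs.

A single YAML file can carry ``net``, ``loss``, ``train``, ``postproc`` and
``scoring`` sections; each maps one-to-one onto the corresponding config
dataclass, so a run is fully described by one text file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .losses import LossConfig
from .net import NetConfig
from .postproc import PostprocConfig
from .scoring import ScoringConfig
from .train import TrainConfig
from .types import ValidationError


@dataclass
class Configs:
    net: NetConfig = field(default_factory=lambda: NetConfig(n_classes=3))
    train: TrainConfig = field(default_factory=TrainConfig)
    postproc: PostprocConfig = field(default_factory=PostprocConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)


_SECTIONS = {
    "net": NetConfig,
    "train": TrainConfig,
    "postproc": PostprocConfig,
    "scoring": ScoringConfig,
}


def load_configs(path: str | Path) -> Configs:
    """Build config dataclasses from a YAML file; unknown keys are errors."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValidationError("config file must contain a mapping")
    unknown = set(data) - set(_SECTIONS) - {"loss"}
    if unknown:
        raise ValidationError(f"unknown config sections: {sorted(unknown)}")
    out = Configs()
    for section, cls in _SECTIONS.items():
        if section in data:
            payload = dict(data[section] or {})
            if section == "net" and "input_shape" in payload:
                payload["input_shape"] = tuple(payload["input_shape"])
            try:
                setattr(out, section, cls(**payload))
            except TypeError as exc:
                raise ValidationError(f"bad {section} config: {exc}") from exc
    if "loss" in data:
        try:
            out.train.loss = LossConfig(**(data["loss"] or {}))
        except TypeError as exc:
            raise ValidationError(f"bad loss config: {exc}") from exc
    return out
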