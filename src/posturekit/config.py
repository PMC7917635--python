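"""Pipeline configuration: a single YAML document validated on load.

Unknown keys are rejected so typos fail loudly. ``default_config()`` returns
the fully populated defaults, and ``dump_config`` writes them back out, so a
user can start from ``posturekit config > pipeline.yaml`` and edit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import yaml

from .assessment import AlarmPolicy, MhtRuleSet, OwasRuleSet
from .types import PostureLabel


@dataclass
class PipelineConfig:
    rate: int = 25
    window_s: int = 1
    model_kind: str = "CLN"
    model: dict = field(default_factory=dict)
    split_fractions: tuple[float, float, float] = (0.72, 0.18, 0.10)
    seed: int = 0
    rounds: int = 5
    window_length: int = 1800  # individual assessment window, s
    interval_length: int = 1800  # jobsite interval, s
    mht_thresholds: dict = field(
        default_factory=lambda: {"BT": 60, "KN": 120, "SQ": 60, "WO": 60,
                                 "ST": None, "WK": None, "MO": None}
    )
    alarm_policy: str = "ONCE_PER_RUN"
    owas_bands: dict = field(
        default_factory=lambda: {c: [0.10, 0.30, 0.50] for c in ("BT", "KN", "SQ", "WO")}
    )
    awkward_set: list = field(default_factory=lambda: ["BT", "KN", "SQ", "WO"])
    # synthetic cohort
    n_workers: int = 6
    duration_s: int = 600

    def mht_rules(self) -> MhtRuleSet:
        return MhtRuleSet(
            thresholds={PostureLabel(k): v for k, v in self.mht_thresholds.items()},
            alarm_policy=AlarmPolicy(self.alarm_policy),
        )

    def owas_rules(self) -> OwasRuleSet:
        return OwasRuleSet(
            bands={PostureLabel(k): tuple(v) for k, v in self.owas_bands.items()},
            awkward_set=frozenset(PostureLabel(c) for c in self.awkward_set),
        )


def default_config() -> PipelineConfig:
    return PipelineConfig()


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw: Mapping[str, Any] = yaml.safe_load(fh) or {}
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    cfg = PipelineConfig(**raw)
    if isinstance(cfg.split_fractions, list):
        cfg.split_fractions = tuple(cfg.split_fractions)
    cfg.mht_rules()
    cfg.owas_rules()
    return cfg


def dump_config(cfg: PipelineConfig, path: str | None = None) -> str:
    text = yaml.safe_dump(asdict(cfg), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
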