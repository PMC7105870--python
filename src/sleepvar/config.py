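"""Run configuration: one structured object covering every pipeline stage.

Defaults equal the published analysis parameters wherever one exists
(7-day window, >=2-night filter, correlation threshold 0.7, VIF 10,
alpha grid step 0.05, 10 inner folds, 100 inner and 100 outer repetitions,
70/30 split, FDR 0.05).  Precedence: CLI flags > config file > defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .prediction import ElasticNetConfig


@dataclass
class ScoringConfig:
    rescoring_enabled: bool = True
    min_run_minutes: int = 20
    light_threshold: float | None = None
    overrides_file: str | None = None     # CSV: participant_id, date, start, end


@dataclass
class WindowConfig:
    span_days: int = 7
    min_nights: int = 2
    adjust_start: bool = False


@dataclass
class CohortSimConfig:
    n_asd: int = 139
    n_td: int = 34


@dataclass
class AssociationConfig:
    fdr: float = 0.05
    scales: tuple[str, ...] = ("abi_sleep", "srs2", "abc_irritability",
                               "abc_hyperactivity", "casi_anx")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results"
    log_level: str = "INFO"
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    elastic_net: ElasticNetConfig = field(default_factory=ElasticNetConfig)

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if hasattr(obj, "item"):       # numpy scalar
                return obj.item()
            return obj
        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, sub in (("cohort", CohortSimConfig), ("scoring", ScoringConfig),
                         ("window", WindowConfig), ("association", AssociationConfig),
                         ("elastic_net", ElasticNetConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sec = dict(kwargs[key])
                for k, v in sec.items():
                    if isinstance(v, list):
                        sec[k] = tuple(v)
                kwargs[key] = sub(**sec)
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
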