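"""Pipeline configuration: one YAML-serializable object holding every
threshold, band, seed and generator knob, echoed into the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .synthetic import GeneratorConfig

#: Diagnosis mix of the emulated study cohort (HV through progressive MS),
#: as exact fractions of the 164-subject composition.
STUDY_COUNTS = {
    "HV": 13,
    "NIND": 21,
    "OIND": 13,
    "RRMS": 68,
    "SPMS": 21,
    "PPMS": 23,
    "CIS": 4,
    "RIS": 1,
}
STUDY_MIX = {d: c / sum(STUDY_COUNTS.values()) for d, c in STUDY_COUNTS.items()}


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 60
    diagnosis_mix: dict = field(default_factory=lambda: dict(STUDY_MIX))
    n_trials: int = 2
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    sway_band: tuple = (0.15, 10.0)
    drift_band: tuple = (0.15, 15.0)
    icc_threshold: float = 0.5
    iqr_multiplier: float = 1.5
    alpha: float = 0.05
    train_fraction: float = 0.8
    pi_level: float = 0.95
    age_feature: str = "RMS_Net_EC-FT"
    sway_outcome: str = "neurex_postural_sway"
    drift_outcome: str = "cerebellar_dom"
    global_outcomes: tuple = ("edss", "combiwise", "neurex_total")
    sway_relevant: tuple = (
        "edss",
        "combiwise",
        "neurex_total",
        "neurex_postural_sway",
        "mri_infratentorial",
    )
    drift_relevant: tuple = (
        "edss",
        "combiwise",
        "neurex_total",
        "neurex_pronator_drift",
        "cerebellar_dom",
        "mri_infratentorial",
    )
    cohort_csv: str | None = None  # load instead of simulating when set
    trials_csv: str | None = None
    write_trials: bool = False  # raw trial CSVs are large; opt in

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode("utf8")).hexdigest()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        gen = data.pop("generator", {})
        if isinstance(gen, dict):
            gen = GeneratorConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in gen.items()
                }
            )
        cfg = cls(generator=gen, **data)
        for name in ("sway_band", "drift_band", "global_outcomes", "sway_relevant", "drift_relevant"):
            value = getattr(cfg, name)
            if isinstance(value, list):
                setattr(cfg, name, tuple(value))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=list)), fh)
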