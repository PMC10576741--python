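"""Pipeline configuration: one YAML (or JSON) file drives every stage.

The file has up to four blocks, all optional (defaults are the reference
study conditions)::

    generator:           # GeneratorConfig fields
      seed: 42
      animals_per_time: 5
    constants:           # StudyConstants fields
      v_body_ml: 167
      surface_area_cm2: 11.2
    estimation:
      n_boot: 200
      seed: 0
      pin_intercept: false
      weighted: false
    report:
      sig_figs: 3
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .datagen import GeneratorConfig
from .exceptions import ValidationError
from .model import StudyConstants

__all__ = ["EstimationSettings", "ReportSettings", "PipelineConfig"]


@dataclass
class EstimationSettings:
    n_boot: int = 200
    seed: int = 0
    pin_intercept: bool = False
    weighted: bool = False

    def validate(self) -> None:
        if self.n_boot != 0 and self.n_boot < 100:
            raise ValidationError(f"n_boot must be 0 or >= 100, got {self.n_boot}")


@dataclass
class ReportSettings:
    sig_figs: int = 3

    def validate(self) -> None:
        if self.sig_figs < 1:
            raise ValidationError(f"sig_figs must be >= 1, got {self.sig_figs}")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    constants: StudyConstants = field(default_factory=StudyConstants)
    estimation: EstimationSettings = field(default_factory=EstimationSettings)
    report: ReportSettings = field(default_factory=ReportSettings)

    def validate(self) -> None:
        self.generator.validate()
        self.constants.validate()
        self.estimation.validate()
        self.report.validate()
        if self.constants.t_max_fit_min > max(self.generator.times):
            raise ValidationError(
                "t_max_fit_min exceeds the largest sampling time "
                f"({self.constants.t_max_fit_min} > {max(self.generator.times)})"
            )

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "constants": asdict(self.constants),
            "estimation": asdict(self.estimation),
            "report": asdict(self.report),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        unknown = set(d) - {"generator", "constants", "estimation", "report"}
        if unknown:
            raise ValidationError(f"unknown config block(s): {sorted(unknown)}")

        def _build(klass, block, name):
            block = dict(block or {})
            known = set(klass.__dataclass_fields__)
            bad = set(block) - known
            if bad:
                raise ValidationError(f"unknown {name} field(s): {sorted(bad)}")
            return klass(**block)

        return cls(
            generator=GeneratorConfig.from_dict(d.get("generator") or {}),
            constants=_build(StudyConstants, d.get("constants"), "constants"),
            estimation=_build(EstimationSettings, d.get("estimation"), "estimation"),
            report=_build(ReportSettings, d.get("report"), "report"),
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from YAML (JSON is a YAML subset and parses too)."""
        text = Path(path).read_text(encoding="utf-8")
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ValidationError(f"cannot parse config {path}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValidationError(f"config {path} must be a mapping at the top level")
        cfg = cls.from_dict(data)
        cfg.validate()
        return cfg
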