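"""One run configuration holding generator, threshold, window and report options.

The YAML layout mirrors the dataclasses::

    generator:
      n_episodes_a: 410
      seed: 0
      archetype_mix: {STABLE_HIGH: 0.45, DIP_RECOVER: 0.30, ...}
      visit_schedule: [[-30, 25], [45, 20], ...]
    thresholds:
      index_red: 0.75
      index_green: 0.85
    windows:
      M12: {lower: 180, upper: 365, target: 270}
      BASELINE: {lower: -90, upper: 14, target: 0, fallback: [15, 90]}
    report:
      escalate_on_deterioration: true
      exclude_unknown_from_tests: true
      covariates: [sex, margin_status]

Omitted keys keep their defaults, which are the study's prespecified values
(thresholds and windows) or the generator's emulated study conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .synthetic_cohort import GeneratorConfig
from .traffic_light import Thresholds
from .window_engine import DEFAULT_WINDOWS, Timepoint, WindowSpec


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    windows: dict[Timepoint, WindowSpec] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    escalate_on_deterioration: bool = True
    exclude_unknown_from_tests: bool = True
    covariates: tuple[str, ...] = ("sex", "margin_status", "metastasis_at_dx")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping at the top level")
        cfg = cls()

        gen = raw.get("generator", {})
        if gen:
            known = {f.name for f in dataclasses.fields(GeneratorConfig)}
            bad = set(gen) - known
            if bad:
                raise ConfigError(f"unknown generator fields: {sorted(bad)}")
            if "visit_schedule" in gen:
                gen["visit_schedule"] = tuple(
                    (float(t), float(sd)) for t, sd in gen["visit_schedule"]
                )
            if "archetype_mix" in gen:
                gen["archetype_mix"] = dict(gen["archetype_mix"])
            cfg.generator = dataclasses.replace(cfg.generator, **gen)
            cfg.generator.validate()

        thr = raw.get("thresholds", {})
        if thr:
            known = {f.name for f in dataclasses.fields(Thresholds)}
            bad = set(thr) - known
            if bad:
                raise ConfigError(f"unknown threshold fields: {sorted(bad)}")
            try:
                cfg.thresholds = dataclasses.replace(cfg.thresholds, **thr)
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc

        for name, spec in (raw.get("windows") or {}).items():
            try:
                tp = Timepoint(name)
            except ValueError as exc:
                raise ConfigError(f"unknown window name {name!r}") from exc
            fallback = spec.get("fallback")
            try:
                cfg.windows[tp] = WindowSpec(
                    name=tp,
                    lower=int(spec["lower"]),
                    upper=int(spec["upper"]),
                    target=int(spec["target"]),
                    fallback=tuple(int(v) for v in fallback) if fallback else None,
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"invalid window spec for {name}: {exc}") from exc

        rep = raw.get("report", {})
        if "escalate_on_deterioration" in rep:
            cfg.escalate_on_deterioration = bool(rep["escalate_on_deterioration"])
        if "exclude_unknown_from_tests" in rep:
            cfg.exclude_unknown_from_tests = bool(rep["exclude_unknown_from_tests"])
        if "covariates" in rep:
            cfg.covariates = tuple(str(c) for c in rep["covariates"])
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "generator": {
                **dataclasses.asdict(self.generator),
                "visit_schedule": [list(v) for v in self.generator.visit_schedule],
                "archetype_mix": dict(self.generator.archetype_mix),
            },
            "thresholds": dataclasses.asdict(self.thresholds),
            "windows": {
                tp.value: {
                    "lower": spec.lower,
                    "upper": spec.upper,
                    "target": spec.target,
                    **({"fallback": list(spec.fallback)} if spec.fallback else {}),
                }
                for tp, spec in self.windows.items()
            },
            "report": {
                "escalate_on_deterioration": self.escalate_on_deterioration,
                "exclude_unknown_from_tests": self.exclude_unknown_from_tests,
                "covariates": list(self.covariates),
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
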