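"""Run configuration: one seeded, hashable description of a pipeline run."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import CalibrationTargets, IntakeMultipliers
from .costs import CostInputs
from .hall import HallParameters

__all__ = ["RunConfig", "default_config", "load_config"]

# Table 3 baseline 5-year totals (million 2019 USD) used for the bundled
# default cost inputs.
_DEFAULT_DIRECT_TOTAL = 26_591.0
_DEFAULT_INDIRECT_TOTAL = 17_944.0


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, under a single seed."""

    seed: int = 12345
    n: int = 6049
    scenario: str = "main_canada"
    targets: CalibrationTargets = field(default_factory=CalibrationTargets)
    hall: HallParameters = field(default_factory=HallParameters)
    pal: float = 1.6
    ecf_fraction: float = 0.22
    cutoff: float = 30.0
    n_boot: int = 1000
    baseline_cases_thousands: float = 26_174.0
    steady_prevalence: float = 0.378
    horizon_days: int = 1825
    dt_days: float = 1.0
    cost: CostInputs = field(
        default_factory=lambda: CostInputs.from_usd_totals(
            _DEFAULT_DIRECT_TOTAL, _DEFAULT_INDIRECT_TOTAL
        )
    )
    outdir: str = "results"

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed must be set explicitly (no silent nondeterminism)")
        self.targets.validate()
        self.cost.validate()
        from .scenarios import get_scenario

        get_scenario(self.scenario)  # raises KeyError for unknown names

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cost"]["deflator"] = {str(k): v for k, v in d["cost"]["deflator"].items()}
        return d

    @property
    def config_hash(self) -> str:
        """SHA-256 over the canonical config JSON (output dir excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        payload = json.dumps(d, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "targets" in d and isinstance(d["targets"], dict):
            t = dict(d["targets"])
            if "multipliers" in t and isinstance(t["multipliers"], dict):
                t["multipliers"] = IntakeMultipliers(**t["multipliers"])
            if "ses_probs" in t:
                t["ses_probs"] = tuple(t["ses_probs"])
            d["targets"] = CalibrationTargets(**t)
        if "hall" in d and isinstance(d["hall"], dict):
            d["hall"] = HallParameters(**d["hall"])
        if "cost" in d and isinstance(d["cost"], dict):
            c = dict(d["cost"])
            if "deflator" in c:
                c["deflator"] = {int(k): float(v) for k, v in c["deflator"].items()}
            d["cost"] = CostInputs(**c)
        return cls(**d)


def default_config(seed: int = 12345, **overrides) -> RunConfig:
    """The bundled default configuration (field overrides by keyword)."""
    cfg = RunConfig(seed=seed)
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise AttributeError(f"RunConfig has no field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def load_config(path) -> RunConfig:
    """Load a YAML config file; omitted keys keep their defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    cfg = RunConfig.from_dict(data)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    """Write a config back to YAML (full explicit form)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
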