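"""Run configuration for the command-line pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    model_path: str
    target: str
    model_format: str = "json"
    medium: dict[str, float] = field(default_factory=dict)
    sole_substrate: bool = False
    pathway_path: str | None = None
    delta: float = 1.0
    delta_overrides: dict[str, float] = field(default_factory=dict)
    wt_overrides: dict[str, list[float]] = field(default_factory=dict)
    mutant_overrides: dict[str, list[float]] = field(default_factory=dict)
    min_growth: float = 0.1
    wt_min_growth: float | None = None
    production_fraction: float = 1.0
    K_m: int = 10
    K_ko: int = 5
    use_maximal: bool = False
    solver: str = "highs"
    gap: float = 0.0
    time_limit: float | None = None
    pool_size: int = 1
    seed: int = 0
    output_dir: str = "fluxdesign_out"

    def validate(self) -> None:
        if self.delta <= 0 or any(d <= 0 for d in self.delta_overrides.values()):
            raise ValueError("flux-change threshold delta must be > 0")
        if not 0 <= self.gap < 1:
            raise ValueError("optimality gap must be in [0, 1)")
        if self.K_ko > self.K_m:
            raise ValueError(f"K_ko={self.K_ko} exceeds K_m={self.K_m}")
        if self.min_growth < 0:
            raise ValueError("min_growth must be >= 0")
        if not 0 < self.production_fraction <= 1:
            raise ValueError("production_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def delta_spec(self):
        if not self.delta_overrides:
            return self.delta
        # per-reaction thresholds fall back to the scalar default
        class _DeltaMap(dict):
            def __missing__(inner, key):  # noqa: N805
                return self.delta

        return _DeltaMap(self.delta_overrides)

    def manifest(self, extra: dict | None = None) -> dict:
        data = asdict(self)
        payload = json.dumps(data, sort_keys=True).encode()
        data["config_hash"] = hashlib.sha256(payload).hexdigest()[:16]
        data.update(extra or {})
        return data
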