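"""Run configuration: TOML parsing, defaults, strict key checking."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

STAGES = ("simulate", "respiro", "tpc", "kinematics", "sdi", "thermal")

_SECTION_DEFAULTS: dict[str, dict] = {
    "simulate": {
        "n_per_group": 12,
        "respiro_temps": [27.0, 29.0, 31.0],
        "exclusions_per_group": [3, 4, 4],
        "escape_temps": [25.0, 27.0, 29.0, 31.0],
        "n_escape_per_group": 12,
        "n_trials": 3,
        "respiro_total_duration_h": 24.0,
        "thermal_n_days": 30,
    },
    "respirometry": {
        "scaling_exponent": 0.89,
        "mo2_min_fraction": 0.10,
        "mo2_max_windows": 4,
        "mo2_max_span_s": 30.0,
    },
    "tpc": {
        "n_starts": 64,
        "n_boot": 999,
        "breadth_fraction": 0.8,
        "alpha": 0.05,
    },
    "kinematics": {
        "smooth_window": 5,
        "min_excursion_deg": 10.0,
    },
    "sdi": {
        "threshold": 3.0,
        "depth_min_m": 0.1,
        "depth_max_m": 1.5,
        "depth_step_m": 0.01,
        "fit_intercept": False,
    },
    "thermal": {
        "span_grid": [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
        "degree_grid": [1, 2],
        "n_folds": 5,
        "site": "Papetoai",
        "month": "November",
    },
}

_TOP_LEVEL = {"seed", "out_dir", "stages"} | set(_SECTION_DEFAULTS)


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run.

    Unknown keys anywhere in the file are rejected so typos never silently
    fall back to defaults; every effective parameter is echoed into the run
    manifest.
    """

    seed: int = 0
    out_dir: str = "out"
    stages: tuple = STAGES
    sections: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {}
        for name, defaults in _SECTION_DEFAULTS.items():
            given = dict(self.sections.get(name, {}))
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
            merged[name] = {**defaults, **given}
        extra = set(self.sections) - set(_SECTION_DEFAULTS)
        if extra:
            raise ValueError(f"unknown config sections: {sorted(extra)}")
        self.sections = merged
        bad_stages = set(self.stages) - set(STAGES)
        if bad_stages:
            raise ValueError(f"unknown stages: {sorted(bad_stages)}")

    def __getitem__(self, section: str) -> dict:
        return self.sections[section]

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        unknown = set(raw) - _TOP_LEVEL
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        sections = {k: v for k, v in raw.items() if k in _SECTION_DEFAULTS}
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "out")),
            stages=tuple(raw.get("stages", STAGES)),
            sections=sections,
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "stages": list(self.stages),
            **{k: dict(v) for k, v in self.sections.items()},
        }

    def digest(self) -> str:
        """Stable hash of every effective parameter."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
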