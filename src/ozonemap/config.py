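"""Serializable run configuration for the command-line pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

from ozonemap.interpolation import METHOD_ACRONYMS
from ozonemap.synthetic import FieldConfig


@dataclass
class RunConfig:
    """Everything one end-to-end run needs, YAML round-trippable."""

    season_start: date = date(2007, 4, 1)
    season_end: date = date(2007, 9, 30)
    daylight: tuple[int, int] = (8, 20)
    afternoon: tuple[int, int] = (12, 18)
    min_capture: float = 0.75
    correction_threshold: float = 0.90
    methods: tuple[str, ...] = METHOD_ACRONYMS
    metric: str = "seasonal_mean_ppb"
    idw_power: float = 2.0
    rbf_kernel: str = "thin_plate"
    variogram_model: str = "spherical"
    variogram_bins: int = 10
    refit_variogram: bool = True
    n_periods: int = 2
    seed: int = 0
    field: FieldConfig = field(default_factory=FieldConfig)

    def __post_init__(self) -> None:
        for name in ("min_capture", "correction_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        bad = [m for m in self.methods if m not in METHOD_ACRONYMS]
        if bad:
            raise ValueError(f"unknown methods {bad}; valid: {METHOD_ACRONYMS}")
        self.methods = tuple(self.methods)
        self.daylight = tuple(self.daylight)
        self.afternoon = tuple(self.afternoon)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("season_start", "season_end"):
            d[k] = d[k].isoformat()
        d["methods"] = list(self.methods)
        d["daylight"] = list(self.daylight)
        d["afternoon"] = list(self.afternoon)
        f = d["field"]
        f["extent"] = list(f["extent"])
        for k in ("season_start", "season_end"):
            f[k] = f[k].isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("season_start", "season_end"):
            if isinstance(d.get(k), str):
                d[k] = date.fromisoformat(d[k])
        if "field" in d and isinstance(d["field"], dict):
            f = dict(d["field"])
            f["extent"] = tuple(f.get("extent", FieldConfig.extent))
            for k in ("season_start", "season_end"):
                if isinstance(f.get(k), str):
                    f[k] = date.fromisoformat(f[k])
            d["field"] = FieldConfig(**f)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the canonical configuration."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
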