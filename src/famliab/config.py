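"""Simulation and run configuration objects, YAML-serialisable."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["SimulationConfig", "DEFAULT_DEATH_HAZARD"]

# Annual death probability by attained-age band (band start -> hazard).
# Coarse schedule: low in childhood/adulthood, rising sharply after 60.
DEFAULT_DEATH_HAZARD: dict[int, float] = {0: 0.001, 40: 0.004, 60: 0.015, 80: 0.10}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic population/patient-register simulation.

    The simulator draws nuclear families (two founders plus a Poisson number
    of children), assigns each person a liability under an additive
    liability-threshold model with heritability ``h2`` and prevalence
    ``prevalence_K``, and emits registry-style healthcare visit records for
    affected persons with era-appropriate diagnosis coding.

    Identical config and seed produce byte-identical output tables.
    """

    n_families: int = 1000
    h2: float = 0.4
    prevalence_K: float = 0.01
    mean_offspring: float = 2.0
    birth_year_range: tuple[int, int] = (1920, 1975)
    death_hazard: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DEATH_HAZARD)
    )
    region_count: int = 2
    mimic_rate: float = 0.0
    foreign_born_rate: float = 0.02
    subthreshold_fraction: float = 0.0
    dm_fraction: float = 0.33
    onset_age_range: tuple[int, int] = (16, 80)
    registry_window: tuple[int, int] = (1987, 2017)
    era_switch_year: int = 1997
    visit_interval_years: int = 2
    background_visit_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError(f"n_families must be >= 1, got {self.n_families}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if not 0.0 < self.prevalence_K < 1.0:
            raise ValueError(
                f"prevalence_K must be in (0, 1), got {self.prevalence_K}"
            )
        if self.mean_offspring < 0:
            raise ValueError("mean_offspring must be non-negative")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("birth_year_range must be (low, high)")
        if self.region_count < 1:
            raise ValueError("region_count must be >= 1")
        for name in ("mimic_rate", "foreign_born_rate", "subthreshold_fraction",
                     "dm_fraction", "background_visit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(h < 0 or h > 1 for h in self.death_hazard.values()):
            raise ValueError("death hazards must be probabilities")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["birth_year_range"] = list(self.birth_year_range)
        data["onset_age_range"] = list(self.onset_age_range)
        data["registry_window"] = list(self.registry_window)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("birth_year_range", "onset_age_range", "registry_window"):
            if key in data:
                data[key] = tuple(data[key])
        if "death_hazard" in data:
            data["death_hazard"] = {
                int(k): float(v) for k, v in data["death_hazard"].items()
            }
        return cls(**data)
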