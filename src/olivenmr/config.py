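"""Pipeline configuration: a declarative YAML mapping mirrored by CLI flags."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .synthetic import CohortDesign, FattyAcidProfile, default_design

__all__ = ["PipelineConfig", "load_config", "design_from_mapping"]


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Exactly one of ``input_paths`` (spectrum files) or ``simulation`` (a
    cohort design) must be given. The seed is always set (default 0) and is
    recorded in the run manifest.
    """

    input_paths: list[str] | None = None
    simulation: CohortDesign | None = None
    region_high: float = 10.00
    region_low: float = 0.50
    bucket_width: float = 0.04
    exclusions: tuple[tuple[float, float], ...] = ((7.6, 6.9),)
    normalization_target: float = 100.0
    outlier_alpha: float | None = 0.05
    outlier_components: int = 2
    pca_components: int = 10
    model: str | None = None  # "plsda" | "oplsda" | None
    model_by: str = "cultivar"  # metadata column used as the class
    n_components: int = 2
    n_ortho: int = 1
    cv_folds: int = 7
    n_permutations: int = 0
    quality_configurations: list[dict] = field(
        default_factory=lambda: [
            {"rule": "fixed_k", "value": 2},
            {"rule": "cumvar", "value": 0.99},
        ]
    )
    paired_cultivars: list[str] | None = None
    paired_cumvar: float = 0.99
    seed: int = 0
    output_dir: str = "olivenmr_out"

    def validate(self) -> "PipelineConfig":
        if (self.input_paths is None) == (self.simulation is None):
            raise ValueError(
                "PipelineConfig: exactly one of input_paths or simulation required"
            )
        return self

    def to_jsonable(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("simulation",)
        }
        d["exclusions"] = [list(e) for e in self.exclusions]
        if self.simulation is not None:
            sim = self.simulation
            d["simulation"] = {
                "cultivars": list(sim.cultivars),
                "plants_per_cultivar": sim.plants_per_cultivar,
                "harvests": list(sim.harvests),
                "base_profiles": {
                    c: dict(p.fractions) for c, p in sim.base_profiles.items()
                },
                "year_effects": {c: dict(v) for c, v in sim.year_effects.items()},
                "plant_effect_sd": sim.plant_effect_sd,
                "shift_jitter_sd": sim.shift_jitter_sd,
                "noise_sd": sim.noise_sd,
                "ppm_grid": [
                    float(sim.ppm_grid[0]),
                    float(sim.ppm_grid[-1]),
                    int(sim.ppm_grid.size),
                ],
                "seed": sim.seed,
            }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def design_from_mapping(mapping: dict[str, Any]) -> CohortDesign:
    """Build a CohortDesign from a YAML mapping; omitted fields fall back to
    the study-shaped defaults."""
    mapping = dict(mapping)
    if "base_profiles" in mapping:
        mapping["base_profiles"] = {
            c: FattyAcidProfile(v) for c, v in mapping["base_profiles"].items()
        }
    if "ppm_grid" in mapping:
        hi, lo, n = mapping["ppm_grid"]
        mapping["ppm_grid"] = np.linspace(hi, lo, int(n))
    if "cultivars" in mapping:
        mapping["cultivars"] = tuple(mapping["cultivars"])
    if "harvests" in mapping:
        mapping["harvests"] = tuple(mapping["harvests"])
    simple = {
        k: mapping.pop(k)
        for k in list(mapping)
        if k in ("plants_per_cultivar", "seed")
    }
    if set(mapping) <= {
        "plant_effect_sd",
        "shift_jitter_sd",
        "noise_sd",
        "ppm_grid",
        "cultivars",
        "harvests",
        "base_profiles",
        "year_effects",
    } and not {"cultivars", "base_profiles", "year_effects"} & set(mapping):
        return default_design(**simple, **mapping)
    required = {"cultivars", "harvests", "base_profiles", "year_effects"}
    if not required <= set(mapping):
        raise ValueError(
            "simulation mapping must either override only scalar fields or "
            f"provide all of {sorted(required)}"
        )
    return CohortDesign(**simple, **mapping)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "simulation" in raw and raw["simulation"] is not None:
        raw["simulation"] = design_from_mapping(raw["simulation"])
    if "exclusions" in raw:
        raw["exclusions"] = tuple(tuple(e) for e in raw["exclusions"])
    return PipelineConfig(**raw).validate()
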