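"""Synthetic single-tree olive-oil NMR cohort generator.

Emulates the statistical structure of a two-harvest, four-cultivar olive-oil
study sampled at the level of individual trees: each cultivar has a
characteristic triacylglycerol (TAG) acyl composition, each cultivar responds
to the harvest year with its own composition shift, and each tree (plant)
carries a random composition offset shared across both harvests (the paired
structure). Spectra are synthesized as sums of Lorentzian lines at the
canonical olive-oil acyl-chain chemical shifts, with per-spectrum peak
position jitter and additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocessing import Spectrum

__all__ = [
    "ACYL_COMPONENTS",
    "COMPONENTS",
    "PeakTemplate",
    "FattyAcidProfile",
    "CohortDesign",
    "SyntheticCohort",
    "build_component_library",
    "sample_profile",
    "render_spectrum",
    "generate_cohort",
    "default_design",
]

ACYL_COMPONENTS = ("oleic", "linoleic", "linolenic", "saturated")
COMPONENTS = ACYL_COMPONENTS + ("glycerol_backbone",)

# glycerol backbone: one per three acyl chains in a TAG
_GLYCEROL_FRACTION = 1.0 / 3.0

# Relative tree-to-tree variability per acyl component. Minor components vary
# far less in absolute terms than the dominant ones (a uniform absolute SD
# would imply >100% CV on linolenic and constant clipping at zero), so the
# per-component SD is plant_effect_sd times this profile.
PLANT_VARIABILITY_PROFILE = {
    "oleic": 1.0,
    "linoleic": 0.5,
    "linolenic": 0.1,
    "saturated": 0.67,
}


@dataclass(frozen=True)
class PeakTemplate:
    """One Lorentzian line: component assignment, center (ppm), area weight
    (proportional to proton count) and half-width at half-maximum (ppm)."""

    component: str
    center_shift: float
    relative_area: float
    halfwidth: float = 0.01

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"PeakTemplate: unknown component {self.component!r}")
        if self.halfwidth <= 0:
            raise ValueError("PeakTemplate: halfwidth must be positive")
        if self.relative_area <= 0:
            raise ValueError("PeakTemplate: relative_area must be positive")
        if not 0.3 <= self.center_shift <= 9.9:
            raise ValueError("PeakTemplate: center_shift must lie in [0.3, 9.9] ppm")


def build_component_library() -> list[PeakTemplate]:
    """Fixed line library for the five TAG components.

    Centers follow the canonical olive-oil assignments: olefinic protons near
    5.3-5.4, glycerol backbone 4.1-5.26, bis-allylic CH2 at 2.74 (linoleic)
    and 2.78 (linolenic), allylic CH2 near 2.0, chain methylenes at 1.30
    (unsaturated chains) / 1.26 (saturated chains), terminal CH3 near 0.9.
    Area weights are proportional to proton counts per acyl chain.
    """
    return [
        # oleic (C18:1, per chain)
        PeakTemplate("oleic", 5.34, 2.0),
        PeakTemplate("oleic", 2.02, 2.0),
        PeakTemplate("oleic", 1.98, 2.0),
        PeakTemplate("oleic", 1.30, 20.0),
        PeakTemplate("oleic", 0.88, 3.0),
        # linoleic (C18:2)
        PeakTemplate("linoleic", 5.34, 4.0),
        PeakTemplate("linoleic", 2.74, 2.0),
        PeakTemplate("linoleic", 2.02, 4.0),
        PeakTemplate("linoleic", 1.30, 14.0),
        PeakTemplate("linoleic", 0.89, 3.0),
        # linolenic (C18:3)
        PeakTemplate("linolenic", 5.38, 6.0),
        PeakTemplate("linolenic", 2.78, 4.0),
        PeakTemplate("linolenic", 2.06, 4.0),
        PeakTemplate("linolenic", 1.30, 8.0),
        PeakTemplate("linolenic", 0.90, 3.0),
        # saturated (palmitic/stearic-like)
        PeakTemplate("saturated", 1.60, 2.0),
        PeakTemplate("saturated", 1.26, 24.0),
        PeakTemplate("saturated", 0.88, 3.0),
        # glycerol backbone (per TAG)
        PeakTemplate("glycerol_backbone", 5.26, 1.0),
        PeakTemplate("glycerol_backbone", 4.28, 2.0),
        PeakTemplate("glycerol_backbone", 4.14, 2.0),
    ]


@dataclass(frozen=True)
class FattyAcidProfile:
    """TAG composition: proportion of each acyl component plus the fixed
    glycerol-backbone weight (one backbone per three chains)."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fractions", dict(self.fractions))

    def validate(self) -> "FattyAcidProfile":
        for name, value in self.fractions.items():
            if name not in COMPONENTS:
                raise ValueError(f"FattyAcidProfile: unknown component {name!r}")
            if value < 0:
                raise ValueError(f"FattyAcidProfile: negative proportion for {name!r}")
        total = sum(self.fractions.get(c, 0.0) for c in ACYL_COMPONENTS)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"FattyAcidProfile: acyl proportions sum to {total}, expected 1"
            )
        return self

    def acyl_vector(self) -> np.ndarray:
        return np.array([self.fractions.get(c, 0.0) for c in ACYL_COMPONENTS])

    @staticmethod
    def from_acyl(values: Sequence[float]) -> "FattyAcidProfile":
        fractions = dict(zip(ACYL_COMPONENTS, map(float, values)))
        fractions["glycerol_backbone"] = _GLYCEROL_FRACTION
        return FattyAcidProfile(fractions)


def _default_ppm_grid() -> np.ndarray:
    return np.linspace(10.2, 0.3, 16384)


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic two-harvest single-tree cohort.

    ``year_effect`` vectors (proportion units, per acyl component) apply to
    the second harvest only. ``plant_effect_sd`` is the SD of the zero-mean
    Gaussian per-component tree offsets, drawn once per tree and shared
    across both harvests. ``shift_jitter_sd`` (ppm) perturbs every line
    center per spectrum; ``noise_sd`` is additive intensity noise per point.
    """

    cultivars: tuple[str, ...]
    plants_per_cultivar: int
    harvests: tuple[str, str]
    base_profiles: Mapping[str, FattyAcidProfile]
    year_effects: Mapping[str, Mapping[str, float]]
    plant_effect_sd: float = 0.012
    shift_jitter_sd: float = 0.0005
    noise_sd: float = 0.005
    ppm_grid: np.ndarray = field(default_factory=_default_ppm_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cultivars", tuple(self.cultivars))
        object.__setattr__(self, "harvests", tuple(self.harvests))
        object.__setattr__(self, "ppm_grid", np.asarray(self.ppm_grid, dtype=float))
        if self.plants_per_cultivar < 2:
            raise ValueError("CohortDesign: plants_per_cultivar must be at least 2")
        if len(self.harvests) != 2:
            raise ValueError("CohortDesign: exactly two harvests required")
        if self.ppm_grid.size >= 2 and not np.all(np.diff(self.ppm_grid) < 0):
            raise ValueError("CohortDesign: ppm_grid must be strictly decreasing")
        for sd in (self.plant_effect_sd, self.shift_jitter_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("CohortDesign: sd parameters must be nonnegative")
        for cultivar in self.cultivars:
            if cultivar not in self.base_profiles:
                raise ValueError(f"CohortDesign: missing base profile for {cultivar!r}")
            self.base_profiles[cultivar].validate()


@dataclass
class SyntheticCohort:
    """Realized cohort: spectra, per-spectrum metadata and generative truth."""

    spectra: list[Spectrum]
    metadata: pd.DataFrame
    truth: dict

    def __len__(self) -> int:
        return len(self.spectra)


def default_design(
    plants_per_cultivar: int = 20,
    seed: int = 0,
    **overrides,
) -> CohortDesign:
    """Study-shaped default design: four cultivars, two harvests.

    Base compositions are stylized mono-varietal olive-oil profiles: the
    Coratina-like class oleic-rich, the Peranzana-like class PUFA-rich, the
    other two relatively saturated-rich. Year effects are sum-zero shifts
    (no renormalization distortion) acting mainly on the saturated/oleic
    balance; their magnitudes relative to the tree-to-tree variability are
    ordered coratina < peranzana < cimadimola < ogliarola (roughly
    1 : 1.9 : 2.3 : 2.8), so the Coratina-like class has the most stable
    profile across harvests.
    """
    base = {
        "coratina": FattyAcidProfile.from_acyl([0.760, 0.070, 0.007, 0.163]),
        "peranzana": FattyAcidProfile.from_acyl([0.680, 0.130, 0.012, 0.178]),
        "cimadimola": FattyAcidProfile.from_acyl([0.700, 0.090, 0.008, 0.202]),
        "ogliarola": FattyAcidProfile.from_acyl([0.710, 0.085, 0.009, 0.196]),
    }
    year_effects = {
        "coratina": {"saturated": -0.008, "oleic": 0.008},
        "peranzana": {"saturated": 0.014, "oleic": -0.013, "linolenic": -0.001},
        "cimadimola": {"saturated": -0.018, "oleic": 0.018},
        "ogliarola": {"saturated": 0.022, "oleic": -0.021, "linolenic": -0.001},
    }
    kwargs = dict(
        cultivars=("coratina", "cimadimola", "ogliarola", "peranzana"),
        plants_per_cultivar=plants_per_cultivar,
        harvests=("H1", "H2"),
        base_profiles=base,
        year_effects=year_effects,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


def sample_profile(
    design: CohortDesign,
    cultivar: str,
    harvest: str,
    plant_effect: Sequence[float],
) -> FattyAcidProfile:
    """Realize one tree-harvest TAG composition.

    base + year_effect (second harvest only) + plant_effect, clipped at zero
    and renormalized so acyl proportions sum to one.
    """
    if cultivar not in design.cultivars:
        raise ValueError(f"sample_profile: unknown cultivar {cultivar!r}")
    if harvest not in design.harvests:
        raise ValueError(f"sample_profile: unknown harvest {harvest!r}")
    vec = design.base_profiles[cultivar].acyl_vector()
    if harvest == design.harvests[1]:
        effect = design.year_effects.get(cultivar, {})
        vec = vec + np.array([effect.get(c, 0.0) for c in ACYL_COMPONENTS])
    vec = vec + np.asarray(plant_effect, dtype=float)
    vec = np.clip(vec, 0.0, None)
    total = vec.sum()
    if total <= 0:
        raise ValueError("sample_profile: all acyl proportions clipped to zero")
    return FattyAcidProfile.from_acyl(vec / total)


def _lorentzian(ppm: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Unit-area Lorentzian with half-width at half-maximum ``halfwidth``."""
    return (halfwidth / np.pi) / ((ppm - center) ** 2 + halfwidth**2)


def render_spectrum(
    profile: FattyAcidProfile,
    library: Sequence[PeakTemplate],
    design: CohortDesign,
    seed: int | np.random.Generator = 0,
    sample_id: str = "",
) -> Spectrum:
    """Synthesize one spectrum from a composition and the line library.

    intensity(d) = sum over lines of fraction(component) * relative_area *
    Lorentzian(d; center + jitter, halfwidth) + Gaussian noise. Deterministic
    for a fixed integer seed.
    """
    if design.ppm_grid.size == 0:
        raise ValueError("render_spectrum: ppm grid is empty")
    if not profile.fractions:
        raise ValueError("render_spectrum: empty profile")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ppm = design.ppm_grid
    intensity = np.zeros_like(ppm)
    jitter = rng.normal(0.0, design.shift_jitter_sd, size=len(library))
    for template, dj in zip(library, jitter):
        frac = profile.fractions.get(template.component, 0.0)
        if frac == 0.0:
            continue
        intensity += (
            frac
            * template.relative_area
            * _lorentzian(ppm, template.center_shift + dj, template.halfwidth)
        )
    intensity += rng.normal(0.0, design.noise_sd, size=ppm.size)
    return Spectrum(ppm=ppm, intensity=intensity, sample_id=sample_id)


def generate_cohort(design: CohortDesign) -> SyntheticCohort:
    """Generate the full paired cohort: one spectrum per tree per harvest.

    A tree's random composition offset is drawn once and reused in both
    harvests, so its two records differ only through the cultivar year
    effect, peak jitter and noise. Fully reproducible from ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    library = build_component_library()
    spectra: list[Spectrum] = []
    records: list[dict] = []
    truth_profiles: dict[tuple[str, str], FattyAcidProfile] = {}
    plant_effects: dict[str, np.ndarray] = {}
    for cultivar in design.cultivars:
        for p in range(design.plants_per_cultivar):
            plant_id = f"{cultivar}-P{p:03d}"
            sds = design.plant_effect_sd * np.array(
                [PLANT_VARIABILITY_PROFILE[c] for c in ACYL_COMPONENTS]
            )
            effect = rng.normal(0.0, 1.0, size=len(ACYL_COMPONENTS)) * sds
            plant_effects[plant_id] = effect
            for harvest in design.harvests:
                sample_id = f"{plant_id}-{harvest}"
                profile = sample_profile(design, cultivar, harvest, effect)
                truth_profiles[(plant_id, harvest)] = profile
                spectra.append(
                    render_spectrum(profile, library, design, seed=rng, sample_id=sample_id)
                )
                records.append(
                    {
                        "sample_id": sample_id,
                        "cultivar": cultivar,
                        "harvest": harvest,
                        "plant_id": plant_id,
                    }
                )
    metadata = pd.DataFrame.from_records(records)
    return SyntheticCohort(
        spectra=spectra,
        metadata=metadata,
        truth={"profiles": truth_profiles, "plant_effects": plant_effects},
    )
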