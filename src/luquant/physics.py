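"""Materials, attenuation, radioactive decay and intra-source attenuation.

Internal convention: lengths in mm, linear attenuation coefficients in
mm^-1; the material library stores mass attenuation coefficients in the
customary cm^2/g and densities in g/cm^3, and the conversion happens in
:func:`linear_attenuation`.

Depth identifiability of the multi-photopeak method rests on the ordering
mu(55) > mu(113) > mu(208) that holds for all soft-tissue-like materials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = [
    "Material",
    "AttenuationContext",
    "linear_attenuation",
    "mixture",
    "decay_correct",
    "intra_source_correction",
    "load_material_library",
    "get_material",
    "LU177_HALF_LIFE_S",
]

#: Lu-177 half-life (6.4 days) in seconds.
LU177_HALF_LIFE_S = 6.4 * 86400.0


@dataclass(frozen=True)
class Material:
    """A material with density (g/cm^3) and mu/rho (cm^2/g) per photopeak."""

    name: str
    density_g_cm3: float
    mass_attenuation_cm2_g: dict[int, float]   # photopeak label -> mu/rho

    def __post_init__(self) -> None:
        if not self.density_g_cm3 > 0:
            raise ValidationError(f"material {self.name!r}: density must be positive")
        for e, v in self.mass_attenuation_cm2_g.items():
            if not v >= 0:
                raise ValidationError(
                    f"material {self.name!r}: mu/rho at {e} keV must be non-negative")


@dataclass(frozen=True)
class AttenuationContext:
    """Linear attenuation coefficients mu_i in mm^-1 per photopeak label."""

    mu_mm: dict[int, float]

    def __getitem__(self, label: int) -> float:
        return self.mu_mm[label]

    @property
    def labels(self) -> list[int]:
        return list(self.mu_mm)


def linear_attenuation(material: Material,
                       photopeaks: list[int] | None = None) -> AttenuationContext:
    """mu_i = density * (mu/rho)_i, converted from cm^-1 to mm^-1."""
    labels = photopeaks if photopeaks is not None else list(material.mass_attenuation_cm2_g)
    mu = {}
    for lab in labels:
        if lab not in material.mass_attenuation_cm2_g:
            raise ValidationError(
                f"material {material.name!r} has no mu/rho entry at {lab} keV")
        mu[lab] = material.density_g_cm3 * material.mass_attenuation_cm2_g[lab] / 10.0
    return AttenuationContext(mu_mm=mu)


def mixture(components: list[tuple[Material, float]], name: str | None = None) -> Material:
    """Mass-fraction mixture of materials.

    mu/rho mixes linearly in mass fractions; the mixture density follows the
    mass-weighted inverse-density (volume-additivity) rule
    1/rho = sum_j w_j / rho_j.
    """
    if not components:
        raise ValidationError("mixture requires at least one component")
    fracs = [w for _, w in components]
    if any(w < 0 for w in fracs):
        raise ValidationError("mass fractions must be non-negative")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValidationError(f"mass fractions must sum to 1, got {sum(fracs)}")

    labels = set(components[0][0].mass_attenuation_cm2_g)
    for m, _ in components[1:]:
        labels &= set(m.mass_attenuation_cm2_g)
    if not labels:
        raise ValidationError("mixture components share no photopeak entries")

    mu_rho = {lab: sum(w * m.mass_attenuation_cm2_g[lab] for m, w in components)
              for lab in sorted(labels)}
    inv_density = sum(w / m.density_g_cm3 for m, w in components)
    if name is None:
        name = "+".join(f"{m.name}:{w:g}" for m, w in components)
    return Material(name=name, density_g_cm3=1.0 / inv_density,
                    mass_attenuation_cm2_g=mu_rho)


def decay_correct(activity_mbq: float, dt_s: float,
                  half_life_s: float = LU177_HALF_LIFE_S) -> float:
    """Decay-correct an activity over a signed time offset.

    ``dt_s > 0`` corrects back to a reference time ``dt_s`` seconds earlier
    than the measurement (multiplies by 2^(dt/T_half)); ``dt_s < 0`` decays
    forward.
    """
    if not half_life_s > 0:
        raise ValidationError("half-life must be positive")
    return activity_mbq * 2.0 ** (dt_s / half_life_s)


def _slab_self_attenuation(mu_mm: float, thickness_mm: float) -> float:
    """Mean transmission of a uniform slab source of given thickness.

    f(T) = (1 - exp(-mu T)) / (mu T), the average over emission depths of
    the exponential attenuation along the viewing axis; f(0) = 1.
    """
    x = mu_mm * thickness_mm
    if x < 1e-8:
        return 1.0 - x / 2.0   # series limit, avoids 0/0
    return -math.expm1(-x) / x


def intra_source_correction(mu_mm: float, thickness_measured_mm: float,
                            thickness_calibration_mm: float) -> float:
    """Correction factor for differing intra-source attenuation.

    The camera's depth convention is the collimator-to-nearest-surface
    distance, so self-attenuation within the source volume is part of the
    calibrated sensitivity.  When the measured object's thickness differs
    from the calibration source's, the estimated activity is multiplied by
    f(T_cal) / f(T_meas), with f the uniform-slab self-attenuation factor
    (a slab-geometry interpretation; the actual sources are cylinders and
    spheres, see docs/methods.md).
    """
    if mu_mm < 0:
        raise ValidationError("mu must be non-negative")
    if thickness_measured_mm < 0 or thickness_calibration_mm < 0:
        raise ValidationError("source thicknesses must be non-negative")
    return (_slab_self_attenuation(mu_mm, thickness_calibration_mm)
            / _slab_self_attenuation(mu_mm, thickness_measured_mm))


# ---------------------------------------------------------------------------
# Material library
# ---------------------------------------------------------------------------

def _parse_library(d: dict) -> dict[str, Material]:
    out = {}
    for name, spec in d["materials"].items():
        out[name] = Material(
            name=name,
            density_g_cm3=float(spec["density_g_cm3"]),
            mass_attenuation_cm2_g={int(k): float(v)
                                    for k, v in spec["mass_attenuation"].items()},
        )
    return out


def load_material_library(user_path: str | Path | None = None) -> dict[str, Material]:
    """Built-in material library, optionally merged with a user YAML file.

    User entries with the same name override built-ins.
    """
    text = resources.files("luquant.data").joinpath("materials.yaml").read_text()
    lib = _parse_library(yaml.safe_load(text))
    if user_path is not None:
        lib.update(_parse_library(yaml.safe_load(Path(user_path).read_text())))
    return lib


def get_material(name: str) -> Material:
    lib = load_material_library()
    if name not in lib:
        raise ValidationError(
            f"unknown material {name!r}; available: {sorted(lib)}")
    return lib[name]
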