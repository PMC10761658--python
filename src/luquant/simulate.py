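"""Synthetic measurements from the forward model with Poisson noise.

The generator emulates the three characterization/measurement types the
quantification chain consumes, so the whole pipeline is testable without
instrument data:

* in-air sensitivity series (known activity at distances 0-160 mm),
* fixed-distance PMMA build-up series (thicknesses 0-90 mm),
* single measurements — either window count rates directly, or a full
  16 x 16 x 2500 per-pixel spectral image.

Scatter is injected through an explicit per-window scatter fraction: the
main window receives `frac * R_primary` extra counts and the two abutting
scatter windows are populated so that the TEW trapezoid estimate equals the
injected scatter in expectation.  This makes TEW exactly unbiased here — an
idealization; real CZT spectra add low-energy tailing that TEW does not
fully remove.  No detector physics (tailing, septal-penetration star
patterns) is modelled.

All randomness flows from the single recorded scenario seed; an identical
scenario reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import BuildupModel, SensitivityModel
from .errors import ValidationError
from .physics import Material, get_material, linear_attenuation
from .quantify import MeasurementSet, forward_model
from .spectra import (LU177_WINDOWS, N_BINS, N_COLS, N_ROWS, PIXEL_PITCH_MM,
                      EnergyWindowSet, SpectralImage)
from .tew import RateMeasurement, tew_net_rate

__all__ = [
    "ImageSpec",
    "ScenarioSpec",
    "default_calibration_truth",
    "simulate_measurement",
    "simulate_sensitivity_series",
    "simulate_buildup_series",
    "simulate_spectral_image",
]

_COUNT_GUARD = 1e15   # refuse absurd expected counts before rng.poisson overflows

#: Synthetic per-window scatter fractions (scatter / primary in the main
#: window).  Not derivable from published data; chosen to mimic the
#: qualitative ordering seen on CZT Lu-177 spectra, where the 55 keV window
#: carries the largest scatter burden and 208 keV the smallest.
DEFAULT_SCATTER_FRACTION = {55: 0.40, 113: 0.20, 208: 0.10}


def default_calibration_truth(collimator: str = "MEGP",
                              scatter_corrected: bool = True,
                              source_geometry: str = "cylinder-20mm",
                              ) -> tuple[dict[int, SensitivityModel],
                                         dict[int, BuildupModel]]:
    """Synthetic ground-truth calibration models for simulation studies.

    Magnitudes are chosen to be realistic for a small-FOV CZT camera
    imaging Lu-177: sensitivities of a few cps/MBq with a distance-dependent
    exponential component (strongest, and slowest-decaying, for 208 keV with
    LEHR where septal penetration dominates), and build-up slopes k of order
    0.1-0.4 that are larger without scatter correction and largest in the
    55 keV window where TEW under-corrects.
    """
    base = {
        # (c0, c1, c2) per window: cps/MBq, cps/MBq, 1/mm
        "MEGP": {55: (0.6, 4.0, 0.025), 113: (1.2, 8.0, 0.020), 208: (0.9, 5.0, 0.015)},
        "LEHR": {55: (1.5, 10.0, 0.022), 113: (3.0, 20.0, 0.018), 208: (4.0, 9.0, 0.006)},
    }[collimator]
    k_tew = {55: 0.35, 113: 0.15, 208: 0.08}
    k_gross = {55: 0.55, 113: 0.30, 208: 0.18}
    ks = k_tew if scatter_corrected else k_gross
    if not scatter_corrected:
        # gross-mode sensitivity includes the scatter pedestal
        base = {w: (c0 * (1 + DEFAULT_SCATTER_FRACTION[w]),
                    c1 * (1 + DEFAULT_SCATTER_FRACTION[w]), c2)
                for w, (c0, c1, c2) in base.items()}
    sens = {w: SensitivityModel(c0=c0, c1=c1, c2=c2, window=w,
                                collimator=collimator,
                                scatter_corrected=scatter_corrected,
                                source_geometry=source_geometry)
            for w, (c0, c1, c2) in base.items()}
    bu = {w: BuildupModel(k=ks[w], window=w, collimator=collimator,
                          scatter_corrected=scatter_corrected)
          for w in base}
    return sens, bu


@dataclass
class ImageSpec:
    """Spatial model for simulated spectral images.

    Counts of every window are spread over the detector as an isotropic
    Gaussian centred on the source (FWHM growing linearly with depth,
    FWHM = a + b * d) on top of a uniform background fraction; within a
    window, counts fall uniformly across its energy bins.
    """

    center: tuple[float, float] = (7.5, 7.5)   # (row, col), fractional pixels
    source_radius_mm: float = 10.0
    fwhm_a_mm: float = 5.0
    fwhm_b: float = 0.10                        # mm FWHM per mm depth
    background_fraction: float = 0.0

    def fwhm_mm(self, depth_mm: float) -> float:
        f = self.fwhm_a_mm + self.fwhm_b * depth_mm
        if f <= 0:
            raise ValidationError(f"FWHM model gives {f} mm at d = {depth_mm} mm")
        return f


@dataclass
class ScenarioSpec:
    """A fully specified synthetic measurement scenario.

    Defaults mirror a typical patient-style acquisition with this camera:
    ~20 MBq in a superficial source at 20 mm depth in soft tissue, a 3 min
    acquisition giving on the order of 2 x 10^4 counts in the 113 keV
    window.
    """

    true_activity_mbq: float = 20.0
    true_depth_mm: float = 20.0
    material: Material | None = None                  # default: soft tissue
    sensitivity: dict[int, SensitivityModel] | None = None
    buildup: dict[int, BuildupModel] | None = None
    duration_s: float = 180.0
    seed: int = 0
    windows: EnergyWindowSet = field(default_factory=lambda: LU177_WINDOWS)
    scatter_fraction: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SCATTER_FRACTION))
    image: ImageSpec | None = None

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValidationError("duration must be positive")
        if self.material is None:
            self.material = get_material("soft_tissue")
        if self.sensitivity is None or self.buildup is None:
            sens, bu = default_calibration_truth()
            self.sensitivity = self.sensitivity or sens
            self.buildup = self.buildup or bu
        modes = {m.scatter_corrected for m in self.sensitivity.values()}
        modes |= {m.scatter_corrected for m in self.buildup.values()}
        if len(modes) != 1:
            raise ValidationError(
                "scenario calibration truth mixes scatter-corrected and gross models")
        self.scatter_corrected = modes.pop()
        for w in self.sensitivity:
            if w not in self.scatter_fraction:
                raise ValidationError(f"no scatter fraction for window {w}")

    @property
    def collimator(self) -> str:
        return next(iter(self.sensitivity.values())).collimator

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Expected rates and shared count drawing
# ---------------------------------------------------------------------------

def _expected_window_rates(spec: ScenarioSpec) -> dict[int, dict[str, float]]:
    """Expected (main, lower, upper) rate per photopeak.

    The forward model gives the primary (analysis-window) rate; the scatter
    fraction adds scatter to the main window and fills the scatter windows
    so the TEW trapezoid reproduces it in expectation.  When the truth is
    gross-mode, the forward model already describes the gross main rate and
    no extra scatter is added to it.
    """
    mu = linear_attenuation(spec.material, list(spec.sensitivity))
    primary = forward_model(spec.true_activity_mbq, spec.true_depth_mm, mu,
                            spec.sensitivity, spec.buildup)
    out = {}
    for w, r in primary.items():
        pk = spec.windows[w]
        s = spec.scatter_fraction[w] * r
        w_main, w_lo, w_up = (pk.main.width_kev, pk.lower_scatter.width_kev,
                              pk.upper_scatter.width_kev)
        r_scatter_win = 2.0 * s / (w_main * (1.0 / w_lo + 1.0 / w_up))
        out[w] = {
            "main": r + (s if spec.scatter_corrected else 0.0),
            "lower": r_scatter_win,
            "upper": r_scatter_win,
        }
    return out


def _draw_window_counts(spec: ScenarioSpec, rng: np.random.Generator | None,
                        noise: bool) -> dict[int, dict[str, float]]:
    """Counts per (photopeak, sub-window), drawn in a fixed order.

    The draw order (photopeaks ascending; main, lower, upper within each)
    is shared with :func:`simulate_spectral_image`, so for the same seed the
    image's window sums equal these counts exactly.
    """
    expected = _expected_window_rates(spec)
    t = spec.duration_s
    counts: dict[int, dict[str, float]] = {}
    for w in sorted(expected):
        counts[w] = {}
        for part in ("main", "lower", "upper"):
            lam = expected[w][part] * t
            if lam > _COUNT_GUARD:
                raise ValidationError(
                    f"expected counts {lam:.3g} in window {w}/{part} exceed the "
                    "simulation guard")
            counts[w][part] = float(rng.poisson(lam)) if noise else lam
    return counts


def simulate_measurement(spec: ScenarioSpec, noise: bool = True) -> MeasurementSet:
    """Draw one measurement set from the scenario's forward model.

    With a scatter-corrected truth the TEW correction is applied to the
    drawn gross/scatter window counts, so the returned net rates are
    unbiased for the forward-model rates; with a gross truth the gross main
    rates are returned directly.  ``noise=False`` returns the exact
    expectations (with the corresponding Poisson variances).
    """
    rng = np.random.default_rng(spec.seed)
    counts = _draw_window_counts(spec, rng, noise)
    t = spec.duration_s
    rates, variances, clamped = {}, {}, {}
    for w, c in counts.items():
        main = RateMeasurement(c["main"] / t, c["main"] / t ** 2)
        if spec.scatter_corrected:
            res = tew_net_rate(main,
                               RateMeasurement(c["lower"] / t, c["lower"] / t ** 2),
                               RateMeasurement(c["upper"] / t, c["upper"] / t ** 2),
                               spec.windows[w])
            rates[w], variances[w], clamped[w] = res.net_rate, res.variance, res.clamped
        else:
            rates[w], variances[w], clamped[w] = main.rate, main.variance, False
    return MeasurementSet(
        rates=rates, variances=variances, duration_s=t,
        collimator=spec.collimator, scatter_corrected=spec.scatter_corrected,
        clamped=clamped,
        metadata={"seed": spec.seed, "noise": noise,
                  "window_counts": counts,
                  "true_activity_mbq": spec.true_activity_mbq,
                  "true_depth_mm": spec.true_depth_mm},
    )


# ---------------------------------------------------------------------------
# Calibration series
# ---------------------------------------------------------------------------

def simulate_sensitivity_series(sens_truth: dict[int, SensitivityModel],
                                distances_mm, activity_mbq: float,
                                duration_s: float, seed: int,
                                noise: bool = True) -> pd.DataFrame:
    """In-air distance series: expected rate = activity * eps(d) per window.

    Returns tidy rows (distance_mm, window, rate_cps, rate_var,
    activity_MBq) in the calibration CSV dialect.
    """
    if activity_mbq <= 0 or duration_s <= 0:
        raise ValidationError("activity and duration must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for d in np.asarray(distances_mm, dtype=float):
        for w in sorted(sens_truth):
            lam = activity_mbq * float(sens_truth[w].epsilon(d)) * duration_s
            c = float(rng.poisson(lam)) if noise else lam
            rows.append({"distance_mm": float(d), "window": w,
                         "rate_cps": c / duration_s,
                         "rate_var": c / duration_s ** 2,
                         "activity_MBq": activity_mbq})
    return pd.DataFrame(rows)


def simulate_buildup_series(buildup_truth: dict[int, BuildupModel],
                            thicknesses_mm, mu_pmma_mm: dict[int, float],
                            rate0_cps, duration_s: float, seed: int,
                            noise: bool = True) -> pd.DataFrame:
    """Fixed-distance PMMA series: expected rate = R0 e^(-s mu) (1 + k s mu).

    ``rate0_cps`` is the unattenuated (s = 0) rate, either a scalar applied
    to every window or a per-window mapping.
    """
    if duration_s <= 0:
        raise ValidationError("duration must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for s in np.asarray(thicknesses_mm, dtype=float):
        if s < 0:
            raise ValidationError("PMMA thickness must be non-negative")
        for w in sorted(buildup_truth):
            r0 = float(rate0_cps[w]) if isinstance(rate0_cps, dict) else float(rate0_cps)
            x = s * mu_pmma_mm[w]
            lam = r0 * math.exp(-x) * (1.0 + buildup_truth[w].k * x) * duration_s
            c = float(rng.poisson(lam)) if noise else lam
            rows.append({"pmma_mm": float(s), "window": w,
                         "rate_cps": c / duration_s,
                         "rate_var": c / duration_s ** 2})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spectral images
# ---------------------------------------------------------------------------

def _pixel_probabilities(image: ImageSpec, depth_mm: float) -> np.ndarray:
    sigma_pix = image.fwhm_mm(depth_mm) / (2.0 * math.sqrt(2.0 * math.log(2.0))) \
        / PIXEL_PITCH_MM
    rr, cc = np.mgrid[0:N_ROWS, 0:N_COLS]
    r0, c0 = image.center
    g = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_pix ** 2))
    g /= g.sum()
    bg = image.background_fraction
    if not 0.0 <= bg < 1.0:
        raise ValidationError("background fraction must be in [0, 1)")
    return (1.0 - bg) * g + bg / (N_ROWS * N_COLS)


def simulate_spectral_image(spec: ScenarioSpec) -> SpectralImage:
    """Draw a full per-pixel spectral acquisition for the scenario.

    Per-window total counts are drawn first, with the same rng call order
    as :func:`simulate_measurement`, then distributed multinomially over
    pixels (Gaussian source + uniform background) and uniformly over the
    window's energy bins.  Consequently, for an identical scenario the
    image's window sums equal the measurement simulator's counts exactly.
    """
    if spec.image is None:
        raise ValidationError("scenario has no image spec")
    rng = np.random.default_rng(spec.seed)
    counts = _draw_window_counts(spec, rng, noise=True)
    p = _pixel_probabilities(spec.image, spec.true_depth_mm).ravel()

    cube = np.zeros((N_ROWS, N_COLS, N_BINS), dtype=np.uint32)
    for w in sorted(counts):
        pk = spec.windows[w]
        for part, window in (("main", pk.main), ("lower", pk.lower_scatter),
                             ("upper", pk.upper_scatter)):
            total = int(counts[w][part])
            if total == 0:
                continue
            per_pixel = rng.multinomial(total, p)
            sl = window.bin_slice
            nb = sl.stop - sl.start
            flat = cube.reshape(N_ROWS * N_COLS, N_BINS)
            for idx in np.nonzero(per_pixel)[0]:
                flat[idx, sl] += rng.multinomial(
                    per_pixel[idx], np.full(nb, 1.0 / nb)).astype(np.uint32)
    return SpectralImage(counts=cube, duration_s=spec.duration_s,
                         collimator=spec.collimator)
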