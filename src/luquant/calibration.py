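"""Calibration of the distance-dependent sensitivity and build-up models.

Two characterization series feed the forward model:

* an in-air series of a known activity at source-collimator distances d,
  giving the system sensitivity  eps(d) = c0 + c1 * exp(-d * c2)
  (the NEMA NU 1-2012 functional form; the distance dependence of this
  camera comes mainly from septal penetration and collimator scatter);

* a fixed-distance series with increasing PMMA thickness s, from which the
  build-up factor  B(s * mu) = R(s) / R(0) * exp(s * mu)  is computed and
  linearized as  B(x) = 1 + k * x  with the intercept fixed at 1.

Both are fitted per collimator, photopeak window, scatter-correction mode
and source geometry, and stored in a :class:`CalibrationLibrary` keyed
exactly on those attributes: a quantification run must use entries whose
mode and geometry match, and mismatches are hard errors.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import curve_fit

from . import __version__
from .errors import CalibrationKeyError, FitError, ValidationError
from .physics import decay_correct
from .spectra import (EnergyWindowSet, Roi, SpectralImage, WindowImage,
                      apply_uniformity, auto_roi, extract_window_image,
                      roi_count_rate)
from .tew import RateMeasurement, tew_net_rate

__all__ = [
    "SensitivityModel",
    "BuildupModel",
    "CalibrationEntry",
    "CalibrationLibrary",
    "fit_sensitivity",
    "compute_buildup",
    "fit_buildup",
    "sensitivity_from_measurement",
    "file_sha256",
]


@dataclass
class SensitivityModel:
    """eps(d) = c0 + c1 * exp(-d * c2): distance-dependent system sensitivity.

    Units: c0, c1 in cps/MBq; c2 in 1/mm; d in mm.
    """

    c0: float
    c1: float
    c2: float
    window: int
    collimator: str
    scatter_corrected: bool
    source_geometry: str = "cylinder-20mm"
    covariance: list | None = None     # 3x3, order (c0, c1, c2)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.c1 > 0 and self.c2 > 0):
            raise ValidationError(
                f"sensitivity model requires c1 > 0 and c2 > 0 "
                f"(got c1={self.c1}, c2={self.c2}): eps(d) must decrease with d")
        if self.c0 < 0:
            warnings.warn(f"fitted c0 = {self.c0:g} < 0 (window {self.window}); "
                          "the constant sensitivity term should be non-negative")

    def epsilon(self, d_mm) -> np.ndarray | float:
        return self.c0 + self.c1 * np.exp(-np.asarray(d_mm, dtype=float) * self.c2)

    def epsilon_prime(self, d_mm) -> np.ndarray | float:
        """d eps / d d, used by the estimator's analytic Jacobian."""
        return -self.c1 * self.c2 * np.exp(-np.asarray(d_mm, dtype=float) * self.c2)

    @property
    def stderr(self) -> tuple[float, float, float] | None:
        if self.covariance is None:
            return None
        cov = np.asarray(self.covariance)
        return tuple(float(x) for x in np.sqrt(np.clip(np.diag(cov), 0, None)))


@dataclass
class BuildupModel:
    """B(x) = 1 + k * x with x = d * mu; k is energy-window dependent.

    With gross count rates k absorbs broad-beam build-up; with TEW-corrected
    rates it absorbs the residual over/under-estimation of scatter.
    B(0) = 1 by construction.  k is expected non-negative but a fit on noisy
    data may legitimately return a small negative value.
    """

    k: float
    window: int
    collimator: str
    scatter_corrected: bool
    k_stderr: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def b(self, x) -> np.ndarray | float:
        return 1.0 + self.k * np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

def fit_sensitivity(distances_mm, sensitivities, variances=None, *,
                    window: int, collimator: str,
                    scatter_corrected: bool, source_geometry: str = "cylinder-20mm",
                    max_iterations: int = 200) -> SensitivityModel:
    """Ordinary (unweighted) nonlinear least squares of eps(d) = c0 + c1 e^(-d c2).

    Initialization: c0 starts at the lowest measured sensitivity; c1 and c2
    come from a linear regression of log(sensitivity - c0_init) on distance,
    excluding points where the subtraction is non-positive.

    The point estimate is always the unweighted fit.  When per-point
    ``variances`` (Poisson, from the count rates) are supplied, the
    parameter covariance is the heteroscedasticity-consistent sandwich
    (J'J)^-1 J'VJ (J'J)^-1 rather than the homoscedastic residual-based
    one, since the absolute noise varies strongly along the series.
    """
    d = np.asarray(distances_mm, dtype=float)
    s = np.asarray(sensitivities, dtype=float)
    if d.shape != s.shape or d.ndim != 1:
        raise ValidationError("distances and sensitivities must be matching 1-D arrays")
    if len(np.unique(d)) < 4:
        raise ValidationError("sensitivity fit requires >= 4 distinct distances")
    if np.any(s <= 0):
        raise ValidationError("sensitivities must be positive")

    c0_0 = float(s.min())
    excess = s - c0_0
    mask = excess > 0
    if mask.sum() < 2:
        raise FitError("degenerate sensitivity series: no distance dependence "
                       "above the minimum (c1 -> 0)")
    slope, intercept = np.polyfit(d[mask], np.log(excess[mask]), 1)
    c2_0 = max(-float(slope), 1e-6)
    c1_0 = float(np.exp(intercept))

    def model(dd, c0, c1, c2):
        return c0 + c1 * np.exp(-dd * c2)

    try:
        popt, pcov = curve_fit(model, d, s, p0=[c0_0, c1_0, c2_0],
                               maxfev=max_iterations * 10)
    except RuntimeError as exc:
        raise FitError(f"sensitivity fit did not converge: {exc}") from exc
    c0, c1, c2 = (float(v) for v in popt)
    if c1 <= 0 or c2 <= 0:
        raise FitError(f"degenerate sensitivity fit: c1={c1:g}, c2={c2:g} "
                       "(no resolvable distance dependence)")
    resid = s - model(d, *popt)
    if variances is not None:
        v = np.asarray(variances, dtype=float)
        if v.shape != d.shape or np.any(v < 0):
            raise ValidationError("variances must match the series and be >= 0")
        e = np.exp(-d * c2)
        jac = np.column_stack([np.ones_like(d), e, -d * c1 * e])
        jtj_inv = np.linalg.inv(jac.T @ jac)
        pcov = jtj_inv @ (jac.T @ (jac * v[:, None])) @ jtj_inv
    return SensitivityModel(
        c0=c0, c1=c1, c2=c2, window=window, collimator=collimator,
        scatter_corrected=scatter_corrected, source_geometry=source_geometry,
        covariance=np.asarray(pcov).tolist(),
        diagnostics={"n_points": int(len(d)),
                     "rss": float(np.sum(resid ** 2)),
                     "init": [c0_0, c1_0, c2_0]},
    )


def compute_buildup(series, mu_pmma_mm: float) -> list[tuple[float, float]]:
    """Build-up points (x = s * mu, B) from a fixed-distance PMMA series.

    ``series`` is an iterable of (thickness_mm, rate_cps).  Requires the
    s = 0 reference; B(s * mu) = R(s) / R(0) * exp(s * mu).  Points with a
    non-positive rate (e.g. a TEW net rate clamped to zero) have no defined
    build-up and are dropped with a warning.
    """
    pts = [(float(s), float(r)) for s, r in series]
    if mu_pmma_mm <= 0:
        raise ValidationError("mu_pmma must be positive")
    zero = [r for s, r in pts if s == 0.0]
    if not zero:
        raise ValidationError("build-up series must contain the s = 0 reference")
    r0 = float(np.mean(zero))
    if r0 <= 0:
        raise ValidationError("s = 0 reference rate must be positive")
    out = []
    for s, r in pts:
        if s < 0:
            raise ValidationError("PMMA thickness must be non-negative")
        if r <= 0:
            warnings.warn(f"dropping build-up point at s = {s} mm: "
                          "non-positive rate has no defined build-up")
            continue
        out.append((s * mu_pmma_mm, r / r0 * math.exp(s * mu_pmma_mm)))
    return out


def buildup_covariance(series, mu_pmma_mm: float, rate_variances) -> np.ndarray:
    """Covariance of the build-up points returned by :func:`compute_buildup`.

    Propagates the Poisson rate variances through B = R(s)/R(0) e^(s mu) by
    first-order error propagation, including the covariance all points share
    through the common R(0) reference.  Row/column order matches the point
    order of :func:`compute_buildup` (non-positive-rate points dropped; the
    s = 0 point has zero variance by construction).
    """
    pts = [(float(s), float(r)) for s, r in series]
    var = [float(v) for v in rate_variances]
    if len(var) != len(pts):
        raise ValidationError("rate_variances must match the series length")
    zero = [(r, v) for (s, r), v in zip(pts, var) if s == 0.0]
    if not zero:
        raise ValidationError("build-up series must contain the s = 0 reference")
    r0 = float(np.mean([r for r, _ in zero]))
    v0 = float(np.mean([v for _, v in zero])) / len(zero)
    kept = [(s, r, v) for (s, r), v in zip(pts, var) if r > 0]
    n = len(kept)
    cov = np.zeros((n, n))
    for i, (si, ri, vi) in enumerate(kept):
        for j, (sj, rj, vj) in enumerate(kept):
            if si == 0.0 or sj == 0.0:
                continue   # the reference point is B = 1 identically
            e = math.exp((si + sj) * mu_pmma_mm)
            cov[i, j] = e * ri * rj * v0 / r0 ** 4
            if i == j:
                cov[i, j] += e * vi / r0 ** 2
    return cov


def fit_buildup(points, *, window: int, collimator: str,
                scatter_corrected: bool, covariance=None) -> BuildupModel:
    """Least squares of B = 1 + k x with the intercept fixed at 1.

    Closed form: k = sum(x (B - 1)) / sum(x^2).  If a point ``covariance``
    (from :func:`buildup_covariance`) is given, the standard error of k is
    propagated through the closed form, x' C x / (sum x^2)^2; otherwise it
    falls back to the homoscedastic residual estimate.
    """
    x = np.asarray([p[0] for p in points], dtype=float)
    b = np.asarray([p[1] for p in points], dtype=float)
    if len(x) < 2:
        raise ValidationError("build-up fit requires >= 2 points")
    if not np.any(x > 0):
        raise ValidationError("build-up fit requires points with x > 0")
    sxx = float(np.sum(x ** 2))
    k = float(np.sum(x * (b - 1.0)) / sxx)
    resid = b - 1.0 - k * x
    if covariance is not None:
        c = np.asarray(covariance, dtype=float)
        if c.shape != (len(x), len(x)):
            raise ValidationError("covariance shape must match the points")
        k_stderr = math.sqrt(float(x @ c @ x)) / sxx
    else:
        dof = len(x) - 1
        k_stderr = math.sqrt(float(np.sum(resid ** 2)) / dof / sxx) if dof > 0 else None
    return BuildupModel(k=k, window=window, collimator=collimator,
                        scatter_corrected=scatter_corrected, k_stderr=k_stderr,
                        diagnostics={"n_points": int(len(x)),
                                     "rss": float(np.sum(resid ** 2))})


def sensitivity_from_measurement(img: SpectralImage, known_activity_mbq: float,
                                 windows: EnergyWindowSet, photopeak: int, *,
                                 distance_mm: float, tew: bool = False,
                                 roi: Roi | None = None,
                                 source_radius_mm: float | None = None,
                                 fwhm_mm: float | None = None,
                                 uniformity: np.ndarray | None = None,
                                 assay_to_acquisition_s: float = 0.0) -> dict:
    """One distance-tagged sensitivity point from a known-activity acquisition.

    The ROI is taken from the 113 keV main-window image (count-weighted
    centre of mass, radius = source radius + FWHM/2) unless given explicitly,
    and the identical circle is applied to every window.  The known activity
    is decayed forward by ``assay_to_acquisition_s`` to the acquisition time.
    """
    if known_activity_mbq <= 0:
        raise ValidationError("known activity must be positive")
    pk = windows[photopeak]
    if roi is None:
        if source_radius_mm is None or fwhm_mm is None:
            raise ValidationError("auto ROI requires source_radius_mm and fwhm_mm")
        roi = auto_roi(extract_window_image(img, windows[113].main),
                       source_radius_mm, fwhm_mm)

    def windowed(w) -> WindowImage:
        wi = extract_window_image(img, w)
        return apply_uniformity(wi, uniformity) if uniformity is not None else wi

    main = roi_count_rate(windowed(pk.main), roi)
    if tew:
        res = tew_net_rate(RateMeasurement(**main),
                           RateMeasurement(**roi_count_rate(windowed(pk.lower_scatter), roi)),
                           RateMeasurement(**roi_count_rate(windowed(pk.upper_scatter), roi)),
                           pk)
        rate, var = res.net_rate, res.variance
    else:
        rate, var = main["rate"], main["variance"]

    a_acq = decay_correct(known_activity_mbq, -assay_to_acquisition_s)
    return {"distance_mm": float(distance_mm),
            "sensitivity": rate / a_acq,
            "variance": var / a_acq ** 2}


# ---------------------------------------------------------------------------
# Library
# ---------------------------------------------------------------------------

Key = tuple[str, str, int, bool, str]  # (radionuclide, collimator, window, tew, geometry)


@dataclass
class CalibrationEntry:
    sensitivity: SensitivityModel | None = None
    buildup: BuildupModel | None = None
    provenance: dict = field(default_factory=dict)


class CalibrationLibrary:
    """Fitted sensitivity/build-up models keyed exactly on
    (radionuclide, collimator, window, scatter_corrected, source_geometry).

    Lookups require an exact key match; a missing entry raises
    :class:`CalibrationKeyError` listing the available keys.  Cross-geometry
    reuse (e.g. a tube-calibrated sensitivity applied to a large source) is
    refused unless explicitly overridden, because septal penetration makes
    the sensitivity source-size dependent.
    """

    def __init__(self) -> None:
        self._entries: dict[Key, CalibrationEntry] = {}

    @staticmethod
    def _key(radionuclide: str, collimator: str, window: int,
             scatter_corrected: bool, source_geometry: str) -> Key:
        return (radionuclide, collimator, int(window), bool(scatter_corrected),
                source_geometry)

    def _entry(self, key: Key) -> CalibrationEntry:
        return self._entries.setdefault(key, CalibrationEntry())

    def add_sensitivity(self, model: SensitivityModel, radionuclide: str = "Lu-177",
                        provenance: dict | None = None) -> None:
        key = self._key(radionuclide, model.collimator, model.window,
                        model.scatter_corrected, model.source_geometry)
        e = self._entry(key)
        e.sensitivity = model
        if provenance:
            e.provenance.update(provenance)

    def add_buildup(self, model: BuildupModel, radionuclide: str = "Lu-177",
                    source_geometry: str = "cylinder-20mm",
                    provenance: dict | None = None) -> None:
        key = self._key(radionuclide, model.collimator, model.window,
                        model.scatter_corrected, source_geometry)
        e = self._entry(key)
        e.buildup = model
        if provenance:
            e.provenance.update(provenance)

    @property
    def keys(self) -> list[Key]:
        return sorted(self._entries)

    def lookup(self, *, radionuclide: str = "Lu-177", collimator: str, window: int,
               scatter_corrected: bool, source_geometry: str,
               allow_geometry_override: bool = False) -> CalibrationEntry:
        key = self._key(radionuclide, collimator, window, scatter_corrected,
                        source_geometry)
        if key in self._entries:
            return self._entries[key]
        if allow_geometry_override:
            same_mode = [k for k in self._entries
                         if k[:4] == key[:4] and self._entries[k].sensitivity]
            if len(same_mode) == 1:
                warnings.warn(
                    f"calibration geometry override: using {same_mode[0][4]!r} "
                    f"in place of {source_geometry!r} for window {window}")
                return self._entries[same_mode[0]]
        raise CalibrationKeyError(
            f"no calibration entry for {key}; available: {self.keys}")

    # -- YAML persistence --------------------------------------------------

    def to_dict(self) -> dict:
        entries = []
        for key in self.keys:
            e = self._entries[key]
            rec: dict = {
                "radionuclide": key[0], "collimator": key[1], "window": key[2],
                "scatter_corrected": key[3], "source_geometry": key[4],
                "provenance": e.provenance,
            }
            if e.sensitivity is not None:
                s = e.sensitivity
                rec["sensitivity"] = {"c0": s.c0, "c1": s.c1, "c2": s.c2,
                                      "covariance": s.covariance,
                                      "diagnostics": s.diagnostics}
            if e.buildup is not None:
                b = e.buildup
                rec["buildup"] = {"k": b.k, "k_stderr": b.k_stderr,
                                  "diagnostics": b.diagnostics}
            entries.append(rec)
        return {"luquant_version": __version__, "entries": entries}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationLibrary":
        lib = cls()
        for rec in d.get("entries", []):
            key_kwargs = dict(radionuclide=rec["radionuclide"],
                              source_geometry=rec["source_geometry"])
            if "sensitivity" in rec:
                s = rec["sensitivity"]
                lib.add_sensitivity(SensitivityModel(
                    c0=s["c0"], c1=s["c1"], c2=s["c2"], window=rec["window"],
                    collimator=rec["collimator"],
                    scatter_corrected=rec["scatter_corrected"],
                    source_geometry=rec["source_geometry"],
                    covariance=s.get("covariance"),
                    diagnostics=s.get("diagnostics", {})),
                    radionuclide=rec["radionuclide"],
                    provenance=rec.get("provenance"))
            if "buildup" in rec:
                b = rec["buildup"]
                lib.add_buildup(BuildupModel(
                    k=b["k"], window=rec["window"], collimator=rec["collimator"],
                    scatter_corrected=rec["scatter_corrected"],
                    k_stderr=b.get("k_stderr"),
                    diagnostics=b.get("diagnostics", {})),
                    provenance=rec.get("provenance"), **key_kwargs)
        return lib

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationLibrary":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def file_sha256(path: str | Path) -> str:
    """Hex digest of a file, recorded as calibration provenance."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
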