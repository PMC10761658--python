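"""Per-pixel spectral acquisitions: I/O, energy windowing, uniformity and ROIs.

The detector is a single CZT module read out through a 16 x 16 anode array
with 2.46 mm pitch.  Every acquisition stores, for each detector element, a
count histogram in 0.1 keV bins from 0 to 250 keV, so images for any energy
window can be formed after the fact.  This module provides the open on-disk
dialects for such acquisitions (HDF5, or CSV with a YAML metadata sidecar),
window extraction, uniformity correction, and circular / mask ROI count
rates with Poisson variance bookkeeping.

Energy-bin convention: bin ``b`` spans ``[0.1 b, 0.1 (b + 1))`` keV.  Energy
windows are half-open ``[lo, hi)`` so that abutting windows (a photopeak's
main window and its scatter windows share edges) can never double count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import yaml

from .errors import FormatError, NoPixelsError, NoSignalError, ValidationError

N_ROWS = 16
N_COLS = 16
N_BINS = 2500
BIN_WIDTH_KEV = 0.1
E_MAX_KEV = N_BINS * BIN_WIDTH_KEV
PIXEL_PITCH_MM = 2.46

__all__ = [
    "EnergyWindow",
    "PhotopeakWindows",
    "EnergyWindowSet",
    "SpectralImage",
    "WindowImage",
    "Roi",
    "read_spectral_image",
    "write_spectral_image",
    "extract_window_image",
    "apply_uniformity",
    "auto_roi",
    "roi_count_rate",
    "LU177_WINDOWS",
]


def _to_bin(energy_kev: float, what: str) -> int:
    """Convert a window edge to a bin index, enforcing the 0.1 keV grid."""
    b = energy_kev / BIN_WIDTH_KEV
    bi = round(b)
    if abs(b - bi) > 1e-6:
        raise ValidationError(
            f"{what} = {energy_kev} keV is not a multiple of {BIN_WIDTH_KEV} keV"
        )
    return int(bi)


@dataclass(frozen=True)
class EnergyWindow:
    """A half-open energy interval [lo, hi) on the 0.1 keV bin grid."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        lo_b = _to_bin(self.lo, f"window '{self.name}' lo")
        hi_b = _to_bin(self.hi, f"window '{self.name}' hi")
        if not (0 <= lo_b < hi_b <= N_BINS):
            raise ValidationError(
                f"window '{self.name}' bounds [{self.lo}, {self.hi}) keV are "
                f"not ordered within [0, {E_MAX_KEV}] keV"
            )

    @property
    def width_kev(self) -> float:
        return round(self.hi - self.lo, 10)

    @property
    def bin_slice(self) -> slice:
        """Bins fully contained in [lo, hi)."""
        return slice(_to_bin(self.lo, "lo"), _to_bin(self.hi, "hi"))


@dataclass(frozen=True)
class PhotopeakWindows:
    """Main + abutting lower/upper scatter windows around one photopeak."""

    label: int                 # nominal photopeak energy used as key (55, 113, 208)
    photon_energy_kev: float
    lower_scatter: EnergyWindow
    main: EnergyWindow
    upper_scatter: EnergyWindow

    def __post_init__(self) -> None:
        if not (abs(self.lower_scatter.hi - self.main.lo) < 1e-9
                and abs(self.main.hi - self.upper_scatter.lo) < 1e-9):
            raise ValidationError(
                f"photopeak {self.label}: scatter windows must abut the main window"
            )


class EnergyWindowSet(Mapping[int, PhotopeakWindows]):
    """Ordered mapping photopeak label -> :class:`PhotopeakWindows`."""

    def __init__(self, photopeaks: list[PhotopeakWindows]):
        self._peaks = {p.label: p for p in photopeaks}

    def __getitem__(self, label: int) -> PhotopeakWindows:
        return self._peaks[label]

    def __iter__(self):
        return iter(self._peaks)

    def __len__(self) -> int:
        return len(self._peaks)

    @property
    def labels(self) -> list[int]:
        return list(self._peaks)

    @classmethod
    def lu177_default(cls) -> "EnergyWindowSet":
        """The standard Lu-177 windows for this camera (keV).

        Three photopeaks are used: the ~55 keV characteristic X-rays and the
        113 and 208 keV gamma emissions, each with abutting narrow scatter
        windows on either side of the main window.
        """
        def pk(label, e, l_lo, l_hi, m_hi, u_hi):
            return PhotopeakWindows(
                label=label,
                photon_energy_kev=e,
                lower_scatter=EnergyWindow(f"{label}-lower", l_lo, l_hi),
                main=EnergyWindow(f"{label}-main", l_hi, m_hi),
                upper_scatter=EnergyWindow(f"{label}-upper", m_hi, u_hi),
            )

        return cls([
            pk(55, 55.8, 45.8, 49.7, 59.7, 63.6),
            pk(113, 112.9, 96.5, 100.5, 120.8, 124.8),
            pk(208, 208.4, 186.5, 193.8, 216.7, 224.0),
        ])

    # -- YAML serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "photopeaks": [
                {
                    "label": p.label,
                    "photon_energy_kev": p.photon_energy_kev,
                    "lower_scatter": [p.lower_scatter.lo, p.lower_scatter.hi],
                    "main": [p.main.lo, p.main.hi],
                    "upper_scatter": [p.upper_scatter.lo, p.upper_scatter.hi],
                }
                for p in self._peaks.values()
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyWindowSet":
        peaks = []
        for e in d["photopeaks"]:
            lab = int(e["label"])
            (ll, lh), (ml, mh), (ul, uh) = (
                e["lower_scatter"], e["main"], e["upper_scatter"])
            peaks.append(PhotopeakWindows(
                label=lab,
                photon_energy_kev=float(e["photon_energy_kev"]),
                lower_scatter=EnergyWindow(f"{lab}-lower", ll, lh),
                main=EnergyWindow(f"{lab}-main", ml, mh),
                upper_scatter=EnergyWindow(f"{lab}-upper", ul, uh),
            ))
        return cls(peaks)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnergyWindowSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


LU177_WINDOWS = EnergyWindowSet.lu177_default()


@dataclass
class SpectralImage:
    """A per-pixel energy-spectrum acquisition (16 x 16 x 2500 counts cube)."""

    counts: np.ndarray          # uint/int, shape (16, 16, 2500)
    duration_s: float
    collimator: str             # "LEHR" or "MEGP"
    radionuclide: str = "Lu-177"
    acquired_at: str | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_ROWS, N_COLS, N_BINS):
            raise FormatError(
                f"counts cube has shape {c.shape}, expected ({N_ROWS}, {N_COLS}, {N_BINS})"
            )
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.mod(c, 1) == 0):
                raise ValidationError("counts must be integral")
            c = c.astype(np.int64)
        if np.any(c < 0):
            raise ValidationError("counts must be non-negative")
        self.counts = c
        if not self.duration_s > 0:
            raise ValidationError(f"duration must be positive, got {self.duration_s}")
        if self.collimator not in ("LEHR", "MEGP"):
            raise ValidationError(f"unknown collimator {self.collimator!r}")

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    def energy_shifted(self, shift_bins: int) -> "SpectralImage":
        """Apply a global integer energy shift (coarse drift compensation).

        Counts shifted past either spectrum edge are discarded; bins exposed
        by the shift are zero-filled.
        """
        if shift_bins == 0:
            return self
        shifted = np.zeros_like(self.counts)
        if shift_bins > 0:
            shifted[:, :, shift_bins:] = self.counts[:, :, :-shift_bins]
        else:
            shifted[:, :, :shift_bins] = self.counts[:, :, -shift_bins:]
        return dataclasses.replace(self, counts=shifted)


@dataclass
class WindowImage:
    """16 x 16 image of (possibly uniformity-scaled) counts in one window.

    ``variance`` tracks the per-pixel count variance.  For a freshly
    extracted image it equals the raw counts (Poisson); uniformity
    correction scales it by the squared correction so ROI rate variances
    remain correct for non-Poisson scaled counts.
    """

    values: np.ndarray          # float, shape (16, 16), >= 0
    window: EnergyWindow
    duration_s: float
    variance: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_ROWS, N_COLS):
            raise FormatError(f"window image shape {v.shape}, expected ({N_ROWS}, {N_COLS})")
        if np.any(v < 0):
            raise ValidationError("window image values must be non-negative")
        self.values = v
        if self.variance is None:
            self.variance = v.copy()
        else:
            self.variance = np.asarray(self.variance, dtype=float)
            if self.variance.shape != v.shape:
                raise FormatError("variance shape must match values")
        if not self.duration_s > 0:
            raise ValidationError("duration must be positive")

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class Roi:
    """A circular (fractional-pixel centre, mm radius) or boolean-mask ROI."""

    kind: str                                  # "circle" | "mask"
    center: tuple[float, float] | None = None  # (row, col), fractional pixels
    radius_mm: float | None = None
    mask: np.ndarray | None = None             # (16, 16) bool
    pixel_pitch_mm: float = PIXEL_PITCH_MM

    def __post_init__(self) -> None:
        if self.kind == "circle":
            if self.center is None or self.radius_mm is None:
                raise ValidationError("circle ROI requires center and radius")
            if not self.radius_mm > 0:
                raise ValidationError("circle ROI radius must be positive")
        elif self.kind == "mask":
            if self.mask is None:
                raise ValidationError("mask ROI requires a mask")
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (N_ROWS, N_COLS):
                raise FormatError(f"mask shape {m.shape}, expected ({N_ROWS}, {N_COLS})")
            if not m.any():
                raise ValidationError("mask ROI must select at least one pixel")
            self.mask = m
        else:
            raise ValidationError(f"unknown ROI kind {self.kind!r}")

    @classmethod
    def circle(cls, center: tuple[float, float], radius_mm: float,
               pixel_pitch_mm: float = PIXEL_PITCH_MM) -> "Roi":
        return cls(kind="circle", center=center, radius_mm=radius_mm,
                   pixel_pitch_mm=pixel_pitch_mm)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "Roi":
        return cls(kind="mask", mask=mask)

    def membership(self) -> np.ndarray:
        """Boolean pixel-membership map (pixel-centre-in-circle rule)."""
        if self.kind == "mask":
            return self.mask
        rr, cc = np.mgrid[0:N_ROWS, 0:N_COLS]
        r0, c0 = self.center
        dist_mm = self.pixel_pitch_mm * np.hypot(rr - r0, cc - c0)
        return dist_mm <= self.radius_mm

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "pixel_pitch_mm": self.pixel_pitch_mm}
        if self.kind == "circle":
            d["center"] = [float(self.center[0]), float(self.center[1])]
            d["radius_mm"] = float(self.radius_mm)
        else:
            d["mask"] = self.mask.astype(int).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Roi":
        if d["kind"] == "circle":
            return cls.circle(tuple(d["center"]), d["radius_mm"],
                              d.get("pixel_pitch_mm", PIXEL_PITCH_MM))
        return cls.from_mask(np.asarray(d["mask"], dtype=bool))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Roi":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_H5_SUFFIXES = {".h5", ".hdf5", ".hdf"}


def write_spectral_image(img: SpectralImage, path: str | Path) -> None:
    """Write an acquisition in the open dialect chosen by file suffix.

    ``.h5``/``.hdf5``: one ``counts`` dataset (uint32, 16 x 16 x 2500) with
    scalar attributes.  ``.csv``: 256 rows (row-major pixels) x 2500 integer
    columns, with metadata in a ``<stem>.yaml`` sidecar next to the file.
    """
    path = Path(path)
    if path.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("counts", data=img.counts.astype(np.uint32),
                                  compression="gzip", compression_opts=4)
            ds.attrs["bin_width_kev"] = BIN_WIDTH_KEV
            f.attrs["bin_width_kev"] = BIN_WIDTH_KEV
            f.attrs["energy_origin_kev"] = 0.0
            f.attrs["duration_s"] = float(img.duration_s)
            f.attrs["collimator"] = img.collimator
            f.attrs["radionuclide"] = img.radionuclide
            if img.acquired_at is not None:
                f.attrs["acquired_at"] = img.acquired_at
    elif path.suffix.lower() == ".csv":
        flat = img.counts.reshape(N_ROWS * N_COLS, N_BINS)
        np.savetxt(path, flat, fmt="%d", delimiter=",")
        meta = {
            "bin_width_kev": BIN_WIDTH_KEV,
            "energy_origin_kev": 0.0,
            "duration_s": float(img.duration_s),
            "collimator": img.collimator,
            "radionuclide": img.radionuclide,
        }
        if img.acquired_at is not None:
            meta["acquired_at"] = img.acquired_at
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    else:
        raise FormatError(f"unsupported spectral-image suffix {path.suffix!r}")


def read_spectral_image(path: str | Path, energy_shift_bins: int = 0) -> SpectralImage:
    """Read an acquisition written by :func:`write_spectral_image`.

    ``energy_shift_bins`` applies an optional user-supplied global integer
    energy shift before any windowing (coarse compensation for
    temperature-related calibration drift; a full recalibration is outside
    this package).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(path, "r") as f:
            if "counts" not in f:
                raise FormatError(f"{path}: missing 'counts' dataset")
            counts = f["counts"][()]
            meta = dict(f.attrs)
    elif path.suffix.lower() == ".csv":
        try:
            counts = np.loadtxt(path, delimiter=",", dtype=np.int64)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed CSV spectral image: {exc}") from exc
        if counts.shape != (N_ROWS * N_COLS, N_BINS):
            raise FormatError(
                f"{path}: CSV shape {counts.shape}, expected ({N_ROWS * N_COLS}, {N_BINS})"
            )
        counts = counts.reshape(N_ROWS, N_COLS, N_BINS)
        sidecar = path.with_suffix(".yaml")
        if not sidecar.exists():
            raise FormatError(f"missing metadata sidecar {sidecar}")
        meta = yaml.safe_load(sidecar.read_text())
    else:
        raise FormatError(f"unsupported spectral-image suffix {path.suffix!r}")

    if counts.shape != (N_ROWS, N_COLS, N_BINS):
        raise FormatError(
            f"{path}: counts shape {counts.shape}, expected ({N_ROWS}, {N_COLS}, {N_BINS})"
        )
    bw = float(meta.get("bin_width_kev", BIN_WIDTH_KEV))
    if abs(bw - BIN_WIDTH_KEV) > 1e-9:
        raise FormatError(f"{path}: bin width {bw} keV unsupported (expected {BIN_WIDTH_KEV})")
    img = SpectralImage(
        counts=np.asarray(counts),
        duration_s=float(meta["duration_s"]),
        collimator=str(meta["collimator"]),
        radionuclide=str(meta.get("radionuclide", "Lu-177")),
        acquired_at=(str(meta["acquired_at"]) if "acquired_at" in meta else None),
    )
    return img.energy_shifted(energy_shift_bins)


# ---------------------------------------------------------------------------
# Windowing, uniformity, ROIs
# ---------------------------------------------------------------------------

def extract_window_image(img: SpectralImage, window: EnergyWindow) -> WindowImage:
    """Sum the bins fully contained in ``[window.lo, window.hi)`` per pixel.

    A count recorded in the bin starting exactly at ``window.hi`` is excluded
    (it belongs to the abutting next window), so splitting a wide window into
    abutting sub-windows conserves counts exactly.
    """
    vals = img.counts[:, :, window.bin_slice].sum(axis=2).astype(float)
    return WindowImage(values=vals, window=window, duration_s=img.duration_s)


def apply_uniformity(wi: WindowImage, correction: np.ndarray) -> WindowImage:
    """Multiply a window image element-wise by a uniformity correction array.

    Correction arrays are measured per (radionuclide, collimator, window)
    and supplied by the user; they are consumed here, never derived.
    Variance scales by the squared correction (scaled counts are no longer
    Poisson).
    """
    corr = np.asarray(correction, dtype=float)
    if corr.shape != (N_ROWS, N_COLS):
        raise FormatError(f"correction shape {corr.shape}, expected ({N_ROWS}, {N_COLS})")
    if np.any(corr <= 0):
        raise ValidationError("uniformity correction must be strictly positive")
    return WindowImage(values=wi.values * corr, window=wi.window,
                       duration_s=wi.duration_s, variance=wi.variance * corr ** 2)


def auto_roi(wi: WindowImage, source_radius_mm: float, fwhm_mm: float,
             pixel_pitch_mm: float = PIXEL_PITCH_MM) -> Roi:
    """Automatic circular ROI: centre at the count-weighted centre of mass,
    radius = source radius + half the spatial-resolution FWHM.

    By convention the ROI is derived from the 113 keV main-window image
    (best image characteristics) and the identical circle is reused for all
    windows of the same acquisition, so that quantification and sensitivity
    calibration share one delineation rule.
    """
    if source_radius_mm < 0 or fwhm_mm < 0:
        raise ValidationError("source radius and FWHM must be non-negative")
    total = wi.values.sum()
    if total <= 0:
        raise NoSignalError("cannot place ROI on an all-zero image")
    rr, cc = np.mgrid[0:N_ROWS, 0:N_COLS]
    r0 = float((rr * wi.values).sum() / total)
    c0 = float((cc * wi.values).sum() / total)
    return Roi.circle((r0, c0), source_radius_mm + fwhm_mm / 2.0, pixel_pitch_mm)


def roi_count_rate(wi: WindowImage, roi: Roi) -> dict:
    """ROI count rate and its variance.

    rate = (sum of member-pixel values) / duration; variance propagates the
    per-pixel count variances (raw Poisson counts, or correction-squared
    scaled counts after uniformity) divided by duration squared.
    """
    member = roi.membership()
    if not member.any():
        raise NoPixelsError("ROI selects no pixels on the 16 x 16 grid")
    t = wi.duration_s
    return {
        "rate": float(wi.values[member].sum() / t),
        "variance": float(wi.variance[member].sum() / t ** 2),
    }
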