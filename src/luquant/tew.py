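"""Triple-energy-window (TEW) scatter correction.

The scatter contribution under a photopeak is estimated as the trapezoid
spanned by two narrow windows abutting the main window:

    scatter = (R_lower / w_lower + R_upper / w_upper) * w_main / 2

with w the window widths in keV.  The net rate is the gross main-window
rate minus this estimate, clamped at zero.  On pixelated CZT spectra the
low-energy tailing makes TEW imperfect (notably in the 55 keV window), so
a clamped result is flagged and the residual scatter tendency is absorbed
downstream by the energy-dependent build-up correction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .spectra import PhotopeakWindows

__all__ = ["RateMeasurement", "TewResult", "tew_net_rate"]


@dataclass(frozen=True)
class RateMeasurement:
    """A count rate (cps) with its variance ((cps)^2)."""

    rate: float
    variance: float = 0.0


@dataclass(frozen=True)
class TewResult:
    gross_rate: float
    scatter_rate: float
    net_rate: float
    variance: float
    clamped: bool


def tew_net_rate(main: RateMeasurement, lower: RateMeasurement,
                 upper: RateMeasurement, photopeak: PhotopeakWindows) -> TewResult:
    """Scatter-corrected net count rate for one photopeak.

    Variance propagates the main-window variance plus the scatter-window
    variances through the trapezoid weights; clamping does not reduce the
    reported variance.
    """
    w_main = photopeak.main.width_kev
    w_lo = photopeak.lower_scatter.width_kev
    w_up = photopeak.upper_scatter.width_kev
    if min(w_main, w_lo, w_up) <= 0:
        raise ValidationError("TEW requires strictly positive window widths")

    scatter = (lower.rate / w_lo + upper.rate / w_up) * w_main / 2.0
    net = main.rate - scatter
    clamped = net < 0
    variance = main.variance + (w_main / 2.0) ** 2 * (
        lower.variance / w_lo ** 2 + upper.variance / w_up ** 2)
    return TewResult(
        gross_rate=main.rate,
        scatter_rate=scatter,
        net_rate=max(net, 0.0),
        variance=variance,
        clamped=bool(clamped),
    )
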