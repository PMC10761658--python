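"""Joint activity/depth estimation from multi-photopeak count rates.

The measured ROI count rate in photopeak window i is modelled as

    R_i(A, d) = A * eps_i(d) * exp(-d * mu_i) * B_i(d * mu_i)

with A the source activity (MBq), d the collimator-to-source-surface depth
(mm), eps_i the distance-dependent system sensitivity, mu_i the linear
attenuation coefficient of the interposed material, and B_i = 1 + k_i d mu_i
the linearized build-up (or residual-scatter) correction.  Because
mu(55) > mu(113) > mu(208), the relative rates of the three windows encode
the depth, and a weighted least-squares fit of (A, d) against the two or
three measured rates recovers both parameters from a single planar view.

The minimizer is a damped Gauss-Newton (gradient-expansion /
Levenberg-Marquardt) iteration with analytic Jacobian.  The default fit is
unconstrained in d — a measurement whose relative window rates fall outside
what the model predicts at physical depths (e.g. excess 55 keV signal) then
converges to a flagged negative depth; an optional bounded mode enforces
d >= 0 instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .calibration import BuildupModel, SensitivityModel
from .errors import DegenerateDesignError, FitError, ValidationError
from .physics import LU177_HALF_LIFE_S, AttenuationContext, decay_correct

__all__ = [
    "MeasurementSet",
    "QuantificationResult",
    "forward_model",
    "initial_estimate",
    "estimate",
    "relative_deviation",
    "depth_error",
]

D_FIX_DEFAULT_MM = 20.0


@dataclass
class MeasurementSet:
    """Per-window ROI count rates feeding the estimator.

    ``rates``/``variances`` map photopeak label -> cps / (cps)^2;
    ``clamped`` marks windows whose TEW net rate was clamped at zero.
    ``scatter_corrected`` records whether the rates are TEW net rates, so
    calibration-mode discipline can be enforced downstream.
    """

    rates: dict[int, float]
    variances: dict[int, float]
    duration_s: float
    collimator: str
    scatter_corrected: bool
    clamped: dict[int, bool] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValidationError("duration must be positive")
        positive = [w for w, r in self.rates.items() if r > 0]
        if len(positive) < 2:
            raise ValidationError(
                "need >= 2 windows with positive rate (the fit has 2 free parameters)")
        for w in positive:
            if self.variances.get(w, 0.0) < 0:
                raise ValidationError(f"window {w}: variance must be non-negative")
        for w in self.rates:
            self.clamped.setdefault(w, False)


@dataclass
class QuantificationResult:
    activity_mbq: float
    depth_mm: float
    activity_stderr: float
    depth_stderr: float
    chi2: float
    n_iterations: int
    converged: bool
    negative_depth: bool
    initial_estimate: tuple[float, float]
    residuals: dict[int, float]          # R_meas - R_model per window used
    windows_used: list[int]
    weight_mode: str
    bounded: bool
    covariance: list | None = None       # 2x2, order (A, d)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "activity_mbq": self.activity_mbq,
            "depth_mm": self.depth_mm,
            "activity_stderr": self.activity_stderr,
            "depth_stderr": self.depth_stderr,
            "chi2": self.chi2,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "negative_depth": self.negative_depth,
            "initial_estimate": list(self.initial_estimate),
            "residuals": {int(k): float(v) for k, v in self.residuals.items()},
            "windows_used": list(self.windows_used),
            "weight_mode": self.weight_mode,
            "bounded": self.bounded,
            "covariance": self.covariance,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def forward_model(activity_mbq: float, depth_mm: float, mu: AttenuationContext,
                  sens: dict[int, SensitivityModel],
                  buildup: dict[int, BuildupModel],
                  windows: list[int] | None = None) -> dict[int, float]:
    """Modelled count rate per window: A * eps(d) * exp(-d mu) * (1 + k d mu).

    Negative depths are evaluated (extrapolation outside the calibrated
    range) but produce a warning.
    """
    if activity_mbq < 0:
        raise ValidationError("activity must be non-negative")
    labels = list(windows) if windows is not None else list(sens)
    for w in labels:
        if w not in sens or w not in buildup:
            raise KeyError(f"missing calibration entry for window {w}")
        if w not in mu.mu_mm:
            raise KeyError(f"missing attenuation coefficient for window {w}")
    if depth_mm < 0:
        warnings.warn(f"forward model evaluated at negative depth {depth_mm:g} mm "
                      "(extrapolation outside the calibrated range)")
    out = {}
    for w in labels:
        x = depth_mm * mu[w]
        out[w] = float(activity_mbq * sens[w].epsilon(depth_mm)
                       * np.exp(-x) * buildup[w].b(x))
    return out


def _model_and_jacobian(a: float, d: float, mu: AttenuationContext,
                        sens: dict[int, SensitivityModel],
                        buildup: dict[int, BuildupModel],
                        labels: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """Model rates and analytic Jacobian d(R)/d(A, d) for the fit windows."""
    r = np.empty(len(labels))
    jac = np.empty((len(labels), 2))
    for i, w in enumerate(labels):
        m = mu[w]
        eps = float(sens[w].epsilon(d))
        epsp = float(sens[w].epsilon_prime(d))
        att = np.exp(-d * m)
        b = 1.0 + buildup[w].k * d * m
        base = eps * att * b
        r[i] = a * base
        jac[i, 0] = base
        jac[i, 1] = a * att * (epsp * b - eps * m * b + eps * buildup[w].k * m)
    return r, jac


# ---------------------------------------------------------------------------
# Initial estimate
# ---------------------------------------------------------------------------

def initial_estimate(meas: MeasurementSet, mu: AttenuationContext,
                     sens: dict[int, SensitivityModel],
                     d_fix: float = D_FIX_DEFAULT_MM,
                     windows: list[int] | None = None) -> tuple[float, float]:
    """Starting values from the fixed-sensitivity log-linear model.

    Approximating eps_i(d) by eps_i(d_fix) makes
    ln(R_i / eps_i(d_fix)) = ln A - d * mu_i, so a linear regression of the
    left side on mu_i yields d from the slope and A from the intercept.
    Windows with non-positive rates are excluded; fewer than two usable
    windows, or effectively equal mu values, are errors.
    """
    labels = [w for w in (windows if windows is not None else meas.rates)
              if meas.rates.get(w, 0.0) > 0 and w in sens]
    if len(labels) < 2:
        raise ValidationError("initial estimate needs >= 2 windows with positive rates")
    mus = np.array([mu[w] for w in labels])
    if (mus.max() - mus.min()) / mus.max() < 1e-6:
        raise DegenerateDesignError(
            "all attenuation coefficients equal: depth is unidentifiable")
    y = np.array([np.log(meas.rates[w] / float(sens[w].epsilon(d_fix)))
                  for w in labels])
    slope, intercept = np.polyfit(mus, y, 1)
    return float(np.exp(intercept)), float(-slope)


# ---------------------------------------------------------------------------
# WLS fit
# ---------------------------------------------------------------------------

def _select_windows(meas: MeasurementSet, mu: AttenuationContext,
                    sens: dict, buildup: dict,
                    windows: list[int] | None,
                    warn_sink: list[str]) -> list[int]:
    labels = []
    for w in (windows if windows is not None else sorted(meas.rates)):
        if w not in meas.rates:
            raise ValidationError(f"window {w} not present in the measurement set")
        if w not in sens or w not in buildup:
            raise KeyError(f"missing calibration entry for window {w}")
        if w not in mu.mu_mm:
            raise KeyError(f"missing attenuation coefficient for window {w}")
        if meas.clamped.get(w) and meas.rates[w] == 0.0:
            msg = (f"window {w}: TEW net rate clamped at zero, excluded from fit")
            warn_sink.append(msg)
            warnings.warn(msg)
            continue
        if meas.rates[w] <= 0:
            msg = f"window {w}: non-positive rate, excluded from fit"
            warn_sink.append(msg)
            warnings.warn(msg)
            continue
        labels.append(w)
    if len(labels) < 2:
        raise ValidationError("fewer than 2 usable windows remain for the fit")
    mus = np.array([mu[w] for w in labels])
    if (mus.max() - mus.min()) / mus.max() < 0.01:
        raise DegenerateDesignError(
            "attenuation coefficients of the included windows are within 1% "
            "of each other: depth is unidentifiable")
    return labels


def _weights(meas: MeasurementSet, labels: list[int], mode: str) -> np.ndarray:
    """Per-window variance estimates sigma_i^2 for the WLS objective."""
    if mode == "poisson":
        var = np.array([meas.rates[w] / meas.duration_s for w in labels])
    elif mode == "inverse_rate":
        # literal inverse-measured-count-rate weighting
        var = np.array([meas.rates[w] for w in labels])
    elif mode == "provided":
        var = np.array([meas.variances[w] for w in labels])
    else:
        raise ValidationError(f"unknown weight mode {mode!r}")
    if np.any(var <= 0):
        raise ValidationError("weighting requires positive variance estimates")
    return var


def estimate(meas: MeasurementSet, mu: AttenuationContext,
             sens: dict[int, SensitivityModel],
             buildup: dict[int, BuildupModel], *,
             weight_mode: str = "poisson",
             bounded: bool = False,
             windows: list[int] | None = None,
             d_fix: float = D_FIX_DEFAULT_MM,
             tol: float = 1e-8,
             max_iterations: int = 200,
             d_max_mm: float = 200.0) -> QuantificationResult:
    """Weighted least-squares fit of (A, d) to the measured window rates.

    Minimizes sum_i (R_i,meas - R_i,model)^2 / sigma_i^2 by a damped
    Gauss-Newton iteration (damping x10 on a rejected step, /10 on an
    accepted one) starting from :func:`initial_estimate`.  ``weight_mode``:

    * ``"poisson"`` (default) — sigma_i^2 = R_i,meas / t, the Poisson rate
      variance; differs from literal inverse-rate weighting only by the
      common factor 1/t, leaving the optimum unchanged.
    * ``"inverse_rate"`` — sigma_i^2 = R_i,meas, the literal weighting.
    * ``"provided"`` — use the measurement set's propagated variances
      (e.g. TEW-propagated).

    In the default unconstrained mode a negative fitted depth is returned
    and flagged; with ``bounded=True`` the fit is repeated on the profile
    objective over d in [0, d_max_mm] (activity solved in closed form at
    each depth, the model being linear in A) and the boundary candidate
    d = 0 is compared explicitly, so a boundary solution is exact.
    """
    warn_sink: list[str] = []
    labels = _select_windows(meas, mu, sens, buildup, windows, warn_sink)
    var = _weights(meas, labels, weight_mode)
    sigma = np.sqrt(var)
    y = np.array([meas.rates[w] for w in labels])

    a0, d0 = initial_estimate(meas, mu, sens, d_fix=d_fix, windows=labels)

    def chi2_of(av, dv):
        r, _ = _model_and_jacobian(av, dv, mu, sens, buildup, labels)
        return float(np.sum(((y - r) / sigma) ** 2))

    # Safeguarded start: the fixed-sensitivity estimate approximates eps(d)
    # by eps(d_fix) and degrades far from d_fix, so also scan the profile
    # objective (A has a closed form at each depth) on a coarse depth grid
    # and start the iteration from the best candidate.  The analytic
    # estimate is still reported as `initial_estimate`.
    w_inv_all = 1.0 / var

    def profile_a(dv: float) -> float:
        m, _ = _model_and_jacobian(1.0, dv, mu, sens, buildup, labels)
        denom = float(np.sum(w_inv_all * m ** 2))
        return float(np.sum(w_inv_all * y * m)) / denom

    candidates = [(a0, d0)]
    for dv in np.arange(0.0, d_max_mm + 1e-9, 2.0):
        candidates.append((profile_a(dv), float(dv)))
    a, d = min(candidates, key=lambda c: chi2_of(*c))

    def lm(a: float, d: float) -> tuple[float, float, float, int, bool]:
        lam = 1e-3
        chi2 = chi2_of(a, d)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iterations + 1):
            r, jac = _model_and_jacobian(a, d, mu, sens, buildup, labels)
            jw = jac / sigma[:, None]
            rw = (y - r) / sigma
            jtj = jw.T @ jw
            g = jw.T @ rw
            accepted = False
            while lam < 1e12:
                try:
                    delta = np.linalg.solve(jtj + lam * np.diag(np.diag(jtj)), g)
                except np.linalg.LinAlgError as exc:
                    raise DegenerateDesignError(
                        f"singular normal equations in the (A, d) fit: {exc}") from exc
                if not np.all(np.isfinite(delta)):
                    raise FitError("non-finite step in the (A, d) fit")
                a_new, d_new = a + delta[0], d + delta[1]
                chi2_new = chi2_of(a_new, d_new)
                if chi2_new <= chi2:
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                break
            rel = max(abs(delta[0]) / max(abs(a_new), 1e-12),
                      abs(delta[1]) / max(abs(d_new), 1e-3))
            a, d, chi2 = a_new, d_new, chi2_new
            lam = max(lam / 10.0, 1e-12)
            if rel < tol:
                converged = True
                break
        return a, d, chi2, n_iter, converged

    a, d, chi2, n_iter, converged = lm(a, d)

    # The (A, d) objective forms a long, gently curved valley (the windows'
    # rates decay nearly proportionally at large depth), where the damped
    # step can stall short of the minimum.  Polish along the valley with a
    # 1-D Brent minimization of the profile objective in d, then re-run the
    # damped iteration from the polished point if it improved.
    res_polish = minimize_scalar(lambda dv: chi2_of(profile_a(dv), float(dv)),
                                 bounds=(d - 50.0, d + 50.0), method="bounded",
                                 options={"xatol": 1e-10})
    if res_polish.fun < chi2:
        a2, d2, chi2_2, n2, conv2 = lm(profile_a(float(res_polish.x)),
                                       float(res_polish.x))
        if chi2_2 <= chi2:
            a, d, chi2, converged = a2, d2, chi2_2, conv2
            n_iter += n2

    if not converged:
        msg = (f"(A, d) fit did not converge within {max_iterations} iterations "
               f"(last iterate A={a:g} MBq, d={d:g} mm)")
        warn_sink.append(msg)
        warnings.warn(msg)

    if bounded and d < 0:
        w_inv = 1.0 / var

        def profile_chi2(dv: float) -> float:
            m, _ = _model_and_jacobian(1.0, dv, mu, sens, buildup, labels)
            denom = float(np.sum(w_inv * m ** 2))
            a_hat = max(float(np.sum(w_inv * y * m)) / denom, 0.0)
            return float(np.sum(w_inv * (y - a_hat * m) ** 2))

        res = minimize_scalar(profile_chi2, bounds=(0.0, d_max_mm),
                              method="bounded", options={"xatol": 1e-8})
        d = 0.0 if profile_chi2(0.0) <= res.fun else float(res.x)
        m, _ = _model_and_jacobian(1.0, d, mu, sens, buildup, labels)
        a = max(float(np.sum(w_inv * y * m)) / float(np.sum(w_inv * m ** 2)), 0.0)
        chi2 = chi2_of(a, d)
        converged = True

    r_fin, jac_fin = _model_and_jacobian(a, d, mu, sens, buildup, labels)
    jw = jac_fin / sigma[:, None]
    try:
        cov = np.linalg.inv(jw.T @ jw)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    return QuantificationResult(
        activity_mbq=float(a), depth_mm=float(d),
        activity_stderr=float(stderr[0]), depth_stderr=float(stderr[1]),
        chi2=float(chi2), n_iterations=n_iter, converged=bool(converged),
        negative_depth=bool(d < 0), initial_estimate=(a0, d0),
        residuals={w: float(y[i] - r_fin[i]) for i, w in enumerate(labels)},
        windows_used=labels, weight_mode=weight_mode, bounded=bounded,
        covariance=cov.tolist(), warnings=warn_sink,
    )


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

def relative_deviation(activity_est_mbq: float, activity_ref_mbq: float,
                       dt_s: float = 0.0,
                       half_life_s: float = LU177_HALF_LIFE_S) -> float:
    """(A_est - A_ref) / A_ref after decay-correcting A_est to the reference
    time (``dt_s > 0`` when the estimate was measured after the reference)."""
    if activity_ref_mbq <= 0:
        raise ValidationError("reference activity must be positive")
    a_corr = decay_correct(activity_est_mbq, dt_s, half_life_s)
    return (a_corr - activity_ref_mbq) / activity_ref_mbq


def depth_error(depth_est_mm: float, depth_ref_mm: float) -> float:
    """Direct difference d_est - d_ref in mm."""
    return depth_est_mm - depth_ref_mm
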