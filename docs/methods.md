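# Methods

## Measurement model

The quantity fitted is the ROI count rate in each photopeak energy window
*i* ∈ {55, 113, 208} keV of ¹⁷⁷Lu:

    R_i(A, d) = A · ε_i(d) · exp(−d·μ_i) · B_i(d·μ_i),
    ε_i(d)    = c₀,ᵢ + c₁,ᵢ · exp(−d·c₂,ᵢ),
    B_i(x)    = 1 + k_i · x.

*A* is the source activity (MBq) and *d* the distance from the collimator
face to the nearest source surface (mm) — not an effective depth; the
self-attenuation of the calibration source is therefore baked into ε and
must be adjusted only when the measured object's thickness differs (see
*Intra-source attenuation* below).

Assumptions: a single dominant source in the field of view; a homogeneous
attenuating medium characterized by one μ per photon energy; sensitivity,
attenuation and build-up factorize; build-up is linear in d·μ over the
calibrated range (d·μ ≤ ~2.1). ε is distance-dependent on this camera
because septal penetration and collimator scatter grow with distance —
strongest for 208 keV photons through an LEHR collimator. Depth
identifiability requires μ₅₅ > μ₁₁₃ > μ₂₀₈, which holds for all
soft-tissue-like materials in the library; the estimator refuses to run if
the μ values of the included windows agree within 1 %.

Energy windows default to the camera's ¹⁷⁷Lu set (keV):
55.8: 45.8–49.7 / 49.7–59.7 / 59.7–63.6; 112.9: 96.5–100.5 / 100.5–120.8 /
120.8–124.8; 208.4: 186.5–193.8 / 193.8–216.7 / 216.7–224.0 (lower scatter
/ main / upper scatter). Windows are half-open [lo, hi) on the 0.1 keV bin
grid, so the abutting windows can never double-count; a count in the bin
starting exactly at a main window's upper edge belongs to the upper scatter
window.

## TEW scatter correction

Scatter under a photopeak is estimated as the trapezoid spanned by the two
abutting scatter windows, scatter = (R_low/w_low + R_up/w_up)·w_main/2, and
subtracted from the gross rate. The net rate is clamped at zero and the
clamp flagged; clamped-zero windows are excluded from the (A, d) fit (a
zero net rate has no defined weight, and exclusion degrades gracefully).
Variance is propagated from all three windows through the trapezoid
weights. On pixelated CZT the low-energy tailing makes TEW imperfect —
particularly in the 55 keV window — which is why B_i is retained in
TEW mode to absorb the residual over/under-correction, with its own k_i
fitted from TEW-corrected calibration rates. Gross-mode and TEW-mode
calibrations are distinct library entries and are never interchangeable.

## Calibration

**Sensitivity.** From an in-air series of a known activity at distances
0–160 mm (the simulator uses 20-mm steps), sensitivity points
rate/activity are fitted by ordinary (unweighted) nonlinear least squares
to ε(d). Initialization: c₀ starts at the lowest measured sensitivity;
(c₁, c₂) from a linear regression of log(sensitivity − c₀⁰) on distance,
excluding non-positive subtractions. The point estimate is the unweighted
fit as the procedure prescribes, but the *reported covariance* is the
heteroscedasticity-consistent sandwich (JᵀJ)⁻¹JᵀVJ(JᵀJ)⁻¹ when per-point
Poisson variances are available, because the absolute noise varies by an
order of magnitude along the series and the homoscedastic residual-based
covariance materially understates the uncertainty of all three parameters.

**Build-up.** From a fixed-distance series with PMMA thicknesses 0–90 mm,
B(s·μ) = R(s)/R(0)·exp(s·μ) with μ the PMMA coefficient at the window
energy; k is the closed-form slope Σx(B−1)/Σx² of the line constrained
through B(0) = 1 (an identity of the construction, so the intercept is
fixed, not fitted). The standard error of k propagates the rate variances
through B, including the covariance all points share via the common R(0)
reference. With the PMMA constants used throughout (ρ = 1.18 g/cm³,
μ/ρ = 0.20/0.16/0.13 cm²/g at 55/113/208 keV), the 0–90 mm range maps to
d·μ from 0 to 2.1 at 55 keV.

**Library discipline.** Entries are keyed exactly on (radionuclide,
collimator, window, scatter-corrected flag, source geometry). Missing keys
are errors listing what is available; cross-geometry reuse requires an
explicit override because septal penetration makes sensitivity
source-size-dependent (a tube-calibrated ε is not valid for a large
source, most visibly for LEHR at 208 keV).

## The (A, d) estimator

The fit minimizes Σᵢ (R_meas − R_model)²/σᵢ² by a damped Gauss–Newton
(gradient-expansion) iteration with analytic Jacobian: damping λ starts at
10⁻³, ×10 on a rejected step, ÷10 on an accepted one; convergence when the
relative parameter change falls below 10⁻⁸ (depth change measured against
max(|d|, 1 mm)); at most 200 iterations, with a non-convergence warning and
`converged = False` otherwise.

**Weights.** Default σᵢ² = R_meas/t, the Poisson variance of a rate from t
seconds of counting. A literal inverse-rate mode (σᵢ² = R_meas) is also
provided; for windows sharing one duration the two differ by a constant
factor and have the same optimum. A third mode uses the TEW-propagated
variances, which additionally down-weights windows whose scatter estimate
is noisy.

**Starting point and valley polish.** The analytic start solves the
fixed-sensitivity model ln(R/ε(d_fix)) = ln A − d·μ by linear regression on
μ (d_fix = 20 mm by default). That approximation degrades far from d_fix,
so the optimizer seeds from the best of this estimate and a coarse scan of
the profile objective (activity has a closed form at each depth, the model
being linear in A) over d = 0…200 mm in 2-mm steps. Because the objective
forms a long, gently curved valley at large depths (the windows' rates
decay nearly proportionally there), the damped iteration is followed by a
1-D Brent polish of the profile objective in d and, if that improves the
fit, a final damped pass. The analytic estimate is always reported in the
diagnostics.

**Unconstrained vs bounded depth.** By default d is unconstrained: a
measurement whose relative window rates fall outside what the model
predicts at physical depths (e.g. excess 55 keV signal) converges to a
negative depth, which is flagged rather than hidden — negative depths are
extrapolations and signal a model violation. The bounded mode does not use
a d = q² reparameterization (q = 0 is a stationary point of that map for
every objective, which makes boundary convergence fragile); instead, when
the unconstrained optimum is negative, the profile objective is minimized
over d ∈ [0, 200] mm with the boundary candidate d = 0 compared
explicitly, so a boundary solution is exact.

**Diagnostics.** Parameter covariance (JᵀWJ)⁻¹ at the optimum, χ²,
iteration count, per-window residuals, windows actually used, and the
initial estimate.

## Physics

Materials carry densities (g/cm³) and μ/ρ (cm²/g) at the three photopeak
energies; internal lengths are mm and μ is mm⁻¹. Water, soft tissue
(ICRU-44) and cortical bone (ICRU-44) values are log-log interpolations of
the standard NIST compilation to 55.8/112.9/208.4 keV; PMMA is pinned to
the calibration constants above. Mixtures combine μ/ρ linearly in mass
fractions with the volume-additive density rule 1/ρ = Σ wⱼ/ρⱼ (bone
lesions are treated as 50 % tissue / 50 % cortical bone by convention).
Decay correction uses the ¹⁷⁷Lu half-life of 6.4 days.

**Intra-source attenuation.** When the measured object's thickness T
differs from the calibration source's, the estimated activity is
multiplied by f(T_cal)/f(T_meas) with f(T) = (1 − e^(−μT))/(μT), the mean
transmission of a uniform slab emitting homogeneously over its thickness
(f(0) = 1). The slab geometry is this package's interpretation; the actual
sources are cylinders and spheres, for which the slab factor is a
first-order approximation along the viewing axis.

## The simulator

`luquant.simulate` generates every input the chain consumes from the
forward model with Poisson noise, all randomness flowing from one recorded
seed. Its defaults are the study conditions used throughout the tests:
sensitivity series at 0–160 mm in 20-mm steps, PMMA series at 0–90 mm in
10-mm steps, and measurements of ~20 MBq at 20 mm depth in soft tissue for
~200 s, giving on the order of 2 × 10⁴ counts in the 113 keV window —
patient-like statistics. The synthetic calibration truth uses sensitivities
of a few cps/MBq with distance-dependent components strongest (and
slowest-decaying) for 208 keV/LEHR, and build-up slopes k of 0.08–0.55,
larger without scatter correction and largest at 55 keV.

Scatter is injected as an explicit per-window fraction of the primary rate
(0.40/0.20/0.10 at 55/113/208 keV — synthetic values, not derived from
measured spectra): the main window receives the extra counts and the two
scatter windows are populated so the TEW trapezoid equals the injected
scatter in expectation. TEW is therefore *exactly unbiased* in this
simulator. Spectral images spread each window's counts over the 16 × 16
grid as an isotropic Gaussian (FWHM = 5 mm + 0.10·d, a linear
depth-resolution model) over a uniform background fraction (default 0, as
in shielded phantom geometries), uniformly across the window's energy
bins.

What the simulator does **not** model — and what passing tests therefore
do not demonstrate about real data: CZT low-energy tailing and the
resulting cross-talk between photopeaks (the reason TEW is imperfect in
practice), septal-penetration star patterns and their ROI-size effects,
collimator X-ray fluorescence, dead time, energy-calibration drift beyond
a global integer bin shift, and source-size dependence of the sensitivity.
End-to-end closure here validates the estimation chain, not the detector
physics.

## Problem sizes of the shipped checks

The test suite and `scripts/acceptance.py` use: 100 random noise-free
recovery scenarios (d ∈ [0, 100] mm); 50 Poisson scenarios compared
against an exhaustive (A, d) grid at 0.1 % × 0.1 mm resolution (agreement
judged within one grid step, with the A tolerance widened by the A-shift a
single d-step induces along the correlated valley); 100-seed calibration
closure at the standard distance and PMMA grids; and 50-seed end-to-end
image-pipeline replication. These sizes give stable statistics while
keeping the whole suite in the minutes range on one CPU.

## Known limitations

- The build-up linearization holds only over the calibrated d·μ range;
  extrapolation beyond ~2.1 is unvalidated.
- The method assumes the ROI captures the source counts consistently
  between calibration and measurement; ROI-rule mismatches bias A directly.
- Negative-depth results indicate model violation (excess low-energy
  signal); the bounded mode masks the symptom but not the cause.
- With an LEHR collimator the strong 208-keV distance dependence weakens
  depth identifiability; dropping the 208 keV window (the `windows` mask)
  can improve stability at the cost of one degree of freedom.
- The 55 keV scatter burden is the largest and least well corrected by
  TEW; its clamp flag should be monitored in low-count acquisitions.
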