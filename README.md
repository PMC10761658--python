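# luquant

Planar activity and source-depth quantification for ¹⁷⁷Lu with a small
pixelated CZT gamma-camera.

## The problem

¹⁷⁷Lu radionuclide therapy (e.g. [¹⁷⁷Lu]Lu-DOTA-TATE, [¹⁷⁷Lu]Lu-PSMA-617)
benefits from frequent activity measurements of superficial lesions or
pre-clinical tumours. A hand-held camera with a 16 × 16-pixel CZT detector
records, for every detector element, a full energy spectrum in 0.1 keV bins
(0–250 keV), so images for any energy window can be formed after the fact.
The obstacle to quantification from a single planar view is that the count
rate depends on the unknown amount of overlying tissue.

¹⁷⁷Lu emits photons at three useful energies — the ~55 keV characteristic
X-rays and the 113 keV and 208 keV gammas — which are attenuated
differently (μ₅₅ > μ₁₁₃ > μ₂₀₈ in soft-tissue-like materials). The relative
count rates of the three photopeak windows therefore encode the source
depth, and the absolute rates encode the activity. `luquant` implements
this multi-photopeak method: for each window *i*,

    R_i(A, d) = A · ε_i(d) · exp(−d·μ_i) · B_i(d·μ_i)

where *A* is the activity (MBq), *d* the collimator-to-source-surface depth
(mm), ε_i(d) = c₀ + c₁·exp(−d·c₂) the distance-dependent system sensitivity
(NEMA NU 1-2012 form; distance-dependent on this camera because of septal
penetration), μ_i the linear attenuation coefficient, and
B_i(x) = 1 + k_i·x a linearized build-up (or residual-scatter) correction.
A weighted least-squares fit of (A, d) to the two or three measured window
rates recovers both parameters from one acquisition. Scatter can be removed
beforehand with the triple-energy-window (TEW) estimate from narrow windows
abutting each photopeak; calibration models are fitted separately for gross
and TEW-corrected rates and the two modes are never mixed.

The package covers the whole chain:

- `luquant.spectra` — spectral-image I/O (open HDF5/CSV dialects), energy
  windowing, uniformity correction, automatic circular ROIs, ROI count
  rates with Poisson variance bookkeeping;
- `luquant.tew` — TEW scatter estimation with variance propagation and
  zero-clamping;
- `luquant.physics` — material library (water, soft tissue, cortical bone,
  PMMA, and mass-fraction mixtures), attenuation coefficients, decay
  correction, intra-source self-attenuation;
- `luquant.calibration` — sensitivity and build-up fits from
  characterization series, and a strictly-keyed calibration library;
- `luquant.quantify` — the joint (A, d) estimator with diagnostics,
  unconstrained (negative depths flagged) and bounded modes;
- `luquant.simulate` — a seeded Poisson simulator for every input the chain
  consumes, from count rates to full per-pixel spectral images;
- `luquant.cli` / `luquant.pipeline` — the `luquant` command-line workflow.

## Worked example

Simulate a patient-like acquisition (20 MBq at 20 mm depth in soft tissue,
3 minutes, ≈2 × 10⁴ counts in the 113 keV window) and quantify it:

```python
from luquant.simulate import ScenarioSpec, ImageSpec, simulate_spectral_image
from luquant.physics import get_material, linear_attenuation
from luquant.pipeline import measurement_from_image
from luquant.quantify import estimate, relative_deviation

spec = ScenarioSpec(true_activity_mbq=20.0, true_depth_mm=20.0,
                    duration_s=180.0, seed=7, image=ImageSpec())
img = simulate_spectral_image(spec)                  # 16 x 16 x 2500 counts
ms = measurement_from_image(img, spec.windows, tew=True,
                            source_radius_mm=10.0, fwhm_mm=7.0)
print("net rates:", {w: round(r, 2) for w, r in ms.rates.items()})

mu = linear_attenuation(get_material("soft_tissue"))
res = estimate(ms, mu, spec.sensitivity, spec.buildup)
print(f"A = {res.activity_mbq:.2f} +/- {res.activity_stderr:.2f} MBq")
print(f"d = {res.depth_mm:.2f} +/- {res.depth_stderr:.2f} mm")
print(f"chi2 = {res.chi2:.3f}, converged = {res.converged}")
print(f"relative deviation = {relative_deviation(res.activity_mbq, 20.0):+.3f}")
```

prints

```
net rates: {55: 44.76, 113: 98.94, 208: 71.02}
A = 19.85 +/- 0.78 MBq
d = 19.53 +/- 1.29 mm
chi2 = 0.927, converged = True
relative deviation = -0.007
```

The three TEW-corrected ROI rates (cps) are fitted jointly; the estimate
recovers the true activity within 0.7 % and the depth within 0.5 mm, with
standard errors from the fit covariance. The same workflow runs from the
shell:

```sh
luquant simulate --out data --seed 3
luquant calibrate-sensitivity --series data/sensitivity_series.csv \
    --library cal.yaml --collimator MEGP --tew
luquant calibrate-buildup --series data/buildup_series.csv \
    --library cal.yaml --collimator MEGP --tew
luquant quantify --input data/measurement.h5 --library cal.yaml \
    --out result.yaml --tew --material tissue:0.5,bone:0.5
```

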