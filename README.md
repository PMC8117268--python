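# flumen

Quantification of false-lumen (FL) pressurization in dissected vessels from
4D flow velocity fields. The package implements three metrics:

- **FLEF** — false lumen ejection fraction: the ratio (in %) of retrograde
  diastolic flow volume to antegrade flow volume through the entry tear.
- **MSDR** — maximum systolic deceleration rate (cm/s³): the absolute
  difference between maximum and minimum systolic acceleration of the
  FL-subsection mean speed, divided by the time between the extrema.
- **vWERP ΔP** — relative pressure between an inlet and an outlet plane from
  a virtual work-energy balance of the Navier–Stokes equations, using a
  divergence-free unit-flow virtual field obtained from a staggered-grid
  Stokes solve over the lumen segmentation. Traces are length-normalized
  (mmHg/m) and reduced to ΔP_max / ΔP_min; transseptal pressure is the
  frame-wise TL − FL difference.

It also ships:

- `flumen.phantom` — synthetic dissected-vessel phantoms (two-lumen masks
  with an entry tear, steady Poiseuille and pulsatile velocity fields with
  analytic ground truth, velocity noise at a prescribed VNR, simulated
  cohorts), so the whole pipeline is testable without any imaging data.
- `flumen.flow_analysis` — plane flow quantification, cardiac-phase
  detection, FL subsections, mean-speed/acceleration traces, centerline
  lengths, VNR estimation, and mask/plane perturbations for reproducibility
  analysis.
- `flumen.cohort_stats` — growth-rate outcome (≥ 3 mm/year ⇒ "enlarging"),
  Shapiro–Wilk-routed group comparisons, Pearson correlation matrices,
  OLS with heteroskedasticity-robust standard errors, and Bland–Altman
  limits-of-agreement summaries.
- `flumen.io` — NIfTI velocity volumes/masks with JSON sidecars, CSV
  traces/tables, provenance records.

## CLI

```sh
# generate a pulsatile dissection phantom (velocity + mask + tear plane + truth)
flumen phantom make --config phantom.yaml --seed 1 --out phantom/

# metrics
flumen metrics flef  --in phantom/velocity.nii --plane phantom/tear_plane.json --out out/
flumen metrics msdr  --in phantom/velocity.nii --mask phantom/mask.nii \
    --tear-axial-mm 100 --reference-plane phantom/tear_plane.json --out out/
flumen metrics vwerp --in phantom/velocity.nii --mask phantom/mask.nii \
    --lumen both --inlet inlet.json --outlet outlet.json --out out/

# cohort statistics and reproducibility perturbations
flumen cohort simulate --seed 1 --out cohort.csv
flumen cohort analyze --table cohort.csv --out out/
flumen repro perturb --mask phantom/mask.nii --mode larger --seed 1 --out out/
```

Planes are JSON files: `{"origin_mm": [...], "normal": [...],
"roi_radius_mm": r, "antegrade_sign": 1}`.

## Conventions

Velocities are stored in cm/s, grid spacing in mm, frame intervals in ms;
vWERP works in SI internally and reports mmHg (1 mmHg = 133.322 Pa). Mask
labels are 0 = background, 1 = true lumen (TL), 2 = false lumen (FL).
Default fluid constants: ρ = 1060 kg/m³, μ = 4 mPa·s.
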