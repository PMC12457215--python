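# doseqa

Patient-specific QA analytics on paired 3D dose distributions: global 3D
gamma-index evaluation, mean-target-dose difference (ΔD), percentile-based
action-level calibration at controlled failure rates, and the TG-218
action-interval formalism — driven either by real dose grids (DICOM RTDOSE /
NRRD) or by a built-in synthetic cohort generator.

## What it does

Given a reference dose grid (treatment planning system) and an evaluated dose
grid (independent secondary dose calculation), plus a target structure mask,
the package computes:

* **Gamma pass rates** `GPR(DD, DTA)` from a global 3D gamma evaluation with
  sub-voxel interpolated search, low-dose exclusion (default 5% of the
  reference maximum) and a brute-force oracle for validation
  (`doseqa.gamma_engine`).
* **Mean target dose difference** ΔD in percent, positive when the evaluated
  dose is higher (`doseqa.plan_metrics`).
* **Action levels** per metric from cohort percentiles at target failure
  rates q ∈ {0.02, 0.05, 0.1, 0.2}, rounded to multiples of 5 (GPR) and 0.5
  (|ΔD|), plus the combined-criteria 2×2 tabulation
  (`doseqa.action_levels`).
* **TG-218 statistics**: the action interval `2A = β·√(σ² + (x̄ − T)²)`,
  β/2 ↔ q conversion through the standard normal distribution, expected
  failure rates with binomial errors, and a simulated β/2 correction factor
  for right-truncated GPR distributions (`doseqa.tg218_stats`).
* **Synthetic cohorts** at two tiers: voxel-level paired grids (ellipsoidal
  target, exponential falloff, systematic/local/shift/noise perturbations)
  and result-level cohorts with Gaussian ΔD and clipped-Gaussian GPR
  distributions per ISDC flavor (`doseqa.synthetic_cohort`).

## CLI

```bash
# voxel-level: simulate paired grids, evaluate, calibrate
doseqa simulate --out cohort/ --seed 1 --n-plans 5
doseqa evaluate --plan-dir cohort/ --out results.csv --criteria "5,3;3,3;2,2;2,1"
doseqa action-levels --results results.csv --out al.csv --q "0.02,0.05,0.1,0.2"
doseqa tg218 --results results.csv --out tg218.csv

# full study in one shot (result-level synthetic cohort by default)
doseqa all --seed 1 --out report/ --fixed-al "gpr:3,3:90;dd:4.5"
```

Stages exchange a plan-results CSV (`plan_id, case_class, technique,
delta_d, gpr_5_3, gpr_3_3, gpr_2_2, gpr_2_1`); reports are CSV bundles with a
JSON provenance block (seed, config hash, version). Same config + seed gives
byte-identical outputs.

## Conventions worth knowing

* Grids are axis-aligned, indexed `(x, y, z)`, voxel-center origins, mm
  spacing, doses in Gy. Tilted DICOM orientations are rejected.
* Gamma is evaluated at reference voxel centers; the evaluated grid is
  sampled by trilinear interpolation with search step DTA/10 and a search
  radius bounded by the gamma cap (2.0). A point passes at γ < 1 (strict).
* Global normalization and the low-dose threshold both use the reference
  grid maximum.
* Percentiles use the linear-interpolation convention; threshold rounding is
  nearest-multiple with lenient ties by default (`rounding="up"` selects the
  round-toward-lenient convention).
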