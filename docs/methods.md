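# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `fltquant`.

## The quantification problem

FLT ([<sup>18</sup>F]-fluorothymidine) is a PET tracer retained by
proliferating cells, so falling FLT uptake is an early marker of treatment
response — often earlier than any change in tumor volume. In heterogeneous
tumors (PDX models in particular), a large necrotic core dilutes whole-tumor
summary statistics: the mean SUV barely moves even when the viable rim
responds strongly. The pipeline therefore (a) separates proliferative from
non-proliferative voxels with a per-scan reference threshold and (b)
analyzes the full voxel-SUV distribution rather than its mean.

## Proliferative threshold

A tumor voxel is proliferative iff `SUV ≥ mean_muscle + k·sd_muscle` with
`k = 2` by default (`threshold_sd_multiplier`). Conventions, each chosen
where the underlying procedure admits more than one reading:

- **Sample SD (n−1)** for the muscle reference and all ROI summaries — the
  conservative choice for small ROIs.
- **Inclusive boundary**: a voxel exactly at the threshold is proliferative
  ("greater than or equal"). Tie handling is exercised explicitly in tests.
- **Per-scan reference**: muscle statistics are recomputed for each animal
  and timepoint, so the threshold tracks each scan's own physiology; no
  pooling across scans.
- **Degenerate ROIs**: a single-voxel ROI yields sd = 0 with a warning in
  summaries, but the threshold operation refuses n < 2 (a spread estimated
  from one voxel is meaningless). An empty proliferative set is flagged, not
  summarized.

SUV is the body-weight convention, `SUV = C·w/A` for concentration C
(Bq/mL), weight w (g) and injected activity A (Bq), with tissue density
1 g/mL; decay correction is assumed applied upstream. Volumes may also be
supplied already in SUV units. Masks are strictly binary (any nonzero value
is membership); volumes and masks must share shape exactly and affine within
1e-4 — resampling is out of scope and mismatches are hard errors.

## Heterogeneity analysis

The fractional frequency of a bin is its voxel count divided by the total
tumor voxel count, normalizing distributions for tumor volume. Bins are
left-closed/right-open with the last bin closed; values outside the edges
raise an error naming the value (silently dropping them would break the
sum-to-one invariant). Default binning for reports: width 0.1 SUV from 0 to
the 99.9th percentile of the pooled sample (extended to the maximum so
nothing falls outside), configurable via `bin_width`.

Distribution comparison uses the two-sample Kolmogorov–Smirnov distance
computed on **raw voxel samples** (exact ECDFs evaluated at every pooled
sample point); binning is for reporting only, because binned KS discards
within-bin information. Cohort comparisons pool voxels across animals within
each cohort-timepoint, giving one D per cohort pair; a per-animal route is
available through `pool_tumor_voxels` but is not the default. Whether KS
sees all tumor voxels or only threshold-passing ones is a flag
(`ks_voxels = all | proliferative`, default `all`).

The p-value is exact when `n1·n2 ≤ 10^4` — lattice-path counting over all
`C(n1+n2, n1)` interleavings in exact integer arithmetic, with the path
constraint expressed on the integer numerator `|i·n2 − j·n1|` so no floating
comparison is involved — and otherwise uses the classic Kolmogorov limiting
distribution at effective size `n1·n2/(n1+n2)`. The method used is always
recorded in the result. The exact method assumes continuous data; with
cross-sample ties it is mildly conservative.

## Growth analysis

Caliper volume `V = (4π/3)(L1/2)(L2/2)((L1+L2)/4)` is evaluated exactly as
printed; it is symmetric in L1, L2 and homogeneous of degree 3, both
property-tested. Percent change is per subject from its own day-0 baseline;
subjects without a baseline are excluded with a logged warning. Vehicle
normalization divides treated subjects' percent changes by the vehicle-arm
mean on that day; a zero vehicle mean is a degenerate-normalization error.

Mann–Whitney U is two-tailed: exact enumeration when `min(n1,n2) ≤ 8` and
the pooled sample is tie-free, else the normal approximation with midranks,
tie-corrected variance and continuity correction (the exact branch refuses
ties rather than midranking them; the method is recorded). Grubbs screening
is one pass per group-day at two-sided α = 0.05 — `G = max|x−x̄|/s` against
`G_crit = ((n−1)/√n)·√(t²/(n−2+t²))`, t the upper α/(2n) Student-t quantile
on n−2 df — and is not re-applied after a removal. No multiple-testing
correction is applied across days or comparisons; raw p-values are reported.

## In-vitro analysis

The module consumes per-well scalar signals (GFP viability, 2DG
bioluminescence, EdU fluorescence); image-to-signal extraction is upstream.
Percent survival is `100·mean(treated)/mean(control)` and percent change is
`100·(mean(treated)−mean(control))/mean(control)` (negative = decrease), so
`survival = 100 + change` holds identically. The reported spread is the
treated-replicate sample SD on the percent scale. No automatic outlier
removal at the plate level — Grubbs is reserved for in-vivo cohorts.
Biomarker-vs-viability regression is ordinary least squares with
`R² = 1 − SS_res/SS_tot` and a two-tailed slope p from Student-t on n−2 df;
a constant response returns R² = 0 with a warning rather than NaN.

## Synthetic data: what it emulates and what it does not

`generate_phantom` builds an ellipsoidal tumor with a **concentric**
necrotic core plus a cuboid muscle region, on a grid with 0.5 mm isotropic
voxels. Region intensities are independent Gaussians clipped at zero:

| parameter | default | rationale |
|---|---|---|
| necrotic core SUV | 0.4 ± 0.05 | level observed for non-proliferative voxels |
| necrotic fraction | 0.45 | midpoint of the 30–60% range typical of necrotic PDX tumors |
| viable rim SUV | 1.2 ± 0.2 | **assumption** — chosen well above muscle so the threshold separates regions; no measured value exists |
| muscle SUV | 0.5 ± 0.05 | typical low reference uptake; gives nominal threshold 0.6 |
| suppression | 1.0 (none) | multiplies the viable mean only; necrotic tissue is treatment-invariant |

The core is the innermost `necrotic_fraction` of tumor voxels by normalized
ellipsoidal radius, selected by stable rank so the realized fraction is
exact to one voxel (a plain radius quantile overshoots by ~1% because the
symmetric ellipsoid produces heavily tied radii). The tumor sits toward the
high corner of the grid and the muscle cuboid at the low corner, so both
fit with maximal separation on small grids; overlap or out-of-bounds
geometry raises a sizing error rather than silently truncating.

With the defaults the closed-form expected proliferative fraction at the
nominal threshold 0.6 is `0.55·Φ(3) + 0.45·Φ(−4) ≈ 0.549`, which the
pipeline recovers within ±0.03 on a ~50,000-voxel phantom (acceptance test).

Longitudinal series share geometry across timepoints; voxel noise is redrawn
per timepoint from a sub-seed derived deterministically from the base seed,
and the viable mean is scaled by each timepoint's suppression factor. The
default in-silico study design is four arms × two timepoints (day 0 and
day 10) with suppressions vehicle 1.0, trastuzumab 0.8, niraparib 0.8,
combination 0.7 — ordered by the intended effect strength, an assumption of
the generator.

Growth cohorts draw baselines uniformly from the 125–300 mm³ enrollment
window and compound per-assessment multiplicative growth
`V ← V·(1 + N(μ, σ)/100)` (floored at 0) over six 3-day assessments; the
default arm rates (+13.8 / +6.1 / +3.3 / −6.3 % per assessment) compound to
endpoint changes of roughly +117 / +43 / +22 / −32 %. Tumors are recorded as
equal perpendicular lengths so stored volumes satisfy the caliper formula
exactly. Plates draw well signals as `N(fraction·control, sd·control)`
clipped at 0, five replicates per condition; the default viability fractions
place 1 µg/mL trastuzumab at 0.60, 1 µM niraparib at 0.80 and the
combination at 0.42 of control, and the EdU fractions encode decreases of
67.5 / 22.9 / 79.7 %.

**Not modeled**: spatial autocorrelation and scanner noise texture, partial
volume effects, attenuation/reconstruction physics, realistic anatomy,
irregular necrosis geometry, growth-driven changes in tumor size between
imaging timepoints, and plate edge effects. Passing tests therefore
demonstrate the correctness and calibration of the *analysis* under the
stated statistical model, not performance on real scanner data — in real
data the threshold and KS comparisons inherit additional variance from
registration, partial volume and ROI annotation that the phantoms do not
carry.

## Determinism and problem sizes

Every generator takes an explicit seed; sub-seeds are derived via
`SeedSequence` and kept below 2^31. NIfTI gzip output uses a zeroed
timestamp, CSV column order is fixed, and manifest JSON keys are sorted, so
a rerun with the same config and seed is byte-identical (checked end to end
in the acceptance suite). Simulation-based checks use phantoms of 24³–32³
voxels (≈600–1,500 tumor voxels) with 500-voxel subsamples for KS
calibration, and one 96³ phantom (≈51,000 tumor voxels) for
proliferative-fraction recovery; these sizes give stable statistics while
keeping the default suite fast.

## Known limitations

- The exact KS p-value is conservative under heavy cross-sample ties; voxel
  SUVs are effectively continuous, so this matters only for artificial data.
- The asymptotic KS p uses the limiting Kolmogorov distribution; scipy's
  finite-n corrected variant differs by ≲0.02 at n ≈ 150 per side.
- Grubbs is single-pass by design; iterative generalized ESD is out of scope.
- `normalize_to_vehicle` is undefined when the vehicle arm's mean change is
  exactly zero (error by contract).
- No image registration or resampling: inputs must be co-registered.
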