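# fltquant

Quantification of early treatment response in heterogeneous tumors imaged
with [<sup>18</sup>F]FLT-PET, for preclinical imaging scientists working with
xenograft and patient-derived xenograft (PDX) models.

PDX tumors often carry large necrotic cores (30–60% of volume), so the mean
standardized uptake value (SUV) of the whole tumor is insensitive to early
proliferative change. This package implements the analysis chain that
addresses that problem:

- **Muscle-referenced proliferative classification.** For each scan, a tumor
  voxel is proliferative iff

  `SUV ≥ SUV_mean(muscle) + 2·SD(muscle)`

  (inclusive boundary; sample SD; muscle statistics recomputed per scan).
  Voxels below the cutoff are treated as necrotic/non-proliferative.
- **Fractional-frequency heterogeneity analysis.** Tumor voxel-SUV histograms
  normalized by total voxel count (so tumors of different sizes compare
  directly), with distribution shifts between timepoints or cohorts
  quantified by the two-sample Kolmogorov–Smirnov distance
  `D = sup_x |F̂_a(x) − F̂_b(x)|` on the raw voxel samples.
- **Caliper growth curves.** `V = (4π/3)·(L1/2)·(L2/2)·((L1+L2)/4)` from two
  perpendicular lengths, percent change from each subject's own baseline,
  vehicle normalization, two-tailed Mann–Whitney comparisons, and one-pass
  Grubbs (extreme studentized deviate) outlier screening.
- **In-vitro quantification.** Dose–response percent survival, assay percent
  changes (2DG glucose uptake, EdU proliferation), and OLS regression of an
  early biomarker against endpoint viability (R², slope p-value).
- **Seeded synthetic generators** for all of the above: SUV phantoms with a
  concentric necrotic core (SUV ≈ 0.4) and viable rim, longitudinal series
  with treatment modeled as multiplicative suppression of the viable-rim
  mean, four-arm growth cohorts, and assay plates.

Volumes travel as NIfTI, tables as CSV, configuration and run manifests as
JSON; reruns with the same seed and config are byte-identical.

## Worked example

```python
import fltquant as fq

# a 64^3 phantom: 45% necrotic core at SUV 0.4±0.05, viable rim 1.2±0.2,
# muscle reference 0.5±0.05
spec = fq.PhantomSpec(seed=42)
study, truth = fq.generate_phantom(spec)

q = fq.quantify_study(study)
print(f"threshold          {q.classification.threshold:.4f}")
print(f"prolif. fraction   {q.classification.proliferative_fraction:.4f}")
print(f"analytic fraction  {truth.true_proliferative_fraction:.4f}")

# baseline vs day 10 under 50% suppression of viable uptake
series = fq.generate_longitudinal_study(spec, [(0, 1.0), (10, 0.5)])
ks = fq.longitudinal_ks([series[0]], [series[1]])
print(f"KS distance        {ks.distance:.4f}  (p = {ks.p_value:.3g}, {ks.method})")
```

prints

```
threshold          0.5955
prolif. fraction   0.5494
analytic fraction  0.5493
KS distance        0.4801  (p = 0, asymptotic)
```

The threshold lands at ≈ 0.6 (muscle 0.5 + 2×0.05); the recovered
proliferative fraction matches the closed-form normal-tail prediction
0.55·Φ(3) + 0.45·Φ(−4) ≈ 0.549; and halving the viable-rim mean produces a
large, highly significant KS shift even though necrotic voxels are
unchanged.

The same pipeline runs end to end from a shell:

```sh
fltquant run-all --seed 1 --out results/run
fltquant simulate phantom --seed 3 --out sim/
fltquant quantify --suv sim/phantom-3_suv.nii.gz \
    --tumor-mask sim/phantom-3_tumor_mask.nii.gz \
    --muscle-mask sim/phantom-3_muscle_mask.nii.gz
```

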