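# fatmap — radial fat-mapping of paraspinal muscles with 1D SPM

`fatmap` quantifies *where* fat accumulates inside the lumbar paraspinal
muscles (multifidus, erector spinae, psoas), not just how much.  It is
aimed at musculoskeletal imaging researchers working with water–fat MRI
fat-fraction maps and muscle segmentations in cohorts of chronic
low-back-pain patients and controls.

## The method

For each subject's axial fat-fraction slice at the L4L5 disc:

1. **Center of rotation (CoR).**  The motion-segment pivot is placed at
   the center of the posterior quarter of the disc's mid-sagittal
   anteroposterior diameter: `CoR = P + 0.125 (A − P)` for posterior and
   anterior endpoints `P`, `A`.
2. **Radial ROIs.**  Concentric one-pixel annuli radiate outward from
   the CoR; annulus `k` holds the mask pixels with distance
   `k ≤ d < k+1`.  The mean fat-infiltration percentage (FI%) per
   annulus forms a radial fat-distribution curve per muscle.
3. **Smoothing and normalization.**  A three-point moving average is
   applied, then each curve is distance-normalized so its x-axis spans
   0–100 % of that muscle's radial width (101 nodes by default).
4. **Statistics.**  Groups are compared with the node-wise two-sample t
   statistic treated as a smooth 1D field, SPM{t}.  Random field theory
   gives the critical threshold `t*` solving

   `α = 1 − exp(−[P(T > u) + R · EC₁(u)])`,  `R = (Q−1)/FWHM`,

   with `EC₁(u) = √(4 ln 2)/(2π) · (1 + u²/ν)^(−(ν−1)/2)` and the
   residual smoothness FWHM estimated from the variance-normalized
   residual curves.  Contiguous spans with `|t| > t*` are reported as
   clusters with RFT extent p-values.  Overall mean FI% is compared with
   ordinary unpaired t-tests, and each curve's global peak is classified
   into deep / intermediate / superficial tertiles of radial width.

Because no imaging data ship with the package, a synthetic phantom
generator (`fatmap.synthetic`) produces cohorts with analytically known
radial FI structure — annular-sector muscles, deep-peaked baseline
curves, a localized patient bump, and smooth noise — so every stage is
testable against closed-form ground truth.

## Worked example

```bash
fatmap simulate --out demo_cohort --seed 7        # 20 patients + 20 controls
printf 'data_dir: demo_cohort\nout_dir: demo_out\n' > demo.yaml
fatmap run --config demo.yaml
```

The phantom cohort adds an 8-FI-point Gaussian bump at 15 % radial depth
to the patients' multifidus only (noise SD 5).  The run prints, among
other things:

```
"group/multifidus": {
 "clusters": [[7.515, 19.260, 0.00759]],
 "n_clusters": 1,
 "overall_mean_difference": -0.639,
 "overall_mean_p": 0.387
}
```

The SPM comparison finds one significant cluster spanning 7.5–19.3 % of
the radial width (cluster p = 0.0076, threshold t* = 3.08 at df = 38) —
it contains the true 15 % bump center — while the whole-muscle mean FI%
difference (−0.64 points, p = 0.39) misses the localized effect
entirely.  That contrast is the point of the method: spatially localized
fat infiltration is invisible to overall means.  The unaffected erector
spinae and psoas show no SPM clusters.  Per-muscle deep-peak prevalence
is also reported (here 1.0 for multifidus and erector spinae, 0.1 for
the flatter psoas).

`demo_out/` contains per-subject curves (`profiles.csv`), peak summaries
(`peaks.csv`), overall means, one JSON per comparison × muscle with the
full t field, threshold and clusters, and a run manifest.

## Library surface

```python
from fatmap import (
    locate_cor, distance_map,                  # geometry
    compute_fat_fraction, read_slice_bundle,   # imaging I/O
    build_radial_profile, smooth_profile,      # fat-maps
    normalize_profile, detect_peak,
    spm_ttest2, rft_threshold, unpaired_ttest, # statistics
    generate_cohort, SyntheticCohortConfig,    # phantoms
    run_analysis, stratify,                    # pipeline
)
```

Stratification rules cover the standard clinical comparisons: patient vs control,
cartilage-endplate damage, Pfirrmann grade > 3 vs ≤ 3, Modic changes,
and VAS > 6 vs ≤ 6, each applicable within a group subset.

See `docs/methods.md` for modeling assumptions, parameter defaults and
numerical choices.
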