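# Methods note

This note records the modeling assumptions, parameter defaults and
numerical choices behind `fatmap`, in the spirit of a statistics
package's model documentation.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Radial fat-mapping model

A subject is represented by one axial fat-fraction slice at the L4L5
disc center (FI% per pixel, missing marker for pixels outside the body
or with zero water+fat signal) and binary masks for multifidus, erector
spinae and psoas.  The analysis assumes isotropic in-plane pixels and a
single slice; volumetric extensions are out of scope.

**CoR.**  The motion-segment center of rotation is the fixed geometric
approximation `P + 0.125 (A − P)` on the disc's mid-sagittal AP
diameter.  Coordinates are continuous `(row, col)`, 0-based, origin
top-left; distances are Euclidean from pixel centers, so the CoR is
generally sub-pixel.

**Annuli.**  Annulus `k` is the half-open radial band `[k, k+1)` in
pixel units.  Half-open binning makes the annuli an exact partition of
the mask (tested as such), and the one-pixel width means each muscle has
its own number of occupied annuli depending on its size and distance
from the CoR.  Pixels with missing FI are excluded from annulus means;
an annulus whose pixels are all missing is itself missing.

**Smoothing, then normalization.**  The raw per-annulus curve receives
a three-point moving average (one-sided two-point means at the ends);
missing interior annuli are first filled by linear interpolation between
their nearest occupied neighbors, because the downstream field
statistics need a gap-free continuum.  The smoothed curve is then
linearly resampled onto `n_nodes = 101` equally spaced nodes spanning
the innermost-to-outermost occupied annulus, so node positions read
directly as percent radial width (0, 1, …, 100).  Endpoint values are
preserved exactly.  101 nodes resolves every annulus of any plausible
muscle (a muscle spanning ~30 annuli has ~3.5 nodes per annulus) without
inflating the resel count, which depends on smoothness, not node count.

**Peaks.**  The curve's global maximum is reported with its depth; ties
break toward the smallest depth (the deterministic choice that makes a
constant curve report depth 0).  Region labels use equal tertiles by
default (deep < 33.3 %, superficial > 66.7 %), configurable, since the
deep/intermediate/superficial qualifiers have no canonical printed
cut-offs.

**Laterality.**  When masks are provided per side, the default policy
builds one curve per side and averages them node-wise per subject
(`average`); `left`, `right` and `merged` (pixel pooling) are available.
Averaging in normalized coordinates respects the fact that the two
sides have different absolute radial spans.

## 1D SPM statistics

**t field.**  At each node the standard pooled-variance two-sample t
statistic; residuals are subject deviations from their group's node-wise
mean.  The implementation is asserted equal to scalar t-tests run
independently per node at 1e-10.

**Smoothness.**  Residual curves are variance-normalized per node,
differentiated along the field with central differences, and the
smoothness recovered from the unit-variance Gaussian-field identity
`E[(dZ/dx)²] = 4 ln 2 / FWHM²`, averaging the squared gradient over
nodes and curves.  The estimate is clamped to `[1, 10·Q]`; identically
constant residuals raise a distinct infinite-smoothness error rather
than returning a clamp value.  Monte-Carlo tests recover a known
20-node kernel within 25 % and confirm white noise estimates below 3
nodes.

**Threshold.**  `t*` solves `α = 1 − exp(−tails · [EC₀(u) + R·EC₁(u)])`
by Brent's method (bracketed from the scalar critical value, residual
tolerance 1e-8), with `R = (Q−1)/FWHM` resels, `EC₀` the t upper tail
and `EC₁` the 1D EC density of a t field.  The exponentiated
(Poisson-clumping) form is used rather than the bare expected-EC sum so
the solved quantity is itself a probability; the two agree to O(α²).
Consequently the resels→0 limit approaches the scalar one-tailed
critical value up to that same O(α²) refinement (≈1 % in t at α=0.05),
which is the tolerance the limit test uses.  Two-sided inference
(default) doubles the expected EC and thresholds `|t|`; directional
statements ("larger in patients") come from the sign of each cluster.

**Clusters.**  Maximal supra-threshold runs; span endpoints are located
by linear interpolation of the threshold crossing between nodes, so
reported ranges such as "13.4–17.2 %" are sub-node.  Cluster p-values
use the standard RFT approximation: expected cluster count
`E_m = tails·(EC₀ + R·EC₁)`, expected supra-threshold volume
`E_n = tails·R·P(T>u)`, extent distribution
`P(extent ≥ k) = exp(−(Γ(3/2)·E_m/E_n)²·k²)` in resel units, and
`p = 1 − exp(−E_m · P(extent ≥ k))`.  Set-level inference and
permutation alternatives are not implemented.  No multiplicity
correction is applied across muscles or comparisons; each comparison
runs at its own α as a standalone hypothesis.

**Calibration.**  The package's own null simulator (white Gaussian node
noise convolved with a Gaussian kernel, variance-renormalized via the
kernel root-sum-of-squares on padded noise, hence exactly stationary
unit variance) drives two independent checks: the empirical 95th
percentile of simulated field maxima against the analytic threshold,
and the family-wise false-positive rate of the complete pipeline
(estimated smoothness, not the true one) against α.  The acceptance
script reruns the latter at 5000 repetitions, n = 20/20, Q = 101,
noise FWHM 10.

## Synthetic phantoms

The generator emulates the *structure* of paraspinal fat-mapping data,
not MRI physics:

- **Geometry.**  Muscles are disjoint annular sectors around a fixed
  CoR, so normalized radial depth has the closed form
  `(d − r_in)/(r_out − r_in)` — analytic ground truth beats anatomical
  realism for testing.  Default radial spans use half-integer radii so
  annulus centers `k + 0.5` align exactly with the depth grid, and the
  default CoR sits off the pixel lattice: with an on-lattice CoR every
  pixel distance is the square root of an integer, and the
  number-theoretic clumping of such distances biases annulus means by
  ~0.1 px.  Disc endpoints are constructed so the 12.5 % rule lands
  exactly on the configured CoR.
- **Curves.**  Baselines are a plateau plus Gaussian peak per muscle:
  multifidus 15 + 28·exp(…) peaking at 15 % depth (FWHM 25 %), erector
  spinae 16 + 32 at 20 % (FWHM 28 %), psoas 10 + 5 at 70 % (FWHM 45 %) —
  deep-peaked posterior muscles, flat low psoas, with magnitudes chosen
  to sit in the realistic 10–55 FI% range rather than asserted as
  literature values.
- **Effect.**  Patients receive a Gaussian bump in one target muscle;
  default 8 FI points at 15 % depth, FWHM 15 % — a localized deep
  multifidus excess of the size that separates groups without being
  trivially visible in overall means.
- **Noise.**  Smooth noise (default SD 5 FI points, FWHM 15 nodes) is
  drawn in the radial-depth domain and painted onto pixels by depth.
  This guarantees the extracted curves satisfy the smooth-Gaussian
  residual model the RFT inference assumes.  Real data differ here:
  pixel noise also varies tangentially within an annulus and partially
  averages out, and segmentation error perturbs the mask edge — so
  passing tests validate the pipeline's statistics under its stated
  model, not robustness to arbitrary real-world noise.
- **Forward model.**  `expected_profile` predicts the noise-free
  extracted curve analytically (continuum annulus mean radii
  `(2/3)(b³−a³)/(b²−a²)`, curve evaluation, three-point smoothing, node
  resampling); phantoms reproduce it to < 0.5 FI points, the residual
  being pixel discretization within annuli.
- **Metadata.**  VAS/ODI/CEP/Pfirrmann/Modic are sampled from
  group-dependent distributions chosen so every stratification rule
  yields two non-empty subgroups at default cohort sizes (patients:
  VAS ≥ 4, ODI ≥ 30, CEP 60 %, Pfirrmann 2–5, Modic 40 %; controls
  low-symptom with milder grades).

## Problem sizes and determinism

Default phantom cohorts are 20 + 20 subjects on 96×96 grids — group
sizes of the order of the motivating study, an image just large enough
for ~30 one-pixel annuli per muscle.  Monte-Carlo checks use 5000
repetitions for error-rate calibration and threshold validation and 200
for effect-recovery power; these sizes put binomial uncertainty well
inside the asserted bands.  Every stochastic routine takes an explicit
seed (NumPy `default_rng`), dataset generation is byte-deterministic
given its seed, and `run_analysis` reruns are byte-identical.

## Known limitations

- Single-slice 2D analysis; no volumetric fat mapping, cross-sectional
  area or atrophy metrics.
- RFT inference relies on the smooth-Gaussian residual model; very
  rough residual fields (FWHM near 1 node) push the EC approximation
  away from nominal α, and no permutation fallback is provided.
- Equivalence with any particular Matlab SPM implementation is not
  claimed; the contract is the set of formulas above plus the
  calibration checks.
- DICOM ingestion, multi-echo water–fat reconstruction and clinical
  grading of discs are explicitly inputs, not package functionality.
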