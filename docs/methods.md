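# Methods

This note records the models, conventions and design choices behind
`aneukit`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the synthetic tests do and
do not demonstrate about real data.

## Blood rheology

Four viscosity laws are implemented (`aneukit.rheology`), with
parameter defaults taken from the standard human-blood literature
values:

| law | form | defaults |
|---|---|---|
| Newtonian | η = μ | μ = 0.004 Pa·s |
| Carreau–Yasuda | η∞ + (η0 − η∞)(1 + (λγ̇)^a)^((n−1)/a) | η0 = 0.16 Pa·s, η∞ = 0.004 Pa·s, λ = 8.2 s, a = 0.64, n = 0.2128 |
| Casson | (√(τ0/γ̇) + √η_c)² | H = 0.40, η_plasma = 1.4 mPa·s |
| Herschel–Bulkley | τ0/γ̇ + k(γ̇/γ̇c)^(n−1) | τ0 = 0.01 Pa, k = 0.04, n = 0.7, γ̇c = 0.001 s⁻¹ |

The Casson law is only specified in the source literature through
hematocrit and plasma viscosity; we close it with the Merrill
relations τ0 = 0.1(0.625·H)³ Pa and η_c = η_plasma(1 − H)^(−2.5).
This is an assumption: other closures exist, and the exact one used
inside commercial solvers is generally unstated.

Casson and Herschel–Bulkley diverge as γ̇ → 0 (yield stress); to keep
viscosity fields finite, evaluations clamp γ̇ from below at a
configurable floor (default 1e−6 s⁻¹), mirroring the internal clipping
that production CFD codes apply. The shear-rate magnitude is
γ̇ = √(2 S:S) with S the symmetric velocity-gradient tensor from
central differences (one-sided at array boundaries). The Reynolds
helper implements the standard pipe formula Re = 4ρQ/(πμD); it does
not attempt to reproduce any particular literature value, since those
depend on unstated waveform details.

## Wall-shear metrics

All six parameters are defined on a per-node shear-vector time series
τ(t) with node areas:

* TAWSS per node: periodic trapezoidal time average of |τ|. All time
  integrals close the cycle (the last→first segment is included), so
  for 20 equispaced frames every frame carries equal weight.
* STA-WSS: area-weighted spatial mean of TAWSS. Spatial aggregates are
  area-weighted throughout (mesh-independence); a node-count-weighted
  OSI aggregate is available for sensitivity checks.
* WSS-max: global max of |τ| over nodes and frames.
* WSS-min: "spatiotemporally averaged minimum" is ambiguous in the
  field; the default reading is the time average of the per-frame
  spatial minimum, with `min_mode="global_min"` as the alternative.
* OSI = ½(1 − |∫τ dt| / ∫|τ| dt) (He–Ku); a node with identically
  zero τ is defined to have OSI 0. The OSI/RRT formulas are the
  universal ones in the aneurysm-CFD literature; sources that report
  these metrics rarely restate them.
* RRT = 1/((1 − 2·OSI)·TAWSS) (Himburg), denominator clamped at 1e−6
  (logged when triggered, i.e. fully oscillatory or zero-shear nodes).
* LSA: percent of wall area with TAWSS strictly below 2 Pa; a node at
  exactly 2 Pa is not low-shear.

## Vortex analysis

Swirling regions are the voxels where the middle eigenvalue of
S² + Ω² is negative (λ2 criterion, threshold 0 by default); the
Q-criterion is available as an alternative detector. Vortex masks are
confined to the one-voxel-eroded sac interior because the difference
stencils straddle the wall in the boundary layer (velocity jumps to
zero there and would register as spurious swirl). Components smaller
than 8 voxels are dropped as noise.

DVO is defined here as the cyclic consecutive-frame Dice coefficient
of the vortex masks, averaged over the cycle: 1 for a temporally
stable vortex, decreasing with vortex motion. A frame pair with two
empty masks contributes 1 (no vortex, nothing moved); exactly one
empty contributes 0. A `reference` mode (each frame against the
temporal union) is provided since the original definition in the
literature is ambiguous between the two; consecutive-pair is the
default because it directly expresses "temporal stability". Vt/V is
the time-averaged vortex-voxel count over the sac-voxel count.

## Directional velocity informatics

The angle θ ∈ [0, π] between each voxel's velocity and the estimated
inflow-jet direction is mapped linearly to gray = round-half-up
(255·θ/π): gray 0 means flow aligned with the jet, 255 opposed. The
linear-in-angle map is a reconstruction — the encodings used in prior
studies live in unavailable supplements — chosen for monotonicity and
simplicity; its anchor (low gray = jet-aligned) matches the reported
interpretation of the features. Voxels slower than 1e−6 mm/s are
excluded (stagnant direction undefined). Jet direction is the mean
velocity over sac voxels within 1.5 voxel spacings of the ostium
plane at the peak-speed frame, falling back to the sac-mean direction
when the near-ostium flux cancels.

First-order features (18) use the raw 0–255 grays; entropy and
uniformity use the discrete integer histogram. Matrix features use an
equal-width quantization of [0, 256) into n_levels bins (default 16;
gray 0 → level 1, 255 → level n). GLCM (24 features) and GLRLM (16)
are computed per direction over the 13 unique 3-D distance-1 offsets
and averaged; GLSZM (16) uses 26-connected equal-level zones. All
formulas follow the IBSI reference definitions; degenerate cases are
pinned (constant volume: skewness/kurtosis 0, GLCM correlation and
MCC 1, IMC1/IMC2 0). Features are extracted from the peak-systole
frame by default; per-frame extraction with feature averaging is
available because the temporal handling in prior studies is unstated.

## Agreement statistics

RPD uses the symmetric signless form 100·|a − b|/((|a| + |b|)/2)
(defined 0 when both magnitudes vanish); cohort tables report its mean
± SD over cases. Regression uses a free intercept (slope-through-
origin optional). Bland–Altman limits are bias ± 1.96·sample SD of the
paired differences. The Wilcoxon rank-sum test uses exact enumeration
for n1 + n2 ≤ 12 without ties and the tie-corrected normal
approximation with continuity correction otherwise. Per-feature
p-values are reported raw; a Benjamini–Hochberg option exists but is
off by default.

The ART ANOVA aligns responses per effect by cell-mean estimation
(subtract the estimates of all other effects, add back the effect's
own estimate), mid-ranks the aligned values, and runs a two-factor
fixed-effects ANOVA on the ranks (type-II sums of squares for the
unbalanced location factor). We deliberately do **not** subtract
per-case block deviations during alignment: with two rows per case
that subtraction makes within-case residuals exactly anti-symmetric,
breaking rank exchangeability and inflating the simulated null
rejection rate several-fold. With cell-mean alignment the measured
type-I error on a 112-case paired null design is ≈ 0.05–0.06 at
α = 0.05 (500-replicate simulation in the test suite). The cost is
that between-case variance stays in the error term, making the
within-case model effect test somewhat conservative when real case
heterogeneity is large.

## Rupture-status prediction

Pipeline: (1) Wilcoxon pre-filter dropping features with p > 0.8
(constant columns are retained but flagged); (2) a baseline model on
morphological predictors only — location (one-hot), parent vessel
diameter, ostium minimum, NRV2 (a Voronoi-diagram-derived shape
feature, treated as an input); (3) greedy forward selection over the
retained velocity-informatics candidates, adding the candidate that
maximises the mean 10-fold CV AUC of the linear SVM and stopping when
the gain falls below 0.002 or after 3 additions (the stopping rule in
prior studies is unstated; 3 matches the number of features their
final models added); (4) evaluation over repeated stratified 9:1
train/test splits — standardization fitted on training data inside
each fold, cost tuned over 2^(−5..5) by 10-fold CV on the training
part, AUC from decision values and per-class accuracy on the held-out
tenth, averaged over repeats (default 100; the acceptance script uses
20 for a single-CPU budget). The SVM is unweighted despite the 44/68
class imbalance (consistent with the characteristically low ruptured
accuracy of such models); stratified splitting is assumed. SHAP
attributions use the exact linear formulation φ_j(x) = w_j(x_j − x̄_j)
with base value f(x̄), valid because the kernel is linear; positive
attributions push toward the ruptured class.

## Synthetic data: what it emulates and what it does not

`make_domain` voxelises a spherical sac truncated at the plane where
its cross-section narrows to the neck radius, and tiles the spherical
cap with near-equal-area Fibonacci wall nodes. `make_flow_series`
builds each frame as waveform(t) × [Σ Lamb–Oseen cores + uniform jet]
+ seeded Gaussian noise, zeroed outside the sac; core centres can
follow per-frame paths, giving controllable vortex-overlap ground
truth. The default waveform is a raised-cosine pulse peaking at 30% of
the cycle with a 0.2 diastolic floor — a shape-plausible stand-in, not
a physiological waveform (measured inlet waveforms are not tabulated
in accessible sources, so any positive periodic samples are accepted).
The synthetic flow is not divergence-free in general: the cores are
individually solenoidal, the jet is uniform, the noise is not. No
downstream metric assumes incompressibility, so this is a documented
limitation rather than a defect.

`make_wall_shear` gives each node a time-constant magnitude and a
direction that flips sign on k of the n frames, so per-node
OSI = k/n exactly under the periodic trapezoid; mixing ⌊q·n⌋ and
⌈q·n⌉ across nodes hits the requested spatial-mean OSI to within
1/n_nodes. Magnitudes are drawn in a low group (< 2 Pa) and a high
group (> 2 Pa) whose area fractions and rescaled means reproduce the
requested LSA and TAWSS. Infeasible target combinations (e.g. every
node below 2 Pa but a mean above it) are rejected.

`make_cohort` draws each feature from group-shifted Gaussians:
ruptured cases are shifted by d·σ for the configured effect size d.
Default effect sizes (≈ 0.36–0.5 SD on a dozen informatics features,
0.2–0.8 on morphology) were chosen once from the magnitude of
published group differences for these features and give the default
cohort a baseline AUC near 0.78 and an augmented AUC near 0.85.
Location counts default to 39 ICA / 52 MCA / 21 ACA over 112 cases
with 44 ruptured.

Because cohort features are independent Gaussians, passing ML tests
demonstrate correctness of the protocol (no leakage, calibrated null
behaviour, recovery of injected signal), not that real aneurysm
features behave this way: real texture features are correlated,
heavy-tailed and location-confounded in ways the generator does not
emulate. Similarly, the closed-loop WSS tests validate the metric
implementations, not any CFD solver.

## Numerical conventions and problem sizes

* Units: lengths mm, velocities mm/s, stresses Pa, time s.
* Rounding: round-half-up for gray encoding, fixed across platforms.
* Time integration: periodic trapezoid; default 20 frames per cycle.
* Determinism: every stochastic routine takes an integer seed and is
  bit-reproducible; derived seeds stay below 2³¹.
* Default test geometry: sac radius 4 mm, neck 2 mm, spacing
  0.4–0.5 mm (≈ 2000–4200 sac voxels) — small enough for a laptop
  CPU while keeping ≥ 16 voxels across the sac. The acceptance script
  uses 20 closed-loop seeds, 500 ART null replicates and 20 ML
  repeats; these sizes are the package's reporting defaults and can
  be raised via the respective parameters.

## Known limitations

* No Navier–Stokes solving, meshing or segmentation: the package
  starts where a CFD solver ends.
* The λ2 computation uses voxel-grid finite differences; on coarse
  grids the vortex boundary is resolution-limited, which is why
  sub-voxel vortex motion changes DVO smoothly rather than sharply.
* The ART ANOVA treats case heterogeneity conservatively (see above);
  a mixed-model rank procedure would be sharper but is out of scope.
* VTK support covers ASCII legacy structured-points export/import
  only; the native compressed container is the round-trip format.
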