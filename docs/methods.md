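# Methods

`covertnf` simulates and analyses a covert connectivity-neurofeedback
paradigm: three ROI mean signals (two training targets and one control,
sampled at TR = 2 s, 270 samples per 9-minute run) drive a streaming
two-point feedback rule, and learning is quantified as day-by-day change in
inter-ROI correlation, with permutation inference throughout.  This note
records the models, conventions and numerical choices; everything stated
here is computed by the test suite or the analysis drivers, not assumed.

## The feedback decision rule

At each TR the engine forms the three signal increments
`Δx_i(t) = x_i(t) − x_i(t−1)` and fires iff

    sign(Δtarget1) = sign(Δtarget2) ≠ sign(Δcontrol),  all increments ≠ 0.

The rule is often written as two ratio conditions (targets' increment ratio
positive, target/control ratio negative); we implement the sign comparison,
which is algebraically identical for nonzero increments and avoids 0/0.
**Tie rule:** an increment of exactly zero never fires.  Zero increments
have measure zero for continuous signals, but quantised or synthetic data
can produce them, and suppressing feedback is the conservative resolution.

Under three independent continuous white-noise signals the eight sign
triples are equiprobable and two satisfy the rule, so the chance fired rate
is exactly 1/4.  This also holds for the k-point generalisation below: for
iid series the two window-covariance signs are conditionally independent
fair coins given the shared target1 window, for any window length.

Score bookkeeping mirrors the covert game: one puzzle piece per fired
decision, 25 pieces per board.

**k-point windows.** The paradigm's designers also considered longer
windows (k = 2..6 TRs).  No formal definition of the longer-window score
exists, so we chose: sliding windows of length k, stride 1; a window counts
when its within-window Pearson r(target1, target2) > 0 and
r(target1, control) < 0.  Since only the signs matter, the implementation
tests the window covariances (rolling sums), which is exact.  k = 2 reduces
to the streaming rule.

## Connectivity measures

Per run we compute the three pairwise Pearson correlations, their Fisher
transforms z = atanh(r), and the composite difference measure

    composite = r(t1,t2) − (r(t1,c) + r(t2,c)) / 2,

which increases both when the trained target–target coupling rises and when
the target–control couplings fall.  ROI-level day aggregation and the
permutation contrasts operate on raw r by default (`use_fisher_z=True`
switches the whole downstream chain to z); the voxelwise analysis always
works on the z scale.

**Proxy validation** correlates the per-run two-point score (fired
*fraction*, chosen over the raw count for run-length invariance) with the
per-run offline Pearson r(t1,t2) across runs, with a run-label permutation
p.  Pooled and within-subject correlations can differ, so both are
reported.

## Synthetic cohort generator

The generator defines the study conditions every analysis is exercised
under.  Per arm: n subjects × days (day1..day4 + followup) × runs per day
(2 pre-feedback rest, 4 feedback, 2 post-feedback rest), 270 TRs per run.

Signal model per run: latent innovations are trivariate Gaussian with the
day's programmed correlation matrix, filtered per ROI by a common AR(1)
coefficient φ, plus additive drift, i.e.

    x(t) = AR1_φ[ L ε(t) ] · √(1−φ²) · σ  +  a·σ·( sin(2πft/T + φ₀) + b(2t/T − 1) )

with f ∈ U(0.5, 2) cycles/run, random phase and slope per ROI.  Units are
arbitrary (z-scored latents); no attempt is made to mimic scanner intensity.
Key choices:

- **Equal AR coefficients** across ROIs preserve the programmed innovation
  correlations in the stationary series (verified empirically in the tests);
  unequal coefficients would attenuate them, so equality is the default and
  only mode.
- **Drift dilutes correlations** multiplicatively by ≈ 1/(1 + a²·p_d) with
  drift power p_d ≈ 0.6; at the default a = 0.2 this is a ≈ 2% shrinkage of
  every empirical correlation (measured: programmed 0.9 → 0.881 at long
  runs).  The parameter-recovery checks apply no correction for this — the
  bias is small relative to their tolerance — but the effect is real and
  documented here.
- **Defaults** (chosen once as the study conditions): TR 2 s, 270 TRs,
  φ = 0.3 (BOLD-like lag-1 autocorrelation at this TR), drift amplitude 0.2,
  unit innovation SD.  Trained-arm baseline r = (0.10, 0.25, 0.05) for
  (t1t2, t1c, t2c) — weak target–target, elevated target1–control — ramping
  linearly to day4 deltas (+0.11, −0.13, −0.03), i.e. a composite change of
  +0.19, held at follow-up.  Control arm: baseline (0.35, 0, 0), no change.
- **Per-subject heterogeneity:** each subject's day deltas are scaled by a
  draw from N(1, 0.5), giving the cohort responders and non-responders (and
  realistic between-subject variance for the brain–behavior analysis).  Set
  `subject_scale_sd=0` for a homogeneous programmed effect.  An extreme
  responder's implied matrix can leave the PSD cone; it is repaired by
  eigenvalue clipping unconditionally (this safety net is independent of the
  spec-level `repair_non_psd` switch, which governs user-requested
  trajectories and is off by default: invalid requests fail naming the day).
- **Determinism:** every run draws from `default_rng([seed, subject, day,
  run])`, so identical specs reproduce bit-identical cohorts and any subset
  can be regenerated independently.

**Voxel grids.** A 24³ grid of 3.2 mm voxels holds three disjoint spherical
"networks" (8 mm radius, 81 voxels) around the three ROI centres, each
containing the 4 mm ROI sphere (7 voxels at this lattice).  Network voxels
share their network's latent AR(1) signal plus white voxel noise
(SD 0.5 ⇒ voxel–latent r ≈ 0.89); background voxels are independent noise.
Inter-network latent correlations follow a per-day coupling trajectory.
Grids are synthesised lazily (float32) because a materialised cohort would
not fit in memory.  The study's published Talairach ROI coordinates span
more than this grid; they are exposed as constants for masking user-supplied
volumes with a real affine, while the synthetic grid uses grid-local
centres.

**Behavior.** SRS change = slope × composite rest change + noise, change
scored pre − post (positive = symptom reduction); BRIEF change is
independent noise of the same scale (the non-social control measure).
Defaults slope = 30 points per unit composite change and noise SD = 4.5
points put the programmed population correlation in the moderate range
(~0.5–0.6) given the default cohort's change spread, with genuine changes
only rarely crossing the 3-SD reference band.  The independent test–retest
reference sample (mean 0, SD 5) is itself synthetic — the real reference
dataset is not distributable — and injected outliers are placed 6 reference
SDs below the mean so the 3-SD rule flags exactly those rows.

## Inference conventions

- **Paired day contrasts:** under the null each subject's two day labels are
  exchangeable, so the null is built by independently sign-flipping each
  subject's change; 5000 iterations by default, add-one smoothing
  (p ≥ 1/(n+1), never zero), two-tailed by default with one-tailed flags.
  Day labels are permuted pairwise per contrast, not jointly across all
  days.  Tie comparisons carry a 1e-12 relative tolerance so p-values are
  invariant to rescaling the measure.
- **Subset robustness:** all C(n, k) subsets enumerated (refused above 10⁶
  unless random sampling is requested); permutation nulls vectorised per
  chunk of subsets.
- **Group interaction:** Welch two-sample t (unequal variances,
  Welch–Satterthwaite df); both-constant-equal groups yield t = 0, p = 1 by
  convention.
- **Retention:** (followup − day1)/(day4 − day1) per subject, compared with
  follow-up via the first-two-feedback-runs scope (the follow-up session is
  abbreviated); zero-denominator subjects are excluded and counted.  The
  ratio is heavy-tailed when training change is small, so the median is the
  stable summary.
- **Brain–behavior:** Pearson r with subject-label permutation p; analyses
  run with and without flagged outliers and both reported.  Partial
  correlations residualise both variables on the covariates (with
  intercept); the permutation shuffles residuals.  Rank-deficient covariate
  matrices are rejected naming the columns.

## Voxelwise maps and cluster correction

Per run, every voxel's series is correlated with the seed-sphere mean
series, z-transformed, and the reference-ROI map subtracted
(z_seed − z_ref); run maps are averaged within day and day_a subtracted
from day_b.  r = ±1 (voxels inside the seed) is capped at atanh(0.999999);
such voxels are flagged and excluded from peak reporting, as are reference
voxels.  Constant voxel series become NaN and are excluded voxelwise with a
count.

Group inference: one-sample t across subjects per voxel, then cluster-size
permutation correction.  The paired null is realised as per-subject sign
flips of the change grids — exact for a day contrast, and verified on
fixtures against recomputing from swapped day averages.  At each voxelwise
threshold p ∈ {0.05, 0.01, 0.005, 0.001, 0.0005} the null distribution of
the maximum supra-threshold cluster size (6-neighbour faces-only
connectivity — the most conservative standard choice — positive and
negative clusters separately) yields the smallest cluster size whose
add-one permutation p ≤ α; the final mask is the union of voxels surviving
at any threshold.  Minimum sizes are threshold-specific and not assumed
monotone.  The union of five dependent tests inflates the familywise error
somewhat above the per-threshold α = 0.05; the acceptance suite measures
the realised FWER on pure-noise grids and bounds it at 0.08.

## Problem sizes used by the tests

The acceptance suite scales the expensive calibrations to desk size:
type-I calibration uses 1000 null cohorts of n = 17 with 2 feedback runs
per day and 500 permutation iterations per test; parameter recovery uses
100 replicate cohorts at the full 4 runs/day; FWER uses 50 pure-noise
replicates of 5–17 subjects at 500 permutations; planted-effect recovery
uses 20 replicates of 10 subjects, 2 runs/day, on the 24³ grid.  The
chance-rate check evaluates 10⁶ decisions through the engine's vectorised
k = 2 path, whose exact equality with the streaming engine is itself an
acceptance property.  The voxel arm uses 10 subjects because with fewer the
per-voxel t has so few degrees of freedom that the strict thresholds are
unreachable while the sign-flip null at loose thresholds is contaminated by
the planted effect itself.

## What passing tests do and do not show

The generator reproduces the statistical skeleton the analyses assume —
programmable inter-regional correlations with AR(1) autocorrelation, slow
drift, day-by-day trajectories, network-structured voxel grids, a linear
brain–behavior link — but not hemodynamic response functions, motion or
physiological artifacts, scanner intensity scales, or the visual task
itself.  Passing tests therefore demonstrate that the statistical machinery
is correct and calibrated under its own assumptions, not that the paradigm
works on real BOLD data.  Empirical feedback rates per run in the original
paradigm are unknown, so the generator is not tuned to any observed
reinforcement density.
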