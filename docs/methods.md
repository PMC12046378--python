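# Methods

## The gestural model

A gesture drives an articulatory variable `x` toward a target as a
damped mass-spring system with unit mass,

    ẍ + a(t) [ D(ẋ) + k (x − T) − d (x − T)³ ] = 0,

with stiffness `k` (1/s²), damping force `D(ẋ) = b ẋ` (linear,
`b` in 1/s) or `b ẋ³` (cubic damping), cubic anharmonic stiffness `d`
(1/(s²·units²)), and target `T` in signal units (mm-like for pellet
data). Activation `a(t)` gates the entire bracketed force: a
rectangular pulse on `[ta, tb]`, or a ramped envelope that rises as the
squared quarter-sine `sin²(2π(t − ta)/(4(tb − ta)))`, holds at 1, and
falls symmetrically. The published rendering of the ramp formula is
ambiguous about grouping; the squared-quarter-sine reading is our
interpretation, chosen because it reaches 1 exactly at `tb` and is
continuous at every junction. The cubic force is target-referenced,
`d (x − T)³`, matching the model's final stated form; a flag
(`cubic_about_target=False`) exposes the origin-referenced variant
`d x³`.

Useful closed forms used throughout: critical damping `b = 2√k`; the
undamped half-cycle from rest lasts `π/√k` and ends at the mirror point
`2T − x0`, which motivates the virtual-target algebra
`Tv = x0 + (T − x0)/2`, `T = 2 Tv − x0` relating the discovered
equilibrium of a minimally damped oscillator to the empirically reached
target. For an underdamped system with damping ratio ζ the half-cycle
endpoint is `T + (T − x0) exp(−ζπ/√(1 − ζ²))`.

Simulation uses the adaptive Dormand–Prince 5(4) method
(`scipy.integrate.solve_ivp`, rtol 1e-10, atol 1e-12) evaluated on a
fixed output grid, Δt = 1 ms by default. At these tolerances undamped
energy drift is below 1e-6 (relative) over one second and the undamped
solution matches `cos(√k t)` to better than 1e-6.

## Sparse discovery

Candidate models are sparse combinations of polynomial library terms:
`Ẋ = Θ(X) Ξ`. Two optimizers are implemented.

**STLSQ** (first-order models): iterated ridge solve with hard
thresholding at λ, on the surviving terms, until the active set is
stable; ridge weight α = 0.05 by default, maximum 20 iterations, and a
final unpenalized solve on the converged support (debiasing). Feature
columns are scaled to unit Euclidean norm internally and coefficients
unscaled on output, so one λ is commensurable across terms of very
different magnitude (a raw x³ column is badly scaled otherwise); the
threshold therefore applies to the normalized coefficients, as does α.

**Constrained SR3** (second-order models): the second-order law is
split into coupled first-order equations (y = ẋ, ẏ = f(x, y)) and both
are fitted subject to linear equality constraints `C vec(Ξ) = d` that
pin the first equation to exactly `y = 1.00 ẋ` — without this, the
auxiliary equation absorbs arbitrary library terms and the substituted
model becomes a generalized Liénard equation. The solver alternates a
KKT-constrained least-squares step for Ξ with an elementwise hard
threshold (the ℓ0 prox, per-term weights available) for the proxy W,
coupling weight 1/(2ν) with ν = 1, maximum 30 iterations.
Constraint-protected entries are never thresholded. On support
convergence a final constrained least-squares polish is returned;
constraint rows touching a single coefficient pin it exactly (no
round-off), so the returned Ξ satisfies the constraints to solver
precision (tested at 1e-10) and the auxiliary equation is exact.

Threshold selection searches the grid {0.001, 0.01, 0.1}, scoring each
candidate by forward-prediction variance-weighted R² and keeping the
first grid value on ties; non-convergent or divergent fits score −∞.
Note that for oscillator-scale coefficients (k ~ 10²–10³) none of these
thresholds can zero a genuinely active term; sparsity decisions at that
scale instead fall to the refinement stage below, mirroring the
empirical observation that discovered second-order models retain all
three linear terms with a near-zero damping coefficient.

## Derivatives and the token pathway

For clean, finely sampled trajectories (the worked replication at
1 kHz), derivatives are plain second-order finite differences
(`numpy.gradient`, one-sided at the edges). The outermost two samples
carry the stencil's largest error and are dropped from the regression
(`edge_trim = 2`); with them included the recovered coefficients err by
~1.3%, with them excluded by ~0.07%, comfortably inside the 0.1%
replication tolerance.

Segmented 160 Hz tokens are a different regime: a token is a half-cycle
of 13–31 samples, and white position noise is amplified by ~(sample
rate)² in the second derivative. `discover_token` therefore:

1. low-pass filters the token together with its raw context margin
   (zero-phase Butterworth, order 5, 15 Hz — articulatory signals live
   below ~8 Hz; real neighboring samples absorb the filter transient);
2. takes derivatives from a cubic spline evaluated on a 4× upsampled
   grid (keeping the finite-difference attenuation bias, ~(ωh)²/3 in
   k, negligible);
3. downweights regression rows by sin(πu) across the token, because
   derivative estimates degrade toward the segment edges where the
   filter sees the neighboring movement's acceleration reversal;
4. fits with constrained SR3 as above.

Structure found, the coefficients of a second-order *linear* structure
are then re-estimated by an **output-error fit**: the closed-form
trajectory of ẍ = −bẋ − k(x − Tv), started from rest, is least-squares
matched to the raw token samples over (k, Tv, x0, τ), where τ (bounded
by ±2.5 samples) absorbs the segmentation boundary's rounding error.
Up to 12 raw samples on each side of the token are fitted jointly as
rest-start cosine "wings" sharing the token's boundary corners: both
token boundaries are velocity zeros shared with the adjacent movements,
so the wing data pin the boundary phase — by far the most informative
quantity for the stiffness. Damping is kept only when the damped
closed form is preferred by BIC; over a half cycle b is weakly
identified and trades against Tv and phase, so an unpenalized damped
fit inflates the variance of every parameter. Position-domain fitting
avoids derivative noise amplification entirely and, against the
numerical Cramér–Rao bound for this estimation problem (~1% relative
sd in k for a 21-sample half-cycle at noise sd = 2% of oscillation
amplitude), the full pipeline is close to efficient: exact recovery at
zero noise, median k error ≈ 1.5–1.7% and 90th percentile < 4.5% at 2%
noise, on 200-token corpora.

## Preprocessing

Articulatory variables: lip aperture LA = |UL_y − LL_y|; tongue
variables TT/TD/TR are the first principal component of the 2-D sensor
coordinates, computed per recording, sign-fixed to correlate positively
with the vertical channel (so "up" is up). PCA coordinates are centered
projections: stiffness and damping are invariant to this affine map,
targets live in the projected frame.

Signals are optionally low-pass filtered (same Butterworth; off by
default, recommended for noisy recordings), differentiated by central
differences, split at annotated pauses, and segmented at velocity
zero crossings: each token is one contiguous same-sign velocity lobe.
Exclusion filters mirror standard practice: more than one velocity peak
(relative prominence ≥ 0.1 of the segment's peak speed — the rule is
scale-free), duration > 200 ms, or contact with the recording edge.
Zero crossings require a strict sign change between samples; an
optional dead band (default 0) suppresses jitter crossings. Manual
outlier exclusion is not reproducible and is not emulated; an optional
amplitude filter exists but is off by default.

## The synthetic corpus

`synthetic_data` emulates the *processed form* of a pellet corpus so
every downstream stage is testable without external data: four
articulatory variables at 160 Hz, speech intervals alternating with
annotated pauses, and within each interval a chain of gesture tokens,
each starting from the previous token's end with alternating movement
direction. Defaults are the study conditions: 50 tokens per variable
(200 total), durations 80–190 ms (capped under the 200 ms inclusion
rule so clean tokens are never excluded by duration), stiffness derived
from duration via the half-period relation k = (π/t)² and clamped to
[250, 3000] 1/s², undamped dynamics by default (the regime the
discovered linear models occupy; critical and fractional damping
available), movement targets drawn in a 4–16 unit range with a 1.5-unit
minimum amplitude. The generator draws the *empirical* target and
places the oscillator equilibrium at the virtual target, so the
movement actually ends where intended; durations are snapped to whole
samples with k adjusted so the closing velocity zero falls exactly on
the final sample. Cubic tokens draw d as a fraction of k normalized by
the squared initial displacement from equilibrium, making the
cubic-to-linear force ratio amplitude-independent.

Measurement noise is i.i.d. Gaussian on position only (velocity is
always recomputed downstream). `noise_sd` sets it absolutely;
`noise_frac` sets it per token as a fraction of the oscillation
amplitude (half the movement excursion — the cosine amplitude of the
half-cycle). Lip channels carry the latent aperture as
`UL_y − LL_y` with noise split across the two channels; tongue
variables embed the latent 1-D signal along a fixed random orientation
in 2-D plus small orthogonal jitter, so principal-component extraction
can recover it. The ledger records every token's true parameters,
sample span, family and amplitude, plus pause/hold spans and embedding
orientations.

Not emulated: X-ray measurement physics, pellet mistracking, head
correction, forced alignment, gestural overlap (tokens never overlap in
time within a variable), and coarticulatory coupling between variables.
Passing tests on this corpus therefore demonstrate correctness of the
pipeline's mechanics and estimator calibration under the stated noise
model — not robustness to the full messiness of real articulatory
recordings.

## Evaluation

Fit scores are variance-weighted R² over position and velocity:
per-signal R² = 1 − SSres/SStot combined with weights proportional to
each signal's variance (position and velocity live on different
scales). R² can be negative — predictions are anchored at the token's
initial conditions, so a bad model scores worse than a horizontal
line. Unstable forward predictions (non-finite values, or exceeding an
integration budget of 1e5 right-hand-side evaluations) score −∞ rather
than raising, keeping grid searches and comparison tables total.

The train/test protocol splits tokens 80/20 per variable under a seed;
ensembling reports per-term inclusion fractions across tokens, the
majority structure (terms present in more than half the models — the
modal full structure is also available in the histogram), and can force
that structure on every token. Library comparison fits degrees 1–4
per variable with the threshold optimized per variable over the grid,
reporting mean/sd/min of per-token scores.

Portrait diagnostics quantify what R² on position/velocity misses:
the Hooke portrait (acceleration against position) is linear for
harmonic motion, and RH² — the R² of a by-token OLS regression of
acceleration on position with intercept — measures anharmonicity.
RH² ≤ 0.9 flags substantial nonlinearity, RH² > 0.95 quasi-linearity.
Simulated linear tokens score RH² > 0.999; cubic tokens (d = 0.95k)
score strictly lower and curve in the direction of the +d(x − T)³
force. Correlation reports between reconstructed |T| = |2Tv − x0| and
the position at the closing velocity zero are Pearson r on absolute
values, per variable.

## Known limitations

* The output-error polish covers the linear second-order family only;
  cubic structures keep their derivative-regression coefficients, which
  are noisier.
* Damping estimation from a single half-cycle is intrinsically weak;
  b is reported as zero unless BIC justifies it. Corpus-level damping
  inference should aggregate across tokens.
* Segmentation assumes non-overlapping gestures; overlapped gestures
  produce multi-peak segments that are excluded, not decomposed.
* The threshold grid {0.001, 0.01, 0.1} is meaningful for normalized
  coefficients but cannot sparsify raw oscillator-scale terms; model
  parsimony at that scale comes from the refinement-stage BIC test.
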