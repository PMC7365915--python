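# Methods

## The model

A migrating cell is represented by its centroid sampled at a fixed interval
Δt.  During interval *i* the cell advances a signed distance
*r<sub>i</sub>* ~ N(μ<sub>r</sub>, σ<sub>r</sub>²Δt) along a polarity angle
θ<sub>i</sub> ~ N(θ<sub>i−1</sub>, σ<sub>θ</sub>²Δt).  Small σ<sub>θ</sub>
means persistent motion; for large σ<sub>θ</sub> the direction becomes
uniform on (−π, π] and the walk is purely diffusive.  Negative *r* is
allowed: the cell keeps its polarization but its centroid slips rearward,
and the next turning draw is still centered on the stored (unwrapped)
polarity angle.

Cells may occupy one of *n* discrete migration states, each with its own
(μ<sub>r</sub>, σ<sub>r</sub>, σ<sub>θ</sub>).  The state of every step is
an independent categorical draw with occupancy fractions α (Σα = 1) — an
i.i.d. mixture, i.e. the memoryless limit of a hidden Markov model.  With
the default Δt = 1 convention all parameters are per-sampling-interval
values.

## Step coordinates and the observed frame

Raw displacements are ambiguous (a large apparent turn may be a true
reorientation or a rearward step), so tracks are analyzed in rotated step
coordinates: each position triplet is rotated rigidly so the previous
displacement points along +x, giving the components Δx∥ (parallel) and
Δy⊥ (perpendicular, positive for counter-clockwise turns).  A track of *m*
points yields *m* − 2 samples; a previous displacement shorter than
10⁻⁹ μm leaves the rotation undefined and the sample is skipped and
counted.  The persistence statistic is P = ⟨cos θ⟩ over the pooled turn
angles.

The analytic density of Δx∥ for one state is

f<sub>X</sub>(x) = ∫₀^π g<sub>r</sub>(x / cos u) / |cos u| · A(u) du,
A(u) = Σ<sub>k</sub> [g<sub>θ</sub>(u + 2πk) + g<sub>θ</sub>(−u + 2πk)],

with g<sub>r</sub>, g<sub>θ</sub> the step and turn Gaussians; the
substitution h = cos u removes the (1 − h²)^(−1/2) endpoint singularity of
the h-space form, and the wrap sum over k handles the angle's periodicity.
Δy⊥ has the same form with the angular weight shifted by π/2 and is
symmetric about zero (it is evaluated at |y|, making the symmetry exact).
The printed h-space kernel divides by a signed h; a signed divisor yields
negative "densities" for h < 0, so 1/|h| is used, validated by the
Monte-Carlo equivalence suite.  Mixture densities are convex combinations
with weights α.

**Reference flips.**  The analytic solution describes steps relative to
the *polarity* axis, but a track transform can only orient each step by
the previous *displacement*.  Whenever the previous step had r < 0, that
observed reference is the polarity axis rotated by π, so the observed
parallel density is the reflection mixture

f<sub>obs</sub>(x) = q·f(x) + (1 − q)·f(−x),
q = Σ<sub>i</sub> α<sub>i</sub> Φ(μ<sub>ri</sub> / (σ<sub>ri</sub>√Δt)),

while the perpendicular density is unchanged (it is symmetric).  The
correction is negligible when every state has μ<sub>r</sub> ≫ σ<sub>r</sub>
but dominant when a state hovers near zero net motion: for the two-state
fixture below, 44% of frames are flipped and the fast state's peak appears
on both sides of zero.  Mixture-level density functions default to the
observed frame; single-state functions expose the polarity-frame analytic
solution.  Simulations confirm the observed-frame densities match
transformed-track histograms bin-for-bin at 10⁶ steps, and that ignoring
the correction leaves systematic residuals at the mirrored mode.

The observed frame also carries an exact mirror degeneracy: negating every
state's μ<sub>r</sub> (forward motion ↔ rearward motion with reversed
polarity) complements q and leaves both observed densities unchanged —
displacements alone cannot distinguish the two physical scenarios.  Fitted
models are therefore canonicalized to non-negative occupancy-weighted mean
drift before reporting.

## Numerical evaluation

The product density has an integrable logarithmic singularity at x = 0
whenever g<sub>r</sub>(0) > 0.  All comparisons against histograms
therefore use *bin-averaged* densities, computed exactly by swapping the
integration order: the x-integral of the kernel over a bin is a difference
of normal CDFs, leaving a single angular quadrature per bin row,

binavg(a, b) = (b − a)⁻¹ ∫₀^π A(u) · |Φ((b/cos u − μ)/σ) − Φ((a/cos u − μ)/σ)| du.

Pointwise evaluation at exactly x = 0 returns a narrow-bin average
(default width 10⁻³ σ<sub>r</sub>√Δt).

Quadrature is Gauss–Legendre on (0, π) with panels concentrated where the
integrand has structure: cores of half-width 8σ<sub>θ</sub>√Δt around the
angular-weight peaks (u = 0 for parallel, π/2 for perpendicular, plus the
mirrored peak when the flip correction is active), and a geometric ladder
of transition panels around u = π/2, where each bin's CDF difference
switches sharply between its saturated values once |cos u| drops below
min|edge| / (|μ| + 9σ).  Inside that scale the integrand is flat, so a
small inner panel integrates it exactly.  The wrap sum is truncated at
k_max = ⌈6σ<sub>θ</sub>√Δt / 2π⌉ + 1 (tail mass < 10⁻⁸; configurable).
Every evaluation self-checks that the angular weight integrates to 1
within `rel_tol` (default 10⁻⁶) and raises otherwise.  With the default
400 nodes, doubling the node count changes bin-averaged densities by
< 10⁻¹⁴ over a parameter grid spanning σ<sub>θ</sub> from 10⁻³ to 20.

## Parameter estimation

The fitting surface is the Freedman–Diaconis density histogram of the
pooled Δx∥ samples.  A model is scored by the sum of squared differences
between its bin-averaged densities and the empirical ones — optionally
weighted by each bin's inverse binomial variance evaluated at the model
density (the Pearson chi-square statistic).  The unweighted sum is the
historical default of this approach and remains `score_sse`'s default;
the weighted form is asymptotically equivalent to multinomial maximum
likelihood and markedly more efficient here, because the minority state's
signature lives in low-density bins that the unweighted sum barely sees
(see "Identifiability" below).

The global search is simulated annealing: single-coordinate Gaussian
proposals in a transformed space (log σ<sub>r</sub>, log σ<sub>θ</sub>,
logit α, raw μ<sub>r</sub>), Metropolis acceptance (downhill always,
uphill with probability e^(−Δs/T)), and geometric cooling
T = t₀·c^epoch.  t₀ defaults to the standard deviation of the objective
over 50 proposal-kernel probes of the starting point; c = 0.90 over 60
epochs of 140 proposals.  Eight restarts mix three deterministic
mixture-style templates (a minority state seeded on a data tail) with
random data-informed starts.  Proposals are confined to a box whose only
scientifically meaningful edge is σ<sub>θ</sub> ≤ 20 rad·interval^(−1/2)
(beyond which the walk is indistinguishable from direction-uniform).  The
search runs on a rebinned (~70-bin) histogram with a 64-node quadrature —
it only needs to find and rank basins — after which the best five restarts
get a simplex (Nelder–Mead) pass and the winner a full-resolution,
full-accuracy polish.  Refinement never returns a worse point than it was
given.

**Identifiability and the consistency check.**  At 10⁵ steps of the
two-state fixture, the parallel-only objective's global minimum sits at
σ<sub>θ1</sub> ≈ 0: a minority state's angular dispersion trades off
almost freely against its step-size parameters in Δx∥, and only the
perpendicular distribution pins it.  The estimation protocol
(`fit_with_consistency`) therefore (1) fits Δx∥ alone, (2) checks the
fitted model against the held-out Δy⊥ histogram — genuine out-of-sample
evidence, since Δy⊥ never entered the objective — requiring every bin
with ≥ 10 expected counts to match within 4 binomial standard errors
*and* the aggregate Pearson chi-square over those bins to stay below its
0.995 reference quantile (per-bin envelopes catch localized misfit, the
aggregate statistic the diffuse kind that no single bin reveals), and
(3) on failure refits against the joint objective (parallel score +
perpendicular score).  On two-state synthetic data the parallel-only fit
reliably fails the check and the joint Pearson-weighted refit recovers α
within ±0.02 and both angular dispersions within ~7% at 10⁵ steps;
unweighted joint fitting leaves α with a standard error of ~0.08, which
is why the weighted objective is the protocol's default.

**Calibration and intervals.**  An acceptance threshold for the objective
is calibrated by bootstrap: resample the pooled steps with replacement
(same N), rebuild the histogram on the original edges, and score each
replicate *against the original empirical densities* — the distance
between two realizations of the same experiment, i.e. the score sampling
noise alone can produce.  The threshold is the 0.95 quantile of that
distribution (quantile and replicate count configurable; no published
value exists for either).  A variant that scores the fixed fitted model
against each replicate is available, but it inherits any model misfit
into every replicate and therefore cannot flag an inadequate model —
unsuitable for model-order selection.  Profile
intervals fix one parameter on a grid, re-optimize all others (visiting
grid points outward from the estimate with warm starts), and report the
widest contiguous sub-grid around the estimate whose profiled score stays
below the threshold.  Model-order selection prefers one state when the
one-state fit's score does not exceed the bootstrap threshold; a two-state
fit of one-state data is expected to collapse (α near 0 or 1, or twin
states).

## State prediction

Bayes' theorem inverts the mixture: for an odd window of steps centered on
the step of interest, P(s|X) ∝ P(X|s)·α<sub>s</sub>, with P(X|s) the
product of per-step densities (Δx∥ by default; an opt-in flag multiplies
in Δy⊥ as if independent — the true joint density is not separable, so
the flag rarely helps).  Posteriors are computed in log space (no NaN up
to |Δx∥| = 10⁶ μm); if every state underflows, the priors are returned.
Ties break toward the larger-α state; the non-assigned state's posterior
doubles as a per-step false-positive probability.  Windows shrink near
track ends to the largest centered odd window that fits.  Because states
are i.i.d. per step, windows longer than 1 mix neighbours' states and
classify slightly *worse* than single-step windows on this model; 1 is the
default.

Under the fixture parameters below, the Bayes-optimal single-step accuracy
— computed by integrating max<sub>i</sub> α<sub>i</sub>f<sub>i</sub>(x)
— is 88.0% in the observed frame (89.4% even with a hypothetical
flip-free transform), against an always-majority baseline of 88%.  The
windowed classifier operates at that ceiling (~88.5% measured); reports of
higher accuracy for this model family correspond to parameter sets whose
states overlap less than this fixture's do.

## Foci detection

Ratiometric biosensor frames are analyzed per cell mask.  A focus is a
connected component (8-connected by default) of pixels above
(1 + 0.60) × the mean in-mask intensity, with area strictly greater than
100 px, and with at least one pixel within 5 px (Euclidean) of the cell
edge — the set of in-mask pixels with an out-of-mask 4-neighbour.  All
three thresholds are configurable.  The criteria are relative to the cell
mean, so detection is invariant to intensity rescaling; the display
normalization (divide by the nearest-rank 5th percentile of in-mask
values, floor rounding) therefore does not affect results.  To avoid
over-weighting long-lived cells, the number of frames analyzed per cell is
the n maximizing n × m, where m is the number of cells with at least n
frames (ties to larger n).

## Synthetic data

No public tracks accompany the analyses this package implements, so the
fixtures module generates the study conditions:

* `mef_like` — two states: 12% occupancy in a fast-persistent state with
  μ<sub>r</sub> = 3.0 μm, σ<sub>θ</sub> = 0.7, and 88% in a slow erratic
  state with σ<sub>θ</sub> = 1.3.  The dispersions never published for
  this system are package defaults — σ<sub>r1</sub> = 1.0, μ<sub>r2</sub> = 0.0,
  σ<sub>r2</sub> = 2.0 — chosen to give a clearly bimodal parallel-step
  distribution with a stationary-on-average slow state.
* `one_state` — a single persistent state (μ<sub>r</sub> = 1.5,
  σ<sub>r</sub> = 1.0, σ<sub>θ</sub> = 0.9).
* synthetic ratiometric frames: disk masks with flat-top blobs of exact
  specified area, plus per-blob ground truth for each criterion.

Everything is byte-reproducible under a fixed seed.  The generators
emulate exactly the model's assumptions (i.i.d. states, Gaussian steps and
turns, uniform sampling); they do not emulate segmentation error,
positional noise, state persistence in time, or cell–cell interaction, so
green tests certify the inference machinery, not robustness to those
real-data effects.

## Problem sizes used in validation

Parameter-recovery experiments use 100 tracks × 1000 steps (≈10⁵ pooled
steps), the size at which the recovery tolerances above were established;
classification experiments use ≥ 2000 steps; density cross-checks use 10⁶
simulated steps against 4σ per-bin binomial envelopes (bins with ≥ 10
expected counts, where the normal approximation holds).  The scaled-down
example scripts state their own sizes.

## Known limitations

* The i.i.d.-state assumption ignores temporal state persistence; a
  cell that dwells in states would be better served by an HMM, and the
  windowed classifier would then benefit from windows > 1.
* The reference-flip correction is exact for the marginal densities but
  consecutive step samples remain weakly dependent (they share position
  and flip indicators); histogram-based objectives treat them as
  independent, which only inflates the effective noise slightly.
* σ<sub>θ</sub> of a low-occupancy state is near-unidentifiable from Δx∥
  alone; always run the consistency check (the default protocol does).
* Foci detection assumes masks are given and correct; no photobleach or
  ratio-computation corrections are applied.
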