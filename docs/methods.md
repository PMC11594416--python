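# Methods

This note documents the models, conventions, and design choices behind
`sdtnet` — what is simulated, how the statistics are defined, and where the
package had to fix details that the underlying experimental designs leave
open.

## The scientific setup

Human observers show *confidence–accuracy dissociations*: when the "energy"
of a stimulus (contrast, color saturation) is increased together with its
variability (orientation spread, noise) so that task accuracy stays
constant, confidence nevertheless rises.  A popular explanation is the
positive-evidence heuristic — confidence weighting choice-consistent
evidence more than choice-inconsistent evidence.  `sdtnet` implements the
competing *signal-and-variance-increase* account: in any observer whose
internal evidence distributions both separate (larger μ_S2 − μ_S1) and
widen (larger class-conditional SD) under energy manipulations, confidence
rises at matched accuracy with no positive-evidence mechanism at all.
Small CNNs trained on two-choice orientation tasks turn out to be exactly
such observers, and the package provides the full chain needed to show it:
stimulus synthesis → CNN ensemble training → decision/confidence readout →
SDT analysis (d′, response-specific meta-d′) → evidence-distribution
statistics → two stand-alone simulations (base-rate criterion shifts, and
the stepped-contrast meta-d′/d′ paradigm).

## Stimuli

Four families, all returning float images in [0, 1]:

| family | canvas | classes | energy pair (low→high) |
|---|---|---|---|
| `gabor_array` | 90×90, 8 patches of 30×30 | mean tilt CCW/CW of horizontal | contrast .2/.25/.3 with orientation SD 7.35°/21.28°/27.28° |
| `superimposed` | 100×100 | dominant grating ±45° of vertical | dominant contrast .2/.4/.6 with non-dominant .168/.375/.575 |
| `single_gabor` | 100×100 | tilt ±45° of vertical | contrast .05/.1/.15 with noise SD .42/.82/1.21 |
| `color_array` | 90×90×3, 8 circles | mean color red/blue | intensity .493/.492/.49 with spread .4/.494/.626 |

Training/validation sets sample parameters uniformly: `gabor_array` mean
tilt [1°, 10°], orientation SD [1°, 20°], contrast [.01, 1];
`superimposed` orientation [1°, 45°], dominant contrast [.01, 1], contrast
difference [.01, dominant]; `single_gabor` contrast [.01, 1], noise SD
[.01, 2]; `color_array` intensity and spread on [0, 1].  Labels are
balanced 50/50 by construction (sign of the generative tilt, identity of
the dominant grating) except for the color task, where the label follows
the realized pre-clip mean intensity, as the task defines it.

Rendering conventions the designs leave open, fixed here once:

* **Gabor internals** — carrier 3 cycles/patch, Gaussian envelope
  SD = patch/6, and an *odd* (sine) carrier phase about the patch center.
  Odd phase makes the noise-free pattern zero-mean with a symmetric range,
  so a patch of contrast *c* has mean intensity exactly 0.5 and
  peak-to-trough amplitude exactly *c* — the two properties the test suite
  pins down.  A cosine phase satisfies neither (non-zero DC, asymmetric
  range).
* **Noise model** — additive zero-mean Gaussian pixel noise applied after
  signal composition, then clipping to [0, 1].  The array and superimposed
  tasks, whose noise level is not a manipulated variable, use a fixed
  nuisance SD of 0.1.
* **Layout** — the eight patches occupy a 3×3 grid with the center cell
  empty (the only arrangement of eight 30×30 patches on a 90×90 canvas).
* **Energy ordering** — for every family, both members of the
  (signal, variability) pair increase strictly from low to high; for the
  color task the signal member is the distance of the mean intensity from
  the neutral point 0.5 (the printed intensities *decrease* slightly from
  .493 to .49, i.e. move away from neutral toward red).  This is asserted
  at import time.
* **Array test stimuli** — the mean tilt of `gabor_array` test images is
  resampled per trial from the training interval [1°, 10°]; the energy
  conditions pin down contrast and orientation spread only.
* **Determinism** — a set uses one master seed; per-image seeds are spawned
  by counter (`SeedSequence([master, index])`), so sets are reproducible
  and order-independent.

## The network

A 4-layer CNN: conv 3×3 → ReLU → maxpool 2×2 → conv 3×3 → ReLU → maxpool
2×2 → flatten → dense(64, ReLU) → dense(1, sigmoid), valid padding.
Training: binary cross-entropy, Adam (lr 10⁻³, ε 10⁻⁸, no weight decay),
batch size 32, 25 epochs with early stopping (patience 10 on validation
loss).  When patience runs out the *final* weights are kept — the default
of the common deep-learning toolchains.  This matters scientifically: on
these tasks validation loss bottoms within the first couple of epochs
while accuracy plateaus, so restoring the best-loss weights
(`restore_best=True`, available as an option) freezes the network in its
least-confident early state and mutes the overconfidence that these
models characteristically develop with continued training.  The
pre-sigmoid logit *z* is the evidence variable; the sigmoid activation
*a* feeds the confidence readout.

The implementation is NumPy + numba (im2col-free direct convolution
kernels, BLAS dense layers), single-threaded and exactly reproducible
given `random_state`.  Choices where the published architecture is silent:

* **Filter counts** (4, 8).  The stimuli are low-complexity oriented
  gratings; at these counts every experiment's validation accuracy clears
  90% while one training epoch on 10,000 100×100 images takes ~10 s on one
  CPU core, which keeps a full 25-instance-style study tractable on a
  desktop.  The counts are ordinary constructor parameters for anyone who
  wants a wider net.
* **Initialization** — He-uniform for ReLU layers with small positive
  biases (0.05), Glorot for the output unit.
* **Input centering** — images are shifted by −0.5 inside the estimator (a
  fixed affine transform, not data-dependent standardization).  Without
  it, the large common-mode drive of all-positive inputs lets Adam push
  the entire 64-unit dense layer into an all-negative (dead-ReLU)
  absorbing state in roughly a quarter of seeds during the first long
  epoch; with centering, training was stable across every seed we tried.
  Centering is decision-neutral and leaves all downstream statistics on
  the logit scale untouched.

Even centered, a few percent of initializations still collapse (the dead
state is absorbing: once every dense unit's pre-activation is negative,
all gradients vanish).  A collapsed run is unmistakable — chance accuracy
with *constant* logits, which no slow-but-live learner shows — so `fit`
detects it from epoch 2 onward and restarts from a reseeded
initialization (derived deterministically from `random_state`; at most 3
restarts, recorded in `n_restarts_`, with `collapsed_` flagging the rare
run that stays dead).  NaN loss aborts training with a diagnostic.

## Behavior and statistics

Responses and confidence use the standard piecewise readout: respond S2
iff *a* ≥ 0.5 (ties to S2, hence confidence 0.5 at the boundary);
confidence *c* = *a* for S2 responses and 1 − *a* otherwise, so
*c* ∈ [0.5, 1].

Ensemble statistics treat network instances as subjects: one-way
repeated-measures ANOVA (statsmodels `AnovaRM`) with textbook df
(k−1, (k−1)(n−1)), and two-sided paired t-tests, with no multiple-testing
correction.  Published analyses of this design sometimes print
df_error = n−1; the output carries a `df_note` flagging the convention
used here.

Evidence statistics are computed per instance × condition on the logit:
separation μ_S2 − μ_S1 and the mean of the two class-conditional sample
SDs (n−1).  The logit is used instead of the sigmoid output because each
network's evidence lives on its own unbounded axis and the sigmoid would
compress both statistics near saturation.

## Signal detection

d′ = Φ⁻¹(HR) − Φ⁻¹(FAR) and c = −(Φ⁻¹(HR) + Φ⁻¹(FAR))/2 with S2 as
target.  Degenerate rates must be corrected first; the rating tables use a
log-linear correction that adds 1/(4K) to every cell of the K×2×2 table
(one pseudo-trial total).

meta-d′ is the sensitivity an ideal equal-variance SDT observer would need
to produce the observed confidence-rating data.  Continuous confidence is
discretized into K = 4 ratings by pooled quantile binning (the analysis
needs discrete ratings; no particular binning is canonical, and quantiles
keep cell counts stable).  The fit maximizes the multinomial likelihood of
rating counts *conditional on response*, with the meta-observer's type-1
criterion tied to the observed one by meta-c = c·(meta-d′/d′) and the
2(K−1) type-2 criteria fitted jointly with meta-d′ (L-BFGS-B on a
log-increment parameterization that enforces their ordering).
Response-specific meta-d′ restricts the likelihood to one response's
trials.  Ideal-observer recovery is accurate to |meta-d′ − d′| < 0.15 at
n = 50,000 across d′ ∈ {0.5, 1, 2, 3}, and the fit agrees with an
independent grid-search maximizer of the same likelihood to within 0.05
(both are test-suite assertions).

Temperature scaling divides logits by a scalar T > 0 fitted by minimizing
binary cross-entropy on held-out trials before the sigmoid; it never
changes a decision (sign(z/T) = sign(z)) and is fitted per network
instance on its validation set.

## The two stand-alone simulations

**Base-rate criterion shifts.**  Evidence x ~ N(0, σ) for S1 and N(μ, σ)
for S2; the criterion sits at μ/2 + c with c ~ N(0, .25) in evidence
units, shifted by ±c_shift ~ N(.4, .2) in S1-/S2-frequent blocks, with the
same criteria in both energy conditions.  Low energy: μ ~ N(1, .5), σ = 1;
high energy: μ doubled, σ = 2.  Doubling μ *per simulated observer*
(rather than sampling it independently from N(2, 1), which has the same
marginal) enforces the equal-sensitivity constraint exactly and makes the
per-simulation d′ difference pure trial noise — matching the near-zero
variance of the published Δd′ statistic, which independent sampling could
not produce.  50 simulations × 10,000 trials; observed d′ and c via the
standard formulas per condition × block.  The closed-form oracle
E[Δbias] = 2·E[c_shift]·(1/σ_low − 1/σ_high) = 0.4 checks the Monte-Carlo
mean within 3 SE.  Block identity only moves the criterion, so stimuli are
generated 50/50; actual frequency changes would alter only the standard
errors, not the expectation.

**Stepped-contrast paradigm.**  S1 (CCW) keeps a fixed contrast while S2
(CW) steps through five levels (`single_gabor`: S1 at .1, S2 at
.05/.075/.1/.125/.15; analogous ladders for the other families).
Confidence is discretized with one set of rating criteria per instance
(quantile edges pooled over the whole ladder), so the simulated observer
holds fixed type-2 criteria across levels.  Non-contrast parameters stay
fixed; for the single-Gabor task the noise SD is calibrated once, by the
same simulation rule that built the ladder, so ensemble d′ spans the
intended 1–3.5 working range (0.45 here; the mid-energy 0.82 compresses
d′ to 1.0–1.7).  Per level and instance: d′, and meta-d′ conditioned on
each response.  The crossover signature is summarized by per-instance
least-squares slopes of response-specific meta-d′ against d′ and asserted
as a sign test (positive for S2 responses, negative for S1), not as exact
values.

A documented divergence: within the 1–3.5 window our networks produce a
*positive* S1-response slope — misses carry progressively less extreme
evidence as S2 contrast rises (mean |logit| of misses falls from ~4.7 to
~3.5 while correct rejections hold at ~6.8), so metacognition among "S1"
responses improves with d′ instead of degrading.  The negative arm of the
crossover appears only at higher sensitivities (noise SD ≲ 0.3, d′ ≳ 3.5),
where the widening S2 evidence distribution finally pushes high-confidence
misses deep into S1-response territory.  This holds for every filter
configuration tried, (4, 8) through (16, 32): under this package's
clipped-pixel-noise rendering the S2 evidence spread grows only ~11%
across the ladder, evidently weaker contrast→variance coupling than in
the networks this paradigm was designed around.  The corresponding test
asserts the expected signature and is allowed to fail rather than being
weakened; treat the S1 arm as an open discrepancy of this model system.

## Accuracy-matching search

A coarse scan (8 steps) over the variability interval finds the region
whose ensemble-mean accuracy falls in [0.65, 0.75], checking empirically
that accuracy decreases monotonically in the variability parameter; then
bisection refines to |accuracy − 0.70| ≤ tolerance.  Every probe draws a
fresh 1000-image evaluation set (fresh seed) so the search cannot overfit
one sample.  Accuracy is matched at the ensemble mean, not per instance.
Degenerate cases are explicit: flat accuracy returns the interval midpoint
with a warning; an unreachable target returns the boundary value.

## Problem sizes and what the tests show

The test suite and the acceptance script run the complete study at reduced
scale, a deliberate package choice: ensembles of 3 instances rather than
25, one experiment (`single_gabor`) trained at full protocol for the
end-to-end checks, 1,000 test images per condition, and the printed
parameter tables taken as-is.  At this scale the qualitative phenomena
(matched accuracy, rising confidence, separation+spread increase, the
meta-d′ crossover) are stable, but exact F statistics and confidence means
of a 25-instance study are not reproduced — only their signs and
significance directions, which is what the assertions check.

The synthetic stimuli emulate parametric psychophysics displays, not
photographs: no display gamma, no luminance calibration, no dynamic
stimuli, and the noise model is i.i.d. Gaussian pixel noise.  Passing
tests therefore demonstrate properties of the model system — networks
trained on these statistics — not claims about human observers.

## Known limitations

* Only the small 4-layer CNN is implemented; transfer-learned deep
  architectures (VGG/ResNet class) are out of scope because they require
  pretrained weights.
* meta-d′ assumes the equal-variance SDT model (s = 1), matching the d′
  formula used; unequal-variance and hierarchical variants are not
  provided.
* The RM-ANOVA is the classical univariate form without sphericity
  correction — adequate for 3 conditions and the sign/significance claims
  made here.
* With very small rating tables the meta-d′ MLE can sit on a flat
  likelihood ridge; the grid-search cross-check bounds this at 0.05 for
  the table sizes used.
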