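# Methods

This note documents the models and procedures implemented in `seqprev`, the
parameters that matter, and the design decisions taken where the problem was
genuinely open.

## Behavioral parsing

A **sequence instance** is a run of consecutive trials whose choices spell a
target pattern. Because a continuous L/R stream can spell patterns by
accident, instances are admitted by context-dependent rules.

**Dominance.** A sequence establishes dominance in a block (where it is the
latent rewarded target) at the start of the first run of three back-to-back,
non-overlapping concatenated instances; the trials of that first run are
themselves included. Dominance then persists to the end of the block.
Past the block boundary the epoch keeps a *tail* while the concatenation is
still alive, and ends when more than two consecutive trials are incompatible
with continuing it. A trial is *incompatible* when the choices since the
last completed instance are not a prefix of the sequence repeated — a
deterministic reading of "incompatible with that sequence". Note an
implication we accept deliberately: applying this termination rule *inside*
blocks would end every epoch at the first three-trial exploratory bout and
empty the exploratory dataset, so within-block interruptions do not
terminate dominance.

**Exploratory selection.** Candidates are matches of a sequence inside the
dominance epochs of a *different* sequence. Candidates sharing any trial
with a raw match of the dominant sequence are removed, then rescued iff
(logical OR) they are immediately preceded by another completed instance of
the same sequence, their final-step side-port dwell exceeds 0.5 s, or their
final-step side-to-center interval exceeds 1 s. The dwell criterion encodes
the expectation that an animal briefly pauses at the side port to "mark"
completion of a genuinely evaluated sequence.

**Global filters.** Instances wholly inside runs of two or more concatenated
`LLRR`/`RRLL` patterns are removed (such runs are a catch-all strategy, not
individual three-step sequences), as are instances containing any
center-to-side interval above 3 s (breaks). Session admission requires at
least 200 `LLR` or `RRL` matches and a production rate — completed
latent-target instances × sequence length / trials — above 0.15 (theoretical
maximum 1/3 for three-step targets).

Overlapping same-sequence candidates are resolved greedily left-to-right (an
executed instance consumes its trials). Circularly permuted sets (`LRR` vs
`RRL`) are parsed only in target-matched dominant mode; exploratory analyses
are restricted to `LLR`/`RRL` sessions, where parsing is unambiguous.

## Prevalence statistics

The kernel is a causal half-Gaussian: weights `g(τ) ∝ exp(−τ²/2σ²)` over
lags τ = 0…support, σ = 20 trials, truncated at 3σ (≈1.2% of mass) and
renormalized to unit sum, so prevalence lives in [0, 1]. The normalization
and truncation are our choices; the 0–1 scale makes session comparisons and
the "every recent trial is a completion → prevalence 1" reading natural. A
signed `offset` shifts the window (positive → future trials; used only as a
control). An instance's prevalence is read **one trial before the instance
begins**, so an instance never contributes to its own covariate; the
read-out trial is a configuration choice, exposed on `instance_prevalence`.

Reward prevalence applies the same kernel to rewarded trials, either all of
them or only those rewarded for a specific sequence. The **condition index**
— sqrt of the eigenvalue ratio of a predictor pair's 2×2 covariance — gates
paired regressions to the band [1, 4].

## State space

Each instance is a vector of square roots of spike counts in five 500 ms
windows centered on port entries (side step 1, center/side steps 2 and 3;
the first center entry is excluded to avoid feedback from the preceding
choice). The square root approximately stabilizes Poisson variance (→ 0.25
asymptotically) so fast-spiking units do not dominate distances. The
ensemble space has 5N dimensions; Euclidean distances are divided by √(5N)
so sessions with different ensemble sizes are on a comparable per-dimension
RMS scale — a normalization we infer rather than copy, chosen for
scale-invariance, not to reproduce any particular printed distance.

Cluster centroids are per-dimension **medians**; context separation is the
centroid distance judged against a null built from label permutations
preserving class counts. The per-unit **transition score** is the centroid
distance in the unit's own five-dimensional space divided by the root mean
within-cloud variance (unbiased sample variance). Context modulation is a
Wilcoxon rank-sum test per unit per window at α = 0.05 with no
multiple-comparison correction, reported per window and as the any-window
fraction; both the test and α are configurable.

## Classifiers

Sequence identity and action context are decoded with a two-class linear
discriminant on windowed firing rates (counts / 0.5 s) of all units, after
subsampling classes to equal size. The pooled covariance is shrunk toward
its diagonal (coefficient 0.1) because the feature count can approach the
instance count; a tiny trace-scaled ridge keeps silent features from making
it exactly singular. Cross-validation is a single stratified five-fold
split; the reported error is the mean of the five held-out error rates.

## Encoding models

Cross-validated explained variance is computed per fold as
`1 − SSE/SStot` on the held-out split (SStot about the held-out mean),
averaged over five folds, and the *average* is clamped at zero — clamping
after averaging, so mild per-fold overfitting can still cancel out.

Per-unit prevalence models are OLS fits of window activity on instance
prevalence, independently per window and per context; "fraction
significant" uses all five per-window values, per-neuron EV uses the best of
five. The default criterion for "prevalence-modulated" is cvEV > 0.2; a
permutation test (1000 shuffles, α = 0.05) is the rigorous option. Context
interactions are fit as the family {prevalence only; + per-context
intercept; + context-specific slope} with context-stratified folds. With
two or three context levels a random intercept is operationally a
per-context offset, so it is estimated as a fixed offset; the model family
is otherwise identical.

Movement covariates: **vigor** is the first-step center-in to last-step
side-in interval; **trajectory PC1** resamples the X/Y snippets of the five
windows to 20 points per window per coordinate (linear interpolation — PCA
needs fixed-length vectors and no resampling rule was given), concatenates
them, and projects onto the leading principal axis (defined up to sign).
Paired regressions z-score response and both predictors per session, fit all
five windows, and report absolute weights from the window with the highest
total EV.

## Population decoders

Decoders regress instance prevalence on spike **counts** (not square roots;
a flag enables sqrt features for sensitivity analyses). The general model
has one weight per (neuron, window); per-window models fit each window
independently ("best of five" is the max); the **shared-weight** model
forces one weight per neuron by stacking the five windows as extra
observations of one regression — folds are drawn over instances so all rows
of an instance stay together. In-sample OLS EV obeys the nesting
shared ≤ per-window(k) ≤ general on every dataset. When the feature count
exceeds half the instance count, ridge regression with a generalized-CV
penalty replaces OLS.

Neurons get a significance score per window and are classed 0–5 by the
number of significant windows; class-0 neurons are dropped and sessions need
at least five neurons in classes 1–5. The default score is a **marginal**
univariate regression t-test per (unit, window) at α = 0.05. A partial
t-test from the general model is available, but a unit tuned in all five
windows has mutually collinear window features, so partial tests
systematically understate exactly the units that belong in class 5; the
marginal score matches the intended "does this neuron in this window track
prevalence" reading. Removing class-5 units and refitting the shared model
tests whether a temporally fixed readout depends on single always-tuned
neurons or on complementary coverage.

The two-axis visualization projects centered count vectors onto the
normalized decoder weights (axis 1) and the leading principal axis of the
residual (axis 2); this is one concrete realization of a
"maximum-prevalence-separation" subspace.

## Synthetic generator

The generator emulates the statistical structure of the task, not its
physiology. The agent adopts each new latent target after a Poisson lag
(mean 15 trials) and then concatenates it; at sequence boundaries it starts
an exploratory bout with probability 0.02, multiplied by 4 for the 6 trials
after a reward omission; bout lengths are geometric (mean 1.5 instances) —
a stand-in distribution, not an inference about animals. Blocks are 250–500
trials; omission probability defaults to 0.2 (the task's 10–30% range).
Port-event timing is normal with positive means (clipped at 20 ms); the
final-step side dwell lengthens from 0.3 s to 0.7 s on unrewarded
completions (and to 1.0 s on rewarded ones), which is what makes the parsing
rescue rule exercisable.

Spiking is inhomogeneous Poisson with a piecewise-constant rate:
`log rate = log(baseline) + step/port tuning + choice tuning + sequence
tuning + context offset + context-specific slope × prevalence (+ reward-
prevalence and movement terms)`, exponentiated and clipped at 100 Hz (the
exponential link guarantees positivity while staying near-linear for small
slopes); outside the peri-event windows units fire at baseline. The
prevalence covariate is the value one trial before the intended instance
start — exactly what the encoding models read — so parameter recovery is
well-posed and the stored ground truth equals the package's own prevalence
recomputation to 1e-9.

What the generator does *not* emulate: non-Poisson spike-train statistics
(refractoriness, bursting, adaptation), slow drift and unit instability,
correlated noise across units, posture/kinematics beyond a scalar execution
-time covariate, and any learning dynamics inside a block. Passing tests
therefore certify the statistical machinery — parsing rules, kernel
algebra, null calibration, estimator consistency, decoder structure — not
that cortical data will show these effects at these magnitudes.

## Numerical choices and degenerate inputs

Seeds enter every stochastic step explicitly; repeated pipeline runs with
one config are byte-identical (no wall-clock content in outputs). Constant
responses make EV undefined and raise; constant or collinear predictor
pairs fail the condition-index gate with a singularity error; contexts with
fewer than 10 instances are skipped in per-context fits; classifiers
require at least `folds` members per class after balancing. Empty sessions
are readable but rejected by the parser with a clear error. Windows are
half-open `[anchor − w/2, anchor + w/2)` and counted independently, so
overlapping windows double-count spikes by design.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems: sessions of 500–1200 trials with 6–20 units, three-session
cohorts, 1000-permutation nulls, 50–100 repetitions for calibration
properties. These sizes give the calibration tests binomial confidence
intervals tight enough to be meaningful while keeping the whole suite under
a minute on one core.

## Known limitations

- The dominance tail rule anchors incompatibility at the last completed
  instance; a single stray choice therefore ends the tail three trials
  later even if concatenation resumes afterwards.
- The shared-weight decoder's per-window cvEV is reported for the five
  analysis windows only; it says nothing about inter-window intervals.
- Mixed-effects context models are fit as fixed per-context offsets, which
  is exact for 2–3 contexts but does not generalize to many-context designs
  with partial pooling.
- The LLRR-run filter requires at least two concatenated copies; a lone
  `LLRR` is treated as an ordinary overlap case.
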