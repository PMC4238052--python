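# Methods

## Task model

The simulated experiment is a two-boundary speed categorization task.
Each trial presents a random-dot stimulus at one of 8 speeds
(2, 4, …, 16 deg/s) moving up or down, after a visual cue announcing the
active category boundary ("slow" reference at 5 deg/s or "fast" at
13 deg/s); the subject reports "slow" or "fast" by a saccade to one of
two targets whose locations are counterbalanced. The full design is
8 × 2 × 2 × 2 = 64 trial types per block. Schedules are
block-randomized: every type appears once per block in random order, and
a trial aborted by a fixation break (Bernoulli with probability 0.13 per
presentation) is re-inserted at a random strictly later position in the
same block, falling back to the block tail when the queue is empty —
the simplest rule consistent with re-shuffling without immediate
repetition. The generator enforces a reinsertion cap so that a break
probability of 1 raises an error instead of looping. Five analysis
epochs are carried per trial: baseline (400 ms fixation), cue (700 ms),
decision (800 ms), post-saccade (400 ms from saccade onset), and reward
(600 ms from reward onset). Fixation-break trials keep no choice and no
post-decision epochs and are excluded from all spike analyses.

## Behavioral model

Choices are Bernoulli draws from a boundary-specific Naka-Rushton curve
P(fast | s) = ℓ + (u − ℓ)·sᵉ/(sᵉ + s₅₀ᵉ). Generator defaults place the
points of subjective equality at 6.9 deg/s (slow boundary) and
11.3 deg/s (fast boundary) — inward of the true references, which makes
error and fixation-break rates peak at the near-boundary speeds 6 and
12. The curve's steepness and lapse rate are not constrained by the
behavioral summaries the model is built to match; the defaults
(exponent 4, symmetric 2% lapses) give error-rate profiles in the
realistic 5–35% range. Saccade onsets are lognormal with median 309 ms
and are metadata only.

Fitting inverts the same model: binomial maximum likelihood over
per-speed choice proportions, with both asymptotes free (lapses), a
multi-start grid over the exponent (the likelihood is non-convex and a
single start can collapse onto a step), and L-BFGS-B within bounds
(lapse ≤ 0.45, exponent ∈ [0.25, 64], s₅₀ within 0.5–2× the tested
range). The PSE is found by bisection on P(s) = 0.5, which handles
asymmetric asymptotes uniformly; it is undefined (and the fit flagged
degenerate) when 0.5 does not lie between the fitted asymptotes or when
the four-parameter fit fails to beat a constant-rate model by at least
2 log-likelihood units — the latter guard catches unidentifiable data
such as responses constant at 0.5. Group curves pool trials per
boundary; per-session fits feed PSE histograms.

## Single-neuron metrics

Responsiveness compares baseline against each task epoch on firing
*rates* (spikes/s), because the windows differ in length; at least 10
trials per side are required. Boundary sensitivity tests each speed's
slow- vs fast-boundary spike counts with Bonferroni correction at
α/8 over the 8 speeds; a neuron is category-sensitive if any speed
survives. The test's α defaults to 0.05 and is configurable.

The category index CI = |(R_slow − R_fast)/(R_slow + R_fast)| uses mean
counts per condition; it is symmetric under boundary relabeling,
invariant to rate rescaling, and undefined (reported missing, never 0)
when both means are zero. The ratio-difference index takes the unsigned
difference of mean counts between neighboring speeds 4/6 and 12/14
separately per boundary; the difference under the boundary the pair
straddles (4/6 straddles the slow cue, 12/14 the fast cue) is the
inter-category value and the other the intra-category value, and the
pair with the larger maximum is selected per neuron.

## Resampling

Both tests are two-sided on |statistic| with add-one smoothed p-values,
(k + 1)/(B + 1), so p is never exactly 0. The bootstrap test resamples
trial values with replacement from the pooled groups at the original
group sizes. The permutation test enumerates all label assignments
exactly for two groups when C(n, n_a) ≤ 10,000 (the observed assignment
then counts itself, giving an exact p) and otherwise shuffles labels
Monte-Carlo style; the default mean-difference statistic uses a
vectorized shuffle path. Every result records its seed, the null
quantiles, and the Bonferroni-corrected threshold used for its
significance flag.

## Population decoder

The decoder assumes each neuron's count is Poisson with a class-specific
mean and that neurons are conditionally independent — appropriate for a
pseudo-population assembled from sequential recordings, where no
trial-by-trial noise correlations exist by construction. The class
log likelihood drops the stimulus-independent log r! term; a property
test proves on exhaustively enumerated small instances that this never
changes the argmax relative to the full Poisson pmf. Training-side class
means are floored at 1 spike per window (configurable) so a silent
training condition cannot produce log 0; with the floor disabled, a
zero-mean class is disqualified (−∞) as soon as any neuron fires, and
contributes 0 when none does (0·log 0 := 0). Exact likelihood ties —
and zero log-likelihood ratios in pair discrimination — are broken
uniformly at random from the seeded stream, which is unbiased under the
null.

Class order follows speed-major-within-boundary indexing: classes 1–8
are the 8 speeds under the slow boundary and 9–16 under the fast; with
direction the 8-speed block repeats per (boundary, direction) for 32
classes (two blocks of 8 per boundary).

**Equalization.** Every (neuron, class) cell is brought to exactly
n = 10 trials: surpluses are subsampled without replacement, deficits
filled with Poisson surrogate trials at the observed class mean, with
the surrogate fraction reported per boundary. Neurons with an empty cell
after outcome filtering are excluded with a logged reason. Decoding
uses correct trials only by default; "all" and "incorrect-only" filters
are provided, and incorrect-trial decoding restricts the near-boundary
speeds (6, 12) to incorrect trials while other classes keep correct
ones.

**Cross-validation.** The default scheme trains on one randomly selected
trial per (neuron, class) and tests on the remaining n − 1; this
inverted split is implemented as stated in the protocol it follows, and
a conventional leave-one-out (train on n − 1, test on 1) is available
behind `scheme="loo"`. Per draw, trial pairing across neurons is
re-randomized within class, since pairing across sequentially recorded
neurons is arbitrary. Accuracy draws (default 1000) are independent
train/test splits; reported marginals count a speed (or boundary,
or direction) as correct when that component of the joint argmax
matches. Accuracy versus population size subsamples neurons without
replacement per draw and normalizes accuracy as
(σ̂ − chance)/(1 − chance), with chance 1/8 for speed and 1/2 for
boundary or direction.

**Pair discrimination.** For each of the seven neighboring speed pairs
and each boundary, the log-likelihood ratio
log LR(s₁, s₂) = log L(s₁) − log L(s₂) classifies held-out trials
(s₁ when LR > 0); a pair is inter-category under a boundary whose
reference speed lies between its members and intra-category otherwise.

## Synthetic tuning families

One session is generated per neuron, emulating sequential recording; a
master seed spawns independent substreams for tuning, schedule, choices,
and spikes. Rates (Hz) convert to expected counts by epoch length; the
cue/decision epochs stay at the baseline rate (3 Hz default, matching
low-baseline projection-neuron activity), putting condition information
only in the two post-decision epochs.

- `flat` — identical mean across classes; the chance-level benchmark.
- `speed_tuned` — Gaussian speed tuning (default amplitude 10 Hz,
  width 3 deg/s) with a random preferred speed, identical across
  boundaries.
- `boundary_gated` — speed tuning plus a boundary-contingent rate change
  confined to one speed per neuron, with near-boundary speeds 6 and 12
  preferentially gated; mirrors single-speed context sensitivity.
- `category_step` — rate steps when the stimulus falls on the fast side
  of the *currently cued* boundary; the generative idealization of
  boundary accentuation.
- `redundant` — every neuron carries the boundary signal, only a subset
  (30% default) is speed tuned; produces boundary accuracy saturating at
  smaller ensembles than speed accuracy.

With `incorrect_spikes="chosen_category"`, post-decision counts on
incorrect trials are drawn from the tuning of the nearest speed in the
wrongly chosen category, modeling a subjective rather than veridical
stimulus trace; this is what makes correct-only decoding beat all-trial
decoding and degrades incorrect-trial readout of speeds 6 and 12.

The generator emulates per-epoch Poisson counts, block structure,
psychometric choice behavior, and fixation breaks. It does not model
spike timing, inter-trial dependencies (adaptation, reward history),
noise correlations, or non-Poisson dispersion; passing tests therefore
certify the analysis machinery under the decoder's own assumptions, not
robustness of the conclusions to violations of those assumptions in
real recordings.

## Numerical choices and test design

The Naka-Rushton curve is evaluated in log space
(1/(1 + exp(e·(log s₅₀ − log s)))) so steep exponents cannot overflow.
Decoding accuracy over draws within one equalized ensemble is not an
independent sample: all draws share the ensemble's frozen 10-trial
pools, whose luck shifts the draw-mean by about ±0.005 (speed) to
±0.01 (boundary) around chance for the 20-neuron benchmark. Calibration
tests therefore average over several independently generated ensembles
and compute the standard error across ensembles (the chance-level suite
uses 8 ensembles × 125 draws), rather than pretending the 1000 draws
are independent. Simulation sizes in the test suite (for example 150
null neurons for family-wise error, 2000 simulations for resampling
calibration, 80–200 decoding draws in qualitative checks) were chosen
as the smallest sizes at which the tested effects are distinguishable
from their Monte-Carlo noise with comfortable margins.

Analyses of variance on draw-level accuracies are deliberately not
reproduced: resampled accuracies violate the independence those tests
assume, so group comparisons are reported as effect sizes with
permutation p-values instead.

## Known limitations

- The decoder ignores noise correlations by design; it is a read-out
  bound for uncorrelated populations, not an optimal decoder for
  simultaneously recorded data.
- Psychometric exponent and lapse defaults are plausible rather than
  measured; absolute error-rate levels in synthetic data depend on them.
- The tail-append rule for re-inserted aborted trials is one of several
  schemes consistent with block-randomized reshuffling without immediate
  repetition; schedule statistics at break rates near 1 are guarded by
  an error, not modeled.
- `in_response_field` is always true for synthetic neurons; the flag
  exists so that real-data ingestion can apply response-field filtering.
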