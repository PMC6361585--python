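# Methods

This note documents the models, statistical procedures, and numerical
choices behind `rmtg_valence`, including the places where the design was
genuinely open and a choice had to be made.

## Synthetic-data generator

The generator is the package's test surface: every classifier is judged
by whether it recovers what the generator planted.

**Spiking model.** Each unit is an inhomogeneous Poisson process whose
rate is a constant baseline multiplied by stimulus-locked kernels. A
kernel is `(stimulus, latency, duration, gain)` with gain > 1 planting
excitation, gain < 1 inhibition, and gain 0 full suppression; a `ramp`
shape interpolates the factor linearly from 1 to the gain across the
phase (used for the sustained reward-cue "ramping" archetype); an
optional second phase `(latency, duration, gain)` plants opponent
biphasic responses at either timescale. Spikes are realized by thinning:
candidates are drawn homogeneously at the rate ceiling (product of the
maximal kernel gains times the maximal baseline) and kept with
probability rate(t)/ceiling, which is exact for bounded rate functions.

**Absolute refractory period.** A 1.5 ms dead time is enforced on every
clean train (greedy left-to-right removal). Without it a 10 Hz Poisson
process would carry ~1% of ISIs under 1 ms and every clean unit would
fail the < 0.2% refractory acceptance rule; real well-isolated units do
not. The dead time thins a rate-λ process to λ/(1 + λτ) — about 1.5% at
10 Hz — and the generator's rate tests account for this correction.

**Burstiness.** A Neyman–Scott cluster process is superimposed: cluster
centers arrive as a Poisson process, each spawning 1 + Poisson(μ − 1)
spikes with exponential within-cluster ISIs. This gives the burst
detector a non-Poisson positive control; no claim is made that it is a
biophysical bursting model.

**Defects.** Rate drift is added to the baseline (Hz/min, clamped at
zero); refractory violations duplicate a chosen fraction of spikes at
+0.5 ms (directly exercising the < 1 ms rule); shock artifacts are
spikes planted 1 ms after chosen event onsets.

**Shared magnitude factor.** `gain_scale_sd` draws one lognormal factor
per unit and scales every kernel's (gain − 1) by it, planting the
across-stimulus magnitude correlations (strongly shock-excited units are
also strongly reward-inhibited) that the correlation analyses recover.
Directions are preserved; gains are clamped at 0.

**Calcium.** dF/F is the spike train binned on the frame grid and
convolved with a difference-of-exponentials kernel (0.1 s rise, 0.8 s
decay — a fast-indicator-like shape sampled at the nominal 5 Hz
post-downsampling rate), normalized to a per-spike peak of 0.2, plus
white Gaussian noise (default SD 0.02). Real traces have photobleaching
trends, motion residuals, and correlated background that this model
omits, so passing tests demonstrate correctness of the trial analysis,
not robustness to extraction artifacts.

**Place conditioning.** A three-state Markov walk: side chambers are
reachable only through the center; each center departure enters the
paired chamber with probability `bias_paired`; dwell times are
exponential (default mean 20 s over a 900 s session); the final interval
is truncated so occupancy partitions the session exactly. Photobeam
breaks accrue as 1 + Poisson(3) per transition, so beam counts scale
with locomotion. Occupancy has no spatial kinematics — photobeam counts
are a locomotion proxy only.

**Determinism.** All randomness flows from `numpy.random.default_rng` /
`SeedSequence`; identical (config, schedule, seed) triples reproduce
identical outputs, and population generation spawns one child seed per
unit so populations are stable under reordering of analysis.

## Quality control

* Refractory rule: fraction of spikes whose preceding ISI is < 1 ms
  (half-open interval); accept iff fraction < 0.002, strict.
* Drift: no statistical procedure is canonical for "significant rate
  drift", so the package uses a Spearman rank correlation of per-window
  baseline rate against window index, two-sided, flag at p < 0.05 —
  distribution-free and consistent with the rank-based treatment of
  non-normal data elsewhere in the pipeline. The same mechanism serves
  cross-session baseline-decline exclusion.
* Shock blanking: spikes in [onset, onset + 10 ms) are removed and the
  intervals recorded as excluded time; rates downstream always divide by
  effective (non-blanked) duration. Blanking is idempotent and
  overlapping windows merge.

## PSTH conventions

Bins are half-open `[left, left + width)` with trial-relative time 0 at
stimulus onset; a spike exactly on an edge belongs to the bin starting
there. Phasic analysis uses 50 ms bins against a 1 s baseline; sustained
analysis uses the same operations with 5 min (or 1 min) bins against a
15 min baseline. Blanked time is carried per bin as excluded seconds,
not as zero counts.

Normalization z-scores the trial-averaged rate against the mean and SD
of the baseline bins' trial-averaged rates, with an SD floor of 0.1 Hz
to stabilize near-silent units; a fold-change dialect (rate / baseline
mean) is selectable because the population-average figures could be
drawn either way. Latency is the left edge of the first bin attaining
the window extreme, ties broken earliest; for unclassified units the
larger absolute deflection picks the extreme.

## Per-neuron testing

The elementary test is a two-sided Wilcoxon signed-rank at α = 0.05 of
per-trial response rates against per-trial baseline rates. Two choices
matter:

* **Duration-matched baseline pairing.** Pairing a 100 ms response rate
  against a 1 s baseline rate skews the null difference distribution
  (the short window's rate is far more variable) and inflates the
  signed-rank false-positive rate to ~7–10%. Each trial's response
  window is therefore paired with a baseline slice of the same duration
  ending at onset (clipped to the available 1 s), which makes the paired
  differences exchangeable under the null; measured null rejection is
  4–5% in every window. The z-scored magnitude still uses the full 1 s
  baseline.
* **Direction from the magnitude sign.** Direction is assigned only at
  p < α, with the sign of the mean normalized response, so that
  sign(magnitude) == direction holds exactly for every responsive unit
  (a median-based sign can disagree with the mean on discrete counts).

Classifier definitions: valence-encoding = reward-cue inhibition
(200–400 ms) AND footshock excitation (0–100 ms). VTA typing: pDA =
excitation 0–200 ms; ramping = activation 200–2000 ms and not pDA;
reward-inhibited = inhibition 0–200 ms; precedence pDA > ramping >
reward-inhibited. pDA aversive typing splits the 100–500 ms inhibition
by the presence of an early 0–100 ms excitation (the early window is not
canonical; 0–100 ms mirrors the RMTg aversive window and precedes the
inhibition window). All tests are two-sided: the analyses report both
directions from one procedure.

**Sustained responses.** No per-neuron procedure is canonical at the
minutes timescale (group analyses used repeated-measures ANOVA), so each
phase is tested by a two-sided rank-sum of per-minute rates in the phase
window against the 15 baseline minutes; biphasic = both phases
significant, directions recorded independently. The cocaine rebound
window defaults to 20–30 min (the alternative 15–25 min reading is
config-overridable). Phases extending beyond the recording are marked
unavailable rather than guessed.

## Burst rule

Open strictly below 80 ms; continue inclusively up to 160 ms; close on
the first interval above 160 ms. Bursts are maximal and non-overlapping;
scanning resumes after the closing spike. The inclusive/exclusive
choices at exactly 80 and 160 ms are documented because toolboxes
differ; the suite pins them with boundary fixtures and verifies the
scanner against an independent symbolic-run enumeration on 1,000 random
trains.

## Population statistics

Correlations are Pearson with a least-squares line, invariant to affine
rescaling of either axis; subset filters (e.g. shock-excited units only)
are explicit arguments. Proportion contrasts use chi-square without
continuity correction — validated against a binomial-resampling oracle
that redraws both groups from the pooled proportion (a margin-fixed
permutation test is systematically conservative relative to the
uncorrected statistic on discrete tables, so the unconditional oracle is
the right comparison). Group time courses use repeated-measures one-way
ANOVA with Holm–Šidák-adjusted window-vs-baseline paired comparisons,
preceded by the D'Agostino–Pearson gate: if the pooled values fail the
omnibus test (p < 0.05) the whole matrix is mid-rank transformed first.
The gate requires n ≥ 8 and is idempotent on ranks.

## Calcium analysis

Trials are 20 s windows centered on onset (100 samples at 5 Hz); onsets
within 10 s of a recording edge are dropped and logged. Each trial is
baseline-subtracted by its pre-onset mean — the minimal reading of
"normalized to baseline", chosen because the input is already dF/F; a
fold dialect would divide. Smoothing is a centered 0.6 s moving average
(3 samples at 5 Hz) with shrinking windows at trial edges. The per-cell
test is a two-sided paired t of response-window (default 0–2 s,
matching the 2 s cue) versus baseline-window means, n ≥ 5 trials. The
whole chain is invariant to positive rescaling of dF/F.

## Place conditioning

An entry is a transition into a chamber from the center; brief center
traversals count as center entries only with dwell ≥ 1 s (a debounce the
logs themselves do not define). Scores exclude the center chamber.
Group contrasts run a two-way (group × stimulus) ANOVA on shifts with
Bonferroni-adjusted per-stimulus unpaired contrasts; with a single
stimulus the test reduces exactly to an unpaired t. The analysis scripts
average each animal's baseline preference over three pre-exploration
days, as the conditioning design prescribes, which also stabilizes the
shift estimates at n = 8 per group.

## Problem sizes and runtime choices

Test and demo simulations use 4 s inter-trial intervals (the windows
under analysis span at most −1 to +2 s, so spacing beyond that only adds
dead time), 200-unit null populations for calibration checks, 1,000
repetitions for statistical-calibration rates, and 20–40 units per
archetype for recovery checks; the demo study in `analysis/` uses the
30 s intervals of the recording design. The planted place-conditioning
contrast (entry bias 0.5 → 0.25 sham vs 0.5 → 0.45 lesion, with
sham-only conditioned slowing) was sized for ~90% power at 8 animals
per group.

## Known limitations

* The generator's rate kernels are piecewise-constant (or linear ramps);
  real neurons have smooth, adapting responses. Latency recovery is
  therefore exact only up to bin resolution.
* Null calibration of the signed-rank test holds for the duration-
  matched pairing on Poisson counts; strongly bursty baselines violate
  trial exchangeability and can inflate the false-positive rate.
* The calcium model omits extraction artifacts; projection contrasts
  demonstrate statistical machinery, not robustness to imaging noise.
* No hierarchical modeling across sessions or animals: units are pooled,
  as in the analyses this package reproduces.
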