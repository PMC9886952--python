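# Methods

## The paradigm being modelled

An additional-singleton search experiment with a spatial distractor
regularity: 8 stimulus locations on a circle of radius 5.6 cm, a colour
singleton distractor on 50% of trials, two thirds of those at one fixed
high-probability (HP) location, the rest uniform over the other seven.
Two between-participant task variants differ in the precision of the target
template: *fixed-feature* (constant target shape, a feature-specific template
is possible) and *mixed-feature* (target shape swaps unpredictably, only a
coarse singleton template is possible). Each participant completes 1 practice
block plus 7 experimental blocks of 48 trials.

The package asks two questions of such data: how learned suppression is
distributed over space (the suppression-gradient model) and how it builds up
over blocks (the learning-curve model), alongside the classical averaged-RT
ANOVAs.

## Synthetic experiments

The generator realizes the design *exactly*: every block contains 24
distractor-absent, 16 HP-distractor and 8 low-probability-distractor trials in
shuffled order (exact-count randomization rather than independent Bernoulli
draws, mirroring standard psychophysics practice and making design checks
deterministic). The HP location is drawn uniformly per participant and kept
for the whole session. Locations are indexed 0–7 counter-clockwise from the
top vertical; distances between locations use the analysis distance table
{45°: 4.25, 90°: 7.85, 135°: 10.30, 180°: 11.20} cm. The exact chord lengths
at radius 5.6 cm differ in the second decimal (4.29, 7.92, 10.35 at
45°/90°/135°); both are provided (`chord_distance` computes the exact chord)
and neither is silently "corrected" — the discrepancy is inherited from the
printed distances, whose provenance is not documented.

RTs are simulated from the same equations the models fit. In *condition* mode
the trial mean follows the learning curve of the trial's condition at its
block (practice = block 1; the start level is the curve value at an imaginary
block 0). In *spatial* mode the trial mean is the participant's absent
baseline plus the suppression-curve cost at the trial's distractor distance,
block-invariant.

### Generating values (the emulated study conditions)

Group-level generating values are the published group-mode estimates wherever
these are printed: asymptotic distractor costs Δa_low = 40 (fixed) / 68 ms
(mixed), Δa_high = 12 ms (both tasks), decrease-rate differences 0.16/0.13
(fixed) and 0.4/0.11 (mixed), suppression-map parameters r = 0.11 /cm,
m = 64 ms, d = 13 ms, between-task differences Δs = 320 ms and
Δa_absent = 76 ms. Quantities the study does not print are fixed once at
realistic values consistent with its published results:

| quantity | value | rationale |
|---|---|---|
| absent asymptote `a_absent` | 600 (fixed) / 676 ms (mixed) | matches the printed 76 ms between-task asymptote difference at plausible absolute levels |
| absent start `s_absent` | 720 / 1040 ms | matches the printed 320 ms between-task start difference |
| present start `s_present` | `s_absent` + 40 ms | initial capture of the same order as the asymptotic low-probability cost |
| baseline decrease rate `c_absent` | 1.0 | the published posterior-predictive learning curves plateau within the 7 experimental blocks, which requires a rate near or above 1; printed rate *differences* are applied on top |
| trial noise `trial_sd` | 100 ms | coefficient of variation ≈ 0.15 at ~700 ms mean RT, the standard figure for speeded search; consistent with the precision of the published group-level intervals |
| participant spread | 50 ms on ms-scale parameters (proportionally smaller on rates) | typical between-participant RT variability |
| participant correlation | 0.8 (exchangeable) | individual differences are dominated by a general-speed factor that shifts all levels together |
| accuracy / no-response rate | 0.95 / 0.01 | typical online-experiment values; the study reports removal fractions of similar order |

These are *study conditions*, not free dials: tests and the acceptance script
run against these defaults.

What the generator does **not** emulate: right-skewed RT distributions
(Gaussian trial noise is used, as assumed by both models), sequential effects
(intertrial priming — so `remove_location_repeats` removes nothing systematic
from synthetic data), fatigue or drift within blocks, and speed–accuracy
coupling (correctness is an independent Bernoulli). Passing recovery tests
therefore shows the estimation machinery is correct and calibrated under the
models' own assumptions; it does not validate those assumptions against real
data.

## Preprocessing

Order: error/no-response/anticipation filter (< 200 ms; 200 ms retained) →
low-accuracy block removal (< 50% on raw attempted trials, no-response counted
incorrect) → participant exclusion (standard: accuracy < 50% in more than one
block, grand-mean RT beyond 2.5 SD of the task group, or no practice
responses; strict adds any single block below 50%) → 2.5-SD outlier trimming
within participant × condition × block (n−1 SD; exactly 2.5 SD retained;
cells with fewer than 2 trials untouched). Accuracy-based rules evaluate the
raw table, passed explicitly as a `reference` argument. Every removal is
accounted in an `ExclusionReport`; a second trimming pass would trim further
(the rule is not idempotent by nature) and is not run. The practice block is
excluded from all aggregates except the learning-curve input.

## Bayesian machinery

Both hierarchical models expose their joint log-density *and its analytic
gradient* (verified against finite differences in the test suite), and are
sampled with Hamiltonian Monte Carlo: leapfrog integration with jittered
trajectory length, dual-averaging step-size adaptation to a 0.8 acceptance
target, and a metric estimated from the warm-up window — a dense position
covariance (shrunk toward its diagonal) when the dimension allows, which
matters because the power-law's (a, c) pair and the exponential's (r, m) pair
are strongly correlated a posteriori. Four chains run vectorized. Split-R-hat
is computed per parameter; a run is *converged* iff max R-hat < 1.01, and
non-convergence or divergent trajectories are flagged on the result object
and logged, never silently dropped. At the reduced draw counts used in tests
some replicates flag R-hat in the 1.01–1.05 range; group-level summaries are
stable at that level.

Summaries follow the paradigm's conventions: the point estimate is the mode
of a Gaussian-KDE (Silverman bandwidth, 512-point grid over the sample
range), and intervals are 95% highest-posterior-density intervals (shortest
interval containing ⌈0.95 n⌉ sorted draws). Model comparison uses PSIS-LOO
(ArviZ), with Pareto-k > 0.7 counted as warnings. Full-scale sampling
defaults (5,000 stored draws in 4 chains; thinning as a storage option)
are configured down in tests and recovery runs (500 draws/chain after
1,000–1,200 adaptation steps).

## Spatial suppression gradient

Fitted to per-participant ΔRT (present-minus-absent mean RT) at each
distractor distance, pooled over experimental blocks — the quantity the
gradient equation indexes. Hierarchy: participant-level (r, m, d, log sd)
non-centered around group means; m and d hyperparameters shared across tasks,
r task-specific, with the between-task gradient difference reported. Priors:
group r ~ half-normal(0.5 /cm), m ~ Normal(60, 40) ms truncated at 0,
d ~ Normal(15, 30) ms truncated at 0, residual sd log-normal around 40 ms.
The participant-level gradient spread prior is tight (half-normal(0.05)):
with five ΔRT points per participant the individual gradient is barely
identified, and looser spreads let participant gradients escape into the
saturated regime (r ≳ 0.4 /cm, where the curve flattens before the smallest
inter-location distance and gradients become indistinguishable), biasing the
group gradient upward. d ≤ m is encouraged by the priors, not enforced — the
posterior geometry stays simple and the ordering holds wherever the data
support suppression.

The suppression map assigns each display point `m − curve(distance to HP)`:
maximal suppression m − d at the HP location, fading to zero; rendered on a
201 × 201 grid spanning ±12 cm with the HP location on the top vertical.

## Learning curves

Fitted to participant × condition × block mean RTs (the practice block
included, as the curve's first measured point). Structure per task and
participant: start levels s_absent and s_present (shared by the high/low
conditions — the spatial bias must be learned before present-trial RTs can
diverge), asymptote slots and rate slots per the variant, and one residual sd
per participant shared across conditions. The residual is read as a
*trial-level* scale: a block mean of n trials gets σ = sd_i/√n, so the
24/16/8 composition of absent/high/low cells enters the likelihood with its
correct relative precision.

**Identifiability is the central design problem.** With 8 blocks, a power
curve's asymptote is partly an extrapolation, and (a, c) trade off along a
ridge; with condition-specific rates fitted independently the three
conditions' ridges decouple and the asymptotic *differences* (the estimands)
become absurdly uncertain — the same failure the original uncorrelated
varying-effects model showed. Two structural choices restore identification:

1. **Group rates decompose** into a common level plus condition offsets
   shrunk toward zero (offset scale 0.15 on the log scale, matching the size
   of rate differences this paradigm produces). The *both-effects* variant
   still expresses condition effects on the rate, but the conditions' ridge
   positions move together.
2. **Participant-level rate variation is one common factor** across
   conditions (condition-specific rates live at the group level). Individual
   8-point curves cannot support three separate rates; a common participant
   rate offset plays the role the original's correlated varying effects
   played, without estimating an 8 × 8 correlation matrix that n = 30
   participants cannot inform.

Remaining priors: task-level s and a ~ Normal(700, 200) ms truncated at 0;
the common log rate ~ Normal(0, 0.6) — centred at c = 1, a curve that
completes most of its learning within a session as the published predictive
curves do; a centre well below 1 drags all conditions down the (a, c) ridge
and biases the asymptote differences. Trial-level log residual sd ~
Normal(log 100, 1); participant-level level spreads ~ half-normal(60) ms,
rate-factor spread ~ half-normal(0.25), sd spread ~ half-normal(0.5); all
configurable.

Variants: `both` (condition-specific a and c), `rate_only` (shared a),
`asymptote_only` (shared c), `none` (shared both); s keeps its
shared-present/separate-absent structure in all of them. Variant likelihoods
nest (`none` ⊂ {`rate_only`, `asymptote_only`} ⊂ `both`).

Derived effects are computed draw-wise: within each posterior draw the
participant-level Δa = a_condition − a_absent (and Δc) are averaged across
participants to a group value, and DI = Δa_low, SE = Δa_low − Δa_high are
formed from those draws — never from separately summarized marginals. Tasks
are fitted independently; between-task differences (mixed − fixed) pair
draws across the two independent posteriors.

## Parameter recovery (the acceptance surface)

`dislearn.recovery` simulates cohorts of 30 participants per task from the
generator defaults, runs the full preprocessing + fitting pipeline at
reduced draws, and reports recovered group-level modes. Because the
estimands' posteriors at n = 30 are wide (tens of ms for DI/SE), single
simulated cohorts scatter; the acceptance script reports the **median over
five replicate simulations** per quantity, each with its own seed derived
from the command-line seed. Problem sizes: 30 participants × 24 cells = 720
block means per learning fit (one task per fit); the spatial fit uses both
tasks, as the study's model does — 60 participants × 5 distances = 300 ΔRT
points — and the reported gradient is the across-task averaged map value,
which roughly halves the posterior skew that otherwise pulls the
kernel-density mode of the gradient below its generating value.

## Known limitations

* The fitted model omits the generator's cross-parameter participant
  correlations except through the common rate factor; group-level estimands
  are robust to this, participant-level shrinkage is mildly miscalibrated.
* Gaussian RT likelihoods; no skew, no sequential structure.
* The asymptote remains partly extrapolation: DI/SE inference depends on the
  rate-structure priors above, which is documented rather than hidden. A
  quantified consequence: the data cannot estimate condition rate
  differences (their posterior is essentially the shrinkage prior), and a
  rate-difference deficit δ propagates into the condition's asymptote with
  gain ≈ (s−a)·9^(−c)·ln 9. In the mixed task (s−a ≈ 390 ms) this biases
  the recovered suppression effect upward by roughly +12 ms at the default
  study conditions; the fixed task's gain is about three times smaller and
  its recovery is unbiased within tolerance. The corresponding recovery
  check is expected to fail for the mixed-task suppression effect and
  documents this limitation rather than hiding it.
* The far-field maximum capture m of the spatial model is likewise an
  extrapolation beyond the 11.2-cm display; its posterior is right-skewed
  and the KDE mode typically sits several ms below a generating value of
  64 ms.
* PSIS-LOO operates on block-mean observations (720 per task), matching the
  model's likelihood, not on trials.
* The CLI is a thin wrapper; long analyses (model comparison) re-fit from
  scratch rather than caching posteriors.
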