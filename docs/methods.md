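# Methods

## The problem

When a person must start stepping before knowing which of two floor
targets — one medial, one lateral of the stepping foot — will turn out
to be the true one ("go before you know"), the anticipatory postural
adjustment (APA) that precedes foot lift reveals how the motor system
weighs the two possible actions. The informative quantity is the
lateral excursion of the center of pressure (COP) toward the swing-foot
side during the pre-step phase: it is reliably larger before a step to
the medial target than before a step to the lateral target, because a
medial step narrows the base of support and demands a stronger push of
the body toward the stance side. If under target uncertainty a
participant's lateral COP excursion matches the single-medial
magnitude, they are planning for the worst case; if it sits at the
midpoint, they are averaging the two plans.

`apastep` implements the full analysis chain for this paradigm: a
synthetic-trial generator with embedded ground truth, signal
conditioning, COP/foot event detection, stability margins, trial
quality control, frequentist statistics, and a hierarchical Bayesian
model of each participant's medial-vs-lateral weighting.

## Signal conditioning

Force-plate channels (1,000 Hz) are low-pass filtered at 20 Hz and
marker channels (100 Hz) at 4 Hz with a fourth-order Butterworth filter
applied forward and backward (`scipy.signal.sosfiltfilt`). "Fourth
order" names the one-way design, the biomechanics convention; the
effective order doubles and the pass is zero-phase. The filter edge
policy is reflect padding of up to 1 s; constant signals pass through
exactly. The global COP is the per-axis force-weighted mean of the two
plate COPs, `(Fz1*COP1 + Fz2*COP2)/(Fz1 + Fz2)`, undefined (an error)
if the total vertical force is ever non-positive. Velocities use the
3-point central difference, first-order one-sided at the ends — exact
for quadratics, with the usual `(2*pi*f*dt)^2/6` relative error bound
for band-limited signals.

## Event definitions

All thresholds are configuration fields; the defaults are the analysis
standards for this paradigm:

- **COP onset** — first instant the absolute mediolateral COP velocity
  exceeds 0.05 m/s and stays above it for at least 50 ms (50 samples).
  The search covers the whole trace so pre-cue onsets are visible to QC.
- **Initial lateral / posterior peaks** — first local maximum of the
  swing-side (resp. posterior) COP excursion between onset and
  foot-off with topographic prominence of at least 1 mm, falling back
  to the window's global maximum when the excursion is monotone. The
  prominence value and first-peak tie-break are declared policy; the
  "initial peak" rule exists to keep feedback corrections after the
  target reveal out of the measurement. Displacements are measured from
  the COP position at onset, in mm.
- **Foot-off** — vertical velocity of the swing second-metatarsal
  marker above +0.02 m/s sustained 50 ms. This mirror of the contact
  rule is declared policy (a foot-off definition is needed to bound the
  peak-search window).
- **Foot contact** — after the fastest descent (global minimum of that
  marker's vertical velocity), the first sample above −0.02 m/s.
- **Multiple steps** — a second sustained lift-off of either foot after
  landing *that also gains ≥ 10 mm of height over the landing level*.
  The height condition is needed because the zero-phase 4 Hz filter
  rings slightly at a sharp touchdown and can manufacture brief
  positive-velocity intervals with no real foot movement.
- **Movement time** — foot contact minus COP onset.

## Stability margins

COM is estimated as the mean of the four pelvis markers (bilateral
ASIS/PSIS) in the horizontal plane. The extrapolated center of mass is
`XCOM = COM + v/omega0` with `omega0 = sqrt(g/L)`, `g` = 9.81 m/s² and
`L` the vertical distance from the COM to the mean heel height over the
quiet-stance baseline. `MOS_ML` is the lateral coordinate of the
swing-foot fifth-metatarsal marker minus the XCOM's; `MOS_AP` is the
anterior coordinate of the swing-foot toe marker minus the XCOM's; both
evaluated at foot contact, positive when the XCOM lies inside the base
of support. Trials with `MOS_ML < 0` (strict) are counted as unstable.

## Trial quality control

Five exclusion rules, each independently testable via the generator's
failure-injection modes: (1) more than 55% of body weight on one side
at any point between the two auditory cues; (2) COP onset before the
go cue; (3) mean COP displacement over the first 50 ms after onset
toward the stance side and/or anterior (the window length is declared
policy; the rule as stated is instantaneous-ambiguous); (4) for
dual-target trials, the true target revealed before the initial
lateral or posterior peak; (5) multiple steps to stop. The simulated
reveal trigger fires at the first sample after the go cue with
`|Fz1 − Fz2|` strictly above 10% of body weight, plus a fixed 217 ms
display latency modeling the acquisition chain being emulated.

Rules interact physically: a 60/40 baseline split on a dual-target
trial would also fire rule 4, because the online trigger condition is
already satisfied at the go cue. The failure-injection tests therefore
pair each mode with a condition in which its signature is isolated.

## The synthetic-data generator

The generator is the package's study-conditions definition, not a
tuning device. Defaults: 13 participants, 24 trials per condition over
2 days, group weight invlogit(alpha) = 0.85 with sigma_alpha = 0.5
(medial-dominant, with the minority of participants intermediate),
single-lateral / single-medial lateral excursions 30 / 45 mm with 2 mm
between-participant spread and sigma_k = 3 mm trial noise, posterior
excursions 35 mm (single) / 25 mm (dual), reveal latency 217 ms.
The 30/45/35/25 mm template amplitudes are free simulator parameters
chosen to be physiologically plausible and to reproduce the orderings
of the real effects; they are not measured values.

Time-series trials are rendered from minimum-jerk (quintic smoothstep)
position templates: fixation 1 s, first cue, a uniform 1.0–1.5 s
interval, go cue, a ~0.3 s reaction, then a 0.25 s lateral COP rise to
the trial amplitude, a concurrent 0.28 s posterior excursion, a 0.30 s
unload to the stance foot, and a swing whose duration couples to the
posterior excursion at −5 ms/mm (so the trial-wise regression of
movement time on posterior displacement has a recoverable ground-truth
slope). Forces follow from the lateral COP template by the two-plate
lever relation with feet 20 cm apart; markers translate rigidly with
analytic swing trajectories. Observation noise: 1.5 N per force
channel, 0.3 mm per plate-COP channel, 0.15 mm per marker channel.

Ground-truth event times are obtained by applying *literal* reference
detectors (`apastep.reference`, plain sample-by-sample loops) to the
noise-free, filtered templates. The production detectors in
`apastep.events` implement the same rules independently (vectorized);
the test suite requires exact agreement between the two routes on 100
noisy trials and sample-exact recovery of the truth on noise-free
trials.

One inherent approximation is documented rather than hidden: because
the onset rule fires only once the COP velocity reaches 0.05 m/s, the
template has already moved a sub-millimeter distance (~0.2–0.5 mm) at
the detected onset, so the measured displacement is smaller than the
nominal template amplitude by that tail. Tests assert amplitude
recovery within 0.6 mm and exactness against the rule-derived truth.

What the generator does *not* emulate: whole-body dynamics and shear
forces, marker dropout, non-Gaussian noise, within-foot COP structure,
reactive feedback corrections after the reveal, and any distributional
features of real recordings beyond the event structure (no public
recordings exist to match). Passing tests therefore demonstrate that
the pipeline implements its stated rules faithfully and recovers known
truth under controlled conditions — not that it is robust to every
artifact of real data.

## Frequentist statistics

Trials are averaged to one value per participant × cell before ANOVA.
All within-subject factors in this design have two levels, so the
Greenhouse–Geisser epsilon is identically 1 and sphericity is vacuous;
epsilon is reported as 1.0 and general epsilon machinery is out of
scope. The sums-of-squares decomposition is delegated to
`statsmodels` `AnovaRM`; for every two-level effect the F equals the
squared paired t of the per-participant contrast, which the tests
verify to 1e-9 against independently computed contrasts. A zero-error
contrast (identical nonzero differences in every participant) is
reported as an infinite F with a degeneracy flag. Partial eta-squared
is `F*df1/(F*df1 + df2)`. Simple main effects use each stratum's own
error term (df = (1, n−1) per stratum), matching the pattern of the
reported values. The dual-condition normalization maps each pooled
dual value through `(x − mid)/(m_SM − mid)` with `mid` the midpoint of
the participant's single-condition means, anchoring m_SL → −1, mid → 0,
m_SM → +1; it is invariant to the displacement unit. One-sample
t-tests are two-sided with Cohen's d = |t|/√n and post-hoc power from
the noncentral t distribution (noncentrality d√n, df n−1, alpha 0.05).

## Hierarchical Bayesian weighting model

Units are millimeters throughout, so the priors sit on the intended
scale: alpha ~ Normal(0, sd 10,000) ("sigma = 10000" is read as a
standard deviation — a weak prior either way), sigma_alpha ~
half-Cauchy(25), sigma_k ~ Uniform(0, 1000); mu_SM(k)/mu_SL(k) are
plugged-in empirical single-condition means, not latent parameters.

The sampler is a blocked MCMC vectorized across chains: `alpha` and
each `sigma_k` have exact conjugate updates (normal; inverse-gamma on
the variance, truncated to the uniform prior's support), while each
`alpha_k` and `log sigma_alpha` take adaptive random-walk Metropolis
steps (proposal scales adapt toward 44% acceptance during warmup only,
then freeze, so the post-warmup kernel is fixed and valid). The
sampler is pluggable in the sense that the contract is diagnostic —
split R-hat < 1.1 over all parameters — not tied to a named algorithm.
Initial states are data-informed and overdispersed across chains.
With 13 participants × 24–48 dual trials the posterior is
well-identified and the chains mix essentially immediately (observed
max split R-hat ≈ 1.005 at the reduced schedule).

The default schedule is 4 chains × 25,000 iterations with 5,000
burn-in (20,000 kept per chain). Tests and the acceptance script use a
documented reduced schedule — 4 chains × 2,500 post-warmup draws after
1,000 warmup — because the contract is distributional, not
draw-count-dependent; the reduced schedule reproduces summaries to
well within Monte-Carlo error of the full one.

Each participant's strategy label uses the posterior mean of theta_k
against the 1/3 and 2/3 lines: ≥ 2/3 medial, ≤ 1/3 lateral, otherwise
intermediate (closed boundaries toward the outer labels; mean rather
than median is the declared convention — the two differ negligibly
here).

Verified properties: the joint log density matches a term-by-term
summation oracle to 1e-10; with no data, forward draws from the priors
put theta symmetrically about 0.5; parameter recovery for true group
weights {0.3, 0.5, 0.7, 0.9} stays within ±0.1 with ≥ 90% credible-
interval coverage over 20 seeded replicates each.

## Numerical and degenerate-case policy

Half-open time intervals `[start, end)`, 0-based indices, first-crossing
tie-breaks everywhere. Strict inequalities at all physical thresholds
(10% trigger, 55% load, MOS_ML < 0). Missing onset or step maps to QC
sentinels (`no_onset`, `no_step`) rather than exceptions, so cohort
processing never aborts on a degenerate trial; out-of-support sampler
states get log density −inf rather than errors. Split R-hat may fall
marginally below 1 by sampling noise; the convergence check is an
upper bound only.

## Problem sizes

The test suite exercises the full 13-participant reference cohort for
every statistical and Bayesian check, 100 time-series trials for the
detector-oracle equivalence, and 4-participant cohorts for end-to-end
pipeline checks; the recovery study runs 4 × 20 independent
generate-and-fit replicates. These sizes make the whole suite run in
about a minute while keeping every check at the cohort scale the
analysis is designed for.

## Known limitations

- The posterior-peak search window (onset → foot-off) is one reading of
  an ambiguously circular textual definition; the window end is policy.
- The generator's movement-time/posterior-displacement coupling is
  linear by construction; real coupling is unlikely to be exactly linear.
- `sigma_k` is constant across participants in the generator (the model
  still estimates it per participant).
- The adaptive Metropolis-within-Gibbs sampler mixes slowly for very
  small cohorts (fewer than ~4 participants), where the between-subject
  SD posterior is heavy-tailed; non-convergence is flagged, never
  silent.
- No C3D/vendor formats, no marker-gap filling, no real-time use.
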