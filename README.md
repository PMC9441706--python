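# apastep

Analysis of **anticipatory postural adjustments (APAs) for stepping
onto competing potential targets**, for researchers in human movement
and posture who study "go-before-you-know" motor planning.

When a person must begin a step before knowing which of two floor
targets — medial or lateral of the stepping foot — is the true one, the
pre-step center-of-pressure (COP) shift reveals their plan. Stepping
medially demands a larger lateral COP excursion toward the swing-foot
side (it narrows the base of support), so under uncertainty a
*worst-case* planner produces a medial-sized excursion while a
*motor-averaging* planner produces the midpoint. `apastep` implements
the full pipeline for this paradigm:

- a **synthetic-trial generator** (dual force plates at 1,000 Hz,
  14 lower-body markers at 100 Hz) with embedded ground-truth events;
- **preprocessing** — zero-phase Butterworth filtering (20 Hz plates,
  4 Hz markers), the two-plate global COP
  `COP = (Fz1·COP1 + Fz2·COP2)/(Fz1 + Fz2)`, central-difference
  velocities;
- **event detection** — COP onset (|v_ML| > 0.05 m/s sustained 50 ms),
  initial lateral/posterior COP peaks, foot-off and foot contact from
  the second-metatarsal marker (−0.02 m/s rule), movement time;
- **stability margins** — extrapolated center of mass
  `XCOM = COM + v/√(g/L)` and the margins of stability MOS_ML / MOS_AP
  at foot contact;
- **trial QC** — the five exclusion rules (uneven stance > 55 % body
  weight, pre-cue onset, abnormal initial direction, target reveal
  before the initial peaks, multiple steps), plus a simulator of the
  10 %-body-weight reveal trigger with its 217 ms display latency;
- **frequentist statistics** — repeated-measures ANOVA with partial
  η² = F·df₁/(F·df₁+df₂), simple main effects, the dual-condition
  normalization (single-lateral → −1, midpoint → 0, single-medial →
  +1), one-sample t-tests with Cohen's d = |t|/√n and noncentral-t
  power, per-participant regression of movement time on posterior COP
  displacement;
- a **hierarchical Bayesian model** of each participant's
  medial-vs-lateral weighting:

  ```
  α      ~ Normal(0, 10000)         σ_α ~ half-Cauchy(25)
  α_k    ~ Normal(α, σ_α)           θ_k = invlogit(α_k) ∈ (0, 1)
  μ_D(k) = θ_k·μ_SM(k) + (1−θ_k)·μ_SL(k)
  Y_k,i  ~ Normal(μ_D(k), σ_k)      σ_k ~ Uniform(0, 1000)
  ```

  fitted by a blocked MCMC sampler (conjugate Gibbs + adaptive
  random-walk Metropolis, vectorized across chains) with split R-hat
  diagnostics and strategy labels at the 1/3 and 2/3 lines.

See `docs/methods.md` for the model, all rule definitions, and the
numerical policy.

## Worked example

`examples/` contains one short script per capability. Estimating the
cohort's weighting policy from a synthetic 13-participant cohort
(`examples/05_bayesian_weights.py`):

```
$ python examples/05_bayesian_weights.py
max split R-hat over all parameters: 1.004 (converged: True)
group weight: mean 0.881, 95% CrI [0.806, 0.940] (generating truth 0.850)

participant  post mean          95% CrI         label  truth
P01              0.937 [0.898, 0.974]        medial  0.940
P02              0.890 [0.808, 0.965]        medial  0.819
...
P10              0.555 [0.468, 0.644]  intermediate  0.579
...
12/13 participants show a medial weighting pattern (theta >= 2/3)
```

The group weight near 0.85 (truth recovered within the credible
interval) and the dominance of `medial` labels mean the simulated
cohort plans its pre-step COP shift for the medial — worst-case —
target rather than averaging the two options; participant P10, whose
true weight is 0.58, is correctly labeled intermediate.

The frequentist side (`examples/04_cohort_statistics.py`) prints the
matching signature:

```
normalized dual values (m_SL -> -1, midpoint -> 0, m_SM -> +1):
  mean = 0.70
  vs midpoint:      t(12) =  10.95, p = 1.3e-07, d = 3.04, power = 1.00
  vs single-medial: t(12) =  -4.59, p = 0.00063, d = 1.27, power = 0.99
movement time on posterior displacement: 13/13 participants with
negative slope (mean slope -5.0 ms/mm)
```

— dual-condition excursions sit far above the midpoint of the two
single-condition magnitudes, and smaller posterior COP shifts go with
longer movement times.

`examples/06_full_pipeline.py` runs the whole chain end to end from
rendered time-series trials (generation → filtering → detection → QC →
statistics → Bayesian fit) and prints the report digest.

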