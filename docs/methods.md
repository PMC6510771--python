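# Methods

## Deviation indices

A tracked swim path is an ordered series of positions C_0, C_1, … sampled at
a uniform unit time t. For each step C_n → C_{n+1} the *optimal route* is the
straight segment from C_n to the platform centre B (for index 4: from the
entry C_0 to B, fixed for the whole trial). With step length
L_n = |C_n C_{n+1}| and offset angle θ_n = ∠C_{n+1} C_n B ∈ [0°, 180°]:

* **index 1** = Σ L_n sin θ_n (cm) — lateral deviation of each step from the
  current optimal route;
* **index 2** = Σ θ_n (degrees) — accumulated heading error;
* **index 3** = Σ 2 L_n sin(θ_n/2) (cm) — length of the correction vector
  that rotates each step onto the optimal route at equal length (the chord
  of the turning angle); per step 2 L sin(θ/2) ≥ L sin θ, so index 3
  dominates index 1 on every trajectory;
* **index 4** = Σ |component of the step ⊥ to C_0 → B| (cm).

Sums run from release up to and including the step that first touches the
platform (boundary inclusive: distance ≤ platform radius), or over the whole
capped trial for non-finders, whose escape latency is scored as the cap
(60 s by default). The last partial step before contact is counted in full;
there is no fractional-step proration.

**Degenerate steps.** A zero-length step (floating) and a step taken from
the platform centre itself leave the offset angle undefined. By default such
steps contribute 0 to all four indices — a stationary animal accrues no
*directional* deviation. A literal reading of the defining case expression
(the cosine is *assigned* 0) would instead score the angle as 90°;
`strict_angles=True` provides that behaviour for comparability. The choice
matters only for data with genuine floating episodes; the correction length
keeps its zero branch under both conventions.

**Numerics.** The offset angle is computed as atan2(|d × r|, d · r) (d the
step, r the route), which is algebraically identical to the arccos of the
normalised dot product but well conditioned near 0° and 180°; cosines are
never formed explicitly, so no clamping is needed in the vectorised path.
With integer-valued test geometries the zero-deviation case is exact, not
merely within tolerance. All index computations are rigid-motion invariant
and scale linearly (indices 1, 3, 4) or not at all (index 2) with the
coordinate unit.

## Trajectory handling

Tracker exports (`time_s,x_cm,y_cm`) are validated (strictly increasing
times from 0, ≥ 2 samples, finite values, inside the pool unless clamping is
requested) and linearly resampled onto the analysis grid 0, t, 2t, …, with
the final raw sample retained. The analysis unit time defaults to **0.2 s
(5 Hz)** — a conservative common denominator of commercial tracking systems;
because camera rates vary and are often unreported, the unit time is
configurable, and resampling makes indices comparable across input rates.
Tracking dropouts are bridged by the same interpolation; gaps over 1 s are
logged. Samples after the first platform contact are discarded before any
index is computed, so the sums cover exactly the search period.

## Swim simulator

Raw MWM tracking data are rarely deposited, so the package ships a seeded
generator used by the tests and the acceptance analysis. It is a
three-mode switching biased random walk on the analysis grid:

* **swim** — heading drawn from a von Mises distribution centred on the
  direction to the platform with concentration κ (`goal_bias_kappa`; κ = 0
  is uniform random search), blended with the previous heading by
  `turn_inertia` (default 0.4);
* **thigmotaxis** — heading along the pool-wall tangent closest to the
  current heading, with small von Mises jitter (wall following);
* **float** — near-zero speed (truncated normal around 2 cm/s), heading
  unchanged.

Speeds are truncated-normal draws (swim mean ~20 cm/s, SD 3); positions are
reflected specularly off the pool wall (folding the radial overshoot inward
avoids artificial wall-sticking outside thigmotaxis mode). A trial ends at
first platform contact or at the 60 s cap.

Presets (overridable):

| parameter | control | impaired (model) |
|---|---|---|
| goal_bias_kappa (training 1 → 20) | 2.5 → 8 | 0.5 → 1.2 |
| thigmotaxis_prob | 0.05 | 0.35 |
| float_prob | 0.02 | 0.08 |
| swim speed (cm/s) | 20 | 21 |

κ grows geometrically per training (spatial learning); the impaired preset
barely learns. The impaired swim speed is set slightly above control so
that, with its more frequent floating, the *realised* group mean speeds
agree within a few percent — matching the standard control that lesioned and
sham groups must not differ in motor ability. The default study design is
19 impaired + 20 control animals × 20 trainings (780 trials), with release
points rotating through the four pool quadrants.

What the generator does **not** emulate: circling/chaining strategies as
distinct modes, within-trial strategy switching driven by cue salience,
inter-animal trait heterogeneity (animals differ only through their random
streams), and tracker noise (jitter, dropouts, reflections). Passing tests
therefore demonstrate the correctness and statistical behaviour of the
*measures* under controlled phenotypes, not the biological realism of any
particular rat strain. Effect sizes between the presets are larger than in
typical lesion studies, so absolute AUCs and rejection rates on synthetic
data exceed values reported from real cohorts; only their *ordering*
(indices vs escape latency) is the meaningful comparison.

Every trial's random stream derives from `SeedSequence(seed)` keyed by
(group, animal, training), making study generation a pure function of its
configuration and insensitive to iteration order.

## Statistical evaluation

**Normality gate.** One-sample Kolmogorov–Smirnov with the Lilliefors
correction (reference normal estimated from the sample; statsmodels
implementation). Group comparisons use an independent two-sample t test
when both groups pass the gate at α = 0.05, otherwise a two-sided
Mann–Whitney U test. The t test is Welch by default (the variance assumption
behind published tables is rarely stated); pooled variance is available via
a flag. Table output caps displayed normality p values at 0.200, the
convention of common statistics packages; exact values are returned
programmatically.

**Monte Carlo sensitivity/specificity.** From pooled per-trial databases of
one measure, each cell (sample size n, level α, test) draws `n_replicates`
pairs of samples with replacement: model vs control pool for the
true-positive run, control vs control for the null run (the conservative
definition of a false positive; drawing both null samples from one group
avoids contaminating the null with the group difference). Both tests are
applied unconditionally in separate tracks — the gated protocol is a
separate analysis. Resampling is empirical by default; `parametric=True`
draws from normal fits to the pools instead. All cells derive their streams
from one root seed via keyed seed sequences.

The U test's rejection decision uses **mid-p values from its exact null
distribution** (computed by the classic counting recursion, cached per
sample-size pair) whenever n_a·n_b ≤ 10,000, falling back to the asymptotic
normal approximation beyond. Rationale: U is discrete, and at n ≈ 10 the
attainable size of any conservative rejection region sits well below the
nominal α (e.g. 0.0068 at α = 0.01 for n = m = 10), so a calibration check
of the machinery would be confounded by pure lattice effects; the mid-p
convention (half weight on the observed value) is the standard remedy and
keeps the realised false-positive rate tracking α at every grid cell. Ties
from resampling yield half-integer U, which falls between lattice points
and is handled by the floor. The gated protocol (`compare_groups`) keeps
conventional p values.

**ROC/AUC.** Higher values score as impaired (all five measures rise with
impairment). ROC points come from scikit-learn over all distinct
thresholds; the trapezoidal AUC is cross-checked at run time against the
tie-corrected Mann–Whitney identity U/(n_pos·n_neg) — ties contribute ½ —
and the computation aborts on disagreement. Standard errors and 95% CIs use
the DeLong placement-value variance; the paired Z test for two measures
scored on the same animals uses the DeLong covariance of the paired
placements (implemented in-package; a zero-variance difference, e.g. a
self-comparison, returns Z = 0, p = 1 rather than 0/0).

**Learning-curve stability.** For each animal and measure, the number of
consecutive-training pairs (k, k+1) with value_{k+1} ≥ value_k (ties count
as non-improvement, since a stable learner should keep decreasing). Counts
are compared between a deviation index and escape latency by a paired t
test across animals. This per-pair counting unit is the transparent rule;
published aggregate counts based on other (undocumented) units are not
directly comparable.

**Multiple testing.** No correction is applied across trainings or
measures; per-training p values are reported raw, as is conventional in
this literature. This is a documented limitation, not an oversight.

## Problem sizes

The default evaluation sizes are chosen to make every analysis exact enough
to be decisive while keeping a full run interactive: 10,000 replicates for
null-calibration grids (3-binomial-SE bands of ±0.0065 at α = 0.05), 2,000
replicates for sensitivity sweeps over n = 10…40, and the 780-trial default
study for pooled databases. The acceptance script completes in a few
seconds; the full test suite in well under a minute.

## Known limitations

* Indices are computed on linearly interpolated, truncated paths; very low
  camera rates (< 2 Hz) under-resolve tortuous swims and bias all indices
  downward. Use the native rate when it is known.
* The simulator's phenotypes are stylised; it supports method validation
  and power exploration, not substitution for real behavioural data.
* Escape detection is sample-based: a platform crossing entirely between
  two samples (possible only at coarse unit times) is missed.
* The DeLong variance is asymptotic; with very few animals per group the
  CI coverage of AUC differences degrades.
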