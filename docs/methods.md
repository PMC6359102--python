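# Methods

## Model

`stressvr` predicts a continuous stress level in [0, 1] from windowed
physiological features by local, per-test-instance regression. The three
ingredients are:

1. **Kernel-space ranking.** With kernel *k* and implicit feature map Phi,
   the squared distance `||Phi(x_i) - Phi(z)||^2 = K_ii - 2 K_iz + K_zz`
   ranks training examples by proximity to the test instance without
   materialising Phi. The default kernel is RBF; `gamma` defaults to the
   `scale` heuristic `1 / (n_features * Var(X))`, resolved once per
   training pool so the ranking and the local fit share one concrete
   width.

2. **Robust neighborhood selection.** The candidate pool is the
   `pool_multiplier * N` nearest examples (default 4 x 5 = 20). Labels in
   the pool give a median and a raw median absolute deviation; each
   candidate is scored `kappa_i + rho * |y_i - median| / mad` and the N
   lowest scores win (ties to the lower index, fully deterministic).
   Because the median/MAD pair is fixed at pool level, the objective is
   separable and this greedy choice is exactly the subset optimum for
   that statistic — verified against exhaustive enumeration in the tests.
   When `mad = 0`, a label equal to the median scores 0 and any other
   label scores infinity (the Stahel–Donoho outlyingness convention): a
   unanimous pool has no outliers, and a lone dissenter in a unanimous
   pool is maximally suspect.

3. **Instance-weighted epsilon-SVR.** The selected 0/1 weights Omega
   scale each example's dual box `[0, C * Omega_i]`. In the
   `beta_i = alpha_i - alpha*_i` parameterisation the dual is a
   piecewise-quadratic program with one balance constraint; the in-package
   solver picks the maximally KKT-violating pair and minimises the
   objective *exactly* along the feasible pair direction (the 1-D section
   is piecewise quadratic with kinks where a beta crosses zero), giving
   monotone descent to the optimum. Zero-weight examples are excluded
   from the subproblem — exact, because their box collapses to {0} — so a
   local fit on N = 5 neighbors costs microseconds regardless of pool
   size. The bias is averaged over free support vectors, falling back to
   the midpoint of the KKT interval (which reproduces the label exactly
   when a neighborhood is unanimous).

ST-SVR evaluates this pipeline with training pools drawn from the test
subject's own remaining cross-validation folds; T-SVR adds all other
subjects' examples to the pool. The inductive baselines are a global
epsilon-SVR (the same solver with all weights 1) and ordinary least
squares.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `N` | 5 | neighborhood size; the value the original study design fixed by cross-validation |
| `rho` | 0.1 | dispersion penalty. MAD-normalised scores are O(1–10) for genuine outliers while RBF kappa lives in [0, 2); at 0.1 the penalty vetoes gross label outliers without dragging every neighborhood toward the pool's median label, which a rho of order 1 measurably does |
| `C` | 1.0 | SVR box penalty |
| `epsilon` | 0.05 | tube half-width. Labels are quantised at 1/7 (the eight-level Stroop scale); a tube wider than half that step lets one flat function absorb a mixed 4-vs-1 neighborhood and predict the tube-intersection midpoint instead of the majority label |
| `pool_multiplier` | 4 | candidate pool = 4N nearest; local enough to be relevant, large enough for a meaningful median/MAD |
| `gamma` | `"scale"` | per-pool kernel width (see above); any positive float may be fixed instead |
| window / hop | 3 s / 1 s | the real-time recognition geometry; the label of a window is the label-track value at the window end |
| BVP wavelet / level | db4 / 3 | low band ≈ 0–8 Hz at 128 Hz: keeps the pulse fundamental and first harmonics so diastolic minima stay sharply localised while the notch-and-noise band is stripped; deeper levels distort beat timing by tens of ms through decimation |
| GSR wavelet / level | db2 / 2 | low ≈ 0–0.5 Hz tonic, high = phasic at 4 Hz; db2 because a 3 s window holds only 12 samples |
| SCR prominence | 5% of range, floor 0.03 µS | relative criterion plus the standard minimum-SCR-amplitude floor so event-free windows report zero peaks |
| diastolic separation | 0.3 s | no plausible beat above 200 bpm; minima within one separation of the window edge are discarded as boundary transients |

Hyperparameters (`C`, `epsilon`, `gamma`, `rho`, `N`) are tunable by
`grid_search_cv`, which implements the exhaustive log2 grid
(`2^-8 … 2^8`, step 0.5, 33 values per parameter) with deterministic
smallest-value tie-breaking.

Feature normalisation is per-column min–max fitted on training data only,
clipping at apply time; the model-comparison harness fits one scaler on
the pooled training folds so all four models see the same geometry.
Labels map from the raw Stroop scale by `(raw - 1) / 7`.

## Synthetic data: what it emulates, and what it does not

The generators provide analytic ground truth for every pipeline stage:

* **BVP** — Gaussian pulse train whose inter-beat interval shrinks
  (`0.9 - 0.25·stress` s) and amplitude falls (`1 - 0.4·stress`) with
  stress; pulse width scales with the IBI so adjacent pulses overlap into
  a continuous oscillation with well-defined diastolic troughs at every
  heart rate.
* **GSR** — tonic random-walk baseline plus Poisson SCR events
  (rate `0.05 + 0.25·stress` per second, amplitude `0.1 + 0.4·stress` µS,
  fast-rise/slow-decay kernel).
* **Stroop labels** — alternating congruent/incongruent segments over
  four difficulty levels, raw labels 1–4 / 5–8, normalised by
  `(raw - 1)/7`.
* **Multi-subject features** — all subjects share a smooth
  label-to-centroid constellation; heterogeneity scales a per-subject
  offset (0.2·het), a per-subject *permutation* of the label-to-position
  assignment (a fraction `min(1, het/2)` of levels reassigned), and
  per-level jitter (0.3·het). At heterogeneity 0 the population is one
  homogeneous map (pooled inductive fits match within-subject fits); at 2
  a feature-near example from another subject systematically carries a
  conflicting label. This is the package's operationalisation of
  "dispersed between subjects, irregular within" — the permutation is
  what makes naive pooling fail, and it is the regime in which the
  transductive models dominate. Per subject the labels are balanced
  across levels (as a Stroop protocol with a fixed word count per level
  produces) and thinned geometrically by the `imbalance` parameter.
* **Outlier scenario** — a coherent low-stress cluster plus
  feature-adjacent examples with mislabeled high labels, flags returned
  for assertion.

What the generators do **not** emulate: motion artifacts, sensor
dropouts, respiratory or thermoregulatory coupling, dicrotic-notch
morphology, non-stationary drift of the stress–physiology coupling, and
real labeling noise beyond the explicit outlier scenario. Passing tests
therefore demonstrate correctness of the algorithms and the claimed
qualitative orderings under the stated generative regime — not
field-level accuracy on recorded data, which depends on signal quality
and labeling fidelity no desk-scale simulation can certify.

## Numerical choices

* SMO stops when the dual KKT gap falls below 1e-9 (every fitted model in
  the test suite has gap < 1e-6); non-convergence raises with iteration
  diagnostics rather than returning silently.
* kappa is clipped at −1e-10 to absorb PSD round-off; selection and
  fold assignment contain no randomness beyond the caller's seed.
* Degenerate cases are defined, not special-cased ad hoc: all-equal
  labels fit a flat model with `b` = that label; a constant feature
  column normalises to 0; an all-zero weight vector and a
  single-subject T-SVR raise informative errors; discretisation uses
  half-open thirds `[0, 1/3) / [1/3, 2/3) / [2/3, 1]` with out-of-range
  values clipped under a warning.
* Population (not sample) standard deviations everywhere, so statistics
  are exact for the window at hand and consistent across window lengths.

## Scale of the shipped experiments

The benchmark study runs 5 subjects × 60 examples × 5-fold
cross-validation over 20 seeds, and the outlier study 45 training + 10
test examples over 20 seeds; both complete in a few minutes on one CPU
and reproduce the qualitative results stably across seeds (ordering
fraction 0.9–1.0). Larger populations sharpen the same contrasts but do
not change them.

## Known limitations

* The candidate-pool convention fixes median/MAD at pool level; a fully
  subset-dependent objective would be combinatorial and can select
  differently in contrived cases.
* Each test instance is processed alone (one sigma per instance); joint
  selection for a batch of test points is out of scope.
* The dispersion penalty biases predictions toward the local label median
  when rho is large relative to the kappa scale — that is inherent to the
  objective, and the reason the default rho is small.
* `fit_baseline_lr` falls back to the minimum-norm solution under rank
  deficiency, which is conventional but not unique in meaning.
* Real-time streaming, artifact rejection, and device-specific parsing
  beyond the E4-style CSV dialect are not implemented.
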