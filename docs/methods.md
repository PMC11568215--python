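# Methods

## Optimizer model

All four variants share one population loop.  `n_agents` positions are
initialised uniformly in the box, evaluated, and the best becomes the
incumbent.  Each iteration every agent takes exactly one move — spiral
(probability `switch_probability`), otherwise exploration when the
scalar gate `|A| >= 1` fires, otherwise encirclement — after which
positions are clamped to the box and re-evaluated.  An elitist record
keeps the best solution ever evaluated (ties keep the earlier
incumbent), so the per-iteration history is non-increasing by
construction.

Randomness conventions matter for this algorithm family and are fixed
as follows:

- The step coefficient `A` is drawn **once per agent** per iteration.
  `|A|` is the scalar quantity the exploration gate conditions on, and
  a shared scalar step produces whole-vector contractions toward the
  incumbent (occasionally toward the origin), which is the mechanism
  behind the exact zeros the family attains on Rastrigin- and
  Griewank-type landscapes.  Drawing `A` per axis instead destroys
  that deep-convergence behaviour (measured: sphere stalls around
  1e-40 instead of 1e-60..1e-100, and 30-run Rastrigin means move from
  0 to ~3).
- The wobble coefficient `C` is drawn **per axis**.  The axis-wise
  `|C x* - x|` term preserves directional diversity in exploitation;
  with a scalar `C` the population degenerates onto rays and
  occasionally strands in local minima of low-dimensional functions
  (measured on Goldstein-Price).
- The spiral parameter is `l ~ U[-1, 1]` for `woa`/`mwoa2`.  For
  `mwoa1`/`mwoa3` it follows the second schedule,
  `l = (a2 - 1) u + 1`, `u ~ U[0, 1]`, which reaches slightly below
  -1 (by at most `1/(T-1)`); `spiral_update` therefore accepts any
  real `l`.
- The domains of the modified schedule's random arguments
  (`cos r`, `sin r1`, `sin r2`) are `r, r1, r2 ~ U[0, 1]`, consistent
  with the base algorithm's uniform-on-[0,1] coefficient draws.  Note
  the consequence: `a` ends in `[1, 2 - cos 1]` rather than at 0, so
  the modified schedule explores to the last iteration.
- Branch-specific randomness (peer indices; diffusion normals and
  drifts) is drawn lazily, only for the agents taking the branch.  Two
  variants that make the same common draws and never explore produce
  bit-identical trajectories under one seed, which the test suite
  exercises as a degenerate-limit equivalence.

### Diffusion exploration (MWOA-2/3)

Exploring agents are replaced by a short series of Gaussian diffusion
walks around the incumbent: each candidate is
`Normal(best, sd) + lambda*best - lambda_hat*agent` with
`sd = |agent - best|` per axis and `lambda, lambda_hat` fresh uniform
scalars.  `diffusion_walks` (default **2**) candidates are generated
per exploring agent and the best is kept — greedy selection over the
walk series.  The default was set by measurement: with a single walk
the variant traps on 30-dimensional Rastrigin in ~1.5% of runs and on
Goldstein-Price in ~3.7%; the two-walk series eliminates the former
(0 traps in 200 runs) and reduces the latter to ~0.7%, at ~15% extra
objective evaluations.  An optional `sigma_damping` multiplier
`log(g)/g` on the spread (off by default) reproduces the shrinking-
spread convention of the diffusion method's fractal-search origin; it
measurably *increases* trapping on Goldstein-Price and is kept only as
an option recorded in run metadata.

The spiral distance uses the classical `|X* - X|`; a `spiral_distance
="printed"` switch selects the `|C X* - X|` form that circulates in
derivative implementations, for comparison.

### Parameters

| parameter            | default | meaning                                          |
|----------------------|---------|--------------------------------------------------|
| `n_agents`           | 30      | population size                                  |
| `max_iter`           | 500     | iterations (coefficient schedules span them)     |
| `switch_probability` | 0.5     | probability of the spiral move                   |
| `spiral_constant`    | 1.0     | logarithmic-spiral shape `w`                     |
| `diffusion_walks`    | 2       | Gaussian candidates per exploring agent          |
| `seed`               | 0       | seeds every draw in the run                      |

Bound repair clamps to the nearest bound (no reflection or
re-sampling); repairs are counted in the result.  Non-finite objective
values cause the agent to be re-sampled uniformly in bounds, with the
event logged.

## Benchmark suite

The 23 classical functions (unimodal F1-F7, multimodal F8-F13,
fixed-dimension F14-F23) use their de-facto standard dimensions,
boxes and constant tables (sphere on [-100,100]^30 through Shekel-10 on
[0,10]^4).  F7 adds uniform noise on [0,1) drawn from the caller's
generator so whole runs stay reproducible.  The penalized functions
F12/F13 use the classical piecewise penalty `u(x, a, k, m)`.  The
registry stores each function's minimiser and minimum; fixed-dimension
minima were frozen from a one-off numerical polish so that evaluating
the stored position reproduces the stored minimum to 1e-9, which the
suite asserts for every closed-form function.

## Wrapper feature selection

Subsets are bitmask codes in `[0, 2^d - 1]`, least-significant bit =
feature 0.  The optimizer searches the 1-D continuous interval and
candidates are rounded half-away-from-zero and clamped.  Fitness is
the mean over `N` repeats of the classifier's mean per-class error on
a fresh stratified 70/15/15 train/validation/test split per repeat
(the validation share is held out of training; a 70/10/5 split with
the remainder unused is available through the split fractions).  The
repeat seed is a hash of (base seed, mask code, repeat), so a mask
scores identically wherever it is encountered — this makes results
cacheable, restarts comparable, and the exhaustive-search oracle an
exact lower bound for the wrapper on the same seeds.  Code 0 (empty
subset) cannot train a classifier and is assigned the worst fitness
1.0 rather than an error, keeping search dynamics defined on the whole
range.  Ties between masks prefer fewer selected features, then the
lower code.  The "repetitions" knob restarts the optimizer with seeds
`base + r`; fitness repeats and restarts are independent controls.

## Neural network

One hidden layer of 10 tanh neurons by default (the conventional
reading of a "3-layer" network: input, hidden, output), thresholds
subtracted before activation, outputs one per class, argmax readout
with ties toward the lower class.  Targets are one-hot vectors scaled
to 0.9/-0.9 (tanh) or 0.9/0.1 (sigmoid) to avoid saturation.  Initial
parameters are uniform in [-0.5, 0.5] from the seeded stream.  Training
minimises `W = 1/(2Z) sum (y - d)^2` to a 0.01 target.  Two rules are
implemented: full-batch gradient descent, and damped Levenberg-
Marquardt with multiplicative damping adaptation (steps are accepted
only when they reduce `W`, so accepted epochs are monotone); `auto`
selects LM up to 5,000 parameters, where forming the residual Jacobian
is cheap, and gradient descent beyond.  The analytic gradient is
verified against central finite differences at 1e-5 relative
tolerance.  The step activation is inference-only.

## Preprocessing

- Missing cells in a time-ordered column take the mean of the nearest
  observed neighbours above and below; runs of consecutive misses
  resolve to linear interpolation between the flanking observations
  (the natural closure of the one-step rule), and edge misses copy the
  single nearest observed value.
- Digit normalisation strips the leading digit of the integer part and
  rescales by its place value: `DN = (|x| - 10^(w-1) e) / 10^(w-1)`,
  giving values in [0, 1).  For `|x| < 1` the map is the identity on
  the magnitude.  The sign is discarded — a deliberately lossy rule,
  flagged loudly here; classical min-max scaling is available as the
  alternative, and is the better choice whenever signs carry
  information.  Normalisation is applied per cell on all numeric
  columns by default.
- Borderline-SMOTE synthesises minority rows only from "danger"
  points (k-neighbourhood majority-dominated but not fully majority);
  if a class has no danger points its non-noise points seed instead so
  equalisation is always achievable.  ADASYN apportions the class
  deficit across minority points proportionally to their neighbourhood
  majority share, with largest-remainder rounding so budgets sum
  exactly.  Both use k = 5 neighbours, equalise to the majority count,
  treat multiclass one-vs-rest, never modify original rows, and
  interpolate convexly between same-class points.

## Evaluation

Mean per-class error is the mean over classes of `1 - recall_k`
(equivalently `1 - macro recall`); classes with no true samples are
excluded (or rejected in strict mode).  Multiclass precision and
recall are reported as macro averages over one-vs-rest collapses; a
never-predicted class contributes precision 0, flagged.  The sample
standard deviation uses the `n - 1` denominator.

## Synthetic cohorts

The generator emulates the *shape* of tabular ICU blood-pressure
cohorts: three profiles (hypertensive / hypotensive / normotensive),
11 numeric features with vital-sign-like names, four ordinal severity
classes with default proportions 0.70/0.15/0.10/0.05 (imbalanced
enough that the oversamplers matter), an AR(1) wobble down the row
order (default coefficient 0.3, one baseline standard deviation of
amplitude) standing in for the serial correlation of monitored vitals,
and uniformly random missing cells.  Class means shift monotonically
with severity so "emergency" is most extreme and the signal is
learnable.  Feature semantics are cosmetic; no physiological waveform
simulation is attempted, there are no patient identities, no
within-patient episodes, and missingness is completely at random
rather than clinically structured.  Passing tests on these cohorts
therefore demonstrates mechanical correctness of the pipeline and the
relative behaviour of its components, not clinical performance; the
default desk scale is 2,000 rows with a 35,233-row mode for scale
tests.  The planted-subset generator labels rows by quartile-binning a
linear score over a chosen feature subset, providing exact ground
truth for selection tests.

## Known limitations

- On Shekel's Foxholes (F14) the around-best diffusion cannot
  guarantee landing in the ~3-unit-wide global well within the
  exploration budget of a 30-agent, 500-iteration run: measured
  30-run means fall between roughly 2.5 and 5 depending on the seed
  set, with individual runs either at 0.998 (the global minimum) or at
  a neighbouring foxhole.  Peer-based exploration (the `woa`/`mwoa1`
  branch) shows the same behaviour.  Landscape-hopping of this kind is
  outside what an around-incumbent Gaussian walk can deliver.
- Goldstein-Price retains a ~0.7% per-run trap probability under the
  default two-walk series, so about one 30-run mean in five is pulled
  off the global minimum by a single trapped run.
- The digit normalisation is not monotone across leading-digit
  boundaries (199 maps to 0.99, 200 to 0.0) and discards signs; it is
  kept as the default for fidelity to the pipeline it implements, with
  min-max as the recommended alternative for new data.
- Levenberg-Marquardt forms a dense `(Z*G) x P` Jacobian and is only
  selected for small networks; large-network training falls back to
  plain gradient descent, which may need many more epochs than the
  default cap.
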