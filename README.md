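# mwoa — Modified Whale Optimization Algorithm toolkit

`mwoa` implements a family of whale-optimization metaheuristics and the
classification pipeline they were designed to drive: wrapper feature
selection and feed-forward neural-network classification of four-level
ordinal severity (normal / warning / alert / emergency) in tabular
blood-pressure cohorts.  It is aimed at researchers who want a
reproducible, library-first implementation of the optimizer variants,
a standard benchmark harness to compare them on, and an end-to-end
pipeline that runs on synthetic cohorts without access to restricted
clinical data.

## The optimizers

The baseline Whale Optimization Algorithm (WOA) moves a population of
search agents $X_i$ around the incumbent best $X^*$.  Per agent and
iteration, with $a$ decaying linearly from 2 to 0, coefficients
$A = 2a r_1 - a$ (one draw per agent) and $C = 2 r_2$ (per axis),
$r_1, r_2 \sim U[0,1]$, each agent takes one of three moves:

- **encircle** (exploitation): $X \leftarrow X^* - A\,|C X^* - X|$
- **spiral** (with probability $h = 0.5$):
  $X \leftarrow |X^* - X|\, e^{w\ell} \cos(2\pi \ell) + X^*$,
  $\ell \sim U[-1, 1]$, spiral constant $w = 1$
- **explore** (when $|A| \ge 1$): the encircling move aimed at a random
  peer $X_{rand}$ instead of $X^*$

The three modified variants are:

- **MWOA-1** — cosine/sine-modulated coefficients:
  $a = 2 - \cos(r)\,\frac{j-1}{T-1}$ (never reaches 0, so exploration
  persists), $A = 2a\sin(r_1) - a$, $C = 2\sin(r_2)$, and the spiral
  parameter follows a second schedule
  $a_2 = -1 - \cos(r)\,\frac{j-1}{(T-1)^2}$ via $\ell = (a_2-1)u + 1$.
- **MWOA-2** — the exploration move is replaced by a Gaussian
  diffusion random walk around the best (borrowed from stochastic
  fractal search): a short series of candidates
  $\mathcal N(X^*, |X_i - X^*|) + \lambda X^* - \hat\lambda X_i$
  with $\lambda,\hat\lambda \sim U[0,1]$, keeping the best of the
  series.
- **MWOA-3** — both modifications combined.

All variants share elitism (the returned best-so-far history is
non-increasing), clamp-to-bounds repair, and full seeded determinism.

## The pipeline

`preprocessing` fills missing cells with the mean of the nearest
observed neighbours above/below (vitals are time-ordered), scales
values by the digit rule $DN = (|\beta| - 10^{w-1}\varepsilon)/10^{w-1}$
(leading digit $\varepsilon$, digit count $w$), encodes severity labels
1–4, and equalises class counts with Borderline-SMOTE or ADASYN.
`feature_selection` encodes feature subsets as integers in
$[0, 2^d-1]$ (2047 for the 11-feature cohorts) and minimises the
wrapper fitness $\frac1N \sum_{k=1}^N \mathrm{MCE}(k)$ — the mean over
$N$ seeded resampling repeats of the classifier's mean per-class error.
`ffnn` is a small network $z_m = \tanh(\sum_n q_{mn} x_n - c_{m0})$
trained by Levenberg–Marquardt to the sum-squared-error target
$W = \frac{1}{2Z}\sum_z\sum_g (y^z_g - d^z_g)^2 \le 0.01$.
`synthetic` generates the three patient profiles the pipeline targets.

## Worked example

```bash
python examples/benchmark_table.py
```

```
function variant          avg          std  completed  requested
      F1     woa 7.565416e-24 1.647429e-23          5          5
      F1   mwoa2 4.023617e-65 6.005727e-65          5          5
      F9     woa 9.994628e+01 7.756709e+01          5          5
      F9   mwoa2 0.000000e+00 0.000000e+00          5          5
     F18     woa 3.000024e+00 3.178760e-05          5          5
     F18   mwoa2 3.000034e+00 5.979809e-05          5          5
```

Each row is one benchmark cell: the mean and sample standard deviation
of the final best objective value over 5 seeded runs (30 agents, 500
iterations).  The sphere means (F1) measure exploitation depth — the
diffusion variant converges some 40 orders of magnitude deeper; the
Rastrigin row (F9) shows MWOA-2 reaching the global minimum 0 exactly
in every run where the baseline strands in local optima; on
Goldstein–Price (F18) both sit at the global minimum 3.

`examples/cohort_pipeline.py` runs the full preprocessing + network
pipeline on a synthetic hypertensive cohort (held-out mean per-class
error 0.130, accuracy 0.870), and `examples/wrapper_selection.py` shows
the wrapper search recovering a planted informative feature subset,
matching the brute-force oracle over all 255 masks.

The same functionality is exposed as a thin CLI:

```bash
mwoa benchmark list
mwoa benchmark run --functions F9,F16 --variants woa,mwoa2 --runs 5 --seed 1
mwoa synth --profile hypertensive --n 2000 --missing 0.05 --out cohort.csv
mwoa select-features --data cohort.csv --variant mwoa2 --seed 42
```

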