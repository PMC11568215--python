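"""Wrapper feature selection driven by the whale optimizers.

Feature subsets are encoded as integers in [0, 2^d - 1] (bit i selects
feature i, least-significant-bit first; with the 11-feature cohorts the
search space tops out at 2047).  The optimizer searches the 1-D
continuous interval [0, 2^d - 1]; candidate positions are rounded to
the nearest code and scored by the wrapper fitness: the mean, over N
seeded resampling repeats, of the classifier's mean per-class error on
a held-out test split.  Lower is better; the empty subset is assigned
the worst fitness 1.0 so search dynamics stay defined over the whole
integer range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from . import metrics
from .optimizers import OptimizerConfig, SearchSpace, optimize
from .preprocessing import TabularDataset

__all__ = [
    "FeatureMask",
    "FitnessReport",
    "SelectionResult",
    "decode_mask",
    "continuous_to_code",
    "fitness",
    "select_features",
    "exhaustive_search",
    "OneNearestNeighborClassifier",
]


@dataclass(frozen=True)
class FeatureMask:
    code: int
    include: tuple

    @property
    def n_selected(self) -> int:
        return sum(self.include)

    @property
    def indices(self) -> tuple:
        return tuple(i for i, b in enumerate(self.include) if b)

    @property
    def is_empty(self) -> bool:
        return self.code == 0


@dataclass
class FitnessReport:
    mask: FeatureMask
    repeat_errors: np.ndarray
    N: int
    flagged_empty: bool = False

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.repeat_errors))


@dataclass
class SelectionResult:
    best_mask: FeatureMask
    best_fitness: float
    convergence: np.ndarray  # per-iteration best fitness of the best restart
    repetitions: int
    seed: int
    restart_best: list = field(default_factory=list)  # (code, fitness) per restart

    @property
    def n_features_chosen(self) -> int:
        return self.best_mask.n_selected


def decode_mask(code: int, d: int) -> FeatureMask:
    """Binary-expand ``code`` into a d-length inclusion vector."""
    code = int(code)
    if not 0 <= code <= 2**d - 1:
        raise ValueError(f"mask code {code} outside [0, {2**d - 1}] for d={d}")
    return FeatureMask(code=code, include=tuple(bool(code >> i & 1) for i in range(d)))


def continuous_to_code(x: float, d: int) -> int:
    """Round half away from zero, clamped into [0, 2^d - 1]."""
    rounded = int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
    return int(np.clip(rounded, 0, 2**d - 1))


class OneNearestNeighborClassifier(KNeighborsClassifier):
    """Deterministic 1-NN surrogate; keeps exhaustive oracle runs fast."""

    def __init__(self):
        super().__init__(n_neighbors=1)


def _default_classifier():
    from .ffnn import FFNNClassifier, FFNNConfig

    return FFNNClassifier(FFNNConfig(max_epochs=30))


def fitness(
    mask: FeatureMask,
    dataset: TabularDataset,
    classifier_factory=None,
    N: int = 10,
    seed: int = 0,
    test_fraction: float = 0.15,
    validation_fraction: float = 0.15,
) -> FitnessReport:
    """Mean per-class error of the classifier on the masked columns.

    Each of the N repeats draws a fresh stratified train/validation/test
    split (default 70/15/15; the validation share is simply held out of
    training) and scores mean per-class error on the test part.  The
    empty mask short-circuits to the worst fitness 1.0.
    """
    if mask.is_empty:
        return FitnessReport(
            mask=mask, repeat_errors=np.ones(N), N=N, flagged_empty=True
        )
    if np.any(dataset.missing_mask):
        raise ValueError("fitness requires an imputed dataset")
    X = dataset.features[:, list(mask.indices)]
    y = dataset.labels
    K = int(y.max())
    errors = np.empty(N)
    for rep in range(N):
        rep_seed = int(np.random.SeedSequence((seed, mask.code, rep)).generate_state(1)[0] % (2**31))
        X_rest, X_test, y_rest, y_test = train_test_split(
            X, y, test_size=test_fraction, stratify=y, random_state=rep_seed
        )
        if validation_fraction > 0:
            val_share = validation_fraction / (1.0 - test_fraction)
            X_train, _, y_train, _ = train_test_split(
                X_rest, y_rest, test_size=val_share, stratify=y_rest,
                random_state=rep_seed + 1,
            )
        else:
            X_train, y_train = X_rest, y_rest
        clf = classifier_factory() if classifier_factory else _default_classifier()
        if hasattr(clf, "config"):
            clf.config.seed = rep_seed
        clf.fit(X_train, y_train)
        cm = metrics.confusion(y_test, clf.predict(X_test), K)
        errors[rep] = metrics.mean_per_class_error(cm)
    return FitnessReport(mask=mask, repeat_errors=errors, N=N)


def _better(candidate: tuple, incumbent: tuple) -> bool:
    """Tie-break masks: lower fitness, then fewer features, then lower code."""
    c_fit, c_mask = candidate
    i_fit, i_mask = incumbent
    if c_fit != i_fit:
        return c_fit < i_fit
    if c_mask.n_selected != i_mask.n_selected:
        return c_mask.n_selected < i_mask.n_selected
    return c_mask.code < i_mask.code


def select_features(
    dataset: TabularDataset,
    optimizer_config: OptimizerConfig | None = None,
    classifier_factory=None,
    N: int = 10,
    repetitions: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Run the wrapper search over the integer-coded subset space.

    ``repetitions`` independent optimizer restarts (restart r seeded
    ``seed + r``) each minimise the cached wrapper fitness over
    [0, 2^d - 1]; the best mask across restarts is returned, ties
    preferring fewer selected features then the lower code.  Fitness
    seeds depend only on (seed, code), so a mask scores identically
    in every restart and results are reproducible.
    """
    d = dataset.n_features
    if d > 24:
        raise ValueError("subset space 2^d is intractable beyond d = 24")
    base = optimizer_config or OptimizerConfig(n_agents=10, max_iter=30)
    cache: dict[int, FitnessReport] = {}

    def scored(code: int) -> FitnessReport:
        if code not in cache:
            cache[code] = fitness(
                decode_mask(code, d), dataset, classifier_factory, N=N, seed=seed
            )
        return cache[code]

    def objective(pop: np.ndarray) -> np.ndarray:
        return np.array(
            [scored(continuous_to_code(float(x[0]), d)).mean_error for x in pop]
        )

    space = SearchSpace(np.array([0.0]), np.array([float(2**d - 1)]))
    best: tuple | None = None
    best_convergence = None
    restart_best = []
    for r in range(repetitions):
        cfg = OptimizerConfig(
            **{**base.__dict__, "seed": seed + r}
        )
        result = optimize(objective, space, cfg)
        code = continuous_to_code(float(result.best_position[0]), d)
        report = scored(code)
        restart_best.append((code, report.mean_error))
        candidate = (report.mean_error, report.mask)
        if best is None or _better(candidate, best):
            best = candidate
            best_convergence = result.history
    # prefer any cached mask that ties the optimum with fewer features
    for code, report in cache.items():
        candidate = (report.mean_error, report.mask)
        if _better(candidate, best):
            best = candidate
    return SelectionResult(
        best_mask=best[1],
        best_fitness=best[0],
        convergence=best_convergence,
        repetitions=repetitions,
        seed=seed,
        restart_best=restart_best,
    )


def exhaustive_search(
    dataset: TabularDataset,
    classifier_factory=None,
    N: int = 10,
    seed: int = 0,
) -> tuple[FeatureMask, float]:
    """Brute-force oracle over every non-empty mask (d <= 12 or so).

    Uses the same fitness seeds as :func:`select_features`, so the
    wrapper's reported fitness can never beat this optimum.
    """
    d = dataset.n_features
    best: tuple | None = None
    for code in range(1, 2**d):
        report = fitness(decode_mask(code, d), dataset, classifier_factory, N=N, seed=seed)
        candidate = (report.mean_error, report.mask)
        if best is None or _better(candidate, best):
            best = candidate
    return best[1], best[0]
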