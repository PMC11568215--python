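"""Synthetic blood-pressure cohort generator.

Emulates the shape of the tabular ICU cohorts the pipeline targets —
three patient profiles (hypertensive / hypotensive / normotensive), 11
vital-sign-like numeric features with temporal adjacency, four
imbalanced ordinal severity classes (normal < warning < alert <
emergency) and injectable missingness — so every pipeline stage is
testable without any clinical download.

Feature names are cosmetic placeholders; no physiological simulator is
attempted.  Rows are drawn class-by-class from Gaussian models whose
means shift monotonically with severity (emergency most extreme), then
an AR(1) wobble is laid down the row order to mimic the serial
correlation of monitored vitals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .preprocessing import TabularDataset

__all__ = ["CohortProfile", "generate", "planted_subset_dataset", "FEATURE_NAMES"]

FEATURE_NAMES = [
    "systolic_bp",
    "diastolic_bp",
    "mean_arterial_pressure",
    "heart_rate",
    "respiratory_rate",
    "spo2",
    "temperature",
    "pulse_pressure",
    "bp_variability",
    "hr_variability",
    "perfusion_index",
]

# Baseline feature means per profile; severity shifts each class's mean
# along a fixed direction so "emergency" is the most extreme.
_PROFILE_BASE = {
    "hypertensive": np.array([150.0, 95.0, 113.0, 82.0, 17.0, 96.0, 36.9, 55.0, 8.0, 4.0, 1.3]),
    "hypotensive": np.array([95.0, 58.0, 70.0, 88.0, 19.0, 94.0, 36.5, 37.0, 7.0, 5.0, 0.9]),
    "normotensive": np.array([118.0, 76.0, 90.0, 74.0, 15.0, 98.0, 36.8, 42.0, 5.0, 6.0, 1.1]),
}
_SEVERITY_SHIFT = np.array([12.0, 7.0, 9.0, 9.0, 2.5, -1.5, 0.25, 6.0, 2.5, -1.0, -0.12])
_BASE_SD = np.array([9.0, 6.0, 7.0, 8.0, 2.5, 1.8, 0.45, 6.0, 2.2, 1.6, 0.22])


@dataclass
class CohortProfile:
    """Generator settings for one synthetic patient cohort.

    ``class_proportions`` defaults to a 70/15/10/5 split so the class
    imbalance the oversamplers exist for is actually present;
    ``temporal_autocorrelation`` is the AR(1) coefficient of the wobble
    shared by consecutive rows.
    """

    name: str = "normotensive"
    n_samples: int = 2000
    class_proportions: tuple = (0.70, 0.15, 0.10, 0.05)
    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None
    temporal_autocorrelation: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in _PROFILE_BASE:
            raise ValueError(
                f"unknown profile {self.name!r}; expected one of {sorted(_PROFILE_BASE)}"
            )
        props = np.asarray(self.class_proportions, dtype=float)
        if props.size != 4 or abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
            raise ValueError("class_proportions must be 4 non-negatives summing to 1")
        if not 0.0 <= self.temporal_autocorrelation < 1.0:
            raise ValueError("temporal_autocorrelation must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.feature_means is None:
            base = _PROFILE_BASE[self.name]
            self.feature_means = np.stack(
                [base + k * _SEVERITY_SHIFT for k in range(4)]
            )
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        if self.feature_sds is None:
            self.feature_sds = np.tile(_BASE_SD, (4, 1))
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        if self.feature_means.shape != (4, 11) or self.feature_sds.shape != (4, 11):
            raise ValueError("feature_means/feature_sds must have shape (4, 11)")


def generate(profile: CohortProfile) -> TabularDataset:
    """Draw one synthetic cohort as a :class:`TabularDataset`.

    Labels are iid categorical with the profile's class proportions; a
    class with positive proportion but zero expected count under
    ``n_samples`` is rejected as degenerate.
    """
    rng = np.random.default_rng(profile.seed)
    n = profile.n_samples
    props = np.asarray(profile.class_proportions, dtype=float)
    if np.any((props > 0) & (props * n < 1.0)) and n >= 100:
        raise ValueError("a class with positive proportion has expected count < 1")
    labels = rng.choice(4, size=n, p=props) + 1
    X = (
        profile.feature_means[labels - 1]
        + profile.feature_sds[labels - 1] * rng.standard_normal((n, 11))
    )
    rho = profile.temporal_autocorrelation
    if rho > 0.0:
        # AR(1) wobble down the row order (stationary, unit variance),
        # one baseline sd per feature: monitored vitals drift slowly, so
        # consecutive rows share a sizeable correlated component
        innovations = rng.standard_normal((n, 11))
        wobble = np.empty_like(innovations)
        wobble[0] = innovations[0]
        scale = np.sqrt(1.0 - rho**2)
        for t in range(1, n):
            wobble[t] = rho * wobble[t - 1] + scale * innovations[t]
        X = X + _BASE_SD * wobble
    mask = np.zeros_like(X, dtype=bool)
    if profile.missing_rate > 0.0:
        mask = rng.uniform(size=X.shape) < profile.missing_rate
        X = X.copy()
        X[mask] = np.nan
    return TabularDataset(
        features=X,
        labels=labels,
        missing_mask=mask,
        feature_names=list(FEATURE_NAMES),
        profile=profile.name,
    )


def planted_subset_dataset(
    d: int,
    informative: set | frozenset | list,
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TabularDataset, np.ndarray]:
    """Ground-truth dataset for feature-selection tests.

    Labels are a deterministic function (plus optional Gaussian label
    noise of scale ``noise_sd``) of the sum over the ``informative``
    columns, binned at its quartiles into 4 ordinal classes; every other
    column is pure standard-normal noise.  Returns the dataset together
    with the boolean ground-truth inclusion mask.
    """
    informative = sorted(set(informative))
    if not informative:
        raise ValueError("informative set must be non-empty")
    if min(informative) < 0 or max(informative) >= d:
        raise ValueError("informative indices must lie in [0, d)")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    score = X[:, informative].sum(axis=1)
    if noise_sd > 0.0:
        score = score + noise_sd * rng.standard_normal(n)
    edges = np.quantile(score, [0.25, 0.5, 0.75])
    labels = np.digitize(score, edges) + 1
    truth = np.zeros(d, dtype=bool)
    truth[informative] = True
    dataset = TabularDataset(
        features=X,
        labels=labels,
        feature_names=[f"f{i}" for i in range(d)],
        profile="other",
    )
    return dataset, truth


def truth_mask_json(truth: np.ndarray) -> str:
    """Serialise a ground-truth mask next to an exported cohort CSV."""
    code = int(sum(1 << i for i, b in enumerate(truth) if b))
    return json.dumps({"include": truth.astype(bool).tolist(), "code": code}, indent=2)
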