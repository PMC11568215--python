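"""Robust preprocessing for the blood-pressure cohort pipeline.

Four stages: neighbour-average imputation for missing cells in
time-ordered columns, digit-based normalisation onto [0, 1), ordinal
label encoding (normal/warning/alert/emergency -> 1..4), and minority
oversampling with Borderline-SMOTE or ADASYN to equalise the four
severity classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "TabularDataset",
    "RebalanceReport",
    "impute_missing",
    "normalize_digit",
    "normalize_minmax",
    "encode_labels",
    "borderline_smote",
    "adasyn",
    "LABEL_CODES",
]

LABEL_CODES = {"normal": 1, "warning": 2, "alert": 3, "emergency": 4}


@dataclass
class TabularDataset:
    """A cohort table: features, a missing-cell mask, and ordinal labels.

    ``labels`` take values in {1..4} after encoding; ``profile`` tags
    which patient cohort the rows emulate.
    """

    features: np.ndarray
    labels: np.ndarray
    missing_mask: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)
    profile: str = "other"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("labels and features disagree on sample count")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.features)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.features.shape:
                raise ValueError("missing_mask shape must match features")
        if not self.feature_names:
            self.feature_names = [f"x{i}" for i in range(self.features.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    # ------------------------------------------------------------- I/O
    def to_dataframe(self) -> pd.DataFrame:
        X = self.features.copy()
        X[self.missing_mask] = np.nan
        df = pd.DataFrame(X, columns=self.feature_names)
        df["class"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        label_column: str = "class",
        drop_columns: Sequence[str] = ("id",),
        profile: str = "other",
    ) -> "TabularDataset":
        df = pd.read_csv(path, na_values=["", "NA"])
        df = df.drop(columns=[c for c in drop_columns if c in df.columns])
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        raw = df[label_column]
        if raw.dtype == object:
            labels = encode_labels(raw.tolist())
        else:
            labels = raw.to_numpy(dtype=int)
        X = df.drop(columns=[label_column]).to_numpy(dtype=float)
        return cls(
            features=X,
            labels=labels,
            feature_names=[c for c in df.columns if c != label_column],
            profile=profile,
        )


@dataclass
class RebalanceReport:
    method: str
    counts_before: dict[int, int]
    counts_after: dict[int, int]
    k_neighbors: int
    n_synthetic: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "counts_before": {str(k): v for k, v in sorted(self.counts_before.items())},
                "counts_after": {str(k): v for k, v in sorted(self.counts_after.items())},
                "k_neighbors": self.k_neighbors,
                "n_synthetic": self.n_synthetic,
                "seed": self.seed,
            },
            indent=2,
        )


# --------------------------------------------------------------- cleaning

def impute_missing(column) -> np.ndarray:
    """Fill missing cells with the mean of the nearest observed
    neighbours above and below (time-ordered rows).

    Runs of consecutive misses resolve to linear interpolation between
    the flanking observed values; misses at either end copy the single
    nearest observed value.  NaN marks a missing cell.
    """
    s = pd.Series(np.asarray(column, dtype=float))
    if s.isna().all():
        raise ValueError("column is entirely missing; nothing to impute from")
    return s.interpolate(method="linear", limit_direction="both").to_numpy()


def impute_dataset(dataset: TabularDataset) -> TabularDataset:
    """Column-wise :func:`impute_missing` over a whole dataset."""
    X = dataset.features.copy()
    X[dataset.missing_mask] = np.nan
    filled = np.column_stack([impute_missing(X[:, j]) for j in range(X.shape[1])])
    return replace(
        dataset, features=filled, missing_mask=np.zeros_like(filled, dtype=bool)
    )


def normalize_digit(value: float) -> float:
    """Digit-based scaling onto [0, 1).

    With ``w`` the digit count of the integer part of ``|value|`` and
    ``eps`` its leading digit, returns ``(|value| - 10^(w-1)*eps) /
    10^(w-1)``: the leading digit is stripped and the remainder scaled
    by its place value (345 -> 0.45).  For ``|value| < 1`` the map is
    the identity on the magnitude.  The sign is discarded — a lossy
    choice inherited from the formula's absolute values.
    """
    v = float(value)
    if not np.isfinite(v):
        raise ValueError("normalize_digit requires a finite value")
    v = abs(v)
    if v < 1.0:
        return v
    w = len(str(int(v)))
    eps = int(str(int(v))[0])
    scale = 10.0 ** (w - 1)
    return (v - scale * eps) / scale


def normalize_minmax(values) -> np.ndarray:
    """Classical (x - min) / (max - min) scaling, for comparison."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def normalize_dataset(dataset: TabularDataset, method: str = "digit") -> TabularDataset:
    """Apply per-cell digit normalisation (default) or per-column min-max."""
    if method == "digit":
        X = np.vectorize(normalize_digit)(dataset.features).astype(float)
    elif method == "minmax":
        X = np.column_stack(
            [normalize_minmax(dataset.features[:, j]) for j in range(dataset.n_features)]
        )
    else:
        raise ValueError("method must be 'digit' or 'minmax'")
    return replace(dataset, features=X)


def encode_labels(raw_labels: Sequence[str]) -> np.ndarray:
    """normal/warning/alert/emergency -> 1/2/3/4 (case-insensitive)."""
    out = np.empty(len(raw_labels), dtype=int)
    for i, lab in enumerate(raw_labels):
        key = str(lab).strip().lower()
        if key not in LABEL_CODES:
            raise ValueError(f"unknown class label {lab!r} at row {i}")
        out[i] = LABEL_CODES[key]
    return out


# ------------------------------------------------------------ oversampling

def _check_oversampling_inputs(dataset: TabularDataset, k_neighbors: int) -> None:
    if np.any(dataset.missing_mask):
        raise ValueError("oversampling requires an imputed dataset (no missing cells)")
    counts = dataset.class_counts()
    if len(counts) < 2:
        raise ValueError("oversampling requires at least two classes")
    majority = max(counts.values())
    for cls, cnt in counts.items():
        if cnt < majority and cnt <= k_neighbors:
            raise ValueError(
                f"minority class {cls} has only {cnt} members; "
                f"use k_neighbors < {cnt}"
            )


def _append_synthetic(
    dataset: TabularDataset, rows: list[np.ndarray], labels: list[int], method: str,
    k_neighbors: int, seed: int,
) -> tuple[TabularDataset, RebalanceReport]:
    before = dataset.class_counts()
    if rows:
        X = np.vstack([dataset.features, np.vstack(rows)])
        y = np.concatenate([dataset.labels, np.asarray(labels, dtype=int)])
    else:
        X, y = dataset.features.copy(), dataset.labels.copy()
    out = replace(
        dataset,
        features=X,
        labels=y,
        missing_mask=np.zeros_like(X, dtype=bool),
    )
    report = RebalanceReport(
        method=method,
        counts_before=before,
        counts_after=out.class_counts(),
        k_neighbors=k_neighbors,
        n_synthetic=len(rows),
        seed=seed,
    )
    return out, report


def _interpolate(rng, seed_row: np.ndarray, neighbor_row: np.ndarray) -> np.ndarray:
    return seed_row + rng.uniform(0.0, 1.0) * (neighbor_row - seed_row)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    if total == 0 or weights.sum() == 0:
        return np.zeros_like(weights, dtype=int)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    remainder = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:remainder]] += 1
    return base


def borderline_smote(
    dataset: TabularDataset, k_neighbors: int = 5, seed: int = 0
) -> tuple[TabularDataset, RebalanceReport]:
    """Borderline-SMOTE oversampling toward equal class counts.

    Minority points are graded by the majority share among their
    ``k_neighbors`` nearest neighbours in the full data: fully
    majority-surrounded points are noise (skipped), majority-dominated
    ones are the "danger" borderline seeds, and only those seeds spawn
    synthetic rows by convex interpolation toward random minority
    neighbours.  If a class has no danger points, all its non-noise
    points serve as seeds so the class can still be equalised.
    """
    _check_oversampling_inputs(dataset, k_neighbors)
    rng = np.random.default_rng(seed)
    counts = dataset.class_counts()
    majority_count = max(counts.values())
    X, y = dataset.features, dataset.labels
    nn_all = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    rows: list[np.ndarray] = []
    labels: list[int] = []
    for cls in sorted(counts):
        deficit = majority_count - counts[cls]
        if deficit == 0:
            continue
        members = np.flatnonzero(y == cls)
        neigh = nn_all.kneighbors(X[members], return_distance=False)[:, 1:]
        majority_share = (y[neigh] != cls).sum(axis=1)
        danger = members[(majority_share >= k_neighbors / 2) & (majority_share < k_neighbors)]
        if danger.size == 0:
            danger = members[majority_share < k_neighbors]
        if danger.size == 0:  # every minority point is noise
            danger = members
        nn_min = NearestNeighbors(n_neighbors=min(k_neighbors + 1, members.size)).fit(
            X[members]
        )
        min_neigh = nn_min.kneighbors(X[danger], return_distance=False)[:, 1:]
        for _ in range(deficit):
            j = rng.integers(danger.size)
            seed_idx = danger[j]
            partner = members[min_neigh[j][rng.integers(min_neigh.shape[1])]]
            rows.append(_interpolate(rng, X[seed_idx], X[partner]))
            labels.append(cls)
    return _append_synthetic(dataset, rows, labels, "bsmote", k_neighbors, seed)


def adasyn(
    dataset: TabularDataset, k_neighbors: int = 5, seed: int = 0
) -> tuple[TabularDataset, RebalanceReport]:
    """ADASYN oversampling toward equal class counts.

    Each minority point receives a synthesis budget proportional to the
    majority share of its ``k_neighbors`` neighbourhood (the adaptive
    density distribution), apportioned by largest remainder so budgets
    sum exactly to the class deficit; synthetic rows interpolate toward
    random same-class neighbours.  Points with no majority neighbours
    get budget zero (unless no point has any, in which case budgets are
    uniform).
    """
    _check_oversampling_inputs(dataset, k_neighbors)
    rng = np.random.default_rng(seed)
    counts = dataset.class_counts()
    majority_count = max(counts.values())
    X, y = dataset.features, dataset.labels
    nn_all = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    rows: list[np.ndarray] = []
    labels: list[int] = []
    for cls in sorted(counts):
        deficit = majority_count - counts[cls]
        if deficit == 0:
            continue
        members = np.flatnonzero(y == cls)
        neigh = nn_all.kneighbors(X[members], return_distance=False)[:, 1:]
        r = (y[neigh] != cls).sum(axis=1) / k_neighbors
        if r.sum() == 0:
            r = np.ones_like(r)
        budgets = _largest_remainder(r, deficit)
        nn_min = NearestNeighbors(n_neighbors=min(k_neighbors + 1, members.size)).fit(
            X[members]
        )
        min_neigh = nn_min.kneighbors(X[members], return_distance=False)[:, 1:]
        for j, budget in enumerate(budgets):
            for _ in range(budget):
                partner = members[min_neigh[j][rng.integers(min_neigh.shape[1])]]
                rows.append(_interpolate(rng, X[members[j]], X[partner]))
                labels.append(cls)
    return _append_synthetic(dataset, rows, labels, "adasyn", k_neighbors, seed)
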