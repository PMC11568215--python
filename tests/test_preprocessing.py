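"""Imputation, digit normalisation, label encoding, and oversampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwoa.preprocessing import (
    TabularDataset,
    adasyn,
    borderline_smote,
    encode_labels,
    impute_dataset,
    impute_missing,
    normalize_digit,
    normalize_minmax,
)

NA = np.nan


class TestImpute:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([10, NA, 20], [10, 15, 20]),
            ([NA, 7, 9], [7, 7, 9]),
            ([1, NA, NA, 7], [1, 3, 5, 7]),
            ([4, 8, NA], [4, 8, 8]),
        ],
    )
    def test_neighbour_average_examples(self, column, expected):
        np.testing.assert_allclose(impute_missing(column), expected)

    def test_matches_brute_force_interpolation_oracle(self, rng):
        # oracle: for each miss, walk out to the nearest observed values
        # on both sides and place the miss on the line between them
        values = rng.normal(size=60)
        mask = rng.uniform(size=60) < 0.3
        mask[[0, -1]] = False
        col = values.copy()
        col[mask] = np.nan

        def oracle(c):
            out = c.copy()
            obs = np.flatnonzero(~np.isnan(c))
            for i in np.flatnonzero(np.isnan(c)):
                left = obs[obs < i]
                right = obs[obs > i]
                if left.size and right.size:
                    lo, hi = left[-1], right[0]
                    out[i] = c[lo] + (c[hi] - c[lo]) * (i - lo) / (hi - lo)
                else:
                    out[i] = c[left[-1]] if left.size else c[right[0]]
            return out

        np.testing.assert_allclose(impute_missing(col), oracle(col))

    def test_idempotent_and_exact_on_arithmetic_progression(self):
        col = np.arange(10, dtype=float)
        col[4] = np.nan
        filled = impute_missing(col)
        assert filled[4] == 4.0
        np.testing.assert_array_equal(impute_missing(filled), filled)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing([NA, NA])

    def test_dataset_impute_clears_mask(self, small_cohort):
        out = impute_dataset(small_cohort)
        assert not out.missing_mask.any()
        assert np.isfinite(out.features).all()
        # observed cells are untouched
        obs = ~small_cohort.missing_mask
        np.testing.assert_array_equal(out.features[obs], small_cohort.features[obs])


class TestNormalizeDigit:
    @pytest.mark.parametrize(
        "value, expected",
        [(345, 0.45), (100, 0.0), (9, 0.0), (0.37, 0.37), (-345, 0.45), (1234.5, 0.2345)],
    )
    def test_examples(self, value, expected):
        assert normalize_digit(value) == pytest.approx(expected)

    @given(st.floats(min_value=-1e9, max_value=1e9, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_output_in_unit_interval(self, value):
        assert 0.0 <= normalize_digit(value) < 1.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            normalize_digit(float("inf"))

    def test_minmax_alternative(self):
        out = normalize_minmax([2.0, 4.0, 6.0])
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])


class TestEncodeLabels:
    def test_ordinal_codes(self):
        out = encode_labels(["normal", "warning", "alert", "emergency", "EMERGENCY"])
        np.testing.assert_array_equal(out, [1, 2, 3, 4, 4])

    def test_unknown_label_rejected_with_row(self):
        with pytest.raises(ValueError, match="'critical' at row 1"):
            encode_labels(["normal", "critical"])


def _toy_imbalanced(seed=0, n_major=60, n_minor=12):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal(0.0, 1.0, size=(n_major, 2)),
            rng.normal(2.5, 0.6, size=(n_minor, 2)),
        ]
    )
    y = np.array([1] * n_major + [2] * n_minor)
    return TabularDataset(features=X, labels=y)


@pytest.mark.parametrize("sampler", [borderline_smote, adasyn])
class TestOversamplersShared:
    def test_balanced_input_unchanged(self, sampler):
        ds = _toy_imbalanced(n_major=20, n_minor=20)
        out, report = sampler(ds, k_neighbors=3, seed=1)
        assert report.n_synthetic == 0
        np.testing.assert_array_equal(out.features, ds.features)

    def test_counts_equalized_and_report_reconciles(self, sampler, small_cohort):
        ds = impute_dataset(small_cohort)
        out, report = sampler(ds, seed=3)
        counts = set(out.class_counts().values())
        assert len(counts) == 1
        assert out.n_samples == ds.n_samples + report.n_synthetic
        assert report.counts_after == out.class_counts()

    def test_originals_preserved_verbatim(self, sampler):
        ds = _toy_imbalanced()
        out, _ = sampler(ds, k_neighbors=3, seed=2)
        np.testing.assert_array_equal(out.features[: ds.n_samples], ds.features)
        np.testing.assert_array_equal(out.labels[: ds.n_samples], ds.labels)

    def test_synthetic_rows_are_convex_combinations(self, sampler):
        ds = _toy_imbalanced()
        out, report = sampler(ds, k_neighbors=3, seed=4)
        minority = ds.features[ds.labels == 2]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        synth = out.features[ds.n_samples :]
        assert synth.shape[0] == report.n_synthetic
        assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)

    def test_small_minority_rejected(self, sampler):
        ds = _toy_imbalanced(n_major=30, n_minor=4)
        with pytest.raises(ValueError, match="k_neighbors"):
            sampler(ds, k_neighbors=5, seed=0)


class TestBorderlineSmote:
    def test_danger_points_seed_synthesis(self):
        # minority cluster: 3 safe points far from the majority, 3 danger
        # points at the boundary, 1 noise point deep inside the majority
        majority = np.array(
            [[x, y] for x in np.linspace(0, 2, 5) for y in np.linspace(0, 2, 4)]
        )
        safe = np.array([[8.0, 8.0], [8.2, 8.0], [8.0, 8.2]])
        danger = np.array([[2.6, 1.0], [2.6, 1.4], [2.7, 1.2]])
        noise = np.array([[1.0, 1.05]])
        X = np.vstack([majority, safe, danger, noise])
        y = np.array([1] * len(majority) + [2] * 7)
        ds = TabularDataset(features=X, labels=y)

        # brute-force neighbourhood oracle for the danger set
        k = 5
        minority_idx = np.flatnonzero(y == 2)
        oracle_danger = []
        for i in minority_idx:
            dist = np.linalg.norm(X - X[i], axis=1)
            neigh = np.argsort(dist)[1 : k + 1]
            m = (y[neigh] == 1).sum()
            if k / 2 <= m < k:
                oracle_danger.append(i)
        assert len(oracle_danger) == 3  # construction sanity

        out, report = borderline_smote(ds, k_neighbors=k, seed=0)
        synth = out.features[len(X) :]
        # every synthetic row lies on a segment from a danger point
        # toward a minority neighbour, hence inside the minority hull's
        # danger-adjacent region, never in the safe cluster's far corner
        assert report.n_synthetic > 0
        minority = X[minority_idx]
        for row in synth:
            within = (row >= minority.min(axis=0) - 1e-9) & (
                row <= minority.max(axis=0) + 1e-9
            )
            assert within.all()


class TestAdasyn:
    def test_surrounded_point_gets_larger_budget(self):
        # 1-D toy: one minority point inside the majority mass, one far away
        X = np.array([[0.0], [0.5], [1.0], [1.5], [2.0], [1.0], [10.0], [10.5], [11.0]]).astype(float)
        y = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2])
        ds = TabularDataset(features=X, labels=y)
        out, report = adasyn(ds, k_neighbors=3, seed=0)
        synth = out.features[len(X) :]
        # the surrounded minority point (x=1.0) must seed strictly more
        # synthesis than the isolated far cluster
        near = np.sum(np.abs(synth - 1.0) < 4.0)
        far = np.sum(np.abs(synth - 10.5) < 4.0)
        assert near > far

    def test_zero_majority_neighbours_zero_budget(self):
        # minority cluster fully isolated: density weights all zero ->
        # uniform fallback still equalises counts
        X = np.vstack(
            [
                np.random.default_rng(0).normal(0, 0.5, size=(20, 2)),
                np.random.default_rng(1).normal(50, 0.5, size=(8, 2)),
            ]
        )
        y = np.array([1] * 20 + [2] * 8)
        out, report = adasyn(TabularDataset(features=X, labels=y), k_neighbors=5, seed=0)
        assert report.counts_after[2] == report.counts_after[1]

    def test_budgets_sum_to_requested_total(self):
        from mwoa.preprocessing import _largest_remainder

        w = np.array([0.1, 0.25, 0.65])
        for total in (0, 1, 7, 100):
            budget = _largest_remainder(w, total)
            assert budget.sum() == total


class TestCsvRoundTrip:
    def test_round_trip_preserves_values(self, tmp_path, clean_cohort):
        path = tmp_path / "cohort.csv"
        clean_cohort.to_csv(path)
        back = TabularDataset.from_csv(path)
        np.testing.assert_allclose(back.features, clean_cohort.features)
        np.testing.assert_array_equal(back.labels, clean_cohort.labels)
        assert back.feature_names == clean_cohort.feature_names

    def test_text_labels_and_missing_cells(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("id,a,b,class\n1,1.0,,normal\n2,2.0,5.0,EMERGENCY\n")
        ds = TabularDataset.from_csv(path)
        assert ds.feature_names == ["a", "b"]  # id dropped
        np.testing.assert_array_equal(ds.labels, [1, 4])
        assert ds.missing_mask[0, 1]
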