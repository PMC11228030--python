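import numpy as np
import pytest

import wvcnn
from wvcnn import (
    DatasetBundle,
    ExpressionMatrix,
    LabelVector,
    ResamplingConfig,
    SyntheticSpec,
    ValidationError,
    find_tomek_links,
    generate_dataset,
    smote_oversample,
    smote_tomek,
)

from .conftest import random_bundle


def make_bundle(points, labels, class_names=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if class_names is None:
        class_names = sorted({str(l) for l in labels})
    idx = [class_names.index(str(l)) for l in labels]
    expr = ExpressionMatrix(
        points,
        [f"f{i}" for i in range(points.shape[1])],
        [f"S{i}" for i in range(len(points))],
    )
    return DatasetBundle(expr, LabelVector(idx, class_names))


def brute_force_tomek(X, y):
    """Independent O(n^2) oracle: exhaustive mutual-nearest-neighbor scan."""
    n = len(X)
    links = []
    for i in range(n):
        for j in range(i + 1, n):
            if y[i] == y[j]:
                continue
            d_ij = np.linalg.norm(X[i] - X[j])
            mutual = True
            for k in range(n):
                if k != i and k != j:
                    if np.linalg.norm(X[i] - X[k]) < d_ij:
                        mutual = False
                        break
                    if np.linalg.norm(X[j] - X[k]) < d_ij:
                        mutual = False
                        break
            # ties must also resolve identically: require strict uniqueness
            if mutual:
                for k in range(n):
                    if k in (i, j):
                        continue
                    if np.linalg.norm(X[i] - X[k]) == d_ij and k < j:
                        mutual = False
                    if np.linalg.norm(X[j] - X[k]) == d_ij and k < i:
                        mutual = False
            if mutual:
                links.append((i, j))
    return links


class TestSmote:
    def test_balanced_input_is_returned_unchanged(self):
        bundle = make_bundle(
            [[0, 0], [1, 0], [5, 5], [6, 5], [10, 0], [11, 0]],
            ["a", "a", "b", "b", "c", "c"],
        )
        res = smote_oversample(bundle, ResamplingConfig(k_neighbors=1))
        assert res.as_bundle().n_samples == 6
        assert not res.is_synthetic.any()
        assert np.array_equal(res.expression.values, bundle.expression.values)

    def test_interpolating_identical_points_reproduces_them(self):
        bundle = make_bundle(
            [[1, 1], [1, 1], [0, 0], [0, 1], [1, 0]], ["a", "a", "b", "b", "b"]
        )
        res = smote_oversample(bundle, ResamplingConfig(k_neighbors=1, seed=0))
        syn = res.expression.values[res.is_synthetic]
        assert syn.shape == (1, 2)
        assert np.array_equal(syn[0], [1.0, 1.0])

    def test_synthetic_point_lies_on_segment_and_is_seeded(self):
        bundle = make_bundle(
            [[0, 0], [2, 2], [9, 0], [9, 1], [9, 2]], ["a", "a", "b", "b", "b"]
        )
        cfg = ResamplingConfig(k_neighbors=1, seed=5)
        res = smote_oversample(bundle, cfg)
        (pt,) = res.expression.values[res.is_synthetic]
        assert pt[0] == pt[1]  # collinear with (0,0)-(2,2)
        assert 0.0 <= pt[0] <= 2.0
        res2 = smote_oversample(bundle, cfg)
        assert np.array_equal(res2.expression.values, res.expression.values)

    def test_equalize_to_majority_levels_all_class_counts(self):
        rng = np.random.default_rng(11)
        bundle = random_bundle(rng, n_samples=40, n_features=5, n_classes=3)
        majority = bundle.labels.counts().max()
        res = smote_oversample(bundle)
        assert (res.labels.counts() == majority).all()

    def test_synthetic_samples_are_same_class_convex_combinations(self):
        rng = np.random.default_rng(2)
        bundle = random_bundle(rng, n_samples=30, n_features=4, n_classes=3)
        res = smote_oversample(bundle, ResamplingConfig(seed=3))
        X = bundle.expression.values
        y = bundle.labels.labels
        for row, lab, (p, q) in zip(
            res.expression.values[res.is_synthetic],
            res.labels.labels[res.is_synthetic],
            res.parents[res.is_synthetic],
        ):
            assert y[p] == y[q] == lab
            diff = X[q] - X[p]
            denom = float(diff @ diff)
            lam = 0.0 if denom == 0 else float((row - X[p]) @ diff) / denom
            assert -1e-12 <= lam <= 1 + 1e-12
            assert np.linalg.norm(row - (X[p] + lam * diff)) < 1e-9

    def test_cohort_profile_equalizes_to_518_samples(self):
        spec = SyntheticSpec(n_features=30, n_informative=7, seed=4)
        res = smote_oversample(generate_dataset(spec))
        assert (res.labels.counts() == 74).all()
        assert res.as_bundle().n_samples == 7 * 74 == 518

    def test_singleton_class_needing_synthesis_names_the_class(self):
        bundle = make_bundle([[0, 0], [5, 5], [6, 6]], ["lone", "big", "big"])
        with pytest.raises(ValidationError, match="lone"):
            smote_oversample(bundle)

    def test_explicit_target_below_current_count_rejected(self):
        bundle = make_bundle([[0, 0], [1, 1], [5, 5]], ["a", "a", "b"])
        cfg = ResamplingConfig(
            target_policy="explicit_counts", explicit_counts=[1, 2]
        )
        with pytest.raises(ValidationError, match="never undersamples"):
            smote_oversample(bundle, cfg)

    def test_tiny_class_caps_k_with_warning(self):
        bundle = make_bundle(
            [[0, 0], [0.5, 0], [9, 9], [9, 8], [8, 9], [8, 8]], ["a", "a", "b"] + ["b"] * 3
        )
        with pytest.warns(UserWarning, match="capped"):
            res = smote_oversample(bundle, ResamplingConfig(k_neighbors=5))
        assert (res.labels.counts() == 4).all()


class TestTomekLinks:
    def test_well_separated_clusters_have_no_links(self):
        bundle = make_bundle(
            [[0, 0], [0, 1], [100, 100], [100, 101]], ["a", "a", "b", "b"]
        )
        assert find_tomek_links(bundle) == []

    def test_one_dimensional_worked_example(self):
        # class a at 0.0 and 10.0; class b at 0.1 and 20.0: only (0.0, 0.1)
        # are mutual nearest neighbors with differing labels
        bundle = make_bundle([[0.0], [10.0], [0.1], [20.0]], ["a", "a", "b", "b"])
        assert find_tomek_links(bundle) == [(0, 2)]

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            X = rng.uniform(0, 4, size=(n, int(rng.integers(1, 4))))
            y = rng.integers(int(rng.integers(2, 4)), size=n)
            if len(np.unique(y)) < 2:
                y[0] = (y[1] + 1) % 2
            bundle = make_bundle(X, [str(l) for l in y])
            assert find_tomek_links(bundle) == brute_force_tomek(
                X, bundle.labels.labels
            )


class TestSmoteTomek:
    def test_link_free_data_equals_plain_smote(self):
        bundle = make_bundle(
            [[0, 0], [1, 0], [0, 1], [50, 50], [51, 50]], ["a", "a", "a", "b", "b"]
        )
        cfg = ResamplingConfig(k_neighbors=1, seed=8)
        combined = smote_tomek(bundle, cfg)
        plain = smote_oversample(bundle, cfg)
        assert combined.removed_original_indices == []
        assert np.array_equal(combined.expression.values, plain.expression.values)

    def test_identified_link_members_are_removed(self):
        rng = np.random.default_rng(23)
        # two overlapping gaussian blobs, imbalanced
        Xa = rng.normal(0.0, 1.0, size=(25, 3))
        Xb = rng.normal(0.8, 1.0, size=(10, 3))
        bundle = make_bundle(np.vstack([Xa, Xb]), ["a"] * 25 + ["b"] * 10)
        cfg = ResamplingConfig(seed=1)
        res = smote_tomek(bundle, cfg)
        over = smote_oversample(bundle, cfg)
        links = find_tomek_links(over.as_bundle())
        assert links, "fixture should produce at least one Tomek link"
        expected_removed = sorted({i for pair in links for i in pair})
        assert res.removed_original_indices == expected_removed
        kept_ids = set(res.expression.sample_ids)
        for i, j in links:
            assert over.expression.sample_ids[i] not in kept_ids
            assert over.expression.sample_ids[j] not in kept_ids

    def test_remove_majority_only_keeps_minority_member(self):
        # (1.0, a) and (1.3, b) are mutual nearest neighbors: a Tomek link
        bundle = make_bundle(
            [[0.0], [0.5], [1.0], [1.3], [10.0]], ["a", "a", "a", "b", "b"]
        )
        cfg = ResamplingConfig(
            k_neighbors=1, link_removal="remove_majority_only", seed=0,
            target_policy="explicit_counts", explicit_counts=[3, 2],
        )
        res = smote_tomek(bundle, cfg)
        assert res.removed_original_indices == [2]  # majority-class member
        assert "S3" in res.expression.sample_ids  # minority member kept
        both = smote_tomek(bundle, ResamplingConfig(
            k_neighbors=1, seed=0,
            target_policy="explicit_counts", explicit_counts=[3, 2],
        ))
        assert both.removed_original_indices == [2, 3]

    def test_fixed_seed_gives_bit_identical_output(self):
        rng = np.random.default_rng(31)
        bundle = random_bundle(rng, n_samples=35, n_features=6, n_classes=3)
        cfg = ResamplingConfig(seed=77)
        a, b = smote_tomek(bundle, cfg), smote_tomek(bundle, cfg)
        assert np.array_equal(a.expression.values, b.expression.values)
        assert a.removed_original_indices == b.removed_original_indices
        assert np.array_equal(a.is_synthetic, b.is_synthetic)
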