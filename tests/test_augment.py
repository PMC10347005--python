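import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enose_bench.augment import (
    AugmentConfig,
    augment,
    augment_gaussian,
    augment_interp_extrap,
    augment_noise_and_stretch,
    augment_smote,
    cv_to_bounds,
    interp_extrap_sample,
    k_nearest_same_class,
    stretch_series,
)
from enose_bench.core import Dataset, SensorLayout, Trial


def _recover_alpha(xn, xi, xj):
    """Brute-force alpha recovery: project xn - xi onto xj - xi."""
    d = xj - xi
    return float(np.dot(xn - xi, d) / np.dot(d, d))


def _collinearity_residual(xn, xi, xj):
    d = xj - xi
    alpha = _recover_alpha(xn, xi, xj)
    return np.linalg.norm(xn - (xi + alpha * d)) / np.linalg.norm(d)


class TestKNearestSameClass:
    def test_matches_brute_force(self, tiny_dataset):
        # independent oracle: sort all same-class pairwise distances
        for anchor in range(len(tiny_dataset)):
            got = k_nearest_same_class(tiny_dataset, anchor, k=3)
            a = tiny_dataset.trials[anchor]
            cands = [
                (np.linalg.norm(t.features - a.features), i)
                for i, t in enumerate(tiny_dataset.trials)
                if t.label == a.label and i != anchor
            ]
            expected = [i for _, i in sorted(cands)][:3]
            assert got == expected

    def test_k_capped_at_class_size(self, tiny_dataset):
        got = k_nearest_same_class(tiny_dataset, 0, k=100)
        assert len(got) == 7  # 8 per class minus the anchor

    def test_tie_broken_by_lower_index(self):
        layout = SensorLayout(("x",), 2)
        trials = [
            Trial([0.0, 0.0], 1, "anchor"),
            Trial([1.0, 0.0], 1, "near_a"),
            Trial([0.0, 1.0], 1, "near_b"),  # same distance as near_a
        ]
        ds = Dataset(trials, layout)
        assert k_nearest_same_class(ds, 0, k=1) == [1]

    def test_singleton_class_rejected(self):
        layout = SensorLayout(("x",), 2)
        ds = Dataset(
            [Trial([0.0, 0.0], 1, "a"), Trial([1.0, 1.0], 2, "b"),
             Trial([2.0, 2.0], 2, "c")],
            layout,
        )
        with pytest.raises(ValueError, match="singleton"):
            k_nearest_same_class(ds, 0, k=1)


class TestInterpExtrapSample:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(0.0, [0.0, 0.0]), (1.0, [1.0, 2.0]), (2.0, [2.0, 4.0])],
    )
    def test_affine_combination(self, alpha, expected):
        out = interp_extrap_sample(np.zeros(2), np.array([1.0, 2.0]), alpha)
        np.testing.assert_allclose(out, expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            interp_extrap_sample(np.zeros(2), np.zeros(3), 0.5)


class TestAugmentInterpExtrap:
    def test_exact_count_and_flags(self, tiny_dataset):
        cfg = AugmentConfig(method="interp_extrap", n_synthetic=2000, seed=1)
        syn = augment_interp_extrap(tiny_dataset, cfg)
        assert len(syn) == 2000
        assert all(t.is_synthetic for t in syn)
        assert set(t.label for t in syn) <= set(tiny_dataset.classes)

    def test_collinear_with_some_parent_pair(self, tiny_dataset):
        """Every synthetic point lies on a line through two same-class parents."""
        cfg = AugmentConfig(n_synthetic=200, c1=-2, c2=3, seed=5)
        syn = augment_interp_extrap(tiny_dataset, cfg)
        X = tiny_dataset.feature_matrix()
        y = tiny_dataset.labels()
        for t in syn:
            idx = np.where(y == t.label)[0]
            residuals = [
                _collinearity_residual(t.features, X[i], X[j])
                for i in idx
                for j in idx
                if i != j
            ]
            assert min(residuals) <= 1e-9

    def test_interpolation_bounds_give_envelope_containment(self, tiny_dataset):
        cfg = AugmentConfig(n_synthetic=500, c1=0.0, c2=1.0, seed=2)
        syn = augment_interp_extrap(tiny_dataset, cfg)
        X = tiny_dataset.feature_matrix()
        y = tiny_dataset.labels()
        for t in syn:
            idx = np.where(y == t.label)[0]
            lo, hi = X[idx].min(axis=0), X[idx].max(axis=0)
            assert np.all(t.features >= lo - 1e-12)
            assert np.all(t.features <= hi + 1e-12)

    def test_deterministic_under_seed(self, tiny_dataset):
        cfg = AugmentConfig(n_synthetic=50, seed=7)
        a = augment_interp_extrap(tiny_dataset, cfg)
        b = augment_interp_extrap(tiny_dataset, cfg)
        np.testing.assert_array_equal(a.feature_matrix(), b.feature_matrix())
        assert a.trial_ids() == b.trial_ids()

    def test_originals_not_mutated(self, tiny_dataset):
        before = tiny_dataset.feature_matrix()
        augment_interp_extrap(tiny_dataset, AugmentConfig(n_synthetic=100, seed=3))
        np.testing.assert_array_equal(before, tiny_dataset.feature_matrix())

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="c1 < c2"):
            AugmentConfig(method="interp_extrap", c1=1.0, c2=1.0)


class TestSmote:
    def test_bit_identical_to_interp_extrap_at_unit_bounds(self, tiny_dataset):
        rng_a = np.random.default_rng(123)
        rng_b = np.random.default_rng(123)
        a = augment_smote(tiny_dataset, 300, k=3, rng=rng_a)
        cfg = AugmentConfig(n_synthetic=300, k=3, c1=0.0, c2=1.0)
        b = augment_interp_extrap(tiny_dataset, cfg, rng=rng_b)
        np.testing.assert_array_equal(a.feature_matrix(), b.feature_matrix())
        np.testing.assert_array_equal(a.labels(), b.labels())
        assert a.trial_ids() == b.trial_ids()

    def test_recovered_alpha_within_unit_interval(self, tiny_dataset):
        syn = augment_smote(tiny_dataset, 400, k=3, seed=9)
        X = tiny_dataset.feature_matrix()
        y = tiny_dataset.labels()
        for t in syn:
            idx = np.where(y == t.label)[0]
            best = None
            for i in idx:
                for j in idx:
                    if i == j:
                        continue
                    r = _collinearity_residual(t.features, X[i], X[j])
                    a = _recover_alpha(t.features, X[i], X[j])
                    if best is None or r < best[0]:
                        best = (r, a)
            assert best[0] <= 1e-9
            assert -1e-9 <= best[1] <= 1 + 1e-9

    def test_t_by_m_count_semantics(self, tiny_dataset):
        # T applications of M samples each = T*M total
        rng = np.random.default_rng(0)
        parts = [augment_smote(tiny_dataset, 5, rng=rng) for _ in range(4)]
        assert sum(len(p) for p in parts) == 20


class TestGaussianNoise:
    def test_sigma_zero_copies_parents(self, tiny_dataset):
        syn = augment_gaussian(tiny_dataset, 20, sigma=0.0, seed=1)
        X = tiny_dataset.feature_matrix()
        for t in syn:
            assert any(np.array_equal(t.features, row) for row in X)

    def test_moment_recovery_single_parent(self):
        layout = SensorLayout(("A", "B", "C"), 80)
        parent = Trial(np.linspace(0, 3, 240), 1, "p")
        other = Trial(np.linspace(0, 3, 240) + 1, 2, "q")
        ds = Dataset([parent], layout, classes=(1, 2))
        sigma = 0.05
        syn = augment_gaussian(ds, 10000, sigma=sigma, seed=4)
        D = syn.feature_matrix() - parent.features
        means, sds = D.mean(axis=0), D.std(axis=0, ddof=1)
        assert np.all(np.abs(means) <= 3 * sigma / np.sqrt(10000) * 1.5)
        frac_ok = np.mean((sds >= 0.9 * sigma) & (sds <= 1.1 * sigma))
        assert frac_ok >= 0.99

    def test_negative_sigma_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="sigma"):
            augment_gaussian(tiny_dataset, 5, sigma=-0.1)


class TestStretchSeries:
    def test_length_preserved(self):
        x = np.cumsum(np.random.default_rng(0).random(80))
        assert stretch_series(x, 0.1).shape == (80,)

    def test_near_zero_alpha_is_identity(self):
        x = np.cumsum(np.random.default_rng(1).random(80))
        np.testing.assert_allclose(stretch_series(x, 1e-9), x, atol=1e-6)

    def test_prefix_length_80_alpha_0p1(self):
        # m = round(80 / 1.1) = 73; output endpoint equals x[72]
        x = np.arange(80, dtype=float)
        out = stretch_series(x, 0.1)
        assert out[0] == x[0]
        assert np.isclose(out[-1], x[72])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=5, max_size=40), st.floats(0.01, 0.99))
    def test_monotone_preserved(self, increments, alpha):
        x = np.cumsum(np.abs(increments))
        out = stretch_series(x, alpha)
        assert np.all(np.diff(out) >= -1e-12)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="stretch_alpha"):
            stretch_series(np.arange(10.0), 1.5)

    def test_literal_reading_also_stretches(self):
        x = np.arange(80, dtype=float)
        out = stretch_series(x, 0.1, eq5_literal=True)
        assert out.shape == (80,)
        assert out[-1] < x[-1]  # compressed: end of output is an earlier value


class TestNoiseAndStretch:
    def test_two_t_trials_tagged(self, tiny_dataset):
        syn = augment_noise_and_stretch(tiny_dataset, T=50, seed=2)
        assert len(syn) == 100
        ids = syn.trial_ids()
        assert sum(i.endswith("_noise") for i in ids) == 50
        assert sum(i.endswith("_stretch") for i in ids) == 50

    def test_labels_preserved(self, tiny_dataset):
        syn = augment_noise_and_stretch(tiny_dataset, T=30, seed=3)
        assert set(t.label for t in syn) <= set(tiny_dataset.classes)

    def test_stretch_respects_segment_boundaries(self):
        """Each sensor segment is stretched from its own prefix only."""
        layout = SensorLayout(("A", "B"), 40)
        # segment A in [0,1], segment B in [10,11]: values never mix
        a = np.linspace(0.0, 1.0, 40)
        b = np.linspace(10.0, 11.0, 40)
        ds = Dataset([Trial(np.concatenate([a, b]), 1, "t"),
                      Trial(np.concatenate([a, b]) + 0.01, 1, "u")], layout)
        syn = augment_noise_and_stretch(ds, T=5, sigma=0.0, stretch_alpha=0.3, seed=0)
        for t in syn:
            assert t.features[:40].max() <= 1.1
            assert t.features[40:].min() >= 9.9


class TestCvToBounds:
    @pytest.mark.parametrize(
        "cv,expected",
        [(0.5, (0.0, 1.0)), (2.5, (-2.0, 3.0)), (0.02, (0.48, 0.52))],
    )
    def test_values(self, cv, expected):
        c1, c2 = cv_to_bounds(cv)
        assert np.isclose(c1, expected[0]) and np.isclose(c2, expected[1])

    def test_width_is_twice_cv(self):
        for cv in (0.02, 0.7, 4.0):
            c1, c2 = cv_to_bounds(cv)
            assert np.isclose(c2 - c1, 2 * cv)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cv_to_bounds(0.0)


class TestDispatch:
    @pytest.mark.parametrize(
        "method", ["interp_extrap", "smote", "gaussian", "stretch", "gaussian_and_stretch"]
    )
    def test_count_contract_all_methods(self, tiny_dataset, method):
        for n in (0, 1, 7, 50):
            cfg = AugmentConfig(method=method, n_synthetic=n, seed=1)
            assert len(augment(tiny_dataset, cfg)) == n

    @pytest.mark.parametrize(
        "method", ["interp_extrap", "smote", "gaussian", "stretch", "gaussian_and_stretch"]
    )
    def test_label_preservation_and_determinism(self, tiny_dataset, method):
        cfg = AugmentConfig(method=method, n_synthetic=40, seed=6)
        a, b = augment(tiny_dataset, cfg), augment(tiny_dataset, cfg)
        np.testing.assert_array_equal(a.feature_matrix(), b.feature_matrix())
        assert set(t.label for t in a) <= set(tiny_dataset.classes)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            AugmentConfig(method="mixup")
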