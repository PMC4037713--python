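"""Pair-model fitting, edge weights and network construction."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parenclitic import (
    ExpressionDataset,
    build_network,
    edge_weight,
    fit_pair_model,
    fit_reference_models,
)
from parenclitic.core import (
    STATUS_ABSENT,
    STATUS_VALID,
    edge_weight_with_status,
)

from conftest import ols_oracle


class TestFitPairModel:
    @pytest.mark.parametrize(
        "x, y, slope, intercept, resid_std",
        [
            # exact line: zero residual spread
            ([0, 1, 2, 3], [1, 3, 5, 7], 2.0, 1.0, 0.0),
            # hand-solved normal equations
            ([0, 1, 2], [0, 1, 3], 1.5, -1 / 6, np.sqrt(1 / 12)),
        ],
    )
    def test_known_fits(self, x, y, slope, intercept, resid_std):
        m = fit_pair_model(x, y)
        assert m.slope == pytest.approx(slope)
        assert m.intercept == pytest.approx(intercept)
        assert m.residual_std == pytest.approx(resid_std, abs=1e-12)
        assert m.n_train == len(x)

    def test_constant_predictor_is_degenerate(self):
        m = fit_pair_model([5, 5, 5], [1, 2, 3])
        assert m.degenerate
        assert m.predictor_degenerate
        assert m.slope == 0.0
        assert m.intercept == pytest.approx(2.0)

    def test_perfect_fit_is_degenerate_but_keeps_coefficients(self):
        m = fit_pair_model([0, 1, 2, 3], [1, 3, 5, 7])
        assert m.degenerate  # zero residual spread cannot standardize
        assert not m.predictor_degenerate

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="insufficient training instances"):
            fit_pair_model([0, 1], [0, 1])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_pair_model([0, 1, np.nan], [0, 1, 2])

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 12))
            x = rng.normal(size=n) * rng.uniform(0.5, 10)
            y = rng.normal(size=n) * rng.uniform(0.5, 10)
            m = fit_pair_model(x, y)
            slope, intercept, resid_std = ols_oracle(x, y)
            assert m.slope == pytest.approx(slope, rel=1e-10)
            assert m.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-12)
            assert m.residual_std == pytest.approx(resid_std, rel=1e-10)

    def test_matches_scipy_linregress(self, rng):
        """Independent cross-check against a library OLS implementation."""
        from scipy.stats import linregress

        for _ in range(20):
            x = rng.normal(size=8)
            y = 2.0 * x + rng.normal(size=8)
            m = fit_pair_model(x, y)
            ref = linregress(x, y)
            assert m.slope == pytest.approx(ref.slope, rel=1e-10)
            assert m.intercept == pytest.approx(ref.intercept, rel=1e-10)

    def test_training_residuals_are_standardized(self, rng):
        for _ in range(20):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            m = fit_pair_model(x, y)
            resid = y - (m.slope * x + m.intercept)
            scale = max(1.0, np.abs(y).max())
            assert abs(resid.mean()) < 1e-9 * scale
            assert np.std(resid, ddof=1) == pytest.approx(m.residual_std)


class TestFitReferenceModels:
    def test_directional_model_count(self, rng):
        ds = ExpressionDataset(
            rng.normal(size=(4, 3)), list("wxyz"), list("ABC")
        )
        models = fit_reference_models(ds)
        assert len(models) == 6
        assert len(models.models) == 6

    def test_exact_proportionality(self, rng):
        a = rng.normal(size=5)
        ds = ExpressionDataset(
            np.column_stack([a, 2 * a]), [f"s{i}" for i in range(5)], ["A", "B"]
        )
        m = fit_reference_models(ds).pair_model("A", "B")
        assert m.slope == pytest.approx(2.0)
        assert m.residual_std == pytest.approx(0.0, abs=1e-12)
        assert m.degenerate

    def test_every_model_matches_scalar_fit_and_oracle(self, small_dataset):
        models = fit_reference_models(small_dataset)
        X = small_dataset.values
        for i, fi in enumerate(small_dataset.feature_ids):
            for j, fj in enumerate(small_dataset.feature_ids):
                if i == j:
                    continue
                m = models.pair_model(fi, fj)
                scalar = fit_pair_model(X[:, i], X[:, j])
                slope, intercept, resid_std = ols_oracle(X[:, i], X[:, j])
                for got in (m, scalar):
                    assert got.slope == pytest.approx(slope, rel=1e-10)
                    assert got.intercept == pytest.approx(
                        intercept, rel=1e-10, abs=1e-12
                    )
                    assert got.residual_std == pytest.approx(resid_std, rel=1e-10)

    def test_selector_by_ids_and_mask(self, small_dataset):
        by_ids = fit_reference_models(small_dataset, ["s1", "s2", "s3"])
        mask = np.zeros(6, bool)
        mask[:3] = True
        by_mask = fit_reference_models(small_dataset, mask)
        assert by_ids.n_train == by_mask.n_train == 3
        np.testing.assert_array_equal(by_ids.slope, by_mask.slope)

    def test_too_few_selected_instances(self, small_dataset):
        with pytest.raises(ValueError, match="insufficient"):
            fit_reference_models(small_dataset, ["s1", "s2"])


class TestEdgeWeight:
    def _pair_models(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 3.0])
        m_ab = fit_pair_model(x, y, source_feature="A", target_feature="B")
        m_ba = fit_pair_model(y, x, source_feature="B", target_feature="A")
        return m_ab, m_ba

    def test_subject_on_both_lines_scores_zero(self, rng):
        x = rng.normal(size=6)
        y = 1.3 * x + rng.normal(size=6)  # noisy, non-degenerate
        m_xy = fit_pair_model(x, y, source_feature="X", target_feature="Y")
        m_yx = fit_pair_model(y, x, source_feature="Y", target_feature="X")
        # intersection point lies on both directional lines simultaneously
        sol = np.linalg.solve(
            np.array([[-m_xy.slope, 1.0], [1.0, -m_yx.slope]]),
            np.array([m_xy.intercept, m_yx.intercept]),
        )
        xi, xj = sol
        assert edge_weight(m_xy, m_yx, xi, xj) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_zscores(self):
        """Subject (1, 2) against the hand-solved 3-point model pair."""
        m_ab, m_ba = self._pair_models()
        z_ab = abs(2 - (1.5 * 1 - 1 / 6)) / np.sqrt(1 / 12)  # ≈ 2.3094
        slope, intercept, resid_std = ols_oracle([0, 1, 3], [0, 1, 2])
        z_ba = abs(1 - (slope * 2 + intercept)) / resid_std
        assert z_ab == pytest.approx(2.309401, rel=1e-6)
        w = edge_weight(m_ab, m_ba, 1.0, 2.0, combine="mean")
        assert w == pytest.approx((z_ab + z_ba) / 2, rel=1e-10)
        assert edge_weight(m_ab, m_ba, 1.0, 2.0, combine="max") == pytest.approx(
            max(z_ab, z_ba), rel=1e-10
        )
        assert edge_weight(m_ab, m_ba, 1.0, 2.0, combine="min") == pytest.approx(
            min(z_ab, z_ba), rel=1e-10
        )

    def test_both_directions_degenerate(self, caplog):
        m_ab = fit_pair_model(
            [0, 1, 2], [1, 3, 5], source_feature="A", target_feature="B"
        )
        m_ba = fit_pair_model(
            [1, 3, 5], [0, 1, 2], source_feature="B", target_feature="A"
        )
        assert m_ab.degenerate and m_ba.degenerate
        with caplog.at_level(logging.WARNING, logger="parenclitic.core"):
            w, status = edge_weight_with_status(m_ab, m_ba, 10.0, -3.0)
        assert w == 0.0
        assert status == STATUS_ABSENT
        assert "degenerate" in caplog.text

    def test_mismatched_pair_rejected(self):
        m_ab, m_ba = self._pair_models()
        with pytest.raises(ValueError, match="two directions"):
            edge_weight(m_ab, m_ab, 0.0, 0.0)

    def test_unknown_combine_rejected(self):
        m_ab, m_ba = self._pair_models()
        with pytest.raises(ValueError, match="combine"):
            edge_weight(m_ab, m_ba, 0.0, 0.0, combine="median")


class TestBuildNetwork:
    def test_training_like_subject_on_exact_fits_gives_zero_matrix(self, rng):
        # noiseless proportional features: subject on every fitted line,
        # but exact fits are degenerate -> absent edges, all-zero weights
        base = rng.normal(size=5)
        ds = ExpressionDataset(
            np.column_stack([base, 2 * base, -base + 1]),
            [f"s{i}" for i in range(5)],
            ["A", "B", "C"],
        )
        models = fit_reference_models(ds)
        net = build_network(ds.values[0], models, subject_id="s0")
        np.testing.assert_array_equal(net.weights, 0.0)
        assert np.all(net.edge_status == STATUS_ABSENT)

    def test_matrix_entry_equals_edge_weight(self, small_dataset):
        models = fit_reference_models(small_dataset)
        subject = small_dataset.values[0] + 0.5
        net = build_network(subject, models, subject_id="probe")
        for i, fi in enumerate(small_dataset.feature_ids):
            for j, fj in enumerate(small_dataset.feature_ids):
                if i >= j:
                    continue
                expected = edge_weight(
                    models.pair_model(fi, fj),
                    models.pair_model(fj, fi),
                    subject[i],
                    subject[j],
                )
                assert net.weights[i, j] == pytest.approx(expected, rel=1e-12)

    def test_symmetry_nonnegativity_zero_diagonal(self, small_dataset, rng):
        models = fit_reference_models(small_dataset)
        net = build_network(rng.normal(size=4), models)
        np.testing.assert_array_equal(net.weights, net.weights.T)
        assert np.all(net.weights >= 0)
        assert np.all(np.diag(net.weights) == 0)

    def test_permutation_equivariance(self, small_dataset, rng):
        subject = rng.normal(size=4)
        perm = [2, 0, 3, 1]
        permuted = ExpressionDataset(
            small_dataset.values[:, perm],
            list(small_dataset.instance_ids),
            [small_dataset.feature_ids[p] for p in perm],
        )
        net = build_network(subject, fit_reference_models(small_dataset))
        net_p = build_network(
            subject[perm], fit_reference_models(permuted)
        )
        np.testing.assert_array_equal(
            net.weights[np.ix_(perm, perm)], net_p.weights
        )

    def test_mapping_subject_aligned_by_feature_id(self, small_dataset, rng):
        subject = rng.normal(size=4)
        models = fit_reference_models(small_dataset)
        as_vector = build_network(subject, models)
        shuffled = {
            fid: subject[i]
            for i, fid in sorted(
                enumerate(small_dataset.feature_ids), key=lambda t: -t[0]
            )
        }
        as_mapping = build_network(shuffled, models)
        np.testing.assert_array_equal(as_vector.weights, as_mapping.weights)

    def test_feature_mismatch_rejected(self, small_dataset):
        models = fit_reference_models(small_dataset)
        with pytest.raises(ValueError, match="does not match"):
            build_network(np.zeros(5), models)
        with pytest.raises(ValueError, match="missing"):
            build_network({"A": 1.0, "B": 2.0}, models)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        scale=st.floats(0.1, 50),
        offset=st.floats(-100, 100),
        feature=st.integers(0, 3),
    )
    def test_affine_invariance_of_weights(self, scale, offset, feature):
        """Rescaling one feature in training data + subject leaves W unchanged."""
        rng = np.random.default_rng(7)
        values = rng.normal(size=(6, 4))
        subject = rng.normal(size=4)
        ds = ExpressionDataset(
            values, [f"s{i}" for i in range(6)], list("ABCD")
        )
        transformed = values.copy()
        transformed[:, feature] = scale * transformed[:, feature] + offset
        subject_t = subject.copy()
        subject_t[feature] = scale * subject_t[feature] + offset
        ds_t = ExpressionDataset(
            transformed, [f"s{i}" for i in range(6)], list("ABCD")
        )
        w = build_network(subject, fit_reference_models(ds)).weights
        w_t = build_network(subject_t, fit_reference_models(ds_t)).weights
        np.testing.assert_allclose(w_t, w, rtol=1e-9, atol=1e-9)


class TestExpressionDataset:
    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionDataset(
                np.array([[1.0, np.inf], [0.0, 1.0]]), ["a", "b"], ["x", "y"]
            )

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionDataset(np.zeros((2, 2)), ["a", "a"], ["x", "y"])

    def test_select_instances_keeps_labels(self):
        ds = ExpressionDataset(
            np.arange(8, dtype=float).reshape(4, 2),
            list("abcd"),
            ["x", "y"],
            class_labels=["u", "u", "v", "v"],
        )
        sub = ds.select_instances(["c", "a"])
        assert sub.instance_ids == ["c", "a"]
        assert sub.class_labels == ["v", "u"]
        np.testing.assert_array_equal(sub.values, ds.values[[2, 0]])
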