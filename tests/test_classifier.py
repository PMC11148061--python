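"""Feature-space MFA, custom class weights, training and importance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epiperturb import classifier


def _orthogonal_table(n=400, variances=(4.0, 1.0), seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    a = (a - a.mean()) / a.std()
    b = rng.normal(size=n)
    b -= (b @ a) / (a @ a) * a
    b = (b - b.mean()) / b.std()
    return pd.DataFrame(
        {"x": np.sqrt(variances[0]) * a, "y": np.sqrt(variances[1]) * b}
    )


class TestFeatureSpace:
    def test_variance_shares_of_diagonal_covariance(self):
        tab = _orthogonal_table()
        fs = classifier.build_feature_space({"G": tab}, min_var=0.01)
        assert np.allclose(fs.variance_explained, [0.8, 0.2], atol=1e-10)
        assert fs.features.shape[1] == 2

    def test_duplicated_table_leaves_shares_unchanged(self):
        tab = _orthogonal_table(seed=1)
        fs1 = classifier.build_feature_space({"G": tab}, min_var=0.01)
        fs2 = classifier.build_feature_space(
            {"G": tab, "H": tab.copy()}, min_var=0.01
        )
        assert np.allclose(fs1.variance_explained, fs2.variance_explained)

    def test_impossible_threshold_errors(self):
        tab = _orthogonal_table(seed=2)
        with pytest.raises(ValueError, match="min_var"):
            classifier.build_feature_space({"G": tab}, min_var=1.0)

    def test_descriptor_correlations_bounded_and_informative(self):
        tab = _orthogonal_table(seed=3)
        fs = classifier.build_feature_space({"G": tab}, min_var=0.01)
        assert (fs.descriptors.abs().to_numpy() <= 1 + 1e-9).all()
        # dim1 is the high-variance column up to sign
        assert abs(fs.descriptors.loc["dim1", "G|x"]) > 0.99

    def test_categorical_vtest_sign(self):
        tab = _orthogonal_table(seed=4)
        labels = pd.Series(
            np.where(tab["x"] > 0, "high", "low"), index=tab.index
        )
        fs = classifier.build_feature_space(
            {"G": tab}, min_var=0.01, categorical={"state": labels}
        )
        v_high = fs.vtests.loc["dim1", "state=high"]
        v_low = fs.vtests.loc["dim1", "state=low"]
        assert np.sign(v_high) == -np.sign(v_low)
        assert abs(v_high) > 2


class TestClassWeights:
    def test_printed_example(self):
        cw = classifier.class_weights(80, 15, 5)
        assert (cw.w0s, cw.wds, cw.wus) == pytest.approx((0.2, 0.6, 0.2))

    def test_balanced_symmetric_case(self):
        cw = classifier.class_weights(50, 25, 25)
        assert (cw.w0s, cw.wds, cw.wus) == pytest.approx((0.5, 0.25, 0.25))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n0=st.integers(1, 10_000),
        nd=st.integers(0, 10_000),
        nu=st.integers(0, 10_000),
    )
    def test_identities_for_admissible_counts(self, n0, nd, nu):
        if nd + nu == 0 or n0 + nd + nu < 3:
            return
        cw = classifier.class_weights(n0, nd, nu)
        assert cw.w0s + cw.wds + cw.wus == pytest.approx(1.0, abs=1e-12)
        swapped = classifier.class_weights(n0, nu, nd)
        assert swapped.w0s == pytest.approx(cw.w0s)  # invariant to nd <-> nu
        if nd and nu:
            assert cw.wds / cw.wus == pytest.approx(nd / nu)
        assert (cw.wds > cw.wus) == (nd > nu)

    def test_error_paths(self):
        with pytest.raises(ValueError):
            classifier.class_weights(0, 5, 5)
        with pytest.raises(ValueError):
            classifier.class_weights(10, 0, 0)


def _labelled_features(n=300, seed=1, separable=True):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(
        rng.normal(size=(n, 4)), columns=list("abcd"),
        index=[f"CRE{i}" for i in range(n)],
    )
    if separable:
        y = np.where(x["a"] > 1.0, "up", np.where(x["a"] < -0.5, "down", "none"))
    else:
        y = rng.choice(["down", "none", "up"], size=n, p=[0.25, 0.6, 0.15])
    return x, pd.Series(y, index=x.index)


class TestTrainEval:
    def test_separable_labels_reach_perfect_auc(self):
        x, y = _labelled_features(separable=True)
        ev = classifier.train_eval(x, y, seed=0)
        assert (ev.metrics["roc_auc"] > 0.99).all()

    def test_shuffled_labels_hover_at_chance(self):
        rng = np.random.default_rng(2)
        aucs = []
        for rep in range(20):
            x, y = _labelled_features(n=240, seed=rep, separable=False)
            y = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            ev = classifier.train_eval(
                x, y, seed=rep, params={"max_depth": 3, "n_estimators": 50}
            )
            aucs.append(ev.metrics["roc_auc"].mean())
        assert abs(np.mean(aucs) - 0.5) < 0.06

    def test_split_reproducible_and_stratified(self):
        x, y = _labelled_features(seed=3)
        e1 = classifier.train_eval(x, y, seed=11)
        e2 = classifier.train_eval(x, y, seed=11)
        assert list(e1.train_index) == list(e2.train_index)
        # class proportions preserved within one observation
        for cls, total in y.value_counts().items():
            got = (y[e1.train_index] == cls).sum()
            assert abs(got - 0.7 * total) <= 1

    def test_missing_class_raises_with_guidance(self):
        x, y = _labelled_features(seed=4)
        y[:] = "none"
        y.iloc[0] = "down"
        y.iloc[1] = "up"  # only one 'up' observation
        with pytest.raises(ValueError, match="class"):
            classifier.train_eval(x, y, seed=0)


def brute_force_shapley(predict, x_row, background, n_feat):
    """Exact interventional Shapley values by coalition enumeration."""
    import math

    def value(subset):
        data = background.copy()
        for j in subset:
            data[:, j] = x_row[j]
        return predict(data).mean(axis=0)

    phis = []
    for i in range(n_feat):
        others = [j for j in range(n_feat) if j != i]
        phi = 0.0
        for r in range(len(others) + 1):
            for s in itertools.combinations(others, r):
                w = (
                    math.factorial(len(s))
                    * math.factorial(n_feat - len(s) - 1)
                    / math.factorial(n_feat)
                )
                phi = phi + w * (value(s + (i,)) - value(s))
        phis.append(phi)
    return np.array(phis)  # (n_feat, n_class)


class TestDirectionalImportance:
    def test_zero_attribution_feature_scores_zero(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 3)),
                         columns=list("abc"))
        attr = np.zeros((50, 2, 3))
        attr[:, :, 0] = np.linspace(-1, 1, 50)[:, None]
        imp = classifier.directional_importance(x, attr, classes=("down", "none"))
        assert (imp.loc["b"] == 0).all() and (imp.loc["c"] == 0).all()
        assert imp.abs().max().max() == 1.0

    def test_importance_invariant_to_observation_order(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        attr = rng.normal(size=(60, 3, 3))
        imp1 = classifier.directional_importance(x, attr)
        perm = rng.permutation(60)
        imp2 = classifier.directional_importance(
            x.iloc[perm].reset_index(drop=True), attr[perm]
        )
        pd.testing.assert_frame_equal(imp1, imp2)

    def test_shape_mismatch_rejected(self):
        x = pd.DataFrame(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            classifier.directional_importance(x, np.zeros((10, 3, 4)))

    def test_tree_attributions_agree_with_exact_shapley(self):
        """Signs and rankings match brute-force Shapley on a 3-feature model."""
        import xgboost as xgb

        rng = np.random.default_rng(5)
        n = 400
        x = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "c": rng.normal(size=n),
            }
        )
        # additive ground truth: a strong positive, b weaker negative, c inert
        latent = 2.0 * x["a"] - 1.0 * x["b"]
        y = pd.Series(
            np.where(latent > 1, "up", np.where(latent < -1, "down", "none")),
            index=x.index,
        )
        ev = classifier.train_eval(x, y, seed=0)
        attr = classifier.tree_attributions(ev.model, x)
        imp_tree = classifier.directional_importance(x, attr)

        booster = ev.model.get_booster()

        def predict_margin(data):
            return booster.predict(xgb.DMatrix(data), output_margin=True)

        background = x.to_numpy()[:60]
        sample_idx = np.arange(0, n, 16)
        exact = np.stack(
            [
                brute_force_shapley(predict_margin, x.to_numpy()[i], background, 3)
                for i in sample_idx
            ]
        )  # (n_sample, n_feat, n_class)
        imp_exact = classifier.directional_importance(
            x.iloc[sample_idx].reset_index(drop=True),
            np.transpose(exact, (0, 2, 1)),
        )
        for cls in imp_tree.columns:
            te, ex = imp_tree[cls], imp_exact[cls]
            # feature ranking by magnitude agrees
            assert list(te.abs().sort_values().index) == list(
                ex.abs().sort_values().index
            )
            # signs agree on the informative features
            for f in ("a", "b"):
                assert np.sign(te[f]) == np.sign(ex[f])
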