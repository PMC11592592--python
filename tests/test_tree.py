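"""SVM-split decision tree: gains, stopping rules, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from mirdescribe.tree import (
    Description,
    LatentDescriptionTree,
    TreeConfig,
    extract_descriptions,
    fit_split_svm,
    information_gain,
    make_split,
    predict_tree,
)


def test_information_gain_pure_split():
    assert information_gain([1, 1, 0, 0], [1, 1], [0, 0]) == pytest.approx(1.0)


def test_information_gain_uninformative_split():
    # children keep the parent's 50/50 proportions
    gain = information_gain([1, 0, 1, 0], [1, 0], [1, 0])
    assert gain == pytest.approx(0.0, abs=1e-12)


def test_information_gain_closed_form():
    # parent (6,2): H = -(0.75 log 0.75 + 0.25 log 0.25)
    # split (4,0) / (2,2): weighted child entropy = 0.5 * 1.0
    y = [1] * 6 + [0] * 2
    left, right = [1] * 4, [1, 1, 0, 0]
    h_parent = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
    assert information_gain(y, left, right) == pytest.approx(h_parent - 0.5)


def test_information_gain_errors():
    with pytest.raises(ValueError, match="empty"):
        information_gain([], [], [])
    with pytest.raises(ValueError, match="partition"):
        information_gain([1, 0], [1], [])


def test_fit_split_svm_separable():
    rng = np.random.default_rng(0)
    z = rng.normal(size=(100, 2))
    feat = (z[:, 0] > 0).astype(int)
    svm, acc = fit_split_svm(z, feat, TreeConfig())
    assert acc == 1.0


def test_fit_split_svm_single_valued_feature():
    z = np.random.default_rng(0).normal(size=(20, 2))
    assert fit_split_svm(z, np.ones(20, dtype=int), TreeConfig()) is None


def test_fit_split_svm_conflicting_duplicates():
    z = np.zeros((10, 2))
    feat = np.array([0, 1] * 5)
    svm, acc = fit_split_svm(z, feat, TreeConfig())
    assert acc < 1.0


def test_random_features_rejected_by_accuracy_gate():
    """A feature independent of z is almost never predictable above 0.8."""
    rng = np.random.default_rng(1)
    rejected = 0
    for _ in range(40):
        z = rng.normal(size=(200, 2))
        feat = rng.integers(0, 2, 200)
        _, acc = fit_split_svm(z, feat, TreeConfig())
        rejected += acc <= 0.8
    assert rejected >= 38


def test_pure_node_is_leaf_regardless_of_depth():
    z = np.random.default_rng(0).normal(size=(50, 2))
    f = pd.DataFrame({"a": (z[:, 0] > 0).astype(int)})
    node = make_split(z, np.ones(50, dtype=int), f, TreeConfig())
    assert node.is_leaf and node.majority == 1


def test_min_samples_stopping():
    z = np.random.default_rng(0).normal(size=(9, 2))
    y = (z[:, 0] > 0).astype(int)
    f = pd.DataFrame({"a": y})
    node = make_split(z, y, f, TreeConfig(min_samples=10))
    assert node.is_leaf


def test_max_depth_stopping():
    rng = np.random.default_rng(2)
    z = rng.normal(size=(300, 2))
    y = ((z[:, 0] > 0) ^ (z[:, 1] > 0)).astype(int)  # needs two splits
    f = pd.DataFrame({"a": (z[:, 0] > 0).astype(int),
                      "b": (z[:, 1] > 0).astype(int)})
    res = LatentDescriptionTree(z, y, f, TreeConfig(max_depth=1)).fit()
    assert res.depth() <= 1


def test_signal_feature_beats_noise_feature():
    rng = np.random.default_rng(3)
    z = rng.normal(size=(400, 2))
    z[:, 0] += np.sign(z[:, 0]) * 0.5  # margin so the SVM separates exactly
    y = (z[:, 0] > 0).astype(int)
    f = pd.DataFrame({"noise": rng.integers(0, 2, 400), "signal": y})
    res = LatentDescriptionTree(z, y, f, TreeConfig()).fit()
    assert res.root.split_feature_name == "signal"
    assert res.training_accuracy == 1.0
    # exhaustive re-check: no qualifying feature has higher gain
    for name in f.columns:
        fitted = fit_split_svm(z, f[name].to_numpy(), TreeConfig())
        if fitted is None:
            continue
        svm, acc = fitted
        if acc <= 0.8:
            continue
        pred = svm.predict(z)
        gain = information_gain(y, y[pred == 0], y[pred == 1])
        assert gain <= res.root.split_gain + 1e-12


def test_no_qualifying_feature_gives_leaf():
    rng = np.random.default_rng(4)
    z = rng.normal(size=(100, 2))
    y = rng.integers(0, 2, 100)
    f = pd.DataFrame({"noise": rng.integers(0, 2, 100)})
    node = make_split(z, y, f, TreeConfig())
    assert node.is_leaf


def _id3_oracle(f: pd.DataFrame, y: np.ndarray, cfg: TreeConfig, depth=0):
    """Plain information-gain tree built directly on binary features;
    independent reference for the latent tree when z equals the features."""
    counts = np.bincount(y, minlength=2)
    if (depth >= cfg.max_depth or len(y) < cfg.min_samples
            or counts.max() == len(y)):
        return {"leaf": True, "counts": counts.tolist()}
    best_gain, best_name = 0.0, None
    for name in f.columns:
        col = f[name].to_numpy()
        if len(np.unique(col)) < 2:
            continue
        gain = information_gain(y, y[col == 0], y[col == 1])
        if gain > best_gain:
            best_gain, best_name = gain, name
    if best_name is None:
        return {"leaf": True, "counts": counts.tolist()}
    col = f[best_name].to_numpy()
    return {
        "leaf": False, "feature": best_name, "gain": best_gain,
        "left": _id3_oracle(f[col == 0], y[col == 0], cfg, depth + 1),
        "right": _id3_oracle(f[col == 1], y[col == 1], cfg, depth + 1),
    }


def _compare_trees(node, oracle):
    if oracle["leaf"]:
        assert node.is_leaf
        assert node.class_counts.tolist() == oracle["counts"]
        return
    assert not node.is_leaf
    assert node.split_feature_name == oracle["feature"]
    assert node.split_gain == pytest.approx(oracle["gain"], abs=1e-12)
    _compare_trees(node.left, oracle["left"])
    _compare_trees(node.right, oracle["right"])


def test_oracle_equivalence_on_separable_latents():
    """With z equal to the binary feature matrix, the SVM tree reproduces a
    plain information-gain tree exactly (features are axis-separable)."""
    rng = np.random.default_rng(5)
    n = 500
    f = pd.DataFrame({
        "a": rng.integers(0, 2, n), "b": rng.integers(0, 2, n),
        "c": rng.integers(0, 2, n),
    })
    y = ((f["a"] == 1) & ((f["b"] == 1) | (f["c"] == 0))).to_numpy().astype(int)
    cfg = TreeConfig(max_depth=4)
    res = LatentDescriptionTree(f.to_numpy().astype(float), y, f, cfg).fit()
    oracle = _id3_oracle(f, y, cfg)
    _compare_trees(res.root, oracle)
    assert res.training_accuracy == 1.0


def test_determinism_under_fixed_seed():
    rng = np.random.default_rng(6)
    z = rng.normal(size=(200, 4))
    y = (z[:, 0] + 0.3 * z[:, 1] > 0).astype(int)
    f = pd.DataFrame({"a": y, "b": (z[:, 2] > 0).astype(int)})
    r1 = LatentDescriptionTree(z, y, f, TreeConfig(seed=3)).fit()
    r2 = LatentDescriptionTree(z, y, f, TreeConfig(seed=3)).fit()
    assert r1.to_json() == r2.to_json()


def test_predict_routes_and_paths():
    rng = np.random.default_rng(7)
    z = rng.normal(size=(300, 2))
    z[:, 0] += np.sign(z[:, 0]) * 0.5
    y = (z[:, 0] > 0).astype(int)
    f = pd.DataFrame({"a": y})
    res = LatentDescriptionTree(z, y, f, TreeConfig()).fit()
    labels, paths = predict_tree(res.root, z)
    assert np.array_equal(labels, y)
    assert all(p == [("a", int(lbl))] for p, lbl in zip(paths, labels))


def test_depth_zero_tree_predicts_majority():
    z = np.random.default_rng(8).normal(size=(30, 2))
    y = np.array([1] * 20 + [0] * 10)
    node = make_split(z, y, pd.DataFrame(index=range(30)), TreeConfig())
    assert node.is_leaf
    labels, _ = predict_tree(node, z)
    assert (labels == 1).all()


def test_descriptions_from_pure_positive_root():
    node = make_split(np.zeros((20, 2)), np.ones(20, dtype=int),
                      pd.DataFrame(index=range(20)), TreeConfig())
    descs = extract_descriptions(node)
    assert len(descs) == 1 and descs[0].conditions == []
    assert "no conditions" in descs[0].render()


def test_all_negative_tree_has_no_descriptions():
    node = make_split(np.zeros((20, 2)), np.zeros(20, dtype=int),
                      pd.DataFrame(index=range(20)), TreeConfig())
    assert extract_descriptions(node) == []


def test_config_validation():
    with pytest.raises(ValueError):
        TreeConfig(max_depth=0)
    with pytest.raises(ValueError):
        TreeConfig(min_samples=1)
    with pytest.raises(ValueError):
        TreeConfig(min_acc=0.0)


def test_json_and_dot_serialization():
    rng = np.random.default_rng(9)
    z = rng.normal(size=(100, 2))
    y = (z[:, 0] > 0).astype(int)
    f = pd.DataFrame({"a": y})
    res = LatentDescriptionTree(z, y, f, TreeConfig()).fit()
    blob = res.to_json()
    assert '"feature": "a"' in blob
    dot = res.to_dot()
    assert dot.startswith("digraph") and '"0"' in dot
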