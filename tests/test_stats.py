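"""Univariate screen, volcano/heatmap tables, PCA, PLS-DA, load correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import silhouette_score

from gslscreen.stats import (
    correlate_with_load,
    pca,
    plsda,
    significance_heatmap,
    univariate_screen,
    volcano_table,
)


def _two_group_values(n=10, n_lipids=5, delta=0.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(delta, 1.0, (n, n_lipids))
    b = rng.normal(0.0, 1.0, (n, n_lipids))
    idx = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
    values = pd.DataFrame(np.vstack([a, b]), index=idx,
                          columns=[f"GM3 d{34+2*j}:1" for j in range(n_lipids)])
    return values, idx[:n], idx[n:]


def test_identical_groups_give_null_result():
    values, ids_a, ids_b = _two_group_values(seed=1)
    values.loc[ids_b] = values.loc[ids_a].to_numpy()
    res = univariate_screen(values, ids_a, ids_b)
    assert np.allclose(res["log2_fc"], 0.0)
    assert np.allclose(res["p_value"], 1.0)
    assert (res["adj_p"] >= res["p_value"] - 1e-15).all()


def test_log2_fold_change_definition():
    values, ids_a, ids_b = _two_group_values(seed=2)
    values.loc[ids_a] = values.loc[ids_b].to_numpy() + np.log(2.0)
    res = univariate_screen(values, ids_a, ids_b)
    assert np.allclose(res["log2_fc"], 1.0)


def test_welch_matches_scipy_per_lipid():
    values, ids_a, ids_b = _two_group_values(delta=0.8, seed=3)
    res = univariate_screen(values, ids_a, ids_b)
    for j, lipid in enumerate(values.columns):
        t, p = sps.ttest_ind(values.loc[ids_a, lipid], values.loc[ids_b, lipid], equal_var=False)
        assert res.loc[j, "p_value"] == pytest.approx(p, rel=1e-12)


def test_null_rejection_rate_small_monte_carlo():
    rng = np.random.default_rng(10)
    rejections = []
    for _ in range(100):
        values, ids_a, ids_b = _two_group_values(n=10, n_lipids=20, seed=rng.integers(2**31))
        res = univariate_screen(values, ids_a, ids_b, adjust=False)
        rejections.append((res["p_value"] < 0.05).mean())
    assert 0.02 < np.mean(rejections) < 0.08


def test_volcano_flags_strictly_below_threshold():
    res = pd.DataFrame({"lipid": ["a", "b", "c"], "comparison": "x",
                        "log2_fc": [1.0, -1.0, 0.5],
                        "p_value": [0.05, 0.01, 0.2]})
    vol = volcano_table(res, p_threshold=0.05)
    assert list(vol["significant"]) == [False, True, False]
    assert vol.loc[1, "neg_log10_p"] == pytest.approx(2.0)
    # flag count invariant under row permutation
    vol_perm = volcano_table(res.iloc[::-1].reset_index(drop=True))
    assert vol_perm["significant"].sum() == vol["significant"].sum()


def test_heatmap_shape_ordering_and_values():
    res1 = pd.DataFrame({"lipid": ["ST d36:1", "GM3 d36:1"], "comparison": "c1",
                         "p_value": [0.001, 1.0]})
    res2 = pd.DataFrame({"lipid": ["ST d36:1", "GM3 d36:1"], "comparison": "c2",
                         "p_value": [1.0, 0.1]})
    heat = significance_heatmap({"c1": res1, "c2": res2})
    assert list(heat.index) == ["GM3 d36:1", "ST d36:1"]  # class-sorted
    assert heat.loc["ST d36:1", "c1"] == pytest.approx(3.0)
    assert heat.loc["GM3 d36:1", "c1"] == pytest.approx(0.0)
    assert (heat.to_numpy() >= 0).all()


def test_pca_duplicated_samples_and_variance_bounds():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, (6, 8))
    values = pd.DataFrame(np.vstack([x, x]), index=[f"s{i}" for i in range(12)])
    values -= values.mean(axis=0)
    scores, loadings, varexp = pca(values, n_components=2)
    assert np.allclose(scores.iloc[:6].to_numpy(), scores.iloc[6:].to_numpy())
    assert varexp.sum() <= 100.0 + 1e-9
    assert varexp[0] >= varexp[1]
    # orthonormal loadings
    assert np.allclose(loadings.T @ loadings, np.eye(2), atol=1e-10)


def test_pca_separates_synthetic_clusters():
    rng = np.random.default_rng(5)
    n, p = 20, 30
    shift = np.zeros(p)
    shift[: int(0.3 * p)] = 2.0  # 2 sd on 30% of lipids
    x = np.vstack([rng.normal(0, 1, (n, p)), rng.normal(shift, 1.0, (n, p))])
    values = pd.DataFrame(x)
    values -= values.mean(axis=0)
    scores, _, _ = pca(values, n_components=2)
    labels = np.array([0] * n + [1] * n)
    assert silhouette_score(scores[["PC1"]], labels) > 0.5


def test_pca_rejects_excess_components():
    values = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)))
    with pytest.raises(ValueError, match="n_components"):
        pca(values, n_components=5)


def test_pca_scores_invariant_to_column_order():
    rng = np.random.default_rng(6)
    values = pd.DataFrame(rng.normal(size=(15, 10)),
                          columns=[f"L{j}" for j in range(10)])
    values -= values.mean(axis=0)
    s1, _, _ = pca(values)
    s2, _, _ = pca(values[values.columns[::-1]])
    assert np.allclose(np.abs(s1.to_numpy()), np.abs(s2.to_numpy()), atol=1e-8)


def test_plsda_separates_separable_classes():
    rng = np.random.default_rng(7)
    a = rng.normal(0, 0.5, (8, 12)) + 3.0
    b = rng.normal(0, 0.5, (8, 12))
    values = pd.DataFrame(np.vstack([a, b]))
    values -= values.mean(axis=0)
    labels = ["TG"] * 8 + ["CN"] * 8
    scores, _ = plsda(values, labels, n_components=2)
    lv1_a, lv1_b = scores.iloc[:8, 0], scores.iloc[8:, 0]
    assert min(lv1_a) > max(lv1_b) or min(lv1_b) > max(lv1_a)  # zero overlap


def test_plsda_separation_shrinks_under_label_permutation():
    rng = np.random.default_rng(8)
    a = rng.normal(0.8, 1.0, (10, 15))
    b = rng.normal(0.0, 1.0, (10, 15))
    values = pd.DataFrame(np.vstack([a, b]))
    values -= values.mean(axis=0)
    labels = np.array(["TG"] * 10 + ["CN"] * 10)

    def sep(lab):
        scores, _ = plsda(values, lab, n_components=1)
        lv1 = scores.iloc[:, 0].to_numpy()
        return abs(lv1[lab == "TG"].mean() - lv1[lab == "CN"].mean()) / lv1.std()

    true_sep = sep(labels)
    perm_seps = [sep(rng.permutation(labels)) for _ in range(20)]
    assert true_sep > np.percentile(perm_seps, 95)


def test_plsda_one_component_and_class_validation():
    values = pd.DataFrame(np.random.default_rng(9).normal(size=(8, 5)))
    scores, _ = plsda(values, ["a"] * 4 + ["b"] * 4, n_components=1)
    assert scores.shape == (8, 1)
    with pytest.raises(ValueError, match="two classes"):
        plsda(values, ["a"] * 8, n_components=1)


def test_correlation_exact_linear_and_affine_invariance():
    rng = np.random.default_rng(11)
    cov = pd.Series(rng.normal(0, 1, 12), index=[f"s{i}" for i in range(12)])
    values = pd.DataFrame({"GM3 d42:2": 3.0 * cov + 1.0}, index=cov.index)
    res = correlate_with_load(values, cov)
    assert res.loc[0, "r"] == pytest.approx(1.0)
    assert res.loc[0, "p_value"] == pytest.approx(0.0, abs=1e-12)
    res2 = correlate_with_load(values, cov * 7.0 - 2.0)
    assert res2.loc[0, "r"] == pytest.approx(res.loc[0, "r"])


def test_correlation_matches_scipy_pearsonr():
    rng = np.random.default_rng(12)
    idx = [f"s{i}" for i in range(18)]
    values = pd.DataFrame(rng.normal(size=(18, 6)), index=idx)
    cov = pd.Series(rng.normal(size=18), index=idx)
    res = correlate_with_load(values, cov)
    for j in range(6):
        r, p = sps.pearsonr(values.iloc[:, j], cov)
        assert res.loc[j, "r"] == pytest.approx(r, rel=1e-10)
        assert res.loc[j, "p_value"] == pytest.approx(p, rel=1e-8)


def test_independent_covariate_gives_small_r():
    rng = np.random.default_rng(13)
    idx = [f"s{i}" for i in range(1000)]
    values = pd.DataFrame({"x": rng.normal(size=1000)}, index=idx)
    cov = pd.Series(rng.normal(size=1000), index=idx)
    res = correlate_with_load(values, cov)
    assert abs(res.loc[0, "r"]) < 0.1


def test_zero_variance_covariate_rejected():
    values = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=list("abc"))
    with pytest.raises(ValueError, match="variance"):
        correlate_with_load(values, pd.Series([5.0, 5.0, 5.0], index=list("abc")))
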