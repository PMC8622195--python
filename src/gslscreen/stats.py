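"""Screening statistics: per-lipid univariate tests, volcano/heatmap
tables, PCA, PLS-DA, and correlation with a pathology-load covariate.

Inputs are ln-transformed, mean-centered samples x lipids tables, so group
mean differences are natural-log fold changes; they are reported on the
log2 scale (log2FC = Delta-ln / ln 2).  The default per-lipid test is
Welch's two-sample t-test; Benjamini-Hochberg adjusted p-values are
reported alongside, while the reproduction-mode significance flag follows
the raw p < 0.05 convention of the original screen.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SKPCA
from statsmodels.stats.multitest import multipletests

from .library import parse_shorthand

__all__ = [
    "univariate_screen",
    "volcano_table",
    "significance_heatmap",
    "pca",
    "plsda",
    "correlate_with_load",
]

_LN2 = float(np.log(2.0))


def univariate_screen(
    values: pd.DataFrame,
    group_a: Sequence,
    group_b: Sequence,
    comparison: str = "A vs B",
    adjust: bool = True,
) -> pd.DataFrame:
    """Welch two-sample t-test per lipid on ln-scale values.

    ``group_a`` / ``group_b`` are sample-index labels; the effect size is
    ``log2_fc = (mean_a - mean_b) / ln 2``.  Degenerate lipids with zero
    variance in both groups get p = 1 when the means agree and p = 0
    otherwise.

    Returns a table with columns lipid, comparison, log2_fc, p_value,
    adj_p (Benjamini-Hochberg), n_a, n_b.
    """
    a = values.loc[list(group_a)].to_numpy(dtype=float)
    b = values.loc[list(group_b)].to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 samples per group for a Welch t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=False)
    diff = a.mean(axis=0) - b.mean(axis=0)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate & (np.abs(diff) < 1e-12)] = 1.0
    p[degenerate & (np.abs(diff) >= 1e-12)] = 0.0
    adj = multipletests(p, method="fdr_bh")[1] if adjust else p.copy()
    return pd.DataFrame(
        {
            "lipid": values.columns,
            "comparison": comparison,
            "log2_fc": diff / _LN2,
            "p_value": p,
            "adj_p": adj,
            "n_a": a.shape[0],
            "n_b": b.shape[0],
        }
    )


def volcano_table(results: pd.DataFrame, p_threshold: float = 0.05) -> pd.DataFrame:
    """Plot-ready volcano columns: log2_fc, -log10 p, strict-threshold flag."""
    if results.empty:
        raise ValueError("empty results table")
    out = results.copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"].to_numpy(dtype=float))
    out["significant"] = out["p_value"] < p_threshold
    return out


def _lipid_sort_key(shorthand: str) -> tuple:
    try:
        sp = parse_shorthand(shorthand)
        return (0, sp.headgroup.class_name, sp.ceramide.base_type,
                sp.ceramide.carbons, sp.ceramide.double_bonds)
    except ValueError:
        return (1, shorthand, "", 0, 0)


def significance_heatmap(results_by_comparison: Mapping[str, pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Lipids x comparisons matrix of -log10 p, rows ordered by class then shorthand."""
    if isinstance(results_by_comparison, pd.DataFrame):
        frames = [results_by_comparison]
    else:
        frames = list(results_by_comparison.values())
    if not frames:
        raise ValueError("need at least one comparison")
    long = pd.concat(frames, ignore_index=True)
    with np.errstate(divide="ignore"):
        long["neg_log10_p"] = -np.log10(long["p_value"].to_numpy(dtype=float))
    heat = long.pivot_table(index="lipid", columns="comparison", values="neg_log10_p")
    heat = heat.loc[sorted(heat.index, key=_lipid_sort_key)]
    return heat


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # sign convention: the largest-magnitude loading of each component is positive
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return scores, loadings


def pca(values: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Principal component analysis of a centered samples x lipids table.

    Returns (scores, loadings, variance explained in percent).  Loadings
    are orthonormal; each component's sign is fixed so its largest-
    magnitude loading is positive.
    """
    max_k = min(values.shape)
    if n_components > max_k:
        raise ValueError(f"n_components={n_components} exceeds min(n_samples, n_lipids)={max_k}")
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(values.to_numpy(dtype=float))
    loadings = model.components_.T.copy()
    scores, loadings = _fix_signs(scores, loadings)
    cols = [f"PC{i+1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=values.index, columns=cols),
        pd.DataFrame(loadings, index=values.columns, columns=cols),
        model.explained_variance_ratio_ * 100.0,
    )


def plsda(
    values: pd.DataFrame,
    labels: Sequence,
    n_components: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-class PLS-DA via NIPALS partial least squares.

    The class factor is coded as a +/-1 indicator response and decomposed
    with iterative latent variables; deterministic for a given row order.
    Returns (x-scores, x-loadings) with the same sign convention as
    :func:`pca`.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"PLS-DA requires exactly two classes, got {list(classes)}")
    counts = [(labels == c).sum() for c in classes]
    if min(counts) < 3:
        raise ValueError("PLS-DA requires >= 3 samples per class")
    y = np.where(labels == classes[0], 1.0, -1.0)
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(values.to_numpy(dtype=float), y)
    scores = model.x_scores_.copy()
    loadings = model.x_loadings_.copy()
    scores, loadings = _fix_signs(scores, loadings)
    cols = [f"LV{i+1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=values.index, columns=cols),
        pd.DataFrame(loadings, index=values.columns, columns=cols),
    )


def correlate_with_load(
    values: pd.DataFrame,
    covariate: pd.Series | Sequence[float],
    covariate_name: str = "tau_load",
) -> pd.DataFrame:
    """Pearson correlation of every lipid with a numeric pathology covariate.

    Samples with a missing covariate are dropped; requires >= 3 remaining
    and a non-constant covariate.  Two-sided p-values come from the exact
    t transform of r with n - 2 degrees of freedom.
    """
    cov = pd.Series(covariate, index=values.index if not isinstance(covariate, pd.Series) else None)
    if isinstance(covariate, pd.Series):
        cov = covariate
    cov = cov.reindex(values.index).astype(float)
    keep = cov.notna()
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"covariate present for only {n} samples; need >= 3")
    x = cov[keep].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")
    y = values.loc[keep].to_numpy(dtype=float)
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[~np.isfinite(r)] = np.nan
    return pd.DataFrame(
        {
            "lipid": values.columns,
            "covariate": covariate_name,
            "r": r,
            "p_value": p,
            "n": n,
        }
    )
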