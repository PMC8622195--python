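"""Data-reduction chain for semi-targeted lipidomic screens.

The fixed stage order mirrors the standard pooled-QC workflow:

1. QC-based LOESS drift correction (per lipid, against injection order);
2. QC coefficient-of-variation filter (default: drop CV > 30%);
3. tissue-weight correction of study samples;
4. natural-log transform and per-lipid mean centering.

All stages operate on an :class:`IntensityMatrix` (samples x lipids values
plus sample metadata) and emit structured log records; the runner
:func:`preprocess_pipeline` enforces the order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "PreprocessResult",
    "loess_fit",
    "qc_loess_correct",
    "cv_filter",
    "weight_correct",
    "ln_center",
    "preprocess_pipeline",
]

REQUIRED_META = ("group", "age_months", "weight_mg", "injection_order", "sample_type")


@dataclass
class IntensityMatrix:
    """Samples x lipids intensities with per-sample study metadata.

    ``samples`` is indexed by sample id and carries ``group`` (TG/CN/QC),
    ``age_months``, ``weight_mg``, ``injection_order`` (a permutation of
    1..n) and ``sample_type`` ("study" or "QC").
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_META if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing column(s): {', '.join(missing)}")
        if not self.values.index.equals(self.samples.index):
            self.samples = self.samples.loc[self.values.index]

    def validate(self) -> None:
        order = np.sort(self.samples["injection_order"].to_numpy())
        n = len(self.samples)
        if not np.array_equal(order, np.arange(1, n + 1)):
            raise ValueError("injection_order must be a permutation of 1..n_samples")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        study = self.samples["sample_type"] == "study"
        w = self.samples.loc[study, "weight_mg"]
        bad = w.index[~(w > 0)].tolist()
        if bad:
            raise ValueError(f"non-positive weight_mg for sample(s): {', '.join(map(str, bad))}")

    @property
    def qc_ids(self) -> pd.Index:
        return self.samples.index[self.samples["sample_type"] == "QC"]

    @property
    def study_ids(self) -> pd.Index:
        return self.samples.index[self.samples["sample_type"] == "study"]

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.samples.copy())


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    eval_x: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial (LOESS) fit with tricube weights.

    For each evaluation point the ``ceil(span * n)`` nearest anchors get
    tricube weights and a weighted degree-``degree`` polynomial is fitted.
    Evaluation points outside the anchor range are clamped to the nearest
    anchor position (nearest-fitted-value extrapolation).  The anchor count
    caps the effective degree, so tiny QC sets degrade gracefully to
    linear/constant fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    eval_x = np.asarray(eval_x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 anchor points for a LOESS fit")
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)
    xe = np.clip(eval_x, x.min(), x.max())
    out = np.empty(len(xe))
    for i, x0 in enumerate(xe):
        d = np.abs(x - x0)
        h = np.sort(d)[q - 1]
        if h <= 0:
            # all usable anchors coincide with x0
            out[i] = y[d == 0].mean()
            continue
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        use = w > 0
        deg = min(degree, max(int(use.sum()) - 1, 0))
        coeffs = np.polynomial.polynomial.polyfit(x[use] - x0, y[use], deg, w=np.sqrt(w[use]))
        out[i] = coeffs[0]
    return out


def qc_loess_correct(
    matrix: IntensityMatrix,
    span: float = 0.75,
    degree: int = 2,
) -> tuple[IntensityMatrix, pd.DataFrame, list[dict]]:
    """Remove injection-order drift using the pooled-QC signal.

    Per lipid, a LOESS curve is fitted to QC intensities versus injection
    order and every sample's intensity is divided by the fitted value at
    its injection position, rescaled so the median QC intensity of that
    lipid is preserved.  If the LOESS curve dips to zero or below anywhere,
    the lipid falls back to a straight-line fit (logged); if that also
    fails the lipid is left uncorrected (logged).

    Returns (corrected matrix, drift curves table indexed by injection
    position, log records).
    """
    qcs = matrix.qc_ids
    if len(qcs) < 3:
        raise ValueError(f"QC-LOESS correction requires >= 3 QC samples, found {len(qcs)}")
    inj = matrix.samples["injection_order"].astype(float)
    qc_x = inj.loc[qcs].to_numpy()
    all_x = inj.to_numpy()

    corrected = matrix.values.astype(float).copy()
    curves = {}
    log: list[dict] = []
    for lipid in matrix.values.columns:
        qc_y = matrix.values.loc[qcs, lipid].to_numpy(dtype=float)
        fitted = loess_fit(qc_x, qc_y, all_x, span=span, degree=degree)
        if np.any(fitted <= 0):
            coeffs = np.polynomial.polynomial.polyfit(qc_x, qc_y, 1)
            fitted = np.polynomial.polynomial.polyval(all_x, coeffs)
            log.append({"stage": "loess", "lipid": lipid, "event": "linear_fallback"})
            if np.any(fitted <= 0):
                log.append({"stage": "loess", "lipid": lipid, "event": "uncorrectable"})
                curves[lipid] = np.ones_like(all_x)
                continue
        ratio = matrix.values[lipid].to_numpy(dtype=float) / fitted
        qc_ratio = ratio[matrix.samples["sample_type"].to_numpy() == "QC"]
        med_raw = float(np.median(qc_y))
        med_ratio = float(np.median(qc_ratio))
        scale = med_raw / med_ratio if med_ratio > 0 else med_raw
        corrected[lipid] = ratio * scale
        curves[lipid] = fitted
    drift = pd.DataFrame(curves, index=matrix.values.index)
    drift.insert(0, "injection_order", all_x.astype(int))
    return IntensityMatrix(corrected, matrix.samples.copy()), drift, log


def qc_cv(matrix: IntensityMatrix) -> pd.Series:
    """Per-lipid coefficient of variation (sd/mean) over QC samples."""
    qcs = matrix.qc_ids
    if len(qcs) < 3:
        raise ValueError(f"QC CV requires >= 3 QC samples, found {len(qcs)}")
    qc_vals = matrix.values.loc[qcs]
    mean = qc_vals.mean(axis=0)
    sd = qc_vals.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    return cv.replace([np.inf, -np.inf], np.nan)


def cv_filter(
    matrix: IntensityMatrix, threshold: float = 0.30
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Drop lipids whose pooled-QC CV exceeds ``threshold`` (default 30%).

    Returns the filtered matrix and a report with every lipid's QC CV and
    exclusion flag.  Lipids with undefined CV (zero QC mean) are excluded.
    """
    cv = qc_cv(matrix)
    excluded = cv.isna() | (cv > threshold)
    report = pd.DataFrame({"lipid": cv.index, "qc_cv": cv.to_numpy(), "excluded": excluded.to_numpy()})
    kept = matrix.values.loc[:, ~excluded.to_numpy()]
    return IntensityMatrix(kept.copy(), matrix.samples.copy()), report


def weight_correct(matrix: IntensityMatrix) -> IntensityMatrix:
    """Divide study-sample intensities by tissue weight (mg); QCs untouched."""
    study = matrix.study_ids
    w = matrix.samples.loc[study, "weight_mg"]
    bad = [str(s) for s in w.index[~(w > 0) | w.isna()]]
    if bad:
        raise ValueError(f"missing or non-positive weight_mg for sample(s): {', '.join(bad)}")
    values = matrix.values.astype(float).copy()
    values.loc[study] = values.loc[study].div(w, axis=0)
    return IntensityMatrix(values, matrix.samples.copy())


def ln_center(
    matrix: IntensityMatrix,
    impute_half_min: bool = True,
    max_missing_frac: float = 0.5,
) -> tuple[IntensityMatrix, list[dict]]:
    """Natural-log transform then per-lipid mean centering.

    Zeros are imputed at half the smallest positive value of the lipid
    (logged); lipids missing/zero in more than ``max_missing_frac`` of the
    study samples are dropped with a warning record.  Any non-positive
    value remaining after imputation raises.
    """
    values = matrix.values.astype(float).copy()
    log: list[dict] = []
    study = matrix.study_ids
    drop = []
    for lipid in values.columns:
        col = values[lipid]
        missing_frac = float((col.loc[study] <= 0).mean()) if len(study) else 0.0
        if missing_frac > max_missing_frac:
            drop.append(lipid)
            log.append({"stage": "ln_center", "lipid": lipid, "event": "dropped_missing",
                        "missing_frac": missing_frac})
            continue
        n_zero = int((col <= 0).sum())
        if n_zero:
            if not impute_half_min:
                raise ValueError(f"non-positive intensity in lipid {lipid!r} and imputation disabled")
            positive = col[col > 0]
            if positive.empty:
                drop.append(lipid)
                log.append({"stage": "ln_center", "lipid": lipid, "event": "dropped_all_zero"})
                continue
            values.loc[col <= 0, lipid] = positive.min() / 2.0
            log.append({"stage": "ln_center", "lipid": lipid, "event": "imputed_half_min",
                        "n_imputed": n_zero})
    values = values.drop(columns=drop)
    if (values.to_numpy() <= 0).any():
        raise ValueError("non-positive value after imputation; cannot ln-transform")
    transformed = np.log(values)
    centered = transformed - transformed.mean(axis=0)
    return IntensityMatrix(centered, matrix.samples.copy()), log


@dataclass
class PreprocessResult:
    matrix: IntensityMatrix
    drift_curves: pd.DataFrame
    cv_report: pd.DataFrame
    log: list[dict] = field(default_factory=list)


def preprocess_pipeline(
    matrix: IntensityMatrix,
    span: float = 0.75,
    degree: int = 2,
    cv_threshold: float = 0.30,
    apply_weight_correction: bool = True,
) -> PreprocessResult:
    """Run the fixed chain LOESS -> CV filter -> weight -> ln + centering."""
    matrix.validate()
    log: list[dict] = []

    corrected, drift, loess_log = qc_loess_correct(matrix, span=span, degree=degree)
    log.append({"stage": "qc_loess", "n_lipids": corrected.values.shape[1],
                "n_fallback": sum(1 for r in loess_log if r["event"] == "linear_fallback")})
    log.extend(loess_log)

    filtered, cv_report = cv_filter(corrected, threshold=cv_threshold)
    log.append({"stage": "cv_filter", "n_in": corrected.values.shape[1],
                "n_excluded": int(cv_report["excluded"].sum()),
                "n_out": filtered.values.shape[1]})

    if apply_weight_correction:
        filtered = weight_correct(filtered)
        log.append({"stage": "weight_correct", "n_samples": len(filtered.study_ids)})

    final, ln_log = ln_center(filtered)
    log.append({"stage": "ln_center", "n_lipids": final.values.shape[1]})
    log.extend(ln_log)

    return PreprocessResult(final, drift, cv_report, log)
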