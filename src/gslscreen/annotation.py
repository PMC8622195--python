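"""Accurate-mass annotation of MS1 features against the in-silico library.

Observed features (m/z, retention time, charge, per-sample intensities) are
matched to theoretical deprotonated ions within a signed-ppm tolerance
(default +/-10 ppm, the positive-identification threshold used for the
screen).  Candidates are ranked by absolute ppm error; an optional HILIC
retention-time plausibility re-ranking is available but never rejects a
mass match.  The module also predicts aggregated isotopologue patterns from
elemental formulas and removes the M+2 overlap that a species casts onto
its one-double-bond-less neighbour at the same nominal m/z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import IonSpecies, parse_shorthand

__all__ = [
    "Feature",
    "Annotation",
    "ppm_error",
    "match_features",
    "annotation_table",
    "isotope_pattern",
    "isotope_correct",
]


@dataclass
class Feature:
    """An MS1 feature: centroid m/z, retention time, charge, intensities."""

    feature_id: str
    obs_mz: float
    rt: float = float("nan")
    charge: int = 0  # 0 = unknown, matches any library charge state
    intensities: Mapping[str, float] = field(default_factory=dict)


@dataclass
class Annotation:
    """A feature <-> library-ion match within tolerance."""

    feature_id: str
    candidate: IonSpecies
    obs_mz: float
    ppm_error: float
    rank: int


def ppm_error(obs_mz: float, theo_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theo_mz <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theo_mz}")
    return 1e6 * (obs_mz - theo_mz) / theo_mz


def _as_features(features) -> list[Feature]:
    if isinstance(features, pd.DataFrame):
        out = []
        for idx, row in features.iterrows():
            fid = str(row["feature_id"]) if "feature_id" in row else str(idx)
            out.append(
                Feature(
                    feature_id=fid,
                    obs_mz=float(row["mz"]),
                    rt=float(row.get("rt", float("nan"))),
                    charge=int(row.get("charge", 0) or 0),
                )
            )
        return out
    return list(features)


def match_features(
    features,
    library: Sequence[IonSpecies],
    tol_ppm: float = 10.0,
    require_charge_agreement: bool = True,
    rt_rerank: bool = False,
) -> list[Annotation]:
    """Match features to library ions within ``tol_ppm``.

    Every (feature, candidate) pair within tolerance is returned, ranked per
    feature by absolute ppm error (rank 1 = best).  Features with no
    candidate yield a single ``Annotation`` with ``candidate=None`` and
    ``rank=0`` so that unannotated features stay visible downstream.  When
    ``rt_rerank`` is set, ties and near-ties are re-ordered by HILIC
    plausibility (classes with more sialic acids elute later), which never
    adds or removes matches.

    Parameters
    ----------
    features : DataFrame (columns mz [, rt, charge, feature_id]) or list of Feature
    library : sequence of IonSpecies
    tol_ppm : half-width of the signed ppm acceptance window (> 0)
    """
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    feats = _as_features(features)
    if not library:
        warnings.warn("empty ion library: all features reported unannotated")
        return [Annotation(f.feature_id, None, f.obs_mz, float("nan"), 0) for f in feats]

    lib_mz = np.array([ion.theo_mz for ion in library])
    order = np.argsort(lib_mz, kind="stable")
    lib_mz_sorted = lib_mz[order]
    lib_sorted = [library[i] for i in order]

    annotations: list[Annotation] = []
    for f in feats:
        half = f.obs_mz * tol_ppm * 1e-6
        lo = np.searchsorted(lib_mz_sorted, f.obs_mz - half, side="left")
        hi = np.searchsorted(lib_mz_sorted, f.obs_mz + half, side="right")
        cands = []
        for i in range(lo, hi):
            ion = lib_sorted[i]
            if require_charge_agreement and f.charge and ion.charge != f.charge:
                continue
            err = ppm_error(f.obs_mz, ion.theo_mz)
            if abs(err) <= tol_ppm:
                cands.append((ion, err))
        if not cands:
            annotations.append(Annotation(f.feature_id, None, f.obs_mz, float("nan"), 0))
            continue
        if rt_rerank and np.isfinite(f.rt):
            # more sialylated -> later elution; penalty re-orders, never rejects
            cands.sort(key=lambda c: (round(abs(c[1]), 3), -c[0].species.headgroup.n_sialic))
        else:
            cands.sort(key=lambda c: (abs(c[1]), c[0].species.shorthand, c[0].charge))
        # dense competition ranking: exact-isobar ties share a rank
        rank = 0
        prev_abs = None
        for ion, err in cands:
            if prev_abs is None or abs(err) - prev_abs > 1e-3:
                rank += 1
                prev_abs = abs(err)
            annotations.append(Annotation(f.feature_id, ion, f.obs_mz, err, rank))
    return annotations


def annotation_table(annotations: Sequence[Annotation]) -> pd.DataFrame:
    """Flat delimited-table view of annotations (unannotated rows included)."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "feature_id": a.feature_id,
                "shorthand": a.candidate.species.shorthand if a.candidate else "",
                "charge": a.candidate.charge if a.candidate else 0,
                "theo_mz": a.candidate.theo_mz if a.candidate else float("nan"),
                "obs_mz": a.obs_mz,
                "ppm_error": a.ppm_error,
                "rank": a.rank,
            }
        )
    return pd.DataFrame(rows)


# Natural isotope abundances per element, as probability over nominal mass
# shifts 0/1/2 Da relative to the lightest isotope.
_ISOTOPE_SHIFTS: dict[str, np.ndarray] = {
    "C": np.array([0.9893, 0.0107, 0.0]),
    "H": np.array([0.999885, 0.000115, 0.0]),
    "N": np.array([0.99636, 0.00364, 0.0]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425]),
}


def isotope_pattern(formula: Mapping[str, int], n_peaks: int = 3) -> np.ndarray:
    """Aggregated isotopologue abundances M+0 .. M+(n_peaks-1), M+0 = 1.

    Computed by convolving per-element nominal-mass-shift distributions
    (13C, 2H, 15N, 17O/18O, 33S/34S) raised to the atom counts; fine mass
    splits within a nominal shift are aggregated, which is the resolution
    regime relevant for overlap correction at 2- charge states.
    """
    if not formula:
        raise ValueError("empty formula")
    dist = np.zeros(n_peaks)
    dist[0] = 1.0
    for element, count in formula.items():
        if element not in _ISOTOPE_SHIFTS:
            raise ValueError(f"unknown element {element!r} in formula")
        if count < 0:
            raise ValueError(f"negative count for element {element!r}")
        base = _ISOTOPE_SHIFTS[element][:n_peaks]
        # exponentiation by squaring with truncation to n_peaks
        acc = np.zeros(n_peaks)
        acc[0] = 1.0
        power = base.copy()
        k = count
        while k:
            if k & 1:
                acc = np.convolve(acc, power)[:n_peaks]
            power = np.convolve(power, power)[:n_peaks]
            k >>= 1
        dist = np.convolve(dist, acc)[:n_peaks]
    return dist / dist[0]


def isotope_correct(
    values: pd.DataFrame,
    charges: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove M+2 isotopologue overlap between double-bond neighbours.

    At negative-mode charge states the 2H mass split between a species with
    ``db`` double bonds and the M+2 isotopologue of its ``db+1`` neighbour
    (same class, base type and carbon count) is ~9 mDa per charge and may
    not be resolved, so the more-saturated species inherits signal from the
    more-unsaturated one.  Working from most- to least-unsaturated, the
    predicted M+2 contribution (M+2/M+0 abundance ratio x corrected donor
    signal) is subtracted and clipped at zero.

    Parameters
    ----------
    values : samples x lipids intensity table, columns keyed by shorthand
    charges : optional shorthand -> charge map; when given, only pairs with
        equal charge are corrected (columns are otherwise assumed to be
        species-level, charge-aggregated signals)

    Returns
    -------
    (corrected values, report) where the report lists one row per corrected
    column with the donor species and subtracted fraction.
    """
    corrected = values.astype(float).copy()
    groups: dict[tuple, dict[int, str]] = {}
    for col in values.columns:
        try:
            sp = parse_shorthand(col)
        except ValueError:
            continue  # unparseable columns pass through untouched
        key = (sp.headgroup.class_name, sp.ceramide.base_type, sp.ceramide.carbons)
        groups.setdefault(key, {})[sp.ceramide.double_bonds] = col

    report_rows = []
    for key, by_db in groups.items():
        for db in sorted(by_db, reverse=True):
            donor_col = by_db[db]
            acceptor_col = by_db.get(db - 1)
            if acceptor_col is None:
                continue
            if charges is not None and charges.get(donor_col) != charges.get(acceptor_col):
                continue
            donor_sp = parse_shorthand(donor_col)
            ratio = isotope_pattern(donor_sp.formula, 3)[2]
            contribution = ratio * corrected[donor_col]
            corrected[acceptor_col] = (corrected[acceptor_col] - contribution).clip(lower=0.0)
            report_rows.append(
                {
                    "corrected": acceptor_col,
                    "donor": donor_col,
                    "m2_over_m0": ratio,
                    "mean_subtracted": float(contribution.mean()),
                }
            )
    report = pd.DataFrame(report_rows, columns=["corrected", "donor", "m2_over_m0", "mean_subtracted"])
    return corrected, report
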