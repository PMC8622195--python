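"""Delimited-table and MGF input/output.

All tabular interchange uses tab-separated files with documented headers;
intensity matrices travel as a values table (rows = samples) plus a sample
metadata sidecar.  MS/MS peak lists use MGF via pyteomics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .fragmentation import MsmsSpectrum
from .preprocess import REQUIRED_META, IntensityMatrix

__all__ = [
    "read_table",
    "write_table",
    "read_features",
    "read_intensity_matrix",
    "write_intensity_matrix",
    "read_mgf",
    "write_mgf",
]

FEATURE_REQUIRED = ("mz",)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    """Read an MS1 feature table (columns: mz [, rt, charge, feature_id,
    one intensity column per sample])."""
    df = read_table(path)
    _require_columns(df, FEATURE_REQUIRED, f"feature table {path}")
    if "feature_id" not in df.columns:
        df.insert(0, "feature_id", [f"F{i+1:05d}" for i in range(len(df))])
    if "charge" not in df.columns:
        df["charge"] = 0
    if "rt" not in df.columns:
        df["rt"] = np.nan
    return df


def read_intensity_matrix(values_path: str | Path, samples_path: str | Path) -> IntensityMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    _require_columns(samples, REQUIRED_META, f"sample metadata {samples_path}")
    return IntensityMatrix(values, samples.loc[values.index])


def write_intensity_matrix(
    matrix: IntensityMatrix, values_path: str | Path, samples_path: str | Path
) -> None:
    write_table(matrix.values, values_path, index=True)
    write_table(matrix.samples, samples_path, index=True)


def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Read centroided MS/MS spectra from an MGF file (negative mode)."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pepmass = params["pepmass"]
            mz0 = pepmass[0] if isinstance(pepmass, (tuple, list)) else float(pepmass)
            charge = abs(int(params.get("charge", [1])[0]))
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            spectra.append(MsmsSpectrum(float(mz0), charge, peaks))
    return spectra


def write_mgf(spectra: Sequence[MsmsSpectrum], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(spectra, start=1):
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": f"spectrum_{i}",
                    "pepmass": (s.precursor_mz, None),
                    "charge": f"{s.precursor_charge}-",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
    return path
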