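import numpy as np
import pandas as pd
import pytest

from gslscreen.preprocess import IntensityMatrix


def build_matrix(
    n_study: int = 20,
    n_qc: int = 5,
    n_lipids: int = 4,
    seed: int = 0,
    qc_noise_cv: float = 0.0,
    drift_amplitude: float = 0.0,
    lipids=None,
) -> IntensityMatrix:
    """Small hand-rolled study matrix for unit tests.

    QC injections are spread evenly across the run; optional multiplicative
    linear drift (1+A .. 1-A) and lognormal QC/study noise.
    """
    rng = np.random.default_rng(seed)
    n = n_study + n_qc
    qc_pos = np.linspace(1, n, n_qc).round().astype(int)
    qc_pos = np.unique(qc_pos)
    ids, types, orders = [], [], []
    study_i = qc_i = 0
    for pos in range(1, n + 1):
        if pos in qc_pos:
            qc_i += 1
            ids.append(f"QC_{qc_i:02d}")
            types.append("QC")
        else:
            study_i += 1
            ids.append(f"S_{study_i:02d}")
            types.append("study")
        orders.append(pos)
    groups = ["QC" if t == "QC" else ("TG" if i % 2 else "CN") for i, t in enumerate(types)]
    samples = pd.DataFrame(
        {
            "group": groups,
            "age_months": [np.nan if t == "QC" else 12 for t in types],
            "weight_mg": [1.0 if t == "QC" else 15.0 for t in types],
            "injection_order": orders,
            "sample_type": types,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    if lipids is None:
        lipids = [f"GM3 d{34 + 2 * j}:1" for j in range(n_lipids)]
    base = rng.uniform(1e5, 1e6, len(lipids))
    pos = np.array(orders, dtype=float)
    drift = 1.0 + drift_amplitude * (1.0 - 2.0 * (pos - 1) / (n - 1))
    sigma = np.sqrt(np.log1p(qc_noise_cv**2)) if qc_noise_cv > 0 else 0.0
    noise = rng.lognormal(0.0, sigma, size=(n, len(lipids))) if sigma else np.ones((n, len(lipids)))
    values = pd.DataFrame(base[None, :] * drift[:, None] * noise, index=samples.index, columns=lipids)
    return IntensityMatrix(values, samples)


@pytest.fixture
def flat_matrix() -> IntensityMatrix:
    """Drift-free, noise-free matrix: QC signal exactly constant per lipid."""
    return build_matrix()


@pytest.fixture
def drifting_matrix() -> IntensityMatrix:
    """30% linear decay across the run, no analytical noise."""
    return build_matrix(drift_amplitude=0.3)
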