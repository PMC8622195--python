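"""Synthetic study generator for end-to-end pipeline testing.

Emulates the shape of a two-genotype (TG transgenic vs CN control),
six-age (4-14 months) rat brainstem lipidomic screen: lognormal lipid
baselines with class-level offsets, multiplicative analytical noise at a
stated CV, smooth injection-order drift shared by study and pooled-QC
injections, genotype x age effects on selected lipid classes, tissue
weights around 15 +/- 5 mg, and a sarkosyl-insoluble-tau load covariate
that rises with age in TG animals and plateaus at 10 months.  Feature
lists carry m/z values drawn from the in-silico library with ppm-scale
Gaussian error, and MS/MS spectra are built from predicted fragments plus
noise peaks.

Every generator is a pure function of (config, seed): the same inputs
yield byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fragmentation import MsmsSpectrum, predict_fragments
from .library import IonSpecies, LipidSpecies, default_charge_states, parse_shorthand
from .preprocess import IntensityMatrix

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "default_effects",
    "default_lipid_panel",
    "make_design",
    "simulate_intensity_matrix",
    "simulate_feature_list",
    "simulate_msms",
    "tau_load_curve",
]


@dataclass(frozen=True)
class EffectSpec:
    """A ground-truth group effect on one lipid or a whole class.

    ``pattern`` is a shorthand ("GM3 d42:2") or a class name ("ST");
    ``factor`` is "genotype" (applied to TG only, at ``ages``) or "age"
    (applied to both groups, scaled linearly from 0 at the youngest age to
    ``log2_fc`` at the oldest).
    """

    pattern: str
    factor: str  # "age" or "genotype"
    log2_fc: float
    ages: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.factor not in ("age", "genotype"):
            raise ValueError(f"factor must be 'age' or 'genotype', got {self.factor!r}")
        if not np.isfinite(self.log2_fc):
            raise ValueError("log2_fc must be finite")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shape parameters for the synthetic generators."""

    seed: int = 0
    n_per_group: int = 10
    ages: tuple[int, ...] = (4, 6, 8, 10, 12, 14)
    groups: tuple[str, ...] = ("CN", "TG")
    qc_every: int = 10
    weight_range_mg: tuple[float, float] = (10.0, 20.0)
    weight_response: bool = True  # study signal scales with extracted tissue mass
    baseline_ln_mean: float = 13.8  # ~1e6 counts
    baseline_ln_sd: float = 1.0  # between-lipid spread
    class_offset_sd: float = 0.5
    analytical_cv: float = 0.10
    drift_amplitude: float = 0.10
    drift_shape: str = "linear"  # "linear" or "quadratic"
    ppm_sd: float = 2.0
    n_decoys: int = 0
    tau_plateau_age: float = 10.0
    tau_rate: float = 1.2
    tau_noise_cv: float = 0.10
    tau_lipid: str = "GM3 d42:2"
    tau_r_target: float = 0.8


def default_effects() -> list[EffectSpec]:
    """Ground-truth effects mirroring the screen's qualitative findings:
    GM3 elevation in transgenic animals from 8 months, sulfatide decline
    with age, and a GM1a d42:2 rise with age."""
    return [
        EffectSpec("GM3", factor="genotype", log2_fc=1.0, ages=(8, 10, 12)),
        EffectSpec("ST", factor="age", log2_fc=-1.0),
        EffectSpec("dihexST", factor="age", log2_fc=-0.7),
        EffectSpec("GM1a d42:2", factor="age", log2_fc=0.8),
        EffectSpec("GM1a d40:2", factor="age", log2_fc=0.6),
    ]


def default_lipid_panel() -> list[str]:
    """A compact, study-like panel of lipid shorthands."""
    panel = []
    for cls in ("GM3", "GM2", "GM1a", "GD1a", "GD1b", "GT1b", "GQ1b"):
        for cer in ("d34:1", "d36:1", "d38:1", "d40:2", "d42:2"):
            panel.append(f"{cls} {cer}")
    for cls in ("ST", "dihexST"):
        for cer in ("d34:1", "d36:1", "d42:1", "d42:2", "t36:1"):
            panel.append(f"{cls} {cer}")
    return panel


def make_design(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Sample metadata table: study samples per group x age plus interleaved QCs.

    A QC injection opens the run and another follows every ``qc_every``
    study injections; study injection order is randomized by the seed.
    Tissue weights are drawn uniformly from ``weight_range_mg``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for group in config.groups:
        for age in config.ages:
            for i in range(config.n_per_group):
                rows.append({"sample_id": f"{group}{age}_{i+1:02d}", "group": group,
                             "age_months": age, "sample_type": "study"})
    rng.shuffle(rows)
    n_study = len(rows)
    n_qc = n_study // config.qc_every + 1

    design_rows = []
    inj = 0
    study_iter = iter(rows)
    qc_count = 0
    for block in range(n_qc):
        inj += 1
        qc_count += 1
        design_rows.append({"sample_id": f"QC_{qc_count:02d}", "group": "QC",
                            "age_months": np.nan, "sample_type": "QC",
                            "injection_order": inj})
        for _ in range(config.qc_every):
            try:
                row = next(study_iter)
            except StopIteration:
                break
            inj += 1
            design_rows.append({**row, "injection_order": inj})
    for row in study_iter:  # remainder if n_study % qc_every != 0
        inj += 1
        design_rows.append({**row, "injection_order": inj})

    design = pd.DataFrame(design_rows).set_index("sample_id")
    weights = rng.uniform(*config.weight_range_mg, size=len(design))
    design["weight_mg"] = np.where(design["sample_type"] == "study", weights, np.nan)
    design.loc[design["sample_type"] == "QC", "weight_mg"] = 1.0
    return design[["group", "age_months", "weight_mg", "injection_order", "sample_type"]]


def _drift_multiplier(positions: np.ndarray, amplitude: float, shape: str) -> np.ndarray:
    """Smooth injection-order drift in [1-amplitude, 1+amplitude]."""
    if amplitude == 0 or len(positions) == 0:
        return np.ones_like(positions, dtype=float)
    span = positions.max() - positions.min()
    t = (positions - positions.min()) / span if span > 0 else np.zeros_like(positions, dtype=float)
    if shape == "linear":
        s = 1.0 - 2.0 * t  # monotone decay from +1 to -1
    elif shape == "quadratic":
        s = 1.0 - 2.0 * (2.0 * t - 1.0) ** 2  # dip-and-recover
    else:
        raise ValueError(f"unknown drift shape {shape!r}")
    return 1.0 + amplitude * s


def tau_load_curve(age_months: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Mean sarkosyl-insoluble tau load in TG animals: logistic rise in age
    that plateaus around ``tau_plateau_age`` (arbitrary densitometry units)."""
    age = np.asarray(age_months, dtype=float)
    midpoint = config.tau_plateau_age - 3.0  # half-maximal rise before the plateau
    return 1.0 / (1.0 + np.exp(-(age - midpoint) / config.tau_rate))


def _effect_ln_shift(
    effects: Sequence[EffectSpec],
    lipid: str,
    group: str,
    age: float,
    config: SimulationConfig,
) -> float:
    """Total ln-scale shift of one lipid in one group x age cell."""
    sp = parse_shorthand(lipid)
    shift = 0.0
    age_lo, age_hi = min(config.ages), max(config.ages)
    for eff in effects:
        if eff.pattern != lipid and eff.pattern != sp.headgroup.class_name:
            continue
        if eff.factor == "genotype":
            if group == "TG" and (not eff.ages or age in eff.ages):
                shift += eff.log2_fc * np.log(2.0)
        else:  # age effect, both groups, linear ramp across the age range
            frac = (age - age_lo) / (age_hi - age_lo) if age_hi > age_lo else 0.0
            shift += eff.log2_fc * np.log(2.0) * frac
    return shift


def simulate_intensity_matrix(
    design: pd.DataFrame,
    effects: Sequence[EffectSpec],
    config: SimulationConfig,
    lipids: Sequence[str] | None = None,
    seed: int | None = None,
) -> tuple[IntensityMatrix, dict]:
    """Simulate a samples x lipids intensity matrix with known ground truth.

    Study values are lognormal around per-lipid baselines (with class-level
    offsets), shifted by the requested effects, multiplied by the shared
    injection-order drift and by analytical noise at ``analytical_cv``.
    QC values are the pooled study mean under the same drift and noise.

    Returns the matrix and a ground-truth record with the true ln shifts
    per (lipid, group, age), the drift curve, baselines and tau loads.
    """
    if lipids is None:
        lipids = default_lipid_panel()
    lipids = list(lipids)
    for eff in effects:
        classes = {parse_shorthand(l).headgroup.class_name for l in lipids}
        if eff.pattern not in lipids and eff.pattern not in classes:
            raise ValueError(f"effect pattern {eff.pattern!r} matches no simulated lipid")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_samples = len(design)
    n_lipids = len(lipids)

    classes = [parse_shorthand(l).headgroup.class_name for l in lipids]
    class_names = sorted(set(classes))
    class_offset = dict(zip(class_names, rng.normal(0.0, config.class_offset_sd, len(class_names))))
    baseline_ln = (
        rng.normal(config.baseline_ln_mean, config.baseline_ln_sd, n_lipids)
        + np.array([class_offset[c] for c in classes])
    )

    sigma = float(np.sqrt(np.log1p(config.analytical_cv**2)))
    positions = design["injection_order"].to_numpy(dtype=float)
    drift = _drift_multiplier(positions, config.drift_amplitude, config.drift_shape)

    is_qc = (design["sample_type"] == "QC").to_numpy()
    group = design["group"].to_numpy()
    age = design["age_months"].to_numpy(dtype=float)

    # tau load covariate (TG only)
    tau = np.zeros(n_samples)
    tg = (group == "TG") & ~is_qc
    if tg.any():
        mean_load = tau_load_curve(age[tg], config)
        tau[tg] = mean_load * rng.lognormal(0.0, config.tau_noise_cv, tg.sum())

    ln_shift = np.zeros((n_samples, n_lipids))
    for j, lipid in enumerate(lipids):
        for i in range(n_samples):
            if is_qc[i]:
                continue
            ln_shift[i, j] = _effect_ln_shift(effects, lipid, group[i], age[i], config)

    # QC pools average the study-sample true levels of each lipid
    ln_true = baseline_ln[None, :] + ln_shift
    study_mean_level = np.exp(ln_true[~is_qc]).mean(axis=0)
    ln_true[is_qc] = np.log(study_mean_level)[None, :]

    noise = rng.normal(0.0, sigma, size=(n_samples, n_lipids)) if sigma > 0 else np.zeros((n_samples, n_lipids))

    # optional correlation of one lipid with tau load among TG samples
    if (
        config.tau_lipid in lipids
        and tg.sum() >= 3
        and 0 < abs(config.tau_r_target) <= 1
        and tau[tg].std() > 0
    ):
        j = lipids.index(config.tau_lipid)
        z_tau = (tau[tg] - tau[tg].mean()) / tau[tg].std()
        w = rng.standard_normal(tg.sum())
        r = config.tau_r_target
        noise[tg, j] = sigma * (r * z_tau + np.sqrt(1 - r**2) * w) if sigma > 0 else 0.0

    values = np.exp(ln_true + noise) * drift[:, None]
    if config.weight_response:
        # raw signal is proportional to the tissue mass extracted; QC pools
        # are fixed-volume aliquots and carry no weight dependence
        w = design["weight_mg"].to_numpy(dtype=float)
        nominal = float(np.mean(config.weight_range_mg))
        values[~is_qc] *= (w[~is_qc] / nominal)[:, None]
    matrix = IntensityMatrix(
        pd.DataFrame(values, index=design.index, columns=lipids),
        design.copy(),
    )
    truth = {
        "lipids": lipids,
        "baseline_ln": dict(zip(lipids, baseline_ln)),
        "ln_shift": pd.DataFrame(ln_shift, index=design.index, columns=lipids),
        "drift": pd.Series(drift, index=design.index),
        "tau_load": pd.Series(tau, index=design.index),
        "effects": list(effects),
    }
    return matrix, truth


def simulate_feature_list(
    ions: Sequence[IonSpecies],
    config: SimulationConfig,
    seed: int | None = None,
    n_decoys: int | None = None,
    decoy_min_ppm: float = 50.0,
    mz_range: tuple[float, float] = (300.0, 2000.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One MS1 feature per ion with ppm-scale mass error, plus decoys.

    Observed m/z = theoretical * (1 + eps), eps ~ N(0, ppm_sd * 1e-6).
    Decoy features are drawn uniformly in ``mz_range`` and re-drawn until
    at least ``decoy_min_ppm`` away from every library ion.

    Returns (features table, truth map linking feature ids to shorthands).
    """
    if not ions:
        raise ValueError("need a non-empty ion subset")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    theo = np.array([ion.theo_mz for ion in ions])
    eps = rng.normal(0.0, config.ppm_sd * 1e-6, len(ions))
    obs = theo * (1.0 + eps)

    rows, truth_rows = [], []
    for i, ion in enumerate(ions):
        fid = f"F{i+1:05d}"
        rows.append({"feature_id": fid, "mz": obs[i], "rt": float("nan"),
                     "charge": ion.charge, "intensity": 1.0})
        truth_rows.append({"feature_id": fid, "shorthand": ion.species.shorthand,
                           "charge": ion.charge, "theo_mz": ion.theo_mz, "decoy": False})

    n_decoys = config.n_decoys if n_decoys is None else n_decoys
    sorted_theo = np.sort(theo)
    made = 0
    while made < n_decoys:
        mz = rng.uniform(*mz_range)
        j = np.searchsorted(sorted_theo, mz)
        near = [sorted_theo[k] for k in (j - 1, j) if 0 <= k < len(sorted_theo)]
        if near and min(abs(mz - t) / t for t in near) * 1e6 < decoy_min_ppm:
            continue
        made += 1
        fid = f"D{made:05d}"
        rows.append({"feature_id": fid, "mz": mz, "rt": float("nan"), "charge": 0, "intensity": 1.0})
        truth_rows.append({"feature_id": fid, "shorthand": "", "charge": 0,
                           "theo_mz": float("nan"), "decoy": True})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_msms(
    species: LipidSpecies,
    config: SimulationConfig,
    seed: int | None = None,
    precursor_charge: int | None = None,
    n_noise: int = 0,
    mz_range: tuple[float, float] = (300.0, 2000.0),
    noise_exclusion_th: float = 0.5,
) -> MsmsSpectrum:
    """Synthetic MS/MS spectrum: predicted fragments plus avoiding noise.

    Fragment intensities are uniform in (0.2, 1.0]; ``n_noise`` noise peaks
    are placed uniformly in ``mz_range`` but never within
    ``noise_exclusion_th`` Th of a true fragment, with lower intensities.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if precursor_charge is None:
        precursor_charge = max(default_charge_states(species.headgroup))
    frags = predict_fragments(species, precursor_charge)
    frag_mz = np.array([f.theo_mz for f in frags])
    peaks = [(mz, rng.uniform(0.2, 1.0)) for mz in frag_mz]

    made = 0
    while made < n_noise:
        mz = rng.uniform(*mz_range)
        if np.abs(frag_mz - mz).min() < noise_exclusion_th:
            continue
        made += 1
        peaks.append((mz, rng.uniform(0.01, 0.15)))

    precursor_mz = IonSpecies(species, precursor_charge).theo_mz
    return MsmsSpectrum(precursor_mz, precursor_charge, np.array(peaks))
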