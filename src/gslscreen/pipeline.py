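"""End-to-end orchestration: library -> annotate -> preprocess -> stats.

A run is driven by a :class:`RunConfig` (flat dataclass, loadable from
YAML), executes the stages in fixed order, writes every intermediate table
into the run directory, and returns a machine-readable report with per-
stage record counts.  Reproduction mode pins the screen's conventions:
+/-10 ppm identification tolerance, 30% QC-CV filter, raw-p volcano
threshold 0.05, and old-vs-young / transgenic-vs-control comparisons.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation, io, library, plots, preprocess, simulate, stats

__all__ = ["RunConfig", "run_pipeline", "default_comparisons", "matrix_from_features"]


@dataclass
class RunConfig:
    outdir: str = "gslscreen_run"
    seed: int = 0
    simulate: bool = True
    values_path: str | None = None
    samples_path: str | None = None
    features_path: str | None = None
    tol_ppm: float = 10.0
    loess_span: float = 0.75
    cv_threshold: float = 0.30
    p_threshold: float = 0.05
    isotope_correction: bool = True
    weight_correction: bool = True
    make_plots: bool = False
    classes: tuple[str, ...] | None = None
    carbon_range: tuple[int, int] = (28, 48)
    db_range: tuple[int, int] = (0, 4)
    base_types: tuple[str, ...] = ("d", "t")
    n_decoys: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**raw)
        for name in ("classes", "base_types", "carbon_range", "db_range"):
            val = getattr(cfg, name)
            if isinstance(val, list):
                setattr(cfg, name, tuple(val))
        return cfg


def default_comparisons(samples: pd.DataFrame) -> list[tuple[str, tuple, tuple]]:
    """Old-vs-young controls plus transgenic vs age-matched control per age."""
    study = samples[samples["sample_type"] == "study"]
    ages = sorted(study["age_months"].dropna().unique())
    comps: list[tuple[str, tuple, tuple]] = []
    if ages:
        youngest = ages[0]
        for age in ages[-2:]:
            if age != youngest:
                comps.append(
                    (f"CN{age:g} vs CN{youngest:g}", ("CN", age), ("CN", youngest))
                )
    for age in ages:
        comps.append((f"TG{age:g} vs CN{age:g}", ("TG", age), ("CN", age)))
    return comps


def _group_ids(samples: pd.DataFrame, group: str, age) -> list:
    mask = (
        (samples["sample_type"] == "study")
        & (samples["group"] == group)
        & (samples["age_months"] == age)
    )
    return list(samples.index[mask])


def matrix_from_features(
    features: pd.DataFrame,
    annotations_table: pd.DataFrame,
    samples: pd.DataFrame,
) -> preprocess.IntensityMatrix:
    """Collapse annotated features into a samples x lipids intensity matrix.

    Rank-1 annotations assign each feature to a species; intensity columns
    (any numeric column that is not mz/rt/charge) are summed over features
    of the same species (charge states combined).
    """
    best = annotations_table[(annotations_table["rank"] == 1) & (annotations_table["shorthand"] != "")]
    meta_cols = {"feature_id", "mz", "rt", "charge"}
    sample_cols = [c for c in features.columns if c not in meta_cols]
    merged = features.merge(best[["feature_id", "shorthand"]], on="feature_id", how="inner")
    values = merged.groupby("shorthand")[sample_cols].sum().T
    values.index.name = "sample_id"
    return preprocess.IntensityMatrix(values, samples.loc[values.index])


def _stage(report: dict, name: str, **info) -> None:
    report["stages"].append({"name": name, "status": "ok", **info})


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screen and return the run report (also written as
    ``report.json`` in the run directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "config": {k: v for k, v in asdict(config).items()}}

    # 1. library ------------------------------------------------------------
    ions = library.enumerate_library(
        classes=list(config.classes) if config.classes else None,
        carbons=range(config.carbon_range[0], config.carbon_range[1] + 1),
        double_bonds=range(config.db_range[0], config.db_range[1] + 1),
        base_types=config.base_types,
    )
    lib_table = library.library_table(ions)
    io.write_table(lib_table, outdir / "library.tsv")
    _stage(report, "library", n_species=int(lib_table["shorthand"].nunique()), n_ions=len(ions))

    # 2. data ---------------------------------------------------------------
    sim_cfg = simulate.SimulationConfig(seed=config.seed, n_decoys=config.n_decoys)
    if config.simulate:
        design = simulate.make_design(sim_cfg)
        matrix, truth = simulate.simulate_intensity_matrix(
            design, simulate.default_effects(), sim_cfg
        )
        panel_ions = [
            library.IonSpecies(sp, max(library.default_charge_states(sp.headgroup)))
            for sp in (library.parse_shorthand(s) for s in matrix.values.columns)
        ]
        features, feature_truth = simulate.simulate_feature_list(panel_ions, sim_cfg)
        io.write_table(feature_truth, outdir / "feature_truth.tsv")
        matrix.samples["tau_load"] = truth["tau_load"]
    else:
        if not (config.values_path and config.samples_path):
            raise ValueError("non-simulated runs require values_path and samples_path")
        matrix = io.read_intensity_matrix(config.values_path, config.samples_path)
        features = io.read_features(config.features_path) if config.features_path else None
    io.write_intensity_matrix(matrix, outdir / "intensities_raw.tsv", outdir / "samples.tsv")
    _stage(report, "data", n_samples=len(matrix.values), n_lipids=matrix.values.shape[1])

    # 3. annotation ---------------------------------------------------------
    if features is not None:
        io.write_table(features, outdir / "features.tsv")
        annots = annotation.match_features(features, ions, tol_ppm=config.tol_ppm)
        annot_table = annotation.annotation_table(annots)
        io.write_table(annot_table, outdir / "annotations.tsv")
        n_feat = features["feature_id"].nunique()
        n_annotated = annot_table.loc[annot_table["rank"] == 1, "feature_id"].nunique()
        _stage(report, "annotate", n_features=int(n_feat), n_annotated=int(n_annotated),
               n_unannotated=int(n_feat - n_annotated))
    else:
        _stage(report, "annotate", skipped=True)

    # 4. isotopologue overlap correction -------------------------------------
    if config.isotope_correction:
        corrected_values, iso_report = annotation.isotope_correct(matrix.values)
        matrix = preprocess.IntensityMatrix(corrected_values, matrix.samples)
        io.write_table(iso_report, outdir / "isotope_corrections.tsv")
        _stage(report, "isotope_correction", n_corrected=len(iso_report))
    else:
        _stage(report, "isotope_correction", skipped=True)

    # 5. preprocessing chain --------------------------------------------------
    prep = preprocess.preprocess_pipeline(
        matrix,
        span=config.loess_span,
        cv_threshold=config.cv_threshold,
        apply_weight_correction=config.weight_correction,
    )
    io.write_intensity_matrix(prep.matrix, outdir / "intensities_processed.tsv",
                              outdir / "samples_processed.tsv")
    io.write_table(prep.cv_report, outdir / "cv_report.tsv")
    io.write_table(prep.drift_curves, outdir / "drift_curves.tsv", index=True)
    _stage(report, "preprocess", n_lipids_in=matrix.values.shape[1],
           n_cv_excluded=int(prep.cv_report["excluded"].sum()),
           n_lipids_out=prep.matrix.values.shape[1])

    # 6. statistics -----------------------------------------------------------
    processed = prep.matrix
    study_ids = processed.study_ids
    study_values = processed.values.loc[study_ids]
    sig_counts: dict[str, int] = {}
    if processed.values.shape[1] == 0:
        _stage(report, "stats", note="no lipids survived filtering", n_comparisons=0)
    else:
        all_results = []
        for label, (ga, aa), (gb, ab) in default_comparisons(processed.samples):
            ids_a = _group_ids(processed.samples, ga, aa)
            ids_b = _group_ids(processed.samples, gb, ab)
            if len(ids_a) < 2 or len(ids_b) < 2:
                continue
            res = stats.univariate_screen(processed.values, ids_a, ids_b, comparison=label)
            all_results.append(stats.volcano_table(res, p_threshold=config.p_threshold))
            sig_counts[label] = int(all_results[-1]["significant"].sum())
        if all_results:
            results = pd.concat(all_results, ignore_index=True)
            io.write_table(results, outdir / "univariate_results.tsv")
            heat = stats.significance_heatmap(results)
            io.write_table(heat.reset_index(), outdir / "significance_heatmap.tsv")
        # multivariate survey on study samples
        if min(study_values.shape) >= 2:
            scores, loadings, varexp = stats.pca(study_values, n_components=2)
            io.write_table(scores.reset_index(), outdir / "pca_scores.tsv")
            io.write_table(loadings.reset_index(), outdir / "pca_loadings.tsv")
            groups = processed.samples.loc[study_ids, "group"]
            if groups.nunique() == 2 and groups.value_counts().min() >= 3:
                lv_scores, _ = stats.plsda(study_values, groups, n_components=2)
                io.write_table(lv_scores.reset_index(), outdir / "plsda_scores.tsv")
        # correlation with pathology load, when the covariate is present
        if "tau_load" in processed.samples.columns:
            tg_ids = [s for s in study_ids if processed.samples.loc[s, "group"] == "TG"]
            if len(tg_ids) >= 3:
                corr = stats.correlate_with_load(
                    processed.values.loc[tg_ids],
                    processed.samples.loc[tg_ids, "tau_load"],
                )
                io.write_table(corr, outdir / "tau_correlations.tsv")
        _stage(report, "stats", n_comparisons=len(sig_counts), significant=sig_counts)

        if config.make_plots and all_results:
            for df in all_results:
                label = df["comparison"].iloc[0]
                safe = label.replace(" ", "_").replace("/", "-")
                plots.volcano_plot(df, outdir / f"volcano_{safe}.png",
                                   p_threshold=config.p_threshold, title=label)
            plots.heatmap_plot(heat, outdir / "heatmap.png")

    report["significant_per_comparison"] = sig_counts
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
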