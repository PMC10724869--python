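"""End-to-end driver: simulate/load -> indices -> classify -> robustness -> group stats.

Everything here is a thin orchestration over the stage modules; it exists so
the command line, the analysis scripts and the test surface share one code
path.  All outputs are deterministic CSV (plus a JSON manifest) so that two
runs with the same seed are byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_index_table
from .groupstats import group_contrast, hemisphere_contrast, sex_correlation_profile
from .indices import INDEX_KINDS, compute_index_tables
from .io import write_manifest, write_table
from .robustness import classify_outcome, robustness_ttests
from .simulate import Cohort, SimulationConfig, generate_cohort

__all__ = ["config_from_dict", "run_pipeline"]


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain (YAML-friendly) mapping."""
    d = dict(d)
    if "age_range" in d:
        d["age_range"] = tuple(d["age_range"])
    if "measures" in d:
        d["measures"] = tuple(d["measures"])
    if "roi_means" in d:
        d["roi_means"] = {k: np.asarray(v, dtype=float) for k, v in d["roi_means"].items()}
    if "iqm_params" in d:
        d["iqm_params"] = {
            m: {s: tuple(v) for s, v in per.items()} for m, per in d["iqm_params"].items()
        }
    return SimulationConfig(**d)


def _jsonable_config(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["roi_means"] = {k: np.asarray(v).tolist() for k, v in d["roi_means"].items()}
    return d


def run_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    config: SimulationConfig | None = None,
    cohort: Cohort | None = None,
    kinds: tuple[str, ...] = INDEX_KINDS,
    n_trees: int = 500,
    mtry_grid: tuple | None = None,
    train_frac: float = 0.8,
    cv_folds: int = 10,
    importance_repeats: int = 5,
    n_per_level: int = 80,
    level_overrides: dict[str, int] | None = None,
) -> dict:
    """Run every stage and write one CSV per result table under ``out_dir``.

    When ``cohort`` is not supplied one is simulated from ``config`` (default
    configuration if that is ``None`` too) with its seed replaced by ``seed``.
    Returns the in-memory results keyed by stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        from dataclasses import replace

        config = replace(config or SimulationConfig(), seed=seed)
        cohort = generate_cohort(config)
    else:
        config = cohort.config

    meta = cohort.meta
    write_table(meta, out_dir / "participants.csv")
    write_table(cohort.quality.values, out_dir / "iqm.csv")

    index_tables = {}
    qc_rows = []
    for measure, morph in cohort.morphometry.items():
        for kind, table in compute_index_tables(morph, kinds=kinds).items():
            index_tables[(kind, measure)] = table
            write_table(table.values, out_dir / f"index_{kind}_{measure}.csv")
            qc_rows.append({"index": kind, "measure": measure, **table.qc})
    write_table(pd.DataFrame(qc_rows), out_dir / "index_qc.csv", index_label="row")

    summary_rows, confusion_rows, importance_rows = [], [], []
    for (kind, measure), table in index_tables.items():
        s = classify_index_table(
            table.values, meta, seed=seed, train_frac=train_frac,
            cv_folds=cv_folds, mtry_grid=mtry_grid, n_trees=n_trees,
            importance_repeats=importance_repeats,
        )
        summary_rows.append({
            "index": kind, "measure": measure, "accuracy": s.accuracy,
            "kappa": s.kappa, "kappa_label": s.kappa_label, "nir": s.nir,
            "p_value": s.p_value, "n_test": int(s.confusion.to_numpy().sum()),
            "top6": ";".join(s.top6),
        })
        c = s.confusion.reset_index().melt(
            id_vars="prediction", var_name="target", value_name="count"
        )
        c.insert(0, "measure", measure)
        c.insert(0, "index", kind)
        confusion_rows.append(c)
        imp = s.importances.copy()
        imp.insert(0, "measure", measure)
        imp.insert(0, "index", kind)
        importance_rows.append(imp)
    classification = pd.DataFrame(summary_rows)
    write_table(classification, out_dir / "classification_summary.csv", index_label="row")
    write_table(pd.concat(confusion_rows, ignore_index=True),
                out_dir / "classification_confusion.csv", index_label="row")
    write_table(pd.concat(importance_rows, ignore_index=True),
                out_dir / "classification_importances.csv", index_label="row")

    report = robustness_ttests(
        index_tables, meta, cohort.quality,
        n_per_level=n_per_level, overrides=level_overrides,
    )
    verdicts = classify_outcome(report)
    write_table(report, out_dir / "robustness_report.csv", index_label="row")
    write_table(verdicts, out_dir / "robustness_verdicts.csv", index_label="row")

    contrast_rows, corr_rows = [], []
    for (kind, measure), table in index_tables.items():
        gc = group_contrast(table, meta)
        contrast_rows.append({
            "index": kind, "measure": measure, "t_statistic": gc.t_statistic,
            "p_value": gc.p_value, "tier": gc.tier, "direction": gc.direction,
            "male_grand_mean": float(gc.male_profile.mean()),
            "female_grand_mean": float(gc.female_profile.mean()),
        })
        sc = sex_correlation_profile(table.values, meta)
        corr_rows.append({
            "index": kind, "measure": measure, "grand_mean_r": sc.grand_mean,
            "grand_mean_abs_r": sc.grand_mean_abs, "n_defined": sc.n_defined,
        })
    hemi_rows = []
    for measure, morph in cohort.morphometry.items():
        hc = hemisphere_contrast(morph, meta)
        hemi_rows.append({
            "measure": measure, "left_grand_mean_r": hc.left_grand_mean,
            "right_grand_mean_r": hc.right_grand_mean,
            "t_statistic": hc.t_statistic, "p_value": hc.p_value, "tier": hc.tier,
        })
    contrasts = pd.DataFrame(contrast_rows)
    correlations = pd.DataFrame(corr_rows)
    hemispheres = pd.DataFrame(hemi_rows)
    write_table(contrasts, out_dir / "group_contrasts.csv", index_label="row")
    write_table(correlations, out_dir / "sex_correlations.csv", index_label="row")
    write_table(hemispheres, out_dir / "hemisphere_contrasts.csv", index_label="row")

    write_manifest(
        {
            "seed": seed,
            "asymkit_version": __version__,
            "atlas": "FreeSurfer aparc (Desikan-Killiany/DKT cortical set, 34 parcels)",
            "config": _jsonable_config(config),
            "n_subjects": int(len(meta)),
            "stages": ["simulate", "indices", "classify", "robustness", "groupstats"],
        },
        out_dir / "manifest.json",
    )
    return {
        "cohort": cohort,
        "index_tables": index_tables,
        "classification": classification,
        "robustness_report": report,
        "robustness_verdicts": verdicts,
        "group_contrasts": contrasts,
        "sex_correlations": correlations,
        "hemisphere_contrasts": hemispheres,
    }
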