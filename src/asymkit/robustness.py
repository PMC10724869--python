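"""Image-quality robustness analysis of the asymmetry indices.

An index is a *robust* marker of a male/female difference if the
difference survives at both extremes of image quality.  For each of the
five image-quality metrics (CJV, CNR, EFC, INU, WM2MAX) two subsamples
are selected — the lowest-valued and highest-valued ``n`` subjects *per
sex*, so metric levels are matched across sexes by construction — and
within each subsample a paired t-test compares the male and female
per-ROI mean index profiles (34 pairs, the ROI is the pairing unit).
Significance tiers: ``*`` p < 0.001, ``x`` 0.001 <= p < 0.05, ``ns``
otherwise.  EFC conventionally uses a smaller subsample (n = 35) because
its distribution is much tighter in females; this is an ``overrides``
entry, not a hard-coded rule.

Verdicts per (index, measure, metric): *robust* if both levels are
significant; *quality-sensitive* if only the preferred level (lower for
CJV/EFC, upper for CNR/INU/WM2MAX) is; *not-robust* if neither is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import IndexTable
from .io import QualityTable
from .stats import paired_profile_ttest, significance_tier  # noqa: F401 (re-export)

log = logging.getLogger(__name__)

__all__ = [
    "IQM_DIRECTIONS",
    "LevelSubsamples",
    "select_level_subsamples",
    "robustness_ttests",
    "classify_outcome",
]

#: Which extreme of each metric indicates *better* image quality.
IQM_DIRECTIONS = {
    "CJV": "lower",
    "CNR": "upper",
    "EFC": "lower",
    "INU": "upper",
    "WM2MAX": "upper",
}


@dataclass
class LevelSubsamples:
    """Lower/upper extreme subsamples for one metric, selected per sex."""

    metric: str
    lower_ids: list[str]
    upper_ids: list[str]
    achieved_means: pd.DataFrame  # (level, sex) -> achieved metric mean
    n_per_sex: int
    warnings: list[str] = field(default_factory=list)


def select_level_subsamples(
    quality: QualityTable,
    meta: pd.DataFrame,
    metric: str,
    n_per_level: int = 80,
    mismatch_tol: float | None = None,
) -> LevelSubsamples:
    """Pick the ``n_per_level`` smallest and largest subjects per sex.

    Sorting is ascending by the metric with ties broken by subject id, so
    the selection is deterministic.  The achieved per-sex metric means are
    reported so the male/female matching quality is auditable; when
    ``mismatch_tol`` is set, a male-female mean gap above it (in units of
    the metric's pooled SD) adds a warning.
    """
    if metric not in quality.values.columns:
        raise ValueError(f"metric {metric!r} not in quality table")
    values = quality.values[metric].drop(labels=quality.flagged, errors="ignore")
    values = values[values.index.isin(meta.index)]
    lower, upper, rows, warns = [], [], [], []
    for sex in ("male", "female"):
        ids = meta.index[meta["sex"] == sex].intersection(values.index)
        if n_per_level > len(ids):
            raise ValueError(
                f"n_per_level={n_per_level} exceeds {len(ids)} available {sex} subjects"
            )
        ordered = values.loc[ids].reset_index().sort_values(
            [metric, "subject"], kind="mergesort"
        )["subject"].tolist()
        lower += ordered[:n_per_level]
        upper += ordered[-n_per_level:]
    for level, sel in (("lower", lower), ("upper", upper)):
        for sex in ("male", "female"):
            ids = [s for s in sel if meta.loc[s, "sex"] == sex]
            rows.append({"level": level, "sex": sex, "mean": float(values.loc[ids].mean())})
    achieved = pd.DataFrame(rows).set_index(["level", "sex"])["mean"].unstack()
    if mismatch_tol is not None:
        sd = float(values.std(ddof=1))
        for level in ("lower", "upper"):
            gap = abs(achieved.loc[level, "male"] - achieved.loc[level, "female"])
            if sd > 0 and gap / sd > mismatch_tol:
                msg = (f"{metric} {level}: male/female mean gap {gap:.4g} "
                       f"exceeds {mismatch_tol} pooled SDs")
                warns.append(msg)
                log.warning(msg)
    return LevelSubsamples(
        metric=metric, lower_ids=lower, upper_ids=upper,
        achieved_means=achieved, n_per_sex=n_per_level, warnings=warns,
    )


def robustness_ttests(
    index_tables: dict[tuple[str, str], IndexTable] | list[IndexTable],
    meta: pd.DataFrame,
    quality: QualityTable,
    n_per_level: int = 80,
    overrides: dict[str, int] | None = None,
    metrics: tuple[str, ...] = tuple(IQM_DIRECTIONS),
    mismatch_tol: float | None = None,
) -> pd.DataFrame:
    """Full robustness report: one row per (metric, level, index, measure).

    Within each subsample the male and female per-ROI mean index profiles
    are compared by a paired t-test across the 34 ROIs.  Rows where more
    than 20% of ROI means are undefined are flagged unreliable.
    """
    if overrides is None:
        overrides = {"EFC": 35}
    if isinstance(index_tables, dict):
        tables = list(index_tables.values())
    else:
        tables = list(index_tables)
    rows = []
    for metric in metrics:
        n = overrides.get(metric, n_per_level)
        sub = select_level_subsamples(quality, meta, metric, n, mismatch_tol)
        for level, ids in (("lower", sub.lower_ids), ("upper", sub.upper_ids)):
            males = [s for s in ids if meta.loc[s, "sex"] == "male"]
            females = [s for s in ids if meta.loc[s, "sex"] == "female"]
            for table in tables:
                male_profile = table.values.loc[males].mean().to_numpy()
                female_profile = table.values.loc[females].mean().to_numpy()
                undef = np.isnan(male_profile) | np.isnan(female_profile)
                res = paired_profile_ttest(male_profile, female_profile)
                rows.append({
                    "metric": metric,
                    "level": level,
                    "index": table.kind,
                    "measure": table.measure,
                    "t_statistic": res.t,
                    "p_value": res.p,
                    "tier": res.tier,
                    "male_mean": float(np.nanmean(male_profile)),
                    "female_mean": float(np.nanmean(female_profile)),
                    "n_per_sex": n,
                    "n_roi_pairs": res.n_pairs,
                    "unreliable": bool(undef.mean() > 0.20),
                })
    return pd.DataFrame(rows)


def classify_outcome(
    report: pd.DataFrame, directions: dict[str, str] | None = None
) -> pd.DataFrame:
    """Collapse the two levels per (index, measure, metric) into a verdict."""
    directions = directions or IQM_DIRECTIONS
    sig = report.assign(significant=report["p_value"] < 0.05)
    rows = []
    for (index, measure, metric), grp in sig.groupby(["index", "measure", "metric"]):
        by_level = grp.set_index("level")["significant"]
        if by_level.get("lower", False) and by_level.get("upper", False):
            verdict = "robust"
        elif by_level.get(directions[metric], False):
            verdict = "quality-sensitive"
        elif by_level.any():
            # significant only at the non-preferred extreme
            verdict = "quality-sensitive"
        else:
            verdict = "not-robust"
        rows.append({"index": index, "measure": measure, "metric": metric,
                     "verdict": verdict})
    return pd.DataFrame(rows)
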