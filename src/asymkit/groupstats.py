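"""Whole-cohort group contrasts and sex-correlation summaries.

Two complementary views of sexual dimorphism in the index tables:

* **group contrast** — the male and female per-ROI mean profiles of one
  index are compared with a paired t-test across the 34 ROI pairs (the ROI
  is the pairing unit, since subjects cannot be paired across sexes), with
  the same significance tiers as the robustness stage;
* **sex correlation** — per ROI, the point-biserial correlation of the
  index (or raw hemisphere) value with sex coded male = 0 / female = 1,
  summarized as a grand mean over ROIs.  With that coding, higher male
  asymmetry gives negative r, so the absolute grand mean is reported as
  the headline and the signed value retained for direction.

The hemisphere contrast asks whether either raw hemisphere alone carries
sex information the other lacks: the per-ROI sex-correlation profiles of
the left and right hemispheres are compared by a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import IndexTable
from .io import MorphometryTable
from .stats import PairedResult, paired_profile_ttest

__all__ = [
    "GroupContrast",
    "group_contrast",
    "SexCorrelationSummary",
    "sex_correlation_profile",
    "HemisphereContrast",
    "hemisphere_contrast",
]

SEX_CODING = {"male": 0.0, "female": 1.0}


@dataclass
class GroupContrast:
    kind: str
    measure: str
    male_profile: pd.Series
    female_profile: pd.Series
    t_statistic: float
    p_value: float
    tier: str
    direction: int          # sign of mean(male - female)
    n_roi_pairs: int
    degenerate: bool


def group_contrast(table: IndexTable, meta: pd.DataFrame) -> GroupContrast:
    """Paired t-test between male and female per-ROI mean index profiles."""
    common = table.values.index.intersection(meta.index)
    values = table.values.loc[common]
    sex = meta.loc[common, "sex"]
    if (sex.value_counts().reindex(["male", "female"]).fillna(0) < 2).any():
        raise ValueError("need at least 2 subjects per sex")
    male_profile = values[sex == "male"].mean()
    female_profile = values[sex == "female"].mean()
    res: PairedResult = paired_profile_ttest(
        male_profile.to_numpy(), female_profile.to_numpy()
    )
    return GroupContrast(
        kind=table.kind,
        measure=table.measure,
        male_profile=male_profile,
        female_profile=female_profile,
        t_statistic=res.t,
        p_value=res.p,
        tier=res.tier,
        direction=int(np.sign(res.mean_diff)),
        n_roi_pairs=res.n_pairs,
        degenerate=res.degenerate,
    )


@dataclass
class SexCorrelationSummary:
    per_roi_r: pd.Series    # signed point-biserial r per ROI (NaN if undefined)
    grand_mean: float       # simple average of defined signed r
    grand_mean_abs: float   # average of |r| — the headline value
    n_defined: int
    coding: dict


def _pointbiserial_columns(values: pd.DataFrame, code: np.ndarray) -> pd.Series:
    """Pearson r of each column against a 0/1 coding; zero-variance -> NaN."""
    x = values.to_numpy(dtype=float)
    code = code - code.mean()
    out = np.full(x.shape[1], np.nan)
    for j in range(x.shape[1]):
        col = x[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 3:
            continue
        c = col[ok] - col[ok].mean()
        g = code[ok] - code[ok].mean()
        den = np.sqrt((c**2).sum() * (g**2).sum())
        if den > 0:
            out[j] = float((c * g).sum() / den)
    return pd.Series(out, index=values.columns)


def sex_correlation_profile(
    values: pd.DataFrame, meta: pd.DataFrame, coding: dict | None = None
) -> SexCorrelationSummary:
    """Per-ROI point-biserial correlation with sex, plus grand means.

    ``values`` is any subjects-by-ROI table (an index table or one raw
    hemisphere).  Zero-variance columns are undefined and excluded from the
    grand means, with their count reflected in ``n_defined``.
    """
    coding = coding or SEX_CODING
    common = values.index.intersection(meta.index)
    sex = meta.loc[common, "sex"]
    if sex.nunique() < 2:
        raise ValueError("both sexes must be present")
    code = sex.map(coding).to_numpy(dtype=float)
    r = _pointbiserial_columns(values.loc[common], code)
    defined = r.dropna()
    return SexCorrelationSummary(
        per_roi_r=r,
        grand_mean=float(defined.mean()),
        grand_mean_abs=float(defined.abs().mean()),
        n_defined=int(defined.size),
        coding=dict(coding),
    )


@dataclass
class HemisphereContrast:
    measure: str
    left_r: pd.Series
    right_r: pd.Series
    left_grand_mean: float
    right_grand_mean: float
    t_statistic: float
    p_value: float
    tier: str


def hemisphere_contrast(morphometry: MorphometryTable, meta: pd.DataFrame) -> HemisphereContrast:
    """Paired t-test between the hemispheres' per-ROI sex-correlation profiles."""
    left = sex_correlation_profile(morphometry.left, meta)
    right = sex_correlation_profile(morphometry.right, meta)
    res = paired_profile_ttest(left.per_roi_r.to_numpy(), right.per_roi_r.to_numpy())
    return HemisphereContrast(
        measure=morphometry.measure,
        left_r=left.per_roi_r,
        right_r=right.per_roi_r,
        left_grand_mean=left.grand_mean,
        right_grand_mean=right.grand_mean,
        t_statistic=res.t,
        p_value=res.p,
        tier=res.tier,
    )
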