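"""Per-ROI asymmetry indices: distance (DI), laterality (LI), subtraction (SI).

For homologous left/right ROI values ``a_L``, ``a_R`` (atlas-ordered
34-vectors per subject):

* **DI** is a *global* asymmetry statistic.  For ROI ``i`` build the vector
  of absolute differences between that ROI and every other ipsilateral ROI,
  once per hemisphere::

      V_L = [|a_{i,L} - a_{j,L}|  for j != i]        (33 entries)
      V_R = [|a_{i,R} - a_{j,R}|  for j != i]

  then ``DI_i = 1 - |r|`` with ``r`` the Pearson correlation of ``V_L`` and
  ``V_R``.  DI is 0 when the hemispheres are proportional (coherent) and
  grows as the inter-ROI difference structure decorrelates across
  hemispheres; it is blind to a uniform left/right scale factor.

* **LI** is the classic weighted pairwise asymmetry, taken as a magnitude:
  ``LI_i = |(a_{i,L} - a_{i,R}) / (a_{i,L} + a_{i,R})|``.

* **SI** is the raw pairwise asymmetry ``SI_i = |a_{i,L} - a_{i,R}|``, in
  measure units.

All three are magnitudes — which hemisphere is larger is deliberately not
encoded.  Undefined entries (zero-variance difference vectors for DI, zero
denominator for LI) are returned as NaN and counted, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import DEFAULT_ATLAS, ROIAtlas
from .io import MorphometryTable

__all__ = [
    "distance_index",
    "laterality_index",
    "subtraction_index",
    "IndexTable",
    "compute_index_tables",
    "INDEX_KINDS",
]

INDEX_KINDS = ("DI", "LI", "SI")


def _as_2d(left, right) -> tuple[np.ndarray, np.ndarray, bool]:
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError(f"shape mismatch: {left.shape} vs {right.shape}")
    squeeze = left.ndim == 1
    if squeeze:
        left, right = left[None, :], right[None, :]
    if left.ndim != 2:
        raise ValueError("expected 1-D or 2-D (subjects x ROIs) arrays")
    if not (np.isfinite(left).all() and np.isfinite(right).all()):
        raise ValueError("non-finite values in input vectors")
    return left, right, squeeze


def _pair_columns(n: int, mode: str) -> list[np.ndarray]:
    """For each ROI i, the ipsilateral partner indices j entering its vector."""
    if mode == "all":
        return [np.array([j for j in range(n) if j != i]) for i in range(n)]
    if mode == "upper":  # the i+1..n reading; trailing ROIs get short vectors
        return [np.arange(i + 1, n) for i in range(n)]
    raise ValueError(f"mode must be 'all' or 'upper', got {mode!r}")


def distance_index(left, right, mode: str = "all") -> np.ndarray:
    """Distance index DI_i = 1 - |Pearson r(V_L, V_R)| per ROI.

    ``mode="all"`` (default) uses all 33 j != i differences; ``mode="upper"``
    restricts to j > i, in which case trailing ROIs whose vectors have fewer
    than 3 entries are returned as NaN.  Zero variance in either difference
    vector also yields NaN for that ROI.
    """
    left, right, squeeze = _as_2d(left, right)
    n_sub, n_roi = left.shape
    if mode == "all" and n_roi < 4:
        raise ValueError("distance index needs at least 4 ROIs (vectors of length >= 3)")

    # (n_sub, n_roi, n_roi) absolute pairwise difference matrices per hemisphere
    dl = np.abs(left[:, :, None] - left[:, None, :])
    dr = np.abs(right[:, :, None] - right[:, None, :])

    di = np.full((n_sub, n_roi), np.nan)
    if mode == "all":
        cols = np.array(_pair_columns(n_roi, "all"))  # (n_roi, n_roi-1)
        vl = dl[:, np.arange(n_roi)[:, None], cols]   # (n_sub, n_roi, n_roi-1)
        vr = dr[:, np.arange(n_roi)[:, None], cols]
        vl = vl - vl.mean(axis=-1, keepdims=True)
        vr = vr - vr.mean(axis=-1, keepdims=True)
        num = (vl * vr).sum(axis=-1)
        den = np.sqrt((vl**2).sum(axis=-1) * (vr**2).sum(axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        di = 1.0 - np.abs(r)
    else:
        for i, js in enumerate(_pair_columns(n_roi, "upper")):
            if js.size < 3:
                continue
            vl = dl[:, i, js]
            vr = dr[:, i, js]
            vl = vl - vl.mean(axis=-1, keepdims=True)
            vr = vr - vr.mean(axis=-1, keepdims=True)
            den = np.sqrt((vl**2).sum(axis=-1) * (vr**2).sum(axis=-1))
            num = (vl * vr).sum(axis=-1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
            di[:, i] = 1.0 - np.abs(r)
    # correlation magnitude can exceed 1 by rounding; clamp into [0, 1]
    di = np.clip(di, 0.0, 1.0, out=di)
    return di[0] if squeeze else di


def laterality_index(left, right) -> np.ndarray:
    """LI_i = |(L - R) / (L + R)|; NaN where L + R == 0.

    Values can exceed 1 when the raw values have mixed signs (possible for
    mean curvature); such entries are legal and are flagged downstream
    rather than clipped.
    """
    left, right, squeeze = _as_2d(left, right)
    denom = left + right
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(denom != 0, np.abs((left - right) / np.where(denom != 0, denom, 1.0)), np.nan)
    return li[0] if squeeze else li


def subtraction_index(left, right) -> np.ndarray:
    """SI_i = |L - R|, in the measure's units."""
    left, right, squeeze = _as_2d(left, right)
    si = np.abs(left - right)
    return si[0] if squeeze else si


@dataclass
class IndexTable:
    """Subjects-by-34 table of one asymmetry index for one measure."""

    kind: str
    measure: str
    values: pd.DataFrame
    qc: dict = field(default_factory=dict)


def compute_index_tables(
    morphometry: MorphometryTable,
    kinds: tuple[str, ...] = INDEX_KINDS,
    atlas: ROIAtlas = DEFAULT_ATLAS,
    di_mode: str = "all",
) -> dict[str, IndexTable]:
    """Compute the requested index tables for every subject.

    Returns ``{kind: IndexTable}``.  Each table's ``qc`` dict counts
    undefined (NaN) entries and, for LI, values above 1.
    """
    unknown = set(kinds) - set(INDEX_KINDS)
    if unknown:
        raise ValueError(f"unknown index kind(s): {sorted(unknown)}")
    left = morphometry.left.to_numpy()
    right = morphometry.right.to_numpy()
    out: dict[str, IndexTable] = {}
    for kind in kinds:
        if kind == "DI":
            arr = distance_index(left, right, mode=di_mode)
        elif kind == "LI":
            arr = laterality_index(left, right)
        else:
            arr = subtraction_index(left, right)
        values = pd.DataFrame(arr, index=morphometry.subjects, columns=list(atlas.names))
        qc = {"n_undefined": int(np.isnan(arr).sum())}
        if kind == "LI":
            qc["n_above_one"] = int((arr > 1).sum())
        out[kind] = IndexTable(kind=kind, measure=morphometry.measure, values=values, qc=qc)
    return out
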