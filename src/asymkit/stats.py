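"""Shared statistical primitives: ROI-profile paired t-test and tier labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["significance_tier", "paired_profile_ttest", "PairedResult"]


def significance_tier(p: float) -> str:
    """Map a p-value to the reporting tier: ``*`` (<0.001), ``x`` (<0.05), ``ns``."""
    if not np.isfinite(p) or not 0 <= p <= 1:
        raise ValueError(f"p-value out of range: {p!r}")
    if p < 0.001:
        return "*"
    if p < 0.05:
        return "x"
    return "ns"


@dataclass
class PairedResult:
    t: float
    p: float
    tier: str
    n_pairs: int
    mean_diff: float
    degenerate: bool = False


def paired_profile_ttest(a, b) -> PairedResult:
    """Two-sided paired t-test across ROI profiles with pairwise NaN removal.

    ``a`` and ``b`` are equal-length profiles (e.g. per-ROI male and female
    group means).  Pairs with a NaN on either side are dropped.  A
    zero-variance difference profile is degenerate: identical profiles give
    t = 0, p = 1; a constant nonzero offset gives a signed infinite t with
    p = 0 and the ``degenerate`` flag set, rather than a numeric overflow.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 defined pairs")
    d = a - b
    mean_diff = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        if np.isclose(mean_diff, 0.0):
            return PairedResult(0.0, 1.0, "ns", n, mean_diff, degenerate=True)
        t = np.inf if mean_diff > 0 else -np.inf
        return PairedResult(float(t), 0.0, "*", n, mean_diff, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedResult(float(t), float(p), significance_tier(float(p)), n, mean_diff)
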