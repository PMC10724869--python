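"""Synthetic bilateral-morphometry cohort generator.

No generative model of hemispheric asymmetry comes with the analysis this
package implements, so the generator operationalizes the two distinct ways
hemispheres can differ, with an independent knob for each:

* **coherence noise** (``coherence_sd``, per sex): the right-hemisphere value
  of each ROI is the left value plus Gaussian noise scaled to that ROI's
  magnitude.  This perturbs the *inter-ROI difference structure* across
  hemispheres, degrading the cross-hemisphere difference-vector correlation
  — it drives the distance index (DI) while leaving the expected pairwise
  offsets at zero.
* **pairwise shift** (``pairwise_shift``, per sex): a fractional left/right
  offset per ROI, ``a_R = a_L * (1 + delta)``.  A shift changes pairwise
  indices (LI, SI) but, being proportional, leaves DI untouched.

The left hemisphere itself combines a template of realistic per-ROI
magnitudes, a per-subject log-normal scale factor (head-size variation),
and ROI-level additive noise.  Image-quality metrics are drawn per sex from
Gaussians with sex-shifted means (and, for EFC, a much tighter female
spread).  Ages are uniform.  Everything derives from one seed; identical
seeds give identical cohorts.

The default configuration is the study condition of the analyses shipped
here: a cohort of 396 males / 430 females in which male coherence noise is
twice the female value and pairwise shifts are zero — males are globally
more asymmetric with no pairwise left/right offset.  ``SimulationConfig.null``
gives the matched no-effect configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import DEFAULT_ATLAS, ROIAtlas
from .io import MEASURES, MorphometryTable, QualityTable

__all__ = ["SimulationConfig", "Cohort", "generate_cohort", "make_fixture_suite"]

# Fixed magnitude templates per measure (34 values each), spanning the ranges
# FreeSurfer aparc tables show: volumes ~7e2-2.4e4 mm^3, areas ~2e2-5e3 mm^2,
# thickness 2-3 mm, mean curvature 0.1-0.2 mm^-1.  A fixed permutation
# decouples magnitude rank from atlas (alphabetical-ish) order.
_PERM = np.random.default_rng(7).permutation(34)


def _template(low: float, high: float, geometric: bool) -> np.ndarray:
    base = np.geomspace(low, high, 34) if geometric else np.linspace(low, high, 34)
    return base[_PERM].copy()


DEFAULT_ROI_MEANS: dict[str, np.ndarray] = {
    "volume": _template(7e2, 2.4e4, True),
    "area": _template(2.5e2, 5.0e3, True),
    "thickness": _template(2.0, 3.0, False),
    "meancurv": _template(0.10, 0.20, False),
}

DEFAULT_IQM_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "CJV": {"male": (0.42, 0.040), "female": (0.40, 0.040)},
    "CNR": {"male": (3.20, 0.350), "female": (3.40, 0.350)},
    # female EFC spread kept deliberately tight (homogeneous female values)
    "EFC": {"male": (0.46, 0.020), "female": (0.45, 0.006)},
    "INU": {"male": (0.82, 0.050), "female": (0.86, 0.050)},
    "WM2MAX": {"male": (0.70, 0.040), "female": (0.73, 0.040)},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level parameters; defaults are the shipped study conditions."""

    n_male: int = 396
    n_female: int = 430
    subject_scale_sd: float = 0.08      # SD of per-subject log scale factor
    roi_noise_cv: float = 0.02          # additive ROI noise, as CV of ROI mean
    coherence_sd: dict = field(
        default_factory=lambda: {"male": 0.02, "female": 0.01}
    )
    pairwise_shift: dict = field(
        default_factory=lambda: {"male": 0.0, "female": 0.0}
    )
    roi_means: dict = field(default_factory=lambda: dict(DEFAULT_ROI_MEANS))
    iqm_params: dict = field(default_factory=lambda: {
        m: {s: v for s, v in p.items()} for m, p in DEFAULT_IQM_PARAMS.items()
    })
    age_range: tuple = (19.0, 26.0)
    measures: tuple = MEASURES
    seed: int = 0

    def __post_init__(self):
        if self.n_male < 2 or self.n_female < 2:
            raise ValueError("need at least 2 subjects per sex")
        for g in ("male", "female"):
            if self.coherence_sd[g] < 0:
                raise ValueError("coherence_sd must be >= 0")
        if self.subject_scale_sd < 0 or self.roi_noise_cv < 0:
            raise ValueError("noise SDs must be >= 0")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """No-effect configuration: equal coherence noise, zero shifts."""
        cfg = cls(
            coherence_sd={"male": 0.015, "female": 0.015},
            pairwise_shift={"male": 0.0, "female": 0.0},
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class Cohort:
    """One simulated cohort: morphometry per measure, metadata, IQMs."""

    morphometry: dict[str, MorphometryTable]
    meta: pd.DataFrame
    quality: QualityTable
    config: SimulationConfig


def _shift_vector(value, n_roi: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_roi, float(arr))
    if arr.shape != (n_roi,):
        raise ValueError(f"pairwise_shift must be scalar or length-{n_roi}")
    return arr


def generate_cohort(config: SimulationConfig, atlas: ROIAtlas = DEFAULT_ATLAS) -> Cohort:
    """Draw one cohort from ``config``; fully reproducible from its seed.

    Left values: ``a_L = m_i * exp(u_s) + eps``, ``u_s ~ N(0, scale_sd)``,
    ``eps ~ N(0, (cv * m_i)^2)``.  Right values:
    ``a_R = a_L * (1 + delta_{i,g}) + zeta``, ``zeta ~ N(0, (sigma_g * m_i)^2)``.
    Positive-valued measures are floored at ``1e-3 * m_i`` (counted); if more
    than 1% of draws for a measure come out non-positive the configuration is
    rejected with an error.
    """
    rng = np.random.default_rng(config.seed)
    n_roi = len(atlas)
    n = config.n_male + config.n_female
    ids = [f"sub-{i + 1:04d}" for i in range(n)]
    sex = np.array(["male"] * config.n_male + ["female"] * config.n_female)
    age = rng.uniform(*config.age_range, size=n)
    meta = pd.DataFrame(
        {"sex": sex, "age": age, "handedness": "right"},
        index=pd.Index(ids, name="subject"),
    )

    morphometry: dict[str, MorphometryTable] = {}
    for measure in config.measures:
        m = np.asarray(config.roi_means[measure], dtype=float)
        if m.shape != (n_roi,):
            raise ValueError(f"roi_means[{measure!r}] must have length {n_roi}")
        u = rng.normal(0.0, config.subject_scale_sd, size=n)
        eps = rng.normal(0.0, 1.0, size=(n, n_roi)) * (config.roi_noise_cv * m)
        left = m * np.exp(u)[:, None] + eps
        sigma = np.where(sex == "male",
                         config.coherence_sd["male"], config.coherence_sd["female"])
        zeta = rng.normal(0.0, 1.0, size=(n, n_roi)) * (sigma[:, None] * m)
        delta = np.where(
            (sex == "male")[:, None],
            _shift_vector(config.pairwise_shift["male"], n_roi),
            _shift_vector(config.pairwise_shift["female"], n_roi),
        )
        right = left * (1.0 + delta) + zeta
        if measure in ("volume", "area", "thickness"):
            floor = 1e-3 * m
            bad = int((left <= 0).sum() + (right <= 0).sum())
            if bad > 0.01 * 2 * n * n_roi:
                raise ValueError(
                    f"{bad} non-positive {measure} draws (>1%); reduce noise SDs"
                )
            left = np.maximum(left, floor)
            right = np.maximum(right, floor)
        morphometry[measure] = MorphometryTable(
            measure=measure,
            left=pd.DataFrame(left, index=meta.index, columns=list(atlas.names)),
            right=pd.DataFrame(right, index=meta.index, columns=list(atlas.names)),
        )

    iqm = {}
    for metric, per_sex in config.iqm_params.items():
        mu = np.where(sex == "male", per_sex["male"][0], per_sex["female"][0])
        sd = np.where(sex == "male", per_sex["male"][1], per_sex["female"][1])
        iqm[metric] = rng.normal(mu, sd)
    quality = QualityTable(values=pd.DataFrame(iqm, index=meta.index))
    return Cohort(morphometry=morphometry, meta=meta, quality=quality, config=config)


# ---------------------------------------------------------------------------
# fixtures

#: 4-ROI toy used in the hand-computed distance-index example (literals).
TOY4_LEFT = (1.0, 2.0, 4.0, 8.0)
TOY4_RIGHT = (1.0, 2.0, 4.0, 7.0)


def _long_format(table: MorphometryTable) -> pd.DataFrame:
    rows = []
    for hemi, frame in (("L", table.left), ("R", table.right)):
        stacked = frame.stack()
        rows.append(pd.DataFrame({
            "subject": stacked.index.get_level_values(0),
            "hemisphere": hemi,
            "roi": stacked.index.get_level_values(1),
            "value": stacked.to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the small canonical fixture files used across the test surface.

    Byte-identical for identical seeds.  Includes a 4-ROI toy table (from
    literals), a complete 34-ROI mini-cohort in long form with participants
    and IQM sidecars, and two deliberately broken tables for validator tests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    toy = pd.DataFrame({
        "subject": ["toy"] * 8,
        "hemisphere": ["L"] * 4 + ["R"] * 4,
        "roi": ["roi_a", "roi_b", "roi_c", "roi_d"] * 2,
        "value": list(TOY4_LEFT) + list(TOY4_RIGHT),
    })
    written["toy4_long"] = out_dir / "toy4_long.csv"
    toy.to_csv(written["toy4_long"], index=False)

    cfg = SimulationConfig(
        n_male=3, n_female=3, seed=seed,
        coherence_sd={"male": 0.02, "female": 0.01},
    )
    cohort = generate_cohort(cfg)
    for measure, table in cohort.morphometry.items():
        p = out_dir / f"mini_{measure}_long.csv"
        _long_format(table).to_csv(p, index=False)
        written[f"mini_{measure}_long"] = p
    written["mini_participants"] = out_dir / "mini_participants.tsv"
    cohort.meta.reset_index().rename(columns={"subject": "participant_id"}).to_csv(
        written["mini_participants"], sep="\t", index=False
    )
    written["mini_iqm"] = out_dir / "mini_iqm.tsv"
    cohort.quality.values.reset_index().to_csv(written["mini_iqm"], sep="\t", index=False)

    long_vol = _long_format(cohort.morphometry["volume"])
    no_hemi = long_vol[~((long_vol["subject"] == "sub-0001") & (long_vol["hemisphere"] == "R"))]
    written["broken_missing_hemisphere"] = out_dir / "broken_missing_hemisphere.csv"
    no_hemi.to_csv(written["broken_missing_hemisphere"], index=False)

    no_roi = long_vol[~((long_vol["subject"] == "sub-0002") & (long_vol["roi"] == "insula"))]
    written["broken_missing_roi"] = out_dir / "broken_missing_roi.csv"
    no_roi.to_csv(written["broken_missing_roi"], index=False)
    return written
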