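"""Readers and writers for the three input tables and all pipeline outputs.

Three tables feed the pipeline:

* bilateral ROI morphometry — one value per (subject, hemisphere, ROI) for a
  given measure (``volume``, ``area``, ``thickness``, ``meancurv``), accepted
  as a long table, a wide table with ``lh_<roi>_<measure>`` /
  ``rh_<roi>_<measure>`` columns, or paired FreeSurfer ``?h.aparc.stats``
  files per subject;
* a BIDS-style participants table (id, sex, age, handedness);
* an image-quality-metric table with the five MRIQC-derived scalars
  CJV, CNR, EFC, INU, WM2MAX.

Validation is strict and exclusion-based: a subject failing any check is
dropped (and recorded), never imputed.  All outputs are UTF-8 CSV with a
header row and deterministic column order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .atlas import DEFAULT_ATLAS, ROIAtlas, UnknownROIError

log = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "MorphometryTable",
    "QualityTable",
    "MEASURES",
    "read_morphometry",
    "read_aparc_stats",
    "read_participants",
    "filter_right_handed",
    "read_quality",
    "write_table",
    "write_manifest",
]

#: The four gray-matter measures the pipeline handles.
MEASURES = ("volume", "area", "thickness", "meancurv")

#: aparc.stats column holding each measure.
_APARC_COLUMNS = {
    "volume": "GrayVol",
    "area": "SurfArea",
    "thickness": "ThickAvg",
    "meancurv": "MeanCurv",
}

_IQM_METRICS = ("CJV", "CNR", "EFC", "INU", "WM2MAX")

_SEX_CODES = {"m": "male", "male": "male", "f": "female", "female": "female"}
_HAND_CODES = {
    "r": "right",
    "right": "right",
    "l": "left",
    "left": "left",
    "a": "ambidextrous",
    "ambidextrous": "ambidextrous",
}


class ValidationError(ValueError):
    """Raised when an input table violates the pipeline's contracts."""


@dataclass
class MorphometryTable:
    """Validated bilateral ROI values for one measure.

    ``left`` and ``right`` are subjects-by-34 frames sharing the same row
    index (subject ids) and atlas-ordered columns.  ``excluded`` records
    subjects dropped during validation and why.
    """

    measure: str
    left: pd.DataFrame
    right: pd.DataFrame
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def subjects(self) -> pd.Index:
        return self.left.index

    def __len__(self) -> int:
        return len(self.left)


@dataclass
class QualityTable:
    """Five image-quality metrics per subject.

    ``flagged`` lists subjects with missing/non-finite metrics; they remain
    in ``values`` (as NaN) but are excluded from the robustness stage.
    """

    values: pd.DataFrame
    flagged: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# morphometry


def _normalize_roi_columns(names: Iterable[str], atlas: ROIAtlas) -> list[str]:
    return [atlas.normalize(n) for n in names]


def _from_long(df: pd.DataFrame, measure: str, atlas: ROIAtlas) -> pd.DataFrame:
    cols = {c.lower(): c for c in df.columns}
    for required in ("subject", "hemisphere", "roi", "value"):
        if required not in cols:
            raise ValidationError(f"long table lacks column {required!r}")
    df = df.rename(columns={v: k for k, v in cols.items()})
    if "measure" in df.columns:
        df = df[df["measure"] == measure]
        if df.empty:
            raise ValidationError(f"no rows for measure {measure!r}")
    hemi = (
        df["hemisphere"]
        .astype(str)
        .str.lower()
        .map({"l": "L", "lh": "L", "left": "L", "r": "R", "rh": "R", "right": "R"})
    )
    if hemi.isna().any():
        bad = sorted(df.loc[hemi.isna(), "hemisphere"].astype(str).unique())
        raise ValidationError(f"unknown hemisphere codes: {bad}")
    out = df.assign(hemisphere=hemi, roi=[atlas.normalize(r) for r in df["roi"]])
    value = pd.to_numeric(out["value"], errors="coerce")
    if value.isna().any() and out["value"].notna().any():
        bad_rows = out.index[value.isna() & out["value"].notna()].tolist()[:5]
        raise ValidationError(f"unparseable numeric cells in rows {bad_rows}")
    out["value"] = value
    wide = out.pivot_table(
        index="subject", columns=["hemisphere", "roi"], values="value", aggfunc="first"
    )
    return wide


def _from_wide(df: pd.DataFrame, measure: str, atlas: ROIAtlas) -> pd.DataFrame:
    id_col = None
    for cand in ("subject", "subject_id", "participant_id"):
        for c in df.columns:
            if c.lower() == cand:
                id_col = c
                break
        if id_col:
            break
    if id_col is None:
        raise ValidationError("wide table needs a subject/participant_id column")
    df = df.set_index(id_col)
    pieces = {}
    for c in df.columns:
        name = c.lower()
        for prefix, hemi in (("lh_", "L"), ("rh_", "R")):
            if name.startswith(prefix):
                rest = name[len(prefix):]
                if rest.endswith("_" + measure):
                    roi = rest[: -len(measure) - 1]
                elif "_" not in rest:
                    roi = rest
                else:
                    continue
                try:
                    roi = atlas.normalize(roi)
                except UnknownROIError:
                    continue
                pieces[(hemi, roi)] = pd.to_numeric(df[c], errors="raise")
    if not pieces:
        raise ValidationError(f"no lh_/rh_ columns for measure {measure!r} found")
    wide = pd.DataFrame(pieces, index=df.index)
    wide.columns = pd.MultiIndex.from_tuples(wide.columns, names=["hemisphere", "roi"])
    return wide


def read_aparc_stats(path: str | Path) -> pd.DataFrame:
    """Parse one FreeSurfer ``?h.aparc.stats`` file into a frame.

    Rows are cortical structures; columns come from the ``# ColHeaders``
    line (StructName, SurfArea, GrayVol, ThickAvg, MeanCurv, ...).
    """
    path = Path(path)
    headers: list[str] | None = None
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("# ColHeaders"):
            headers = line.split()[2:]
            continue
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if headers is not None and len(fields) != len(headers):
            raise ValidationError(f"{path}:{lineno}: expected {len(headers)} fields")
        rows.append(fields)
    if headers is None:
        raise ValidationError(f"{path}: no '# ColHeaders' line found")
    df = pd.DataFrame(rows, columns=headers)
    for c in df.columns:
        if c != "StructName":
            df[c] = pd.to_numeric(df[c], errors="raise")
    return df


def _from_aparc_pairs(
    pairs: Mapping[str, tuple[str | Path, str | Path]], measure: str, atlas: ROIAtlas
) -> pd.DataFrame:
    col = _APARC_COLUMNS[measure]
    pieces = {}
    for subject, (lh_path, rh_path) in pairs.items():
        row = {}
        for hemi, p in (("L", lh_path), ("R", rh_path)):
            stats = read_aparc_stats(p)
            for name, value in zip(stats["StructName"], stats[col]):
                try:
                    roi = atlas.normalize(name)
                except UnknownROIError:
                    continue  # non-cortical rows
                row[(hemi, roi)] = value
        pieces[subject] = row
    wide = pd.DataFrame.from_dict(pieces, orient="index")
    wide.columns = pd.MultiIndex.from_tuples(wide.columns, names=["hemisphere", "roi"])
    return wide


def read_morphometry(
    source,
    measure: str,
    atlas: ROIAtlas = DEFAULT_ATLAS,
) -> MorphometryTable:
    """Read and validate bilateral ROI morphometry for one measure.

    ``source`` may be a long or wide CSV/TSV path, an equivalent DataFrame,
    or a mapping ``{subject: (lh.aparc.stats, rh.aparc.stats)}``.  Subjects
    with incomplete ROI coverage or a missing hemisphere are excluded and
    recorded in :attr:`MorphometryTable.excluded`.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    if isinstance(source, Mapping):
        wide = _from_aparc_pairs(source, measure, atlas)
    else:
        if isinstance(source, (str, Path)):
            sep = "\t" if str(source).endswith((".tsv", ".txt")) else ","
            df = pd.read_csv(source, sep=sep)
        else:
            df = source.copy()
        lowered = {c.lower() for c in df.columns}
        if {"subject", "hemisphere", "roi", "value"} <= lowered:
            wide = _from_long(df, measure, atlas)
        else:
            wide = _from_wide(df, measure, atlas)

    excluded: dict[str, str] = {}
    keep = []
    for subject, row in wide.iterrows():
        missing = []
        for hemi in ("L", "R"):
            if hemi not in wide.columns.get_level_values(0):
                missing.append(f"hemisphere {hemi} absent from table")
                continue
            present = row[hemi].dropna()
            lacking = [r for r in atlas.names if r not in present.index]
            if lacking:
                missing.append(f"{hemi}: missing {len(lacking)} ROI(s) e.g. {lacking[0]}")
        if missing:
            excluded[str(subject)] = "; ".join(missing)
        else:
            keep.append(subject)
    if not keep:
        raise ValidationError(
            "no subject passed validation; first failures: "
            + "; ".join(f"{s}: {r}" for s, r in list(excluded.items())[:3])
        )
    if excluded:
        log.warning("excluded %d subject(s) during validation: %s",
                    len(excluded), sorted(excluded))
    wide = wide.loc[keep]
    left = wide["L"][list(atlas.names)].astype(float)
    right = wide["R"][list(atlas.names)].astype(float)
    for frame in (left, right):
        frame.columns.name = None
        frame.index = frame.index.astype(str).rename("subject")
    for name, frame in (("left", left), ("right", right)):
        if not np.isfinite(frame.to_numpy()).all():
            raise ValidationError(f"non-finite values remain in {name} hemisphere")
    if measure in ("volume", "area", "thickness"):
        for frame in (left, right):
            if (frame.to_numpy() <= 0).any():
                raise ValidationError(f"non-positive {measure} values present")
    return MorphometryTable(measure=measure, left=left, right=right, excluded=excluded)


# ---------------------------------------------------------------------------
# participants


def read_participants(
    source, sex_map: Mapping | None = None, hand_map: Mapping | None = None
) -> pd.DataFrame:
    """Read a BIDS-style participants table.

    Returns a frame indexed by subject id with normalized ``sex``
    (male/female), ``age`` (years) and, when present, ``handedness``
    (right/left/ambidextrous).  ``sex_map`` extends the accepted sex
    encodings (e.g. ``{0: "male", 1: "female"}``).
    """
    if isinstance(source, (str, Path)):
        sep = "\t" if str(source).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(source, sep=sep)
    else:
        df = source.copy()
    cols = {c.lower(): c for c in df.columns}
    id_col = next((cols[c] for c in ("participant_id", "subject", "subject_id") if c in cols), None)
    if id_col is None or "sex" not in cols or "age" not in cols:
        raise ValidationError("participants table needs participant_id, sex, age columns")
    codes = dict(_SEX_CODES)
    if sex_map:
        codes.update({str(k).lower(): v for k, v in sex_map.items()})
    sex = df[cols["sex"]].map(lambda v: codes.get(str(v).strip().lower()))
    if sex.isna().any():
        bad = sorted(df.loc[sex.isna(), cols["sex"]].astype(str).unique())
        raise ValidationError(f"unknown sex code(s): {bad}")
    out = pd.DataFrame(
        {"sex": sex.to_numpy(), "age": pd.to_numeric(df[cols["age"]]).to_numpy()},
        index=pd.Index(df[id_col].astype(str), name="subject"),
    )
    if out.index.has_duplicates:
        raise ValidationError("duplicate subject ids in participants table")
    if "handedness" in cols:
        hcodes = dict(_HAND_CODES)
        if hand_map:
            hcodes.update({str(k).lower(): v for k, v in hand_map.items()})
        hand = df[cols["handedness"]].map(lambda v: hcodes.get(str(v).strip().lower()))
        if hand.isna().any():
            bad = sorted(df.loc[hand.isna().to_numpy(), cols["handedness"]].astype(str).unique())
            raise ValidationError(f"unknown handedness code(s): {bad}")
        out["handedness"] = hand.to_numpy()
    return out


def filter_right_handed(meta: pd.DataFrame) -> pd.DataFrame:
    """Restrict a participants frame to right-handed subjects."""
    if "handedness" not in meta.columns:
        return meta
    return meta[meta["handedness"] == "right"]


# ---------------------------------------------------------------------------
# image-quality metrics

_IQM_ALIASES = {
    "cjv": "CJV",
    "cnr": "CNR",
    "efc": "EFC",
    "inu": "INU",
    "inu_med": "INU",
    "inu_range": "INU",
    "wm2max": "WM2MAX",
}


def read_quality(source, meta: pd.DataFrame | None = None) -> QualityTable:
    """Read the five-IQM table (MRIQC-style column aliases accepted).

    When ``meta`` is given, the result is aligned to its subjects; subjects
    absent from the IQM table, or with non-finite metrics, are flagged.
    """
    if isinstance(source, (str, Path)):
        sep = "\t" if str(source).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(source, sep=sep)
    else:
        df = source.copy()
    cols = {c.lower(): c for c in df.columns}
    id_col = next(
        (cols[c] for c in ("subject", "participant_id", "subject_id", "bids_name") if c in cols),
        None,
    )
    if id_col is None:
        raise ValidationError("IQM table needs a subject id column")
    rename = {}
    for lower, orig in cols.items():
        if lower in _IQM_ALIASES and _IQM_ALIASES[lower] not in rename.values():
            rename[orig] = _IQM_ALIASES[lower]
    missing = [m for m in _IQM_METRICS if m not in rename.values()]
    if missing:
        raise ValidationError(f"IQM table missing metric column(s): {missing}")
    values = (
        df.rename(columns=rename)
        .set_index(pd.Index(df[id_col].astype(str), name="subject"))[list(_IQM_METRICS)]
        .astype(float)
    )
    if meta is not None:
        values = values.reindex(meta.index)
    flagged = values.index[~np.isfinite(values).all(axis=1)].tolist()
    if flagged:
        log.warning("flagged %d subject(s) with missing IQMs: %s", len(flagged), flagged)
    return QualityTable(values=values, flagged=flagged)


# ---------------------------------------------------------------------------
# outputs


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "subject") -> Path:
    """Write a frame as UTF-8 CSV with header and stable column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index_label=index_label, encoding="utf-8")
    return path


def write_manifest(manifest: dict, path: str | Path) -> Path:
    """Write a JSON run manifest (seed, config, exclusions, versions)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
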