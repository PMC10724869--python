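"""Cortical ROI atlas: the 34 bilateral FreeSurfer ``aparc`` parcels.

All tables in this package are anchored to a fixed, ordered list of 34
cortical regions per hemisphere (the Desikan–Killiany / DKT cortical
parcel set as spelled by FreeSurfer's ``aparc`` output).  Any input
spelling variant (hyphens, underscores, case) is normalized onto this
canonical list, and every matrix produced downstream uses the same ROI
column order, so that homologous left/right columns always align.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["APARC_ROIS", "ROIAtlas", "UnknownROIError", "DEFAULT_ATLAS"]

#: Canonical FreeSurfer aparc cortical labels, fixed order (34 parcels).
APARC_ROIS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)


class UnknownROIError(ValueError):
    """A label could not be matched to any canonical ROI."""


def _squash(label: str) -> str:
    return label.strip().lower().replace("-", "").replace("_", "").replace(" ", "")


@dataclass(frozen=True)
class ROIAtlas:
    """Ordered 34-label cortical atlas with spelling normalization.

    The ordering is shared by left and right hemispheres; position
    ``index(label)`` is the column of that ROI in every subjects-by-ROI
    matrix in this package.
    """

    names: tuple[str, ...] = APARC_ROIS
    _lookup: dict[str, str] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("atlas labels must be unique")
        object.__setattr__(
            self, "_lookup", {_squash(n): n for n in self.names}
        )

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def normalize(self, label: str) -> str:
        """Map a spelling variant onto the canonical label, or raise."""
        try:
            return self._lookup[_squash(label)]
        except KeyError:
            raise UnknownROIError(f"unknown ROI label: {label!r}") from None

    def index(self, label: str) -> int:
        """0-based position of ``label`` in the canonical ordering."""
        return self.names.index(self.normalize(label))


#: Module-level default; callers that do not care about custom atlases use this.
DEFAULT_ATLAS = ROIAtlas()
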