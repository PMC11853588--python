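"""Division staging and semi-quantitative LFM classification.

Tintinnid cell division is staged by features of the opisthe's developing
oral ciliature (the oral primordium), which are recognisable in live, fixed
and stained material alike:

=========  ==========================================================
stage      defining primordium features
=========  ==========================================================
ED         unordered basal bodies, or polykinetids with two rows
EMD        final number of three-rowed polykinetids on the inner wall
           of a cylindroidal/funnel-shaped indentation
LMD        membranellar zone forms a 6-shaped pattern
ELD        circular zone, parallel to the ventral side
VLD        circular zone, obliquely (finally perpendicularly) oriented
=========  ==========================================================

Cells without a primordium are morphostatic specimens or postdividers; the
two are told apart by cell size and macronuclear arrangement (postdividers
are small with mostly a single horizontally oriented macronucleus).

The amount of intracellular lorica-forming material is additionally binned
into four ordered categories (none / low / moderate / high); here the
binning is driven by the measured total volume against two configurable
cutoffs.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from .errors import StageClassificationError, ValidationError

__all__ = [
    "DivisionStage",
    "LfmCategory",
    "OralPrimordiumState",
    "CellDescriptors",
    "DEFAULT_CATEGORY_THRESHOLDS",
    "assign_stage",
    "classify_lfm_category",
]

#: Default LFM-volume cutoffs (µm³) between low/moderate and moderate/high.
#: A calibration of this package (the original categories were assigned by
#: eye): the printed stage means 982 / 3,212 / 8,624 / 12,679 µm³ then fall
#: into low / moderate / high / high, matching the dominant categories
#: observed per stage.
DEFAULT_CATEGORY_THRESHOLDS: tuple[float, float] = (2_000.0, 8_000.0)


class DivisionStage(enum.IntEnum):
    """Cell-cycle stages; the five divider stages are totally ordered
    ED < EMD < LMD < ELD < VLD."""

    MORPHOSTATIC = 0
    ED = 1
    EMD = 2
    LMD = 3
    ELD = 4
    VLD = 5
    POSTDIVIDER = 6

    @property
    def code(self) -> str:
        return _STAGE_CODES[self]

    @classmethod
    def from_code(cls, code: str) -> "DivisionStage":
        try:
            return _CODE_TO_STAGE[code.strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown stage code {code!r}") from None

    @classmethod
    def dividers(cls) -> tuple["DivisionStage", ...]:
        return (cls.ED, cls.EMD, cls.LMD, cls.ELD, cls.VLD)


_STAGE_CODES = {
    DivisionStage.MORPHOSTATIC: "MORPH",
    DivisionStage.ED: "ED",
    DivisionStage.EMD: "EMD",
    DivisionStage.LMD: "LMD",
    DivisionStage.ELD: "ELD",
    DivisionStage.VLD: "VLD",
    DivisionStage.POSTDIVIDER: "POST",
}
_CODE_TO_STAGE = {v: k for k, v in _STAGE_CODES.items()}


class LfmCategory(enum.IntEnum):
    """Ordinal semi-quantitative LFM amount."""

    NONE = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3


# controlled vocabularies for the primordium state
ORGANISATIONS = ("unordered-basal-bodies", "two-rowed", "three-rowed")
ZONE_SHAPES = ("indentation", "six-shaped", "circular")
ZONE_ORIENTATIONS = ("parallel-to-ventral-side", "oblique", "perpendicular")


@dataclass
class OralPrimordiumState:
    """Declared features of the oral primordium of one specimen.

    When ``present`` is False all other fields must be None.  Zone shape
    and orientation are meaningful only once the polykinetids are
    three-rowed; the orientation only once the zone is circular.
    """

    present: bool
    polykinetid_organisation: str | None = None
    zone_shape: str | None = None
    zone_orientation: str | None = None
    final_polykinetid_number_reached: bool | None = None

    def __post_init__(self) -> None:
        if not self.present:
            extras = [
                self.polykinetid_organisation,
                self.zone_shape,
                self.zone_orientation,
                self.final_polykinetid_number_reached,
            ]
            if any(v is not None for v in extras):
                raise StageClassificationError(
                    "primordium absent but primordium features were given"
                )
            return
        if self.polykinetid_organisation not in ORGANISATIONS:
            raise StageClassificationError(
                f"polykinetid_organisation must be one of {ORGANISATIONS}, "
                f"got {self.polykinetid_organisation!r}"
            )
        if self.zone_shape is not None and self.zone_shape not in ZONE_SHAPES:
            raise StageClassificationError(
                f"zone_shape must be one of {ZONE_SHAPES}"
            )
        if (
            self.zone_orientation is not None
            and self.zone_orientation not in ZONE_ORIENTATIONS
        ):
            raise StageClassificationError(
                f"zone_orientation must be one of {ZONE_ORIENTATIONS}"
            )


@dataclass
class CellDescriptors:
    """Auxiliary descriptors used to tell postdividers from morphostatic
    specimens when no oral primordium is present."""

    size_class: str  # "small" | "large"
    macronucleus_pattern: str  # "horizontal" | "two-longitudinal" | ...


def assign_stage(
    state: OralPrimordiumState,
    auxiliary: CellDescriptors | None = None,
) -> DivisionStage:
    """Map declared oral-primordium features to a division stage.

    Contradictory feature combinations (e.g. a circular membranellar zone on
    two-rowed polykinetids) raise :class:`StageClassificationError` naming
    the conflict.  Without a primordium the auxiliary descriptors decide
    between postdivider and morphostatic specimen; if they are absent the
    call returns MORPHOSTATIC with a low-confidence warning.
    """
    if not state.present:
        if auxiliary is None:
            warnings.warn(
                "no auxiliary cell descriptors: returning MORPHOSTATIC with "
                "low confidence (postdivider cannot be excluded)",
                stacklevel=2,
            )
            return DivisionStage.MORPHOSTATIC
        if (
            auxiliary.size_class == "small"
            and auxiliary.macronucleus_pattern == "horizontal"
        ):
            return DivisionStage.POSTDIVIDER
        return DivisionStage.MORPHOSTATIC

    org = state.polykinetid_organisation
    if org in ("unordered-basal-bodies", "two-rowed"):
        if state.zone_shape is not None or state.zone_orientation is not None:
            raise StageClassificationError(
                f"conflict: membranellar-zone features ({state.zone_shape!r}, "
                f"{state.zone_orientation!r}) with {org} polykinetids"
            )
        return DivisionStage.ED

    # three-rowed polykinetids: middle or late divider, by zone shape
    if state.zone_shape is None:
        raise StageClassificationError(
            "three-rowed polykinetids require a membranellar-zone shape"
        )
    if state.zone_shape == "indentation":
        if state.zone_orientation is not None:
            raise StageClassificationError(
                "conflict: zone orientation given for an indentation-stage zone"
            )
        return DivisionStage.EMD
    if state.zone_shape == "six-shaped":
        if state.zone_orientation is not None:
            raise StageClassificationError(
                "conflict: zone orientation given for a 6-shaped zone"
            )
        return DivisionStage.LMD
    # circular zone: late divider, by orientation
    if state.zone_orientation is None:
        raise StageClassificationError(
            "circular membranellar zone requires an orientation"
        )
    if state.zone_orientation == "parallel-to-ventral-side":
        return DivisionStage.ELD
    return DivisionStage.VLD  # oblique or (just before fission) perpendicular


def classify_lfm_category(
    total_lfm: float,
    thresholds: tuple[float, float] = DEFAULT_CATEGORY_THRESHOLDS,
) -> LfmCategory:
    """Bin a total LFM volume (µm³) into the four ordinal categories.

    Category 0 (none) is reserved for exactly zero volume; positive volumes
    fall into half-open bins ``(0, t1)`` → low, ``[t1, t2)`` → moderate,
    ``[t2, ∞)`` → high.
    """
    if total_lfm < 0:
        raise ValidationError(f"LFM volume must be >= 0 µm³, got {total_lfm}")
    t1, t2 = thresholds
    if not 0 < t1 < t2:
        raise ValidationError("thresholds must be strictly ascending and > 0")
    if total_lfm == 0:
        return LfmCategory.NONE
    if total_lfm < t1:
        return LfmCategory.LOW
    if total_lfm < t2:
        return LfmCategory.MODERATE
    return LfmCategory.HIGH
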