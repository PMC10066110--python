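"""Enlarged-vestibular-aqueduct (EVA) classification rules.

Three rules in clinical use, all with *strict* inequalities (a boundary
value classifies as normal):

* Cincinnati: enlarged if operculum width > 1.9 mm and/or midpoint width
  > 0.9 mm on axial CT;
* Valvassori: enlarged if midpoint width > 1.5 mm;
* volumetric: enlarged if the reconstructed VA volume > 15.4 mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidMeasurementError, InvalidParameterError

CINCINNATI_OPERCULUM_MM = 1.9
CINCINNATI_MIDPOINT_MM = 0.9
VALVASSORI_MIDPOINT_MM = 1.5
VOLUMETRIC_MM3 = 15.4


@dataclass(frozen=True)
class CriteriaThresholds:
    cincinnati_operculum: float = CINCINNATI_OPERCULUM_MM
    cincinnati_midpoint: float = CINCINNATI_MIDPOINT_MM
    valvassori_midpoint: float = VALVASSORI_MIDPOINT_MM
    volumetric: float = VOLUMETRIC_MM3

    def __post_init__(self) -> None:
        if min(
            self.cincinnati_operculum,
            self.cincinnati_midpoint,
            self.valvassori_midpoint,
            self.volumetric,
        ) <= 0:
            raise InvalidParameterError("all thresholds must be > 0")


@dataclass(frozen=True)
class CincinnatiResult:
    enlarged: bool
    midpoint_positive: bool
    operculum_positive: bool

    @property
    def trigger(self) -> str:
        """Which clause(s) fired: 'midpoint', 'operculum', 'both' or 'none'."""
        if self.midpoint_positive and self.operculum_positive:
            return "both"
        if self.midpoint_positive:
            return "midpoint"
        if self.operculum_positive:
            return "operculum"
        return "none"


def _check_nonnegative(**values: float) -> None:
    for name, v in values.items():
        if v < 0:
            raise InvalidMeasurementError(f"{name} must be >= 0, got {v}")


def classify_cincinnati(
    midpoint_mm: float,
    operculum_mm: float,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
) -> CincinnatiResult:
    """Inclusive-or of the two strict Cincinnati clauses."""
    _check_nonnegative(midpoint_mm=midpoint_mm, operculum_mm=operculum_mm)
    mid = midpoint_mm > thresholds.cincinnati_midpoint
    oper = operculum_mm > thresholds.cincinnati_operculum
    return CincinnatiResult(enlarged=mid or oper, midpoint_positive=mid, operculum_positive=oper)


def classify_valvassori(
    midpoint_mm: float, thresholds: CriteriaThresholds = CriteriaThresholds()
) -> bool:
    _check_nonnegative(midpoint_mm=midpoint_mm)
    return midpoint_mm > thresholds.valvassori_midpoint


def classify_volumetric(
    volume_mm3: float, thresholds: CriteriaThresholds = CriteriaThresholds()
) -> bool:
    _check_nonnegative(volume_mm3=volume_mm3)
    return volume_mm3 > thresholds.volumetric
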