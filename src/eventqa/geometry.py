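"""Stimulus size and eccentricity in degrees of visual angle.

The visual angle of a stimulus of extent ``s`` viewed at distance ``d`` is
``theta = 2 * atan(s / (2 d))``; at 57.3 cm distance, 1 cm subtends almost
exactly 1 degree.  Eccentricity uses the same formula with the center-to-
center offset in place of the size.  Off-center stimuli are treated under
the small-tilt approximation (no screen-tilt correction); reports label
them as such.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "ScreenGeometry",
    "StimulusGeometry",
    "PxCmConversion",
    "px_cm_conversion",
    "visual_angle",
    "eccentricity_angle",
    "stimulus_angles",
]

#: relative disagreement between width- and height-based conversion factors
#: above which a measurement problem is flagged (non-square pixels aside)
CONVERSION_WARN_REL = 0.02


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and pixel dimensions of the display plus viewing distance."""

    width_px: float
    height_px: float
    width_cm: float
    height_cm: float
    viewing_distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm", "viewing_distance_cm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class StimulusGeometry:
    """Stimulus extent and center offset, in cm or px (unit-tagged)."""

    width: float
    height: float
    offset_horizontal: float = 0.0
    offset_vertical: float = 0.0
    unit: str = "cm"

    def __post_init__(self) -> None:
        if self.unit not in ("cm", "px"):
            raise ValueError(f"unit must be 'cm' or 'px', got {self.unit!r}")
        if not (self.width > 0 and self.height > 0):
            raise ValueError("stimulus sizes must be positive")


@dataclass(frozen=True)
class PxCmConversion:
    """Pixel-to-cm conversion factors from both screen dimensions."""

    factor_height: float  # cm per px, height-based
    factor_width: float  # cm per px, width-based
    rel_disagreement: float

    @property
    def factor(self) -> float:
        """Mean of the two factors; valid for square pixels."""
        return (self.factor_height + self.factor_width) / 2.0


def px_cm_conversion(screen: ScreenGeometry) -> PxCmConversion:
    """Conversion factor between pixels and centimeters, from both axes.

    The height- and width-based factors agree for square pixels; a relative
    disagreement above 2% triggers a warning, since it indicates measurement
    issues (or a declared non-1:1 pixel aspect ratio).
    """
    fh = screen.height_cm / screen.height_px
    fw = screen.width_cm / screen.width_px
    rel = abs(fh - fw) / ((fh + fw) / 2.0)
    if rel > CONVERSION_WARN_REL:
        warnings.warn(
            f"px/cm conversion factors disagree by {rel:.1%} "
            "(height-based vs width-based); check the screen measurements "
            "or declare a non-square pixel aspect ratio",
            stacklevel=2,
        )
    return PxCmConversion(fh, fw, rel)


def visual_angle(size_cm: float, distance_cm: float) -> float:
    """Visual angle in degrees of an extent seen at a viewing distance."""
    if not size_cm > 0:
        raise ValueError(f"size must be positive, got {size_cm}")
    if not distance_cm > 0:
        raise ValueError(f"distance must be positive, got {distance_cm}")
    return math.degrees(2.0 * math.atan2(size_cm / 2.0, distance_cm))


def eccentricity_angle(offset_cm: float, distance_cm: float) -> float:
    """Eccentricity in degrees of a center-to-center offset.

    Applies the same right-angle construction as :func:`visual_angle` with
    the offset in place of the size; an offset of zero is on-center (0 deg).
    """
    if offset_cm < 0:
        raise ValueError(f"offset must be non-negative, got {offset_cm}")
    if offset_cm == 0:
        return 0.0
    return visual_angle(offset_cm, distance_cm)


def stimulus_angles(screen: ScreenGeometry, stim: StimulusGeometry) -> dict:
    """Width/height and horizontal/vertical eccentricity, all in degrees.

    Pixel-specified stimuli are converted to cm through the screen's
    conversion factor first.  Off-center values carry the small-tilt
    approximation; the report labels them accordingly.
    """
    if stim.unit == "px":
        c = px_cm_conversion(screen).factor
        w, h = stim.width * c, stim.height * c
        oh, ov = abs(stim.offset_horizontal) * c, abs(stim.offset_vertical) * c
    else:
        w, h = stim.width, stim.height
        oh, ov = abs(stim.offset_horizontal), abs(stim.offset_vertical)
    d = screen.viewing_distance_cm
    return {
        "width_deg": visual_angle(w, d),
        "height_deg": visual_angle(h, d),
        "eccentricity_horizontal_deg": eccentricity_angle(oh, d),
        "eccentricity_vertical_deg": eccentricity_angle(ov, d),
        "off_center": bool(oh or ov),
        "viewing_distance_cm": d,
    }
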