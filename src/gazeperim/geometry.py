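"""Two-arm perimeter geometry.

The device is a cross of two perpendicular LED arms — one horizontal, one
vertical — with a fixation marker at the crossing point (0°).  Stimulus
locations sit at integer multiples of the angular spacing (1° by default) on
either side of fixation; there is no LED at 0° itself.  Angles follow the
patient's frame: azimuth positive toward the patient's right, elevation
positive upward.  The same convention is used for gaze angles everywhere
downstream.

Physical dimensions (arm span, depth, LED pitch) are carried as metadata
only; the angular grid is the authoritative coordinate system, because no
single arc shape reconciles the printed linear and angular figures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

__all__ = [
    "HORIZONTAL",
    "VERTICAL",
    "ArmGeometry",
    "StimulusLocation",
    "build_default_device",
    "enumerate_locations",
    "angle_to_index",
    "index_to_angle",
]

HORIZONTAL = "horizontal"
VERTICAL = "vertical"
_ARMS = (HORIZONTAL, VERTICAL)


@dataclass(frozen=True)
class StimulusLocation:
    """One addressable LED position on an arm.

    ``angle`` is a signed angle in degrees (horizontal arm: positive =
    patient's right; vertical arm: positive = up) and is never 0 — the
    fixation marker occupies the origin.  ``led_index`` is the 0-based
    position along the strip counting from the negative-extreme end.
    """

    arm: str
    angle: float
    led_index: int

    @property
    def axis(self) -> str:
        """Gaze-angle component this location lives on."""
        return "azimuth" if self.arm == HORIZONTAL else "elevation"


@dataclass(frozen=True)
class ArmGeometry:
    """Geometry of a single perimeter arm.

    Parameters
    ----------
    arm : {"horizontal", "vertical"}
    angular_spacing : float
        Angular pitch between adjacent stimulus locations, degrees.
    extent_neg, extent_pos : int
        Number of locations on the negative / positive side of fixation.
    span_mm, depth_mm, pitch_mm, radius_mm : float, optional
        Physical footprint metadata (device span between arm extremes,
        depth, linear LED pitch, nominal eye-to-LED viewing distance).
        Never used to derive angles.
    """

    arm: str
    angular_spacing: float = 1.0
    extent_neg: int = 95
    extent_pos: int = 95
    span_mm: float | None = None
    depth_mm: float | None = None
    pitch_mm: float | None = None
    radius_mm: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in _ARMS:
            raise ValueError(f"arm must be one of {_ARMS}, got {self.arm!r}")
        if self.angular_spacing <= 0:
            raise ValueError("angular_spacing must be positive")
        if self.extent_neg < 0 or self.extent_pos < 0:
            raise ValueError("extents must be non-negative")
        if self.extent_neg + self.extent_pos == 0:
            raise ValueError("arm must carry at least one location")

    @property
    def n_locations(self) -> int:
        return self.extent_neg + self.extent_pos

    @property
    def min_angle(self) -> float:
        return -self.extent_neg * self.angular_spacing

    @property
    def max_angle(self) -> float:
        return self.extent_pos * self.angular_spacing

    def angles(self) -> list[float]:
        """All location angles, ascending; 0° is absent (fixation)."""
        s = self.angular_spacing
        neg = [-s * k for k in range(self.extent_neg, 0, -1)]
        pos = [s * k for k in range(1, self.extent_pos + 1)]
        return neg + pos

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "spacing_deg": self.angular_spacing,
            "neg": self.extent_neg,
            "pos": self.extent_pos,
            "span_mm": self.span_mm,
            "depth_mm": self.depth_mm,
            "pitch_mm": self.pitch_mm,
            "radius_mm": self.radius_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArmGeometry":
        return cls(
            arm=d["arm"],
            angular_spacing=d.get("spacing_deg", 1.0),
            extent_neg=d["neg"],
            extent_pos=d["pos"],
            span_mm=d.get("span_mm"),
            depth_mm=d.get("depth_mm"),
            pitch_mm=d.get("pitch_mm"),
            radius_mm=d.get("radius_mm"),
        )


def build_default_device() -> tuple[ArmGeometry, ArmGeometry]:
    """Default device: 190 horizontal + 135 vertical locations at 1°.

    The horizontal arm has 95 locations per side (−95°…−1°, +1°…+95°).
    The vertical arm's 135 locations are split 75 inferior / 60 superior,
    matching the asymmetry of the normal monocular field.  Arm span 870 mm,
    depth 525 mm and 10 mm linear LED pitch are recorded as metadata.
    """
    horizontal = ArmGeometry(
        arm=HORIZONTAL, angular_spacing=1.0, extent_neg=95, extent_pos=95,
        span_mm=870.0, depth_mm=525.0, pitch_mm=10.0,
    )
    vertical = ArmGeometry(
        arm=VERTICAL, angular_spacing=1.0, extent_neg=75, extent_pos=60,
        span_mm=870.0, depth_mm=525.0, pitch_mm=10.0,
    )
    return horizontal, vertical


def enumerate_locations(g: ArmGeometry) -> list[StimulusLocation]:
    """All stimulus locations on an arm, sorted by angle ascending.

    ``led_index`` runs 0..N−1 in the same order, so the negative-extreme
    LED is index 0.  Adjacent angles differ by the angular spacing except
    across the 0° fixation gap, where the difference is twice the spacing.
    """
    return [
        StimulusLocation(arm=g.arm, angle=a, led_index=i)
        for i, a in enumerate(g.angles())
    ]


def angle_to_index(g: ArmGeometry, angle: float) -> int:
    """LED index for a location angle; rejects 0° and out-of-range angles."""
    s = g.angular_spacing
    k = round(angle / s)
    if abs(angle - k * s) > 1e-9 * max(1.0, abs(angle)):
        raise ValueError(f"{angle}° is not on the {s}° grid")
    if k == 0:
        raise ValueError("0° is the fixation point; no stimulus location there")
    if k < -g.extent_neg or k > g.extent_pos:
        raise ValueError(
            f"{angle}° outside arm range [{g.min_angle}°, {g.max_angle}°]"
        )
    if k < 0:
        return k + g.extent_neg
    return g.extent_neg + k - 1


def index_to_angle(g: ArmGeometry, index: int) -> float:
    """Location angle for an LED index (inverse of :func:`angle_to_index`)."""
    if not 0 <= index < g.n_locations:
        raise ValueError(f"led index {index} outside 0..{g.n_locations - 1}")
    if index < g.extent_neg:
        return (index - g.extent_neg) * g.angular_spacing
    return (index - g.extent_neg + 1) * g.angular_spacing


def device_to_json(arms: tuple[ArmGeometry, ArmGeometry]) -> str:
    return json.dumps([a.to_dict() for a in arms], indent=2, sort_keys=True)


def device_from_json(text: str) -> tuple[ArmGeometry, ArmGeometry]:
    return tuple(ArmGeometry.from_dict(d) for d in json.loads(text))
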