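"""Styling vocabulary shared by the scene graph and the depiction builder."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

RGB = tuple[int, int, int]

__all__ = ["FillMode", "NodeStyle", "DepictionStyle", "Look"]


class FillMode(Enum):
    SOLID = "solid"
    RADIAL_GRADIENT = "radial_gradient"
    LINEAR_GRADIENT = "linear_gradient"
    STROKE_ONLY = "stroke_only"


@dataclass(frozen=True)
class NodeStyle:
    """Fill and stroke of one scene primitive.

    ``stroke_width`` is in scene units (Ångström × scale). Wires are always
    stroke-only: they have no area to fill.
    """

    fill_mode: FillMode = FillMode.SOLID
    color: RGB = (128, 128, 128)
    opacity: float = 1.0
    stroke_color: RGB = (0, 0, 0)
    stroke_width: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.opacity <= 1.0:
            raise ValueError(f"opacity must be in [0, 1], got {self.opacity}")
        if self.stroke_width < 0:
            raise ValueError(f"stroke width must be >= 0, got {self.stroke_width}")


class DepictionStyle(Enum):
    """The four molecule depiction types."""

    SPACE_FILLING = "space-filling"
    BALL_AND_STICK = "ball-and-stick"
    TUBE = "tube"
    WIREFRAME = "wireframe"


class Look(Enum):
    """Cartoon = flat fills with outline; glossy = gradient fills."""

    CARTOON = "cartoon"
    GLOSSY = "glossy"
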