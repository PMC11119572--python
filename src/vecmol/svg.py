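"""SVG document model and bit-stable serializer.

Draw items become ``<path>`` elements with inline style attributes (no CSS
classes) so every polygon stays individually editable in vector-graphics
editors. Glossy fills reference shared gradient definitions in ``<defs>``;
identical (kind, color) pairs reuse one definition, keyed by a
deterministic id. Serialization is plain string assembly with fixed
attribute order and fixed-precision coordinates, so identical documents
are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .hull import Polygon2D
from .scene import DrawItem
from .style import RGB, FillMode

__all__ = [
    "GradientStop",
    "GradientDef",
    "SvgPath",
    "SvgDocument",
    "compute_view_box",
    "polygon_path",
    "points_path",
    "gradient_for",
    "build_document",
    "serialize",
    "DEFAULT_PRECISION",
    "DEFAULT_PADDING",
]

#: Decimal places written for every coordinate. The main lever behind
#: compact files: 3 decimals at Ångström scale is far below visual
#: resolution.
DEFAULT_PRECISION = 3

#: View-box padding in scene units added on every side of the tight
#: bounding box.
DEFAULT_PADDING = 2.0

# Glossy gradient scheme: three stops, specular highlight lightened and rim
# darkened by a fixed lightness shift. Purely cosmetic; isolated here so the
# look can be retuned in one place.
_GRADIENT_LIGHTEN = 0.35
_GRADIENT_DARKEN = 0.35
_GRADIENT_OFFSETS = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class GradientStop:
    offset: float
    color: RGB


@dataclass(frozen=True)
class GradientDef:
    """One reusable gradient definition; ``id`` is derived from kind+color
    so equal styles dedupe to a single definition."""

    id: str
    kind: str  # "radial" | "linear"
    stops: tuple[GradientStop, ...]


@dataclass(frozen=True)
class SvgPath:
    d: str
    fill: str            # "rgb(...)", "url(#id)" or "none"
    fill_opacity: float
    stroke: str | None
    stroke_width: float
    stroke_opacity: float


@dataclass
class SvgDocument:
    view_box: tuple[float, float, float, float]
    window: tuple[float, float] | None = None
    defs: list[GradientDef] = field(default_factory=list)
    elements: list[SvgPath] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.view_box[2] <= 0 or self.view_box[3] <= 0:
            raise ValueError("view box width and height must be positive")


def _fmt(value: float, precision: int) -> str:
    return f"{value:.{precision}f}"


def _rgb(color: RGB) -> str:
    return f"rgb({color[0]},{color[1]},{color[2]})"


def compute_view_box(
    items: Sequence[DrawItem], padding: float = DEFAULT_PADDING
) -> tuple[float, float, float, float]:
    """Tight bounding box over all item vertices, padded on every side."""
    if not items:
        raise ValueError("cannot compute a view box for an empty scene")
    xs = [p.x for it in items for p in it.points]
    ys = [p.y for it in items for p in it.points]
    min_x, max_x = min(xs), max(xs)
    min_y, max_y = min(ys), max(ys)
    return (
        min_x - padding,
        min_y - padding,
        (max_x - min_x) + 2 * padding,
        (max_y - min_y) + 2 * padding,
    )


def polygon_path(poly: Polygon2D, precision: int = DEFAULT_PRECISION) -> str:
    """Closed SVG path data ("M … L … Z") for a convex polygon."""
    if len(poly.vertices) < 3:
        raise ValueError("polygon path needs at least 3 vertices")
    return points_path(poly.vertices, precision, closed=True)


def points_path(points: Sequence, precision: int, closed: bool) -> str:
    coords = [
        f"{_fmt(p.x, precision)} {_fmt(p.y, precision)}" for p in points
    ]
    body = "M " + " L ".join(coords)
    return body + " Z" if closed else body


def _shift(color: RGB, amount: float) -> RGB:
    """Positive amount lightens toward white, negative darkens toward black."""
    if amount >= 0:
        return tuple(round(c + amount * (255 - c)) for c in color)  # type: ignore[return-value]
    return tuple(round(c * (1 + amount)) for c in color)  # type: ignore[return-value]


def gradient_for(node_kind: str, base_color: RGB) -> GradientDef:
    """Glossy gradient for a primitive kind: radial for spheres, linear for
    cylinders, three stops from specular highlight through base to rim."""
    if node_kind not in ("sphere", "cylinder"):
        raise ValueError(f"no gradient defined for node kind {node_kind!r}")
    kind = "radial" if node_kind == "sphere" else "linear"
    prefix = "rg" if kind == "radial" else "lg"
    r, g, b = base_color
    stops = (
        GradientStop(_GRADIENT_OFFSETS[0], _shift(base_color, _GRADIENT_LIGHTEN)),
        GradientStop(_GRADIENT_OFFSETS[1], base_color),
        GradientStop(_GRADIENT_OFFSETS[2], _shift(base_color, -_GRADIENT_DARKEN)),
    )
    return GradientDef(id=f"{prefix}-{r:02x}{g:02x}{b:02x}", kind=kind, stops=stops)


def build_document(
    items: Sequence[DrawItem],
    precision: int = DEFAULT_PRECISION,
    padding: float = DEFAULT_PADDING,
    window: tuple[float, float] | None = None,
    view_box: tuple[float, float, float, float] | None = None,
) -> SvgDocument:
    """Assemble draw items (already in painter's order) into a document."""
    if view_box is None:
        view_box = compute_view_box(items, padding)
    defs: dict[str, GradientDef] = {}
    elements: list[SvgPath] = []
    for it in items:
        mode = it.style.fill_mode
        if it.closed and mode is not FillMode.STROKE_ONLY:
            d = points_path(it.points, precision, closed=True)
            if mode is FillMode.SOLID:
                fill = _rgb(it.style.color)
            else:
                kind = "sphere" if mode is FillMode.RADIAL_GRADIENT else "cylinder"
                grad = gradient_for(kind, it.style.color)
                defs.setdefault(grad.id, grad)
                fill = f"url(#{grad.id})"
            stroke = _rgb(it.style.stroke_color) if it.style.stroke_width > 0 else None
            elements.append(
                SvgPath(
                    d=d,
                    fill=fill,
                    fill_opacity=it.style.opacity,
                    stroke=stroke,
                    stroke_width=it.style.stroke_width,
                    stroke_opacity=it.style.opacity,
                )
            )
        else:
            d = points_path(it.points, precision, closed=it.closed)
            elements.append(
                SvgPath(
                    d=d,
                    fill="none",
                    fill_opacity=1.0,
                    stroke=_rgb(it.style.stroke_color),
                    stroke_width=it.style.stroke_width,
                    stroke_opacity=it.style.opacity,
                )
            )
    return SvgDocument(
        view_box=view_box,
        window=window,
        defs=sorted(defs.values(), key=lambda g: g.id),
        elements=elements,
    )


def _serialize_gradient(g: GradientDef, precision: int) -> str:
    stops = "".join(
        f'<stop offset="{_fmt(s.offset, 2)}" stop-color="{_rgb(s.color)}"/>'
        for s in g.stops
    )
    if g.kind == "radial":
        # highlight offset toward the upper-left for a lit-from-above look
        head = (
            f'<radialGradient id="{g.id}" cx="0.4" cy="0.4" r="0.75" '
            f'fx="0.34" fy="0.34">'
        )
        return head + stops + "</radialGradient>"
    head = f'<linearGradient id="{g.id}" x1="0" y1="0" x2="0" y2="1">'
    return head + stops + "</linearGradient>"


def serialize(doc: SvgDocument, precision: int = DEFAULT_PRECISION) -> str:
    """Write the document as SVG 1.1 text; byte-identical for equal input.

    ``width``/``height`` appear on the root only when a window is set; the
    ``viewBox`` is always present.
    """
    vb = " ".join(_fmt(v, precision) for v in doc.view_box)
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="{vb}"']
    if doc.window is not None:
        parts.append(
            f' width="{_fmt(doc.window[0], precision)}"'
            f' height="{_fmt(doc.window[1], precision)}"'
        )
    parts.append(">")
    if doc.defs:
        parts.append("<defs>")
        for g in doc.defs:
            parts.append(_serialize_gradient(g, precision))
        parts.append("</defs>")
    for el in doc.elements:
        attrs = [f'<path d="{el.d}" fill="{el.fill}"']
        if el.fill != "none" and el.fill_opacity != 1.0:
            attrs.append(f' fill-opacity="{_fmt(el.fill_opacity, 3)}"')
        if el.stroke is not None and el.stroke_width > 0:
            attrs.append(
                f' stroke="{el.stroke}"'
                f' stroke-width="{_fmt(el.stroke_width, precision)}"'
            )
            if el.stroke_opacity != 1.0:
                attrs.append(f' stroke-opacity="{_fmt(el.stroke_opacity, 3)}"')
        attrs.append("/>")
        parts.append("".join(attrs))
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
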