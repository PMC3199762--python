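"""Deterministic 2D scene construction and SVG/PNG export.

A figure is two horizontal genome rulers — panel A above, panel B below —
with synteny ribbons (or midpoint lines) drawn between them and annotation
tracks stacked outward from each ruler: panel A's tracks above its ruler,
panel B's below, matching the canonical dual-genome layout.

The scene is a flat ordered list of glyphs (z-order = list order):

    panel-A tracks, panel-A ruler+ticks, synteny glyphs,
    panel-B ruler+ticks, panel-B tracks, text labels.

Everything is deterministic: identical (dataset, state, canvas) inputs give
an identical glyph list, and the SVG serializer uses fixed element ordering
and fixed 2-decimal numeric formatting with no timestamps, so exported SVG
bytes are stable across runs and processes.  PNG is a rasterization of the
same scene; byte-stability across rasterizer versions is not promised, so
pipelines that need byte identity should compare SVG.

A forward-orientation record maps to a plain quadrilateral ribbon; a record
whose two sides have opposite orientation (an inversion) has its bottom edge
traversed in the opposite direction, producing the self-crossing "twisted"
ribbon that is the standard visual signature of an inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from PIL import Image, ImageDraw

from . import viewmodel
from .colors import PALETTE, resolve_color, sequential, to_rgb
from .errors import ConfigError
from .formats import AnnotationFeature, Dataset, SyntenyRecord
from .viewmodel import ViewState, Viewport

RIBBON_OPACITY = 0.6  # fixed so overlapping blocks stay readable

GLYPH_KINDS = (
    "ruler", "tick", "tick_label", "ribbon", "segment", "box", "arrow", "bar", "text",
)


@dataclass(frozen=True)
class CanvasSpec:
    """Pixel geometry of the figure."""

    width_px: int = 1000
    height_px: int = 620
    margin: int = 60
    panel_gap: int = 18
    track_lane_height: int = 16
    font_size: int = 10

    def __post_init__(self) -> None:
        if self.drawable_width <= 0:
            raise ConfigError("canvas too narrow: width_px - 2*margin must be > 0")

    @property
    def drawable_width(self) -> int:
        return self.width_px - 2 * self.margin

    @property
    def x_min(self) -> float:
        return float(self.margin)

    @property
    def x_max(self) -> float:
        return float(self.width_px - self.margin)


@dataclass
class Glyph:
    """One drawable primitive; ``source`` links back to its record/feature."""

    kind: str
    points: list[tuple[float, float]]
    fill: str | None = None
    stroke: str | None = None
    opacity: float = 1.0
    text: str | None = None
    source: object = None


@dataclass
class Scene:
    canvas: CanvasSpec
    glyphs: list[Glyph] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Coordinate transform and ruler ticks
# ---------------------------------------------------------------------------

def to_canvas_x(pos: float, viewport: Viewport, canvas: CanvasSpec) -> float:
    """Linear bp -> px map: the left edge of base ``pos`` under the viewport.

    Positions outside the viewport extrapolate linearly; clipping is applied
    later, by the glyph layout.
    """
    span = viewport.span
    return canvas.margin + (pos - viewport.start) / span * canvas.drawable_width


def to_bp(x: float, viewport: Viewport, canvas: CanvasSpec) -> float:
    """Inverse of :func:`to_canvas_x`."""
    return viewport.start + (x - canvas.margin) / canvas.drawable_width * viewport.span


def ruler_ticks(viewport: Viewport, max_ticks: int = 10) -> list[tuple[int, str]]:
    """Tick positions and labels for a viewport.

    The step is the smallest member of the 1-2-5 ladder ({1,2,5} x 10^k)
    placing at most ``max_ticks`` ticks (multiples of the step) inside the
    viewport.  Labels use thousands separators and a bp/kb/Mb unit chosen so
    tick values divide evenly.
    """
    if max_ticks < 2:
        raise ConfigError(f"max_ticks must be >= 2, got {max_ticks}")
    step = tick_step(viewport.start, viewport.end, max_ticks)
    first = ((viewport.start + step - 1) // step) * step
    ticks = []
    pos = first
    while pos <= viewport.end:
        ticks.append((pos, _tick_label(pos, step)))
        pos += step
    return ticks


def tick_step(start: int, end: int, max_ticks: int) -> int:
    """Smallest 1-2-5-ladder step with <= max_ticks multiples in [start, end]."""
    for k in range(0, 15):
        for mult in (1, 2, 5):
            step = mult * 10 ** k
            count = end // step - (start - 1) // step
            if count <= max_ticks:
                return step
    raise ConfigError("no tick step found (span too large)")  # pragma: no cover


def _tick_label(pos: int, step: int) -> str:
    if step % 1_000_000 == 0:
        return f"{pos // 1_000_000:,} Mb"
    if step % 1_000 == 0:
        return f"{pos // 1_000:,} kb"
    return f"{pos:,} bp"


# ---------------------------------------------------------------------------
# Color assignment
# ---------------------------------------------------------------------------

def color_for(
    record: SyntenyRecord,
    scheme: str,
    drawn: Sequence[SyntenyRecord],
) -> str:
    """Ribbon color for one record of the drawn set.

    ``categorical``: cycle the 12-color palette by the record's index in the
    drawn set.  ``attribute:<name>``: min-max normalize the attribute over
    the drawn set and map through the sequential colormap; when all values
    are equal every record gets the colormap midpoint.
    """
    index = next(i for i, r in enumerate(drawn) if r is record)
    return assign_colors(drawn, scheme)[index]


def assign_colors(drawn: Sequence[SyntenyRecord], scheme: str) -> list[str]:
    if scheme == "categorical":
        return [PALETTE[i % len(PALETTE)] for i in range(len(drawn))]
    if scheme.startswith("attribute:"):
        name = scheme.partition(":")[2]
        values = [viewmodel.record_attribute(r, name) for r in drawn]
        if not values:
            return []
        vmin, vmax = min(values), max(values)
        if vmax == vmin:
            return [sequential(0.5)] * len(drawn)
        return [sequential((v - vmin) / (vmax - vmin)) for v in values]
    raise ConfigError(f"unknown color scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Synteny glyphs
# ---------------------------------------------------------------------------

def _clamp_x(x: float, canvas: CanvasSpec) -> float:
    return min(canvas.x_max, max(canvas.x_min, x))


def layout_synteny(
    records: Sequence[SyntenyRecord],
    state: ViewState,
    canvas: CanvasSpec,
    y_a: float,
    y_b: float,
) -> list[Glyph]:
    """One ribbon (blocks mode) or midpoint segment (lines mode) per record.

    Ribbon corners are the canvas-x images of the record's interval endpoints
    (top edge on panel A at ``y_a``, bottom edge on panel B at ``y_b``);
    inverted records have their bottom corners swapped, so the ribbon
    self-crosses.  X extents are clipped to the drawable area.
    """
    colors = assign_colors(records, state.color_scheme)
    glyphs: list[Glyph] = []
    for rec, color in zip(records, colors):
        sides = viewmodel.record_sides(rec, state.pair)
        if sides is None:  # pragma: no cover - callers pre-select the pair
            continue
        iv_a, iv_b = sides
        xa1 = _clamp_x(to_canvas_x(iv_a.start, state.viewport_a, canvas), canvas)
        xa2 = _clamp_x(to_canvas_x(iv_a.end, state.viewport_a, canvas), canvas)
        xb1 = _clamp_x(to_canvas_x(iv_b.start, state.viewport_b, canvas), canvas)
        xb2 = _clamp_x(to_canvas_x(iv_b.end, state.viewport_b, canvas), canvas)
        if state.display_mode == viewmodel.LINES:
            glyphs.append(
                Glyph(
                    kind="segment",
                    points=[((xa1 + xa2) / 2, y_a), ((xb1 + xb2) / 2, y_b)],
                    stroke=color,
                    opacity=RIBBON_OPACITY,
                    source=rec,
                )
            )
            continue
        if rec.is_inverted:
            bottom = [(xb1, y_b), (xb2, y_b)]  # swapped: twisted ribbon
        else:
            bottom = [(xb2, y_b), (xb1, y_b)]
        glyphs.append(
            Glyph(
                kind="ribbon",
                points=[(xa1, y_a), (xa2, y_a), *bottom],
                fill=color,
                opacity=RIBBON_OPACITY,
                source=rec,
            )
        )
    return glyphs


def ribbon_is_crossed(glyph: Glyph) -> bool:
    """True when the ribbon's top and bottom edges run in opposite directions."""
    if glyph.kind != "ribbon" or len(glyph.points) != 4:
        raise ConfigError("ribbon_is_crossed expects a 4-corner ribbon glyph")
    # top edge runs p0->p1, bottom edge is drawn p2->p3; a proper (uncrossed)
    # quad traverses the bottom in the opposite direction to the top
    (x0, _), (x1, _), (x2, _), (x3, _) = glyph.points
    return (x1 - x0) * (x3 - x2) > 0


# ---------------------------------------------------------------------------
# Annotation track glyphs
# ---------------------------------------------------------------------------

def layout_tracks(
    features: Sequence[AnnotationFeature],
    state: ViewState,
    panel: str,
    canvas: CanvasSpec,
    ruler_y: float,
) -> list[Glyph]:
    """Feature glyphs for one panel's visible tracks.

    Tracks stack outward from the ruler (up for panel A, down for panel B) in
    the panel's track order; hidden tracks occupy no lane.  Features wholly
    outside the viewport produce no glyph; others are clipped to the
    viewport.  Track-level style overrides beat per-feature shape/color.
    Shapes: box = filled rectangle; arrow = rectangle with a strand-pointing
    head (strand "." falls back to box); line = bar from the lane floor whose
    height scales with the feature's value (fixed thin bar when absent).
    """
    if panel not in ("A", "B"):
        raise ConfigError(f"panel must be 'A' or 'B', got {panel!r}")
    viewport = state.viewport_a if panel == "A" else state.viewport_b
    order = state.tracks.visible_order(panel)
    lane_h = canvas.track_lane_height
    direction = -1 if panel == "A" else 1

    # per-track value range for variable-height bars (over drawn features)
    track_values: dict[str, list[float]] = {}
    for feat in features:
        if feat.value is not None and feat.track in order:
            track_values.setdefault(feat.track, []).append(feat.value)

    glyphs: list[Glyph] = []
    for feat in features:
        if feat.seq != viewport.seq or feat.track not in order:
            continue
        if not feat.interval.overlaps(viewport.start, viewport.end):
            continue
        lane = order.index(feat.track)
        # lane box: [y_top, y_top + lane_h), stacked outward from the ruler
        offset = canvas.panel_gap + lane * lane_h
        y_top = ruler_y + direction * offset - (lane_h if direction == -1 else 0)
        y_bot = y_top + lane_h
        x1 = _clamp_x(to_canvas_x(feat.interval.start, viewport, canvas), canvas)
        x2 = _clamp_x(to_canvas_x(feat.interval.end + 1, viewport, canvas), canvas)
        shape, color = feat.shape, feat.color
        ov_shape, ov_color = state.tracks.style_override.get(feat.track, (None, None))
        if ov_shape:
            shape = ov_shape
        if ov_color:
            color = ov_color
        color = resolve_color(color)
        pad = 2.0
        if shape == "arrow" and feat.strand in ("+", "-"):
            glyphs.append(
                _arrow_glyph(x1, x2, y_top + pad, y_bot - pad, feat.strand, color, feat)
            )
        elif shape == "line":
            values = track_values.get(feat.track, [])
            if feat.value is None:
                h = 3.0
            else:
                vmin, vmax = min(values), max(values)
                frac = 1.0 if vmax == vmin else (feat.value - vmin) / (vmax - vmin)
                h = (0.15 + 0.85 * frac) * (lane_h - 2 * pad)
            base = y_bot - pad if panel == "A" else y_top + pad
            top = base - h if panel == "A" else base + h
            y_lo, y_hi = (top, base) if panel == "A" else (base, top)
            glyphs.append(
                Glyph(
                    kind="bar",
                    points=_rect(x1, x2, y_lo, y_hi),
                    fill=color,
                    source=feat,
                )
            )
        else:  # box, or arrow with "." strand
            glyphs.append(
                Glyph(
                    kind="box",
                    points=_rect(x1, x2, y_top + pad, y_bot - pad),
                    fill=color,
                    source=feat,
                )
            )
    return glyphs


def _rect(x1: float, x2: float, y1: float, y2: float) -> list[tuple[float, float]]:
    return [(x1, y1), (x2, y1), (x2, y2), (x1, y2)]


def _arrow_glyph(
    x1: float, x2: float, y1: float, y2: float, strand: str, color: str,
    source: object,
) -> Glyph:
    head = min(6.0, max(0.0, x2 - x1) * 0.4)
    ym = (y1 + y2) / 2
    if strand == "+":
        points = [(x1, y1), (x2 - head, y1), (x2, ym), (x2 - head, y2), (x1, y2)]
    else:
        points = [(x2, y1), (x1 + head, y1), (x1, ym), (x1 + head, y2), (x2, y2)]
    return Glyph(kind="arrow", points=points, fill=color, source=source)


# ---------------------------------------------------------------------------
# Full figure
# ---------------------------------------------------------------------------

def _ruler_glyphs(
    viewport: Viewport, canvas: CanvasSpec, y: float, max_ticks: int = 10
) -> list[Glyph]:
    glyphs = [
        Glyph(kind="ruler", points=[(canvas.x_min, y), (canvas.x_max, y)], stroke="#000000")
    ]
    for pos, label in ruler_ticks(viewport, max_ticks):
        x = to_canvas_x(pos, viewport, canvas)
        glyphs.append(Glyph(kind="tick", points=[(x, y - 4), (x, y + 4)], stroke="#000000"))
        glyphs.append(
            Glyph(
                kind="tick_label",
                points=[(x, y + 14)],
                fill="#000000",
                text=label,
            )
        )
    return glyphs


def panel_geometry(dataset: Dataset, state: ViewState, canvas: CanvasSpec) -> tuple[float, float]:
    """Y positions of the two rulers given the visible track lane counts."""
    lanes_a = len(state.tracks.visible_order("A"))
    lanes_b = len(state.tracks.visible_order("B"))
    y_a = canvas.margin + canvas.panel_gap + lanes_a * canvas.track_lane_height
    y_b = canvas.height_px - canvas.margin - canvas.panel_gap - lanes_b * canvas.track_lane_height - 20
    if y_b - y_a < 40:
        raise ConfigError("canvas too short for the requested track lanes")
    return float(y_a), float(y_b)


def render_figure(dataset: Dataset, state: ViewState, canvas: CanvasSpec | None = None) -> Scene:
    """Assemble the full deterministic scene for one view state."""
    canvas = canvas or CanvasSpec()
    y_a, y_b = panel_geometry(dataset, state, canvas)
    records = viewmodel.visible_records(dataset, state)
    feats_a = [f for f in dataset.features if f.seq == state.pair[0]]
    feats_b = [f for f in dataset.features if f.seq == state.pair[1]]

    glyphs: list[Glyph] = []
    glyphs += layout_tracks(feats_a, state, "A", canvas, y_a)
    glyphs += _ruler_glyphs(state.viewport_a, canvas, y_a)
    glyphs += layout_synteny(records, state, canvas, y_a + 5, y_b - 5)
    glyphs += _ruler_glyphs(state.viewport_b, canvas, y_b)
    glyphs += layout_tracks(feats_b, state, "B", canvas, y_b)

    # labels: sequence name left of each ruler, track names left of each lane
    labels: list[Glyph] = [
        Glyph(kind="text", points=[(4.0, y_a + 4)], fill="#000000", text=state.pair[0]),
        Glyph(kind="text", points=[(4.0, y_b + 4)], fill="#000000", text=state.pair[1]),
    ]
    for panel, y in (("A", y_a), ("B", y_b)):
        direction = -1 if panel == "A" else 1
        for lane, track in enumerate(state.tracks.visible_order(panel)):
            offset = canvas.panel_gap + lane * canvas.track_lane_height
            y_top = y + direction * offset - (canvas.track_lane_height if panel == "A" else 0)
            labels.append(
                Glyph(
                    kind="text",
                    points=[(4.0, y_top + canvas.track_lane_height / 2 + 3)],
                    fill="#555555",
                    text=track,
                )
            )
    glyphs += labels
    return Scene(canvas=canvas, glyphs=glyphs)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # fixed 2-decimal formatting; avoid "-0.00"
    s = f"{x:.2f}"
    return "0.00" if s == "-0.00" else s


def scene_to_svg(scene: Scene) -> str:
    """Serialize a scene to SVG 1.1 text with byte-deterministic output."""
    c = scene.canvas
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{c.width_px}" height="{c.height_px}" '
        f'viewBox="0 0 {c.width_px} {c.height_px}">\n',
        f'<rect x="0" y="0" width="{c.width_px}" height="{c.height_px}" fill="#ffffff"/>\n',
    ]
    for g in scene.glyphs:
        if g.kind in ("ruler", "tick", "segment"):
            (x1, y1), (x2, y2) = g.points
            stroke = resolve_color(g.stroke or "#000000")
            opacity = (
                f' stroke-opacity="{_fmt(g.opacity)}"' if g.opacity != 1.0 else ""
            )
            parts.append(
                f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
                f'stroke="{stroke}" stroke-width="{"2" if g.kind == "segment" else "1"}"'
                f"{opacity}/>\n"
            )
        elif g.kind in ("ribbon", "box", "arrow", "bar"):
            pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in g.points)
            fill = resolve_color(g.fill or "#000000")
            opacity = f' fill-opacity="{_fmt(g.opacity)}"' if g.opacity != 1.0 else ""
            parts.append(f'<polygon points="{pts}" fill="{fill}"{opacity}/>\n')
        elif g.kind in ("tick_label", "text"):
            (x, y) = g.points[0]
            anchor = "middle" if g.kind == "tick_label" else "start"
            fill = resolve_color(g.fill or "#000000")
            parts.append(
                f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-family="sans-serif" '
                f'font-size="{c.font_size}" text-anchor="{anchor}" '
                f'fill="{fill}">{_escape(g.text or "")}</text>\n'
            )
        else:  # pragma: no cover
            raise ConfigError(f"unknown glyph kind {g.kind!r}")
    parts.append("</svg>\n")
    return "".join(parts)


def _escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def export_svg(scene: Scene, path: str | Path) -> Path:
    """Write the scene as SVG; identical scenes give identical bytes."""
    path = Path(path)
    path.write_bytes(scene_to_svg(scene).encode("utf-8"))
    return path


def export_png(scene: Scene, path: str | Path, dpi: int = 96) -> Path:
    """Rasterize the scene to PNG at ``dpi`` (96 dpi = 1 px per canvas unit)."""
    c = scene.canvas
    scale = dpi / 96.0
    size = (max(1, round(c.width_px * scale)), max(1, round(c.height_px * scale)))
    img = Image.new("RGB", size, (255, 255, 255))
    draw = ImageDraw.Draw(img, "RGBA")

    def pt(p: tuple[float, float]) -> tuple[float, float]:
        return (p[0] * scale, p[1] * scale)

    for g in scene.glyphs:
        if g.kind in ("ruler", "tick", "segment"):
            rgb = to_rgb(g.stroke or "#000000")
            draw.line(
                [pt(g.points[0]), pt(g.points[1])],
                fill=(*rgb, round(255 * g.opacity)),
                width=max(1, round(scale * (2 if g.kind == "segment" else 1))),
            )
        elif g.kind in ("ribbon", "box", "arrow", "bar"):
            rgb = to_rgb(g.fill or "#000000")
            draw.polygon([pt(p) for p in g.points], fill=(*rgb, round(255 * g.opacity)))
        elif g.kind in ("tick_label", "text"):
            rgb = to_rgb(g.fill or "#000000")
            x, y = pt(g.points[0])
            draw.text((x, y - 8 * scale), g.text or "", fill=(*rgb, 255))
    path = Path(path)
    img.save(path, format="PNG")
    return path
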