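"""Browser state, headless: pair selection, viewports, filters, track state.

The viewing model mirrors an interactive dual-genome browser.  A *pair* of
sequences is selected; each panel has a *viewport* (a 1-based inclusive
window on its sequence) that zoom/pan/reset manipulate; numeric *filters*
restrict which conserved regions are drawn; *track state* controls order,
visibility and style of annotation tracks per panel.

Filter semantics: every record carries the implicit attribute ``length``
(the larger of its two side lengths, so the filter is orientation-symmetric)
plus the file's declared attributes.  A record passes when min <= value <= max
for ALL active filters (inclusive bounds, conjunction).

A record is *visible* when it overlaps EITHER panel's viewport, so ribbons
that leave the window on one side — rearrangements spanning the window edge —
remain drawn.

The whole state serializes to a plain-text ``key=value`` config so that any
figure is reproducible from a single file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import ConfigError
from .formats import Dataset, Interval, SyntenyRecord

BLOCKS = "blocks"
LINES = "lines"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# State types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Viewport:
    """The displayed window [start, end] (1-based, inclusive) of one sequence."""

    seq: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ConfigError(
                f"invalid viewport [{self.start}, {self.end}] on {self.seq!r}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FilterSpec:
    """An inclusive numeric range filter on one record attribute."""

    attribute: str
    min: float = -math.inf
    max: float = math.inf

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ConfigError(
                f"filter {self.attribute}: min {self.min} > max {self.max}"
            )


@dataclass
class TrackState:
    """Per-panel track order and visibility, plus track-level style overrides.

    ``order_a``/``order_b`` list every known track for the panel exactly once;
    tracks in the ``hidden_*`` sets occupy no lane.  ``style_override`` maps a
    track name to (shape or None, color or None); either component overrides
    the per-feature styling on both panels.
    """

    order_a: list[str] = field(default_factory=list)
    order_b: list[str] = field(default_factory=list)
    hidden_a: set[str] = field(default_factory=set)
    hidden_b: set[str] = field(default_factory=set)
    style_override: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    def visible_order(self, panel: str) -> list[str]:
        order = self.order_a if panel == "A" else self.order_b
        hidden = self.hidden_a if panel == "A" else self.hidden_b
        return [t for t in order if t not in hidden]


@dataclass
class ViewState:
    """Complete display state for one figure."""

    pair: tuple[str, str]
    viewport_a: Viewport
    viewport_b: Viewport
    filters: list[FilterSpec] = field(default_factory=list)
    tracks: TrackState = field(default_factory=TrackState)
    display_mode: str = BLOCKS
    color_scheme: str = "categorical"

    def __post_init__(self) -> None:
        if self.display_mode not in (BLOCKS, LINES):
            raise ConfigError(f"display_mode must be 'blocks' or 'lines', got {self.display_mode!r}")
        if self.viewport_a.seq != self.pair[0] or self.viewport_b.seq != self.pair[1]:
            raise ConfigError("viewports must reference the selected pair in order")
        if self.color_scheme != "categorical" and not self.color_scheme.startswith("attribute:"):
            raise ConfigError(
                f"color_scheme must be 'categorical' or 'attribute:<name>', got {self.color_scheme!r}"
            )


# ---------------------------------------------------------------------------
# Pair selection
# ---------------------------------------------------------------------------

def list_pairs(dataset: Dataset) -> list[tuple[str, str]]:
    """Unique unordered sequence pairs, keyed by first-seen orientation.

    A later row naming (B, A) after (A, B) was seen still maps to the (A, B)
    pair; panel assignment follows the first-seen orientation.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    for rec in dataset.records:
        key = frozenset((rec.seq_a, rec.seq_b))
        if key not in seen:
            seen.add(key)
            pairs.append((rec.seq_a, rec.seq_b))
    return pairs


def record_sides(
    rec: SyntenyRecord, pair: tuple[str, str]
) -> tuple[Interval, Interval] | None:
    """The record's intervals on (pair[0], pair[1]), or None if off-pair."""
    if (rec.seq_a, rec.seq_b) == pair:
        return rec.interval_a, rec.interval_b
    if (rec.seq_b, rec.seq_a) == pair:
        return rec.interval_b, rec.interval_a
    return None


def records_for_pair(dataset: Dataset, pair: tuple[str, str]) -> list[SyntenyRecord]:
    return [r for r in dataset.records if record_sides(r, pair) is not None]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def record_attribute(rec: SyntenyRecord, name: str) -> float:
    """Value of a named attribute; ``length`` is implicit (max of both sides)."""
    if name == "length":
        return float(max(rec.interval_a.length, rec.interval_b.length))
    try:
        return float(rec.attributes[name])
    except KeyError:
        available = ["length", *rec.attributes.keys()]
        raise ConfigError(
            f"unknown attribute {name!r}; available: {', '.join(available)}"
        ) from None


def apply_filters(
    records: Sequence[SyntenyRecord], filters: Iterable[FilterSpec]
) -> list[SyntenyRecord]:
    """Records passing every filter (inclusive bounds), in stable order."""
    filters = list(filters)
    return [
        rec
        for rec in records
        if all(f.min <= record_attribute(rec, f.attribute) <= f.max for f in filters)
    ]


# ---------------------------------------------------------------------------
# Viewport algebra
# ---------------------------------------------------------------------------

def zoom(viewport: Viewport, factor: float, length: int, center: float | None = None) -> Viewport:
    """Scale the viewport span by 1/factor about a center position.

    factor > 1 zooms in, factor < 1 zooms out.  The new span is
    round(span / factor), at least 1 bp and at most the sequence length;
    the window is then clamped to [1, length].
    """
    if factor <= 0:
        raise ConfigError(f"zoom factor must be > 0, got {factor}")
    span = viewport.span
    new_span = max(1, _round_half_away(span / factor))
    new_span = min(new_span, length)
    c = center if center is not None else (viewport.start + viewport.end) / 2
    start = _round_half_away(c - new_span / 2)
    end = start + new_span - 1
    if start < 1:
        start, end = 1, new_span
    elif end > length:
        start, end = length - new_span + 1, length
    return Viewport(viewport.seq, start, end)


def pan(viewport: Viewport, fraction: float, length: int) -> Viewport:
    """Shift the viewport by round(fraction x span) bp, clamped to the sequence."""
    span = viewport.span
    shift = _round_half_away(fraction * span)
    start = viewport.start + shift
    end = viewport.end + shift
    if start < 1:
        start, end = 1, span
    elif end > length:
        start, end = length - span + 1, length
    return Viewport(viewport.seq, start, end)


def full_viewport(dataset: Dataset, seq: str) -> Viewport:
    return Viewport(seq, 1, dataset.sequences[seq].length)


def reset_view(state: ViewState, dataset: Dataset) -> ViewState:
    """Both viewports back to the entire sequences; everything else kept."""
    return replace(
        state,
        viewport_a=full_viewport(dataset, state.pair[0]),
        viewport_b=full_viewport(dataset, state.pair[1]),
    )


def initial_state(dataset: Dataset, pair: tuple[str, str] | None = None) -> ViewState:
    """Default view: first pair, full viewports, no filters, tracks in
    first-appearance order, blocks mode."""
    pairs = list_pairs(dataset)
    if not pairs:
        raise ConfigError("dataset has no synteny records, nothing to view")
    if pair is None:
        pair = pairs[0]
    else:
        match = next((p for p in pairs if frozenset(p) == frozenset(pair)), None)
        if match is None:
            raise ConfigError(
                f"pair {pair[0]},{pair[1]} not in dataset; available: "
                + "; ".join(f"{a},{b}" for a, b in pairs)
            )
        pair = match
    tracks = TrackState(
        order_a=_track_order(dataset, pair[0]),
        order_b=_track_order(dataset, pair[1]),
    )
    return ViewState(
        pair=pair,
        viewport_a=full_viewport(dataset, pair[0]),
        viewport_b=full_viewport(dataset, pair[1]),
        tracks=tracks,
    )


def _track_order(dataset: Dataset, seq: str) -> list[str]:
    order: list[str] = []
    for feat in dataset.features:
        if feat.seq == seq and feat.track not in order:
            order.append(feat.track)
    return order


# ---------------------------------------------------------------------------
# Visibility
# ---------------------------------------------------------------------------

def visible_records(dataset: Dataset, state: ViewState) -> list[SyntenyRecord]:
    """Filtered records of the selected pair overlapping either viewport.

    Intervals are not clipped here; clipping is a rendering concern.
    """
    kept = apply_filters(records_for_pair(dataset, state.pair), state.filters)
    out: list[SyntenyRecord] = []
    for rec in kept:
        iv_a, iv_b = record_sides(rec, state.pair)  # type: ignore[misc]
        if iv_a.overlaps(state.viewport_a.start, state.viewport_a.end) or iv_b.overlaps(
            state.viewport_b.start, state.viewport_b.end
        ):
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Plain-text config (key=value) serialization
# ---------------------------------------------------------------------------

def parse_region(text: str) -> Viewport:
    """Parse ``SEQ:START-END`` (1-based inclusive) into a Viewport."""
    seq, sep, span = text.rpartition(":")
    if not sep or "-" not in span:
        raise ConfigError(f"region must look like SEQ:START-END, got {text!r}")
    start_s, _, end_s = span.partition("-")
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ConfigError(f"non-integer region bounds in {text!r}") from None
    return Viewport(seq, start, end)


def format_region(vp: Viewport) -> str:
    return f"{vp.seq}:{vp.start}-{vp.end}"


def parse_filter(text: str) -> FilterSpec:
    """Parse ``attr:min=X`` / ``attr:max=Y`` / ``attr:min=X,max=Y``."""
    attr, sep, bounds = text.partition(":")
    if not sep or not attr:
        raise ConfigError(f"filter must look like attr:min=X,max=Y, got {text!r}")
    lo, hi = -math.inf, math.inf
    for part in bounds.split(","):
        key, eq, value_s = part.partition("=")
        if not eq or key not in ("min", "max"):
            raise ConfigError(f"bad filter bound {part!r} in {text!r}")
        try:
            value = float(value_s)
        except ValueError:
            raise ConfigError(f"non-numeric filter bound {value_s!r} in {text!r}") from None
        if key == "min":
            lo = value
        else:
            hi = value
    return FilterSpec(attr, lo, hi)


def format_filter(f: FilterSpec) -> str:
    parts = []
    if f.min != -math.inf:
        parts.append(f"min={f.min!r}")
    if f.max != math.inf:
        parts.append(f"max={f.max!r}")
    return f"{f.attribute}:{','.join(parts)}"


def parse_style(text: str) -> tuple[str, str | None, str | None]:
    """Parse ``track:shape=arrow,color=blue`` (either component optional)."""
    track, sep, rest = text.partition(":")
    if not sep or not track:
        raise ConfigError(f"style must look like track:shape=S,color=C, got {text!r}")
    shape: str | None = None
    color: str | None = None
    for part in rest.split(","):
        key, eq, value = part.partition("=")
        if not eq or key not in ("shape", "color") or not value:
            raise ConfigError(f"bad style component {part!r} in {text!r}")
        if key == "shape":
            shape = value
        else:
            color = value
    return track, shape, color


def state_to_config(state: ViewState) -> str:
    """Serialize a ViewState to the plain-text key=value config format."""
    lines = [
        f"pair={state.pair[0]},{state.pair[1]}",
        f"region_a={format_region(state.viewport_a)}",
        f"region_b={format_region(state.viewport_b)}",
        f"mode={state.display_mode}",
        f"color={state.color_scheme}",
    ]
    lines += [f"filter={format_filter(f)}" for f in state.filters]
    t = state.tracks
    if t.order_a:
        lines.append("track_order_a=" + ",".join(t.order_a))
    if t.order_b:
        lines.append("track_order_b=" + ",".join(t.order_b))
    if t.hidden_a:
        lines.append("hide_a=" + ",".join(sorted(t.hidden_a)))
    if t.hidden_b:
        lines.append("hide_b=" + ",".join(sorted(t.hidden_b)))
    for track in sorted(t.style_override):
        shape, color = t.style_override[track]
        parts = []
        if shape:
            parts.append(f"shape={shape}")
        if color:
            parts.append(f"color={color}")
        lines.append(f"style={track}:{','.join(parts)}")
    return "\n".join(lines) + "\n"


def parse_config(text: str) -> dict[str, list[str]]:
    """Parse key=value config text; repeated keys accumulate in order."""
    out: dict[str, list[str]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, eq, value = line.partition("=")
        if not eq:
            raise ConfigError(f"config line {lineno}: expected key=value, got {line!r}")
        out.setdefault(key.strip(), []).append(value.strip())
    return out


def state_from_config(text: str, dataset: Dataset) -> ViewState:
    """Rebuild a ViewState from config text against a loaded dataset."""
    cfg = parse_config(text)

    def single(key: str) -> str | None:
        values = cfg.get(key)
        if values is None:
            return None
        if len(values) > 1:
            raise ConfigError(f"config key {key!r} given {len(values)} times")
        return values[0]

    pair_s = single("pair")
    pair = tuple(p.strip() for p in pair_s.split(",")) if pair_s else None
    if pair is not None and len(pair) != 2:
        raise ConfigError(f"pair must name two sequences, got {pair_s!r}")
    state = initial_state(dataset, pair)  # type: ignore[arg-type]

    region_a = single("region_a")
    region_b = single("region_b")
    if region_a:
        vp = parse_region(region_a)
        if vp.seq != state.pair[0]:
            raise ConfigError(f"region_a sequence {vp.seq!r} is not panel A ({state.pair[0]!r})")
        state.viewport_a = vp
    if region_b:
        vp = parse_region(region_b)
        if vp.seq != state.pair[1]:
            raise ConfigError(f"region_b sequence {vp.seq!r} is not panel B ({state.pair[1]!r})")
        state.viewport_b = vp

    mode = single("mode")
    if mode:
        if mode not in (BLOCKS, LINES):
            raise ConfigError(f"mode must be blocks or lines, got {mode!r}")
        state.display_mode = mode
    color = single("color")
    if color:
        state.color_scheme = color

    state.filters = [parse_filter(v) for v in cfg.get("filter", [])]

    for key, attr in (("track_order_a", "order_a"), ("track_order_b", "order_b")):
        value = single(key)
        if value is not None:
            wanted = [t.strip() for t in value.split(",") if t.strip()]
            current = getattr(state.tracks, attr)
            unknown = [t for t in wanted if t not in current]
            if unknown:
                raise ConfigError(f"{key}: unknown tracks {', '.join(unknown)}")
            rest = [t for t in current if t not in wanted]
            setattr(state.tracks, attr, wanted + rest)
    for key, attr in (("hide_a", "hidden_a"), ("hide_b", "hidden_b")):
        value = single(key)
        if value is not None:
            setattr(state.tracks, attr, {t.strip() for t in value.split(",") if t.strip()})
    for style_s in cfg.get("style", []):
        track, shape, color_v = parse_style(style_s)
        state.tracks.style_override[track] = (shape, color_v)

    # re-run the dataclass invariants after mutation
    state.__post_init__()
    return state
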