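"""Color resolution, the categorical palette, and the sequential colormap.

Every color that enters the system (annotation files, track style overrides,
converter style maps) is resolved here to a lowercase ``#rrggbb`` hex string.
Accepted inputs are hex colors (``#RGB`` or ``#RRGGBB``) and CSS named colors.
"""

from __future__ import annotations

from PIL import ImageColor

from .errors import FormatError

#: Categorical palette for synteny ribbons: 12 colorblind-safe hues
#: (Paul Tol's qualitative sets, merged "muted"/"light" selection).
PALETTE: tuple[str, ...] = (
    "#4477aa",
    "#ee6677",
    "#228833",
    "#ccbb44",
    "#66ccee",
    "#aa3377",
    "#bbbbbb",
    "#332288",
    "#ddcc77",
    "#999933",
    "#cc6677",
    "#882255",
)

#: Stops of the sequential colormap used for attribute-driven ribbon coloring
#: (light yellow -> deep blue, linearly interpolated in RGB).
SEQUENTIAL_STOPS: tuple[str, ...] = (
    "#ffffcc",
    "#a1dab4",
    "#41b6c4",
    "#2c7fb8",
    "#253494",
)


def resolve_color(color: str) -> str:
    """Resolve a hex or CSS named color to canonical ``#rrggbb`` form.

    Raises :class:`FormatError` if the color is not recognized.
    """
    if not isinstance(color, str) or not color.strip():
        raise FormatError(f"unresolvable color: {color!r}")
    try:
        r, g, b = ImageColor.getrgb(color.strip())[:3]
    except ValueError as exc:
        raise FormatError(f"unresolvable color: {color!r}") from exc
    return f"#{r:02x}{g:02x}{b:02x}"


def to_rgb(color: str) -> tuple[int, int, int]:
    """Return the (r, g, b) byte triple of a resolvable color."""
    hexcolor = resolve_color(color)
    return int(hexcolor[1:3], 16), int(hexcolor[3:5], 16), int(hexcolor[5:7], 16)


def sequential(t: float) -> str:
    """Map ``t`` in [0, 1] through the sequential colormap (clamped)."""
    t = min(1.0, max(0.0, float(t)))
    stops = [to_rgb(c) for c in SEQUENTIAL_STOPS]
    if t >= 1.0:
        r, g, b = stops[-1]
        return f"#{r:02x}{g:02x}{b:02x}"
    scaled = t * (len(stops) - 1)
    i = int(scaled)
    frac = scaled - i
    lo, hi = stops[i], stops[i + 1]
    r, g, b = (round(a + (b_ - a) * frac) for a, b_ in zip(lo, hi))
    return f"#{r:02x}{g:02x}{b:02x}"
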