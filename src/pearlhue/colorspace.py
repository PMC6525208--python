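"""Exact conversions between 8-bit RGB, hex triplet codes, and HSV.

Hue is expressed as a fraction of the colour wheel in [0, 1) (0 = red,
1/3 = green, 2/3 = blue), matching the convention in which reference
phenotype hue ranges are published (e.g. a red range upper bound of
0.1625770).  Saturation and value follow the hexcone definitions
s = (max - min) / max and v = max / 255.

Achromatic colours (r = g = b) have no defined hue; they are given h = 0
together with an explicit ``achromatic`` flag so that downstream
classification never silently treats a grey as red.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "RGBTriple",
    "HSVTriple",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "rgb_to_hex",
    "hex_to_rgb",
]

_HEX_RE = re.compile(r"\A#[0-9A-F]{6}\Z")


@dataclass(frozen=True)
class RGBTriple:
    """An 8-bit RGB colour; each channel is an integer in [0, 255]."""

    r: int
    g: int
    b: int

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            val = getattr(self, name)
            if not isinstance(val, (int,)) or isinstance(val, bool):
                raise TypeError(f"channel {name} must be an int, got {val!r}")
            if not 0 <= val <= 255:
                raise ValueError(f"channel {name}={val} outside [0, 255]")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.r, self.g, self.b)


@dataclass(frozen=True)
class HSVTriple:
    """A hexcone HSV colour with all components in [0, 1].

    ``achromatic`` is set when saturation is zero; by convention the hue
    of an achromatic colour is stored as 0 and must not be interpreted.
    """

    h: float
    s: float
    v: float
    achromatic: bool = False

    def __post_init__(self) -> None:
        for name in ("h", "s", "v"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"component {name}={val} outside [0, 1]")
        if self.achromatic and self.h != 0.0:
            raise ValueError("achromatic colours must carry h = 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.h, self.s, self.v)


def _coerce_rgb(c) -> tuple[float, float, float]:
    if isinstance(c, RGBTriple):
        return (float(c.r), float(c.g), float(c.b))
    r, g, b = c
    for v in (r, g, b):
        if not 0 <= v <= 255:
            raise ValueError(f"channel value {v} outside [0, 255]")
    return (float(r), float(g), float(b))


def rgb_to_hsv(c) -> HSVTriple:
    """Convert an RGB colour to hexcone HSV.

    Accepts an :class:`RGBTriple` or any ``(r, g, b)`` triple with real
    values in [0, 255] — the pipeline feeds unquantised channel means
    through here so the summary HSV carries no second 8-bit rounding.
    """
    r, g, b = _coerce_rgb(c)
    cmax = max(r, g, b)
    cmin = min(r, g, b)
    delta = cmax - cmin

    v = cmax / 255.0
    if cmax == 0.0 or delta == 0.0:
        s = 0.0 if cmax == 0.0 else delta / cmax
        return HSVTriple(h=0.0, s=s, v=v, achromatic=True)

    s = delta / cmax
    if cmax == r:
        h6 = ((g - b) / delta) % 6.0
    elif cmax == g:
        h6 = (b - r) / delta + 2.0
    else:
        h6 = (r - g) / delta + 4.0
    h = h6 / 6.0
    if h >= 1.0:  # guard the wrap, e.g. tiny negative (g-b)/delta
        h -= 1.0
    return HSVTriple(h=h, s=s, v=v, achromatic=False)


def _quantise(x: float) -> int:
    """Round half away from zero to the nearest 8-bit level."""
    import math

    return min(255, max(0, int(math.floor(x + 0.5))))


def hsv_to_rgb(c: HSVTriple | tuple[float, float, float]) -> RGBTriple:
    """Inverse hexcone transform, quantised round-half-up to 8 bits."""
    if isinstance(c, HSVTriple):
        h, s, v = c.h, c.s, c.v
    else:
        h, s, v = c
        for name, val in zip("hsv", (h, s, v)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"component {name}={val} outside [0, 1]")
    if s == 0.0:
        q = _quantise(255.0 * v)
        return RGBTriple(q, q, q)

    h6 = (h % 1.0) * 6.0
    i = int(h6) % 6
    f = h6 - int(h6)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r, g, b = (
        (v, t, p), (q, v, p), (p, v, t),
        (p, q, v), (t, p, v), (v, p, q),
    )[i]
    return RGBTriple(_quantise(255.0 * r), _quantise(255.0 * g), _quantise(255.0 * b))


def rgb_to_hex(c) -> str:
    """Encode a colour as an uppercase ``#RRGGBB`` hex triplet.

    Real-valued channels (e.g. foreground means) are quantised
    round-half-up first; the hex code is always an 8-bit summary.
    """
    r, g, b = _coerce_rgb(c)
    return "#{:02X}{:02X}{:02X}".format(_quantise(r), _quantise(g), _quantise(b))


def hex_to_rgb(code: str) -> RGBTriple:
    """Parse a ``#RRGGBB`` hex triplet (uppercase) into an RGBTriple."""
    if not isinstance(code, str) or not _HEX_RE.match(code):
        raise ValueError(f"malformed hex triplet: {code!r} (expected '#RRGGBB', uppercase)")
    return RGBTriple(int(code[1:3], 16), int(code[3:5], 16), int(code[5:7], 16))
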