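"""White-background removal.

Sample photographs have their coloured region (pearl sphere or clipped
inner-shell margin) pasted onto a white background.  Before any colour
averaging, background pixels must be identified and discarded.  Pure
white survives lossless encodings exactly, but JPEG compression leaves
near-white halos around region edges, so whiteness is defined by a
threshold: a pixel is background when its *minimum* channel is at least
``tau`` (default 240), or when its hex code is explicitly whitelisted.
Setting ``tau = 255`` restricts background to pure white, which is the
right policy for lossless fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorspace import RGBTriple, hex_to_rgb, rgb_to_hex

__all__ = [
    "BackgroundPolicy",
    "ForegroundMask",
    "EmptyForegroundError",
    "is_background",
    "mask_foreground",
    "whiten_background",
]

DEFAULT_WHITE_THRESHOLD = 240


class EmptyForegroundError(ValueError):
    """Raised when every pixel of an image is classified as background."""


@dataclass(frozen=True)
class BackgroundPolicy:
    """Rule deciding which pixels count as white background.

    Parameters
    ----------
    tau : int
        Whiteness threshold in [0, 255]: a pixel is background when
        ``min(r, g, b) >= tau``.  ``#FFFFFF`` is background under every
        admissible tau.
    explicit_whites : frozenset of str
        Hex triplets always treated as background regardless of tau.
    """

    tau: int = DEFAULT_WHITE_THRESHOLD
    explicit_whites: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0 <= self.tau <= 255:
            raise ValueError(f"tau={self.tau} outside [0, 255]")
        object.__setattr__(self, "explicit_whites", frozenset(self.explicit_whites))
        for code in self.explicit_whites:
            hex_to_rgb(code)  # validates the format


@dataclass(frozen=True)
class ForegroundMask:
    """Boolean pixel grid, True on foreground, plus the foreground count."""

    mask: np.ndarray
    n_foreground: int

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            raise TypeError("mask must be boolean")
        if int(self.mask.sum()) != self.n_foreground:
            raise ValueError("n_foreground inconsistent with mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape


def is_background(c, policy: BackgroundPolicy = BackgroundPolicy()) -> bool:
    """True iff the pixel is white background under the policy."""
    if isinstance(c, RGBTriple):
        r, g, b = c.as_tuple()
    else:
        r, g, b = c
    if min(r, g, b) >= policy.tau:
        return True
    return bool(policy.explicit_whites) and rgb_to_hex((r, g, b)) in policy.explicit_whites


def _background_grid(pixels: np.ndarray, policy: BackgroundPolicy) -> np.ndarray:
    bg = pixels.min(axis=-1) >= policy.tau
    if policy.explicit_whites:
        whites = np.array(
            [hex_to_rgb(c).as_tuple() for c in sorted(policy.explicit_whites)],
            dtype=pixels.dtype,
        )
        for w in whites:
            bg |= (pixels == w).all(axis=-1)
    return bg


def mask_foreground(image: np.ndarray, policy: BackgroundPolicy = BackgroundPolicy()) -> ForegroundMask:
    """Classify every pixel of an (H, W, 3) uint8 array; return the foreground mask.

    Raises
    ------
    EmptyForegroundError
        If no pixel survives — the sample must be reported as
        unprocessable rather than averaged over nothing.
    """
    pixels = np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[-1] != 3 or pixels.size == 0:
        raise ValueError(f"expected a non-empty (H, W, 3) image, got shape {pixels.shape}")
    fg = ~_background_grid(pixels, policy)
    n = int(fg.sum())
    if n == 0:
        raise EmptyForegroundError("every pixel is background; nothing to average")
    return ForegroundMask(mask=fg, n_foreground=n)


def whiten_background(image: np.ndarray, policy: BackgroundPolicy = BackgroundPolicy()) -> np.ndarray:
    """Return a copy with background pixels replaced by pure white.

    Masking the result again yields the identical foreground mask, which
    makes background deletion idempotent.
    """
    pixels = np.asarray(image).copy()
    bg = _background_grid(pixels, policy)
    pixels[bg] = 255
    return pixels
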