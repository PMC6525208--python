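"""Seeded generator of pre-clipped sample images and cohort truth tables.

Real inputs to this tool are photographs whose coloured region (a pearl
sphere, or a clipped inner-shell margin) has been pasted onto a white
background.  The generator emulates exactly that: a near-uniform
coloured region of known (H, S, V) — a raster disc for pearls, an
annulus sector for shell margins — with optional per-pixel Gaussian
channel noise, on a pure-white canvas, written losslessly (PNG) for
exact assertions or as JPEG to exercise the near-white halo problem
that motivates the whiteness threshold.

Cohorts are drawn per group from clipped normal distributions over
hue, saturation and value, with additive depth-effect shifts on
saturation and value; every sample's exact HSV and foreground pixel
count are recorded in a truth table, and everything is deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .colorspace import HSVTriple, hsv_to_rgb

__all__ = [
    "CohortSpec",
    "generate_sample_image",
    "sample_cohort_colours",
    "generate_cohorts",
    "study_cohort_specs",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = ["group", "sample_id", "h", "s", "v", "n_foreground", "seed"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic group (phenotype x depth).

    HSV parameters are colour-wheel fractions / unit-interval values;
    draws are clipped back into [0, 1].  ``sat_shift`` and ``val_shift``
    are the imposed depth effects added to the saturation and value
    means.  ``shape`` is "disc" (pearl) or "annulus_sector" (clipped
    shell margin); ``encoding`` is "png" (lossless) or "jpeg".
    """

    label: str
    n_samples: int
    hue_mean: float
    hue_sd: float = 0.02
    sat_mean: float = 0.55
    sat_sd: float = 0.08
    val_mean: float = 0.65
    val_sd: float = 0.08
    sat_shift: float = 0.0
    val_shift: float = 0.0
    noise_sd: float = 0.0
    canvas: tuple[int, int] = (48, 48)
    shape: str = "disc"
    radius: int = 16
    encoding: str = "png"
    jpeg_quality: int = 95

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.shape not in ("disc", "annulus_sector"):
            raise ValueError(f"unknown region shape {self.shape!r}")
        if self.encoding not in ("png", "jpeg"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        for name in ("hue_mean", "sat_mean", "val_mean"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")


def _region_mask(shape: str, radius: int, canvas: tuple[int, int]) -> np.ndarray:
    w, h = canvas
    if radius < 1:
        raise ValueError("region radius must be >= 1")
    if 2 * radius > min(w, h):
        raise ValueError(f"region of radius {radius} does not fit a {w}x{h} canvas")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
    if shape == "disc":
        return dist2 <= radius**2
    # annulus sector: outer radius r, inner radius r/2, upper half plane —
    # a crescent standing in for a clipped peripheral shell margin
    inner = radius / 2.0
    angle_ok = yy <= cy
    return (dist2 <= radius**2) & (dist2 >= inner**2) & angle_ok


def generate_sample_image(
    hsv: HSVTriple | tuple[float, float, float],
    path,
    shape: str = "disc",
    radius: int = 16,
    noise_sd: float = 0.0,
    canvas: tuple[int, int] = (48, 48),
    encoding: str = "png",
    jpeg_quality: int = 95,
    seed: int = 0,
) -> dict:
    """Write one synthetic sample image; return its ground-truth record.

    The region is filled with ``hsv_to_rgb(hsv)`` plus i.i.d. Gaussian
    channel noise (sd ``noise_sd``, clipped to [0, 255]); everything
    else is pure white.  The truth record stores the exact generating
    HSV, the rasterised foreground pixel count, and the seed.
    """
    if not isinstance(hsv, HSVTriple):
        hsv = HSVTriple(*hsv)
    region = _region_mask(shape, radius, canvas)
    rgb = hsv_to_rgb(hsv).as_tuple()

    w, h = canvas
    pixels = np.full((h, w, 3), 255.0)
    pixels[region] = rgb
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=(int(region.sum()), 3))
        pixels[region] = np.clip(pixels[region] + noise, 0, 255)
    img = Image.fromarray(np.floor(pixels + 0.5).astype(np.uint8), mode="RGB")
    path = Path(path)
    if encoding == "jpeg":
        img.save(path, format="JPEG", quality=jpeg_quality)
    else:
        img.save(path, format="PNG")
    return {
        "sample_id": path.stem,
        "h": hsv.h,
        "s": hsv.s,
        "v": hsv.v,
        "n_foreground": int(region.sum()),
        "seed": seed,
    }


def sample_cohort_colours(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-sample true HSV colours of one cohort (no rendering).

    Hue, saturation and value are independent normals around the spec
    means (depth shifts applied to saturation/value), clipped to [0, 1].
    """
    def draw(mean: float, sd: float) -> np.ndarray:
        return np.clip(rng.normal(mean, sd, size=spec.n_samples), 0.0, 1.0)

    return pd.DataFrame(
        {
            "group": spec.label,
            "sample_id": [f"{spec.label}_{i:04d}" for i in range(spec.n_samples)],
            "h": draw(spec.hue_mean, spec.hue_sd),
            "s": draw(spec.sat_mean + spec.sat_shift, spec.sat_sd),
            "v": draw(spec.val_mean + spec.val_shift, spec.val_sd),
        }
    )


def generate_cohorts(
    specs: Sequence[CohortSpec],
    out_dir,
    seed: int = 0,
    render: bool = True,
) -> pd.DataFrame:
    """Generate a folder tree of sample images plus one truth CSV.

    One subfolder per group label; identical specs + seed reproduce a
    byte-identical truth CSV (and, for lossless encoding, identical
    image bytes).  With ``render=False`` only the truth table is
    produced — enough for statistics-level simulations.
    """
    specs = list(specs)
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels: {labels}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    root_ss = np.random.SeedSequence(seed)
    records = []
    for spec, ss in zip(specs, root_ss.spawn(len(specs))):
        rng = np.random.default_rng(ss)
        colours = sample_cohort_colours(spec, rng)
        group_dir = out_dir / spec.label
        if render:
            group_dir.mkdir(exist_ok=True)
        # per-sample noise seeds drawn from the group stream, kept small
        sample_seeds = rng.integers(0, 2**31 - 1, size=spec.n_samples)
        for row, s_seed in zip(colours.itertuples(index=False), sample_seeds):
            record = {
                "group": spec.label,
                "sample_id": row.sample_id,
                "h": row.h,
                "s": row.s,
                "v": row.v,
                "n_foreground": int(_region_mask(spec.shape, spec.radius, spec.canvas).sum()),
                "seed": int(s_seed),
            }
            if render:
                ext = "jpg" if spec.encoding == "jpeg" else "png"
                truth = generate_sample_image(
                    (row.h, row.s, row.v),
                    group_dir / f"{row.sample_id}.{ext}",
                    shape=spec.shape,
                    radius=spec.radius,
                    noise_sd=spec.noise_sd,
                    canvas=spec.canvas,
                    encoding=spec.encoding,
                    jpeg_quality=spec.jpeg_quality,
                    seed=int(s_seed),
                )
                record["n_foreground"] = truth["n_foreground"]
            records.append(record)
    truth_table = pd.DataFrame(records, columns=TRUTH_COLUMNS)
    truth_path = out_dir / "truth.csv"
    truth_table.to_csv(truth_path, index=False, float_format="%.7f")
    return truth_table


def study_cohort_specs(
    encoding: str = "png",
    noise_sd: float = 0.0,
    scale: float = 1.0,
) -> list[CohortSpec]:
    """Cohort specs mirroring the published study layout.

    Donor shells: GS (green, 4 m, n=9), GD (green, 30 m, n=6), RS (red,
    4 m, n=5), RD (red, 30 m, n=7), as annulus sectors.  Matched pearls:
    GPGS (n=132), GPGD (n=66), RPRS (n=84), RPRD (n=118), as discs.
    Green hues centre at 0.45 and red at 0.05, inside the published
    phenotype ranges; deep (30 m) groups carry a -0.10 saturation shift
    and a -0.05 value shift, the imposed depth effect the statistics
    layer is meant to recover.  ``scale`` shrinks every group size
    (minimum 1) for quick simulations.
    """
    def n(k: int) -> int:
        return max(1, round(k * scale))

    common = dict(encoding=encoding, noise_sd=noise_sd)
    deep = dict(sat_shift=-0.10, val_shift=-0.05)
    shell = dict(shape="annulus_sector", **common)
    pearl = dict(shape="disc", **common)
    return [
        CohortSpec("GS", n(9), hue_mean=0.45, **shell),
        CohortSpec("GD", n(6), hue_mean=0.45, **deep, **shell),
        CohortSpec("RS", n(5), hue_mean=0.05, **shell),
        CohortSpec("RD", n(7), hue_mean=0.05, **deep, **shell),
        CohortSpec("GPGS", n(132), hue_mean=0.45, **pearl),
        CohortSpec("GPGD", n(66), hue_mean=0.45, **deep, **pearl),
        CohortSpec("RPRS", n(84), hue_mean=0.05, **pearl),
        CohortSpec("RPRD", n(118), hue_mean=0.05, **deep, **pearl),
    ]
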