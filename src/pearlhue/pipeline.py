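"""Per-sample and per-folder colour quantification.

For each photograph: white background pixels are deleted, the remaining
pixels are averaged per RGB channel, the (unquantised) channel means are
converted to HSV, the hue is classified against the phenotype hue
ranges, and one summary row is emitted per sample.  The order matters:
the mean is taken in RGB and converted once — averaging per-pixel HSV
values would give a different (and wrong, for this tool) answer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from . import colorspace
from .phenotype import (
    OTHER_LABEL,
    PhenotypeHueRange,
    REFERENCE_RANGES,
    classify_phenotype,
    validate_ranges,
)
from .segmentation import BackgroundPolicy, EmptyForegroundError, ForegroundMask, mask_foreground

__all__ = [
    "SampleColorSummary",
    "mean_foreground_rgb",
    "summarize_sample",
    "summarize_image",
    "batch_process",
    "write_report",
    "REPORT_COLUMNS",
]

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".png"}
REPORT_COLUMNS = [
    "sample_id", "hue", "saturation", "value", "hex", "phenotype", "n_foreground", "status",
]
#: report precision: seven decimals, the precision of the published hue ranges
REPORT_DECIMALS = 7

STATUS_OK = "ok"
STATUS_EMPTY = "empty_foreground"
STATUS_UNREADABLE = "unreadable"


@dataclass(frozen=True)
class SampleColorSummary:
    """One output row: the mean colour of one sample image.

    ``status`` is "ok" for a processed sample; failed samples keep their
    row (with NaN colour fields) so a batch never silently drops files.
    """

    sample_id: str
    h: float
    s: float
    v: float
    hex: str
    phenotype: str
    n_foreground: int
    status: str = STATUS_OK

    def __post_init__(self) -> None:
        if self.status == STATUS_OK:
            if not all(0.0 <= x <= 1.0 for x in (self.h, self.s, self.v)):
                raise ValueError("HSV components outside [0, 1]")
            if self.n_foreground < 1:
                raise ValueError("a processed sample needs >= 1 foreground pixel")

    def as_row(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "hue": self.h,
            "saturation": self.s,
            "value": self.v,
            "hex": self.hex,
            "phenotype": self.phenotype,
            "n_foreground": self.n_foreground,
            "status": self.status,
        }


def mean_foreground_rgb(image: np.ndarray, mask: ForegroundMask) -> np.ndarray:
    """Arithmetic per-channel mean over foreground pixels, unquantised.

    Returns a float array ``[r, g, b]`` in [0, 255]; callers quantise
    only for the hex report, never before the HSV conversion.
    """
    pixels = np.asarray(image)
    if pixels.shape[:2] != mask.shape:
        raise ValueError("mask and image dimensions differ")
    if mask.n_foreground < 1:
        raise EmptyForegroundError("cannot average an empty foreground")
    return pixels[mask.mask].reshape(-1, 3).mean(axis=0)


def summarize_image(
    image: np.ndarray,
    sample_id: str,
    policy: BackgroundPolicy = BackgroundPolicy(),
    ranges: Sequence[PhenotypeHueRange] = REFERENCE_RANGES,
) -> SampleColorSummary:
    """Summarise an in-memory (H, W, 3) uint8 image."""
    ranges = validate_ranges(ranges)
    fg = mask_foreground(image, policy)
    mean_rgb = mean_foreground_rgb(image, fg)
    hsv = colorspace.rgb_to_hsv(mean_rgb)
    label = classify_phenotype(hsv.h, hsv.achromatic, ranges)
    return SampleColorSummary(
        sample_id=sample_id,
        h=hsv.h,
        s=hsv.s,
        v=hsv.v,
        hex=colorspace.rgb_to_hex(mean_rgb),
        phenotype=label,
        n_foreground=fg.n_foreground,
    )


def _failed_summary(sample_id: str, status: str) -> SampleColorSummary:
    return SampleColorSummary(
        sample_id=sample_id, h=float("nan"), s=float("nan"), v=float("nan"),
        hex="", phenotype=OTHER_LABEL, n_foreground=0, status=status,
    )


def summarize_sample(
    path,
    policy: BackgroundPolicy = BackgroundPolicy(),
    ranges: Sequence[PhenotypeHueRange] = REFERENCE_RANGES,
) -> SampleColorSummary:
    """Summarise one image file; the file stem is the sample id.

    Unreadable files and all-background images yield a summary row with
    a failure status instead of raising, so batch runs are error-isolated.
    """
    path = Path(path)
    sample_id = path.stem
    try:
        with Image.open(path) as img:
            pixels = np.asarray(img.convert("RGB"))
    except (OSError, UnidentifiedImageError, ValueError) as exc:
        logger.warning("sample %s: unreadable (%s)", sample_id, exc)
        return _failed_summary(sample_id, STATUS_UNREADABLE)
    try:
        return summarize_image(pixels, sample_id, policy, ranges)
    except EmptyForegroundError:
        logger.warning("sample %s: no foreground pixels", sample_id)
        return _failed_summary(sample_id, STATUS_EMPTY)


def discover_images(folder) -> list[Path]:
    """Image files in a folder (jpg/jpeg/png, case-insensitive), sorted by name."""
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"not a directory: {folder}")
    return sorted(
        (p for p in folder.iterdir() if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS),
        key=lambda p: p.name,
    )


def batch_process(
    folder,
    policy: BackgroundPolicy = BackgroundPolicy(),
    ranges: Sequence[PhenotypeHueRange] = REFERENCE_RANGES,
    output_csv=None,
) -> pd.DataFrame:
    """Summarise every image in a folder into one tabular report.

    Rows follow lexicographic file-name order.  If ``output_csv`` is
    given the report is also written to disk.
    """
    ranges = validate_ranges(ranges)
    paths = discover_images(folder)
    if not paths:
        logger.warning("no images found in %s", folder)
    rows = [summarize_sample(p, policy, ranges).as_row() for p in paths]
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if output_csv is not None:
        write_report(report, output_csv)
    return report


def write_report(report: pd.DataFrame, path) -> None:
    """Write the summary table as CSV with 7-decimal colour fields."""
    report.to_csv(path, index=False, float_format=f"%.{REPORT_DECIMALS}f")
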