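"""Learning phenotype hue ranges from labelled training images.

The published workflow selected five particularly colourful individuals
per phenotype and derived one closed hue interval per phenotype from
their photographs.  Here the interval is the min–max envelope of the
per-image mean hues: each training image is summarised exactly as a
sample would be (background deletion, mean RGB, HSV), and the envelope
of those mean hues delimits the phenotype.

The numeric rule itself lives in
:class:`pearlhue.phenotype.HueRangeClassifier`; this module feeds it
from image files and handles the file-level failure modes (achromatic
or unprocessable training images are rejected with a diagnostic, never
silently folded into a range).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .phenotype import (
    HueRangeClassifier,
    PhenotypeHueRange,
    load_ranges,
    save_ranges,
    validate_ranges,
)
from .pipeline import STATUS_OK, summarize_sample
from .segmentation import BackgroundPolicy

__all__ = [
    "TrainingSet",
    "learn_hue_range",
    "learn_ranges",
    "training_set_from_folders",
    "save_ranges",
    "load_ranges",
    "validate_ranges",
]


@dataclass(frozen=True)
class TrainingSet:
    """Labelled training images: a sequence of (image path, phenotype label)."""

    items: tuple

    def __post_init__(self) -> None:
        items = tuple((Path(p), str(label)) for p, label in self.items)
        object.__setattr__(self, "items", items)
        if not items:
            raise ValueError("empty training set")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted({label for _, label in self.items}))

    def paths_for(self, label: str) -> list[Path]:
        return [p for p, lbl in self.items if lbl == label]


def _training_hues(
    ts: TrainingSet, label: str, policy: BackgroundPolicy
) -> np.ndarray:
    paths = ts.paths_for(label)
    if not paths:
        raise ValueError(f"no training images for label {label!r}")
    hues = []
    for path in paths:
        summary = summarize_sample(path, policy=policy)
        if summary.status != STATUS_OK:
            raise ValueError(f"training image {path} unprocessable ({summary.status})")
        if summary.s == 0.0:
            raise ValueError(
                f"training image {path} is achromatic (s = 0); it carries no hue "
                f"and cannot delimit a phenotype"
            )
        hues.append(summary.h)
    return np.asarray(hues)


def learn_hue_range(
    ts: TrainingSet,
    label: str,
    policy: BackgroundPolicy = BackgroundPolicy(),
) -> PhenotypeHueRange:
    """Min–max envelope of the per-image mean hues carrying ``label``.

    A single training image yields a degenerate (zero-width) range.
    """
    hues = _training_hues(ts, label, policy)
    return PhenotypeHueRange(label, float(hues.min()), float(hues.max()))


def learn_ranges(
    ts: TrainingSet,
    policy: BackgroundPolicy = BackgroundPolicy(),
) -> tuple[PhenotypeHueRange, ...]:
    """Fit one hue range per label and validate pairwise disjointness."""
    clf = HueRangeClassifier()
    hues, labels = [], []
    for label in ts.labels:
        for h in _training_hues(ts, label, policy):
            hues.append(h)
            labels.append(label)
    clf.fit(np.asarray(hues), np.asarray(labels))
    return clf.ranges_


def training_set_from_folders(root) -> TrainingSet:
    """Build a TrainingSet from a ``root/<label>/*.{jpg,jpeg,png}`` layout."""
    from .pipeline import discover_images

    root = Path(root)
    items = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        for img in discover_images(sub):
            items.append((img, sub.name))
    return TrainingSet(tuple(items))
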