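"""Hue-range phenotype classification.

A colour phenotype ("green", "red", ...) is delimited by a closed hue
interval on the colour wheel.  Published reference ranges for the
black-lipped pearl oyster are red = [0, 0.1625770] and green =
[0.3215928, 0.5637775]; samples falling in no interval, and achromatic
samples (zero saturation, hence no hue), are labelled "other".

The learning rule used to derive an interval from labelled training
samples is the min–max envelope of their mean hues; it lives in
:class:`HueRangeClassifier`, a scikit-learn estimator so the ranges can
be fitted, inspected, cross-validated and reused like any classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PhenotypeHueRange",
    "HueRangeClassifier",
    "OTHER_LABEL",
    "REFERENCE_RANGES",
    "classify_phenotype",
    "validate_ranges",
    "save_ranges",
    "load_ranges",
]

OTHER_LABEL = "other"


@dataclass(frozen=True)
class PhenotypeHueRange:
    """A labelled closed hue interval in [0, 1].

    ``wrap=True`` marks an interval that crosses the 1.0 -> 0.0 seam of
    the colour wheel (membership is then h >= lo or h <= hi).  The
    published ranges never need it, but reds near hue 0.99 exist.
    """

    label: str
    lo: float
    hi: float
    wrap: bool = False

    def __post_init__(self) -> None:
        if not self.label or self.label == OTHER_LABEL:
            raise ValueError(f"invalid range label {self.label!r}")
        if not (0.0 <= self.lo <= 1.0 and 0.0 <= self.hi <= 1.0):
            raise ValueError(f"hue bounds ({self.lo}, {self.hi}) outside [0, 1]")
        if not self.wrap and self.lo > self.hi:
            raise ValueError(f"lo={self.lo} > hi={self.hi} without wrap flag")

    def contains(self, h: float) -> bool:
        if self.wrap:
            return h >= self.lo or h <= self.hi
        return self.lo <= h <= self.hi

    def arcs(self) -> list[tuple[float, float]]:
        """The interval as closed arcs on the linear [0, 1] hue axis."""
        if self.wrap:
            return [(self.lo, 1.0), (0.0, self.hi)]
        return [(self.lo, self.hi)]


#: Published reference intervals for the two pearl-oyster phenotypes.
REFERENCE_RANGES: tuple[PhenotypeHueRange, ...] = (
    PhenotypeHueRange("red", 0.0, 0.1625770),
    PhenotypeHueRange("green", 0.3215928, 0.5637775),
)


def validate_ranges(ranges: Iterable[PhenotypeHueRange]) -> tuple[PhenotypeHueRange, ...]:
    """Check pairwise disjointness (wrap-aware); return the ranges or raise."""
    ranges = tuple(ranges)
    if not ranges:
        raise ValueError("at least one phenotype hue range is required")
    labels = [r.label for r in ranges]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate range labels: {labels}")
    for i, a in enumerate(ranges):
        for b in ranges[i + 1:]:
            for lo1, hi1 in a.arcs():
                for lo2, hi2 in b.arcs():
                    if max(lo1, lo2) <= min(hi1, hi2):
                        raise ValueError(
                            f"hue ranges overlap: {a.label!r} and {b.label!r}"
                        )
    return ranges


def classify_phenotype(
    h: float,
    achromatic: bool = False,
    ranges: Iterable[PhenotypeHueRange] = REFERENCE_RANGES,
) -> str:
    """Label of the unique closed interval containing ``h``; "other" otherwise.

    Achromatic samples carry no hue and are always "other".
    """
    if achromatic:
        return OTHER_LABEL
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"hue {h} outside [0, 1]")
    for r in ranges:
        if r.contains(h):
            return r.label
    return OTHER_LABEL


class HueRangeClassifier(ClassifierMixin, BaseEstimator):
    """Interval-membership phenotype classifier over the hue wheel.

    ``fit`` learns, for every label in ``y``, the closed min–max envelope
    of the training hues; ``predict`` assigns the label of the interval
    containing each hue, or ``other_label`` when no interval matches.
    Fitting fails if the learned envelopes overlap, since overlapping
    phenotype definitions make classification ambiguous.

    Parameters
    ----------
    other_label : str
        Label returned for hues outside every learned interval.

    Attributes
    ----------
    ranges_ : tuple of PhenotypeHueRange
        The learned, validated intervals.
    classes_ : ndarray
        Training labels plus ``other_label``, sorted.
    """

    def __init__(self, other_label: str = OTHER_LABEL):
        self.other_label = other_label

    @staticmethod
    def _hues(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError(f"expected a single hue feature, got {X.shape[1]}")
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError(f"expected 1-D hues or an (n, 1) column, got shape {X.shape}")
        if np.any(np.isnan(X)) or np.any((X < 0) | (X > 1)):
            raise ValueError("hues must be finite and within [0, 1]")
        return X

    def fit(self, X, y):
        h = self._hues(X)
        y = np.asarray(y)
        if len(y) != len(h):
            raise ValueError("X and y have different lengths")
        if len(h) == 0:
            raise ValueError("empty training set")
        ranges = []
        for label in np.unique(y):
            sel = h[y == label]
            ranges.append(PhenotypeHueRange(str(label), float(sel.min()), float(sel.max())))
        self.ranges_ = validate_ranges(ranges)
        self.classes_ = np.unique(np.append(y.astype(str), self.other_label))
        return self

    def predict(self, X):
        check_is_fitted(self, "ranges_")
        h = self._hues(X)
        return np.array([self._predict_one(v) for v in h], dtype=object)

    def _predict_one(self, h: float) -> str:
        for r in self.ranges_:
            if r.contains(h):
                return r.label
        return self.other_label


def save_ranges(ranges: Sequence[PhenotypeHueRange], path) -> None:
    """Write ranges to a small JSON file (label, lo, hi, wrap)."""
    payload = [
        {"label": r.label, "lo": r.lo, "hi": r.hi, "wrap": r.wrap} for r in ranges
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_ranges(path) -> tuple[PhenotypeHueRange, ...]:
    """Read and validate a ranges JSON file written by :func:`save_ranges`."""
    payload = json.loads(Path(path).read_text())
    return validate_ranges(
        PhenotypeHueRange(d["label"], d["lo"], d["hi"], d.get("wrap", False))
        for d in payload
    )
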