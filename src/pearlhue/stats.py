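"""Group-level statistics on colour summaries.

Covers the downstream analysis run on per-sample HSV summaries: the hue
diversity index (distinct hues / samples), colour-match rates (pearls
matching their donor's phenotype), 2x2 contingency tests with Yates
continuity correction, Wilcoxon rank-sum tests for saturation and
brightness shifts between rearing depths, a Shapiro-Wilk normality
screen, and dominant-hue detection as local maxima of a kernel density
estimate of the hue distribution.

No multiple-testing correction is applied; each comparison is reported
as-is, which mirrors how such pairwise colour comparisons are usually
reported and is documented as a caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats as sps

__all__ = [
    "ContingencyTable2x2",
    "GroupColourTable",
    "count_distinct_hues",
    "diversity_index",
    "match_rate",
    "chi2_yates",
    "wilcoxon_rank_sum",
    "shapiro_normality",
    "dominant_hues",
    "compare_groups",
    "DegenerateDataWarning",
]

DEFAULT_HUE_DECIMALS = 4
#: exact rank-sum enumeration is used up to this combined sample size (tie-free)
EXACT_MAX_N = 20


class DegenerateDataWarning(UserWarning):
    """Emitted when a test is run on data it cannot discriminate."""


def count_distinct_hues(hues: Sequence[float], precision: int = DEFAULT_HUE_DECIMALS) -> int:
    """Number of distinct hue values after rounding to ``precision`` decimals.

    Mean hues are continuous, so "same hue" needs an explicit
    quantisation rule; 4 decimals matches the precision at which
    dominant hues are customarily reported.
    """
    hues = np.asarray(list(hues), dtype=float)
    if hues.size == 0:
        raise ValueError("cannot count hues of an empty list")
    if np.any((hues < 0) | (hues > 1)):
        raise ValueError("hues must lie in [0, 1]")
    return int(np.unique(np.round(hues, precision)).size)


def diversity_index(n_hues: int, n_samples: int) -> float:
    """Hue diversity D = distinct hues / samples; 1 means every hue unique."""
    if not 1 <= n_hues <= n_samples:
        raise ValueError(f"need 1 <= n_hues ({n_hues}) <= n_samples ({n_samples})")
    return n_hues / n_samples


def match_rate(n_matching: int, n_samples: int) -> float:
    """Percentage of samples whose phenotype matches their donor's."""
    if n_samples < 1 or not 0 <= n_matching <= n_samples:
        raise ValueError(
            f"need 0 <= n_matching ({n_matching}) <= n_samples ({n_samples}), n_samples >= 1"
        )
    return 100.0 * n_matching / n_samples


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of non-negative counts (e.g. match/non-match x depth)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def chi2_yates(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table with Yates continuity correction.

    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d)),
    with the correction clamped at zero so a near-independent table can
    never gain evidence from over-correction.  Returns (statistic,
    upper-tail p on 1 degree of freedom).
    """
    if isinstance(table, (tuple, list)):
        table = ContingencyTable2x2(*table)
    r1, r2, c1, c2 = table.marginals
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-squared undefined: a marginal total is zero")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    excess = max(abs(a * d - b * c) - n / 2.0, 0.0)
    statistic = n * excess**2 / (r1 * r2 * c1 * c2)
    return float(statistic), float(sps.chi2.sf(statistic, df=1))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode`` selects the p-value computation:

    - ``"exact"``  — full enumeration of the rank-sum null distribution;
    - ``"approx"`` — normal approximation with tie and continuity
      corrections;
    - ``"auto"``   — exact when the combined sample size is at most 20
      and there are no ties, otherwise the corrected approximation.

    Returns (U statistic of ``x``, two-sided p).  If every value in both
    samples is identical the test is degenerate: p = 1 with a warning.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples need at least one observation")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn(
            "all observations identical; rank-sum test is degenerate (p = 1)",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return float(x.size * y.size / 2.0), 1.0

    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "approx"
    if mode == "exact" and has_ties:
        raise ValueError("exact enumeration requires tie-free samples")

    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def shapiro_normality(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p; a screen reported alongside the rank tests."""
    x = np.asarray(list(x), dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.all(x == x[0]):
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _reflected_kde(hues: np.ndarray, grid: np.ndarray, bw_method) -> np.ndarray:
    """Gaussian KDE on [0, 1] with boundary reflection at both ends."""
    kde = sps.gaussian_kde(hues, bw_method=bw_method)
    return kde(grid) + kde(-grid) + kde(2.0 - grid)


def dominant_hues(
    hues: Sequence[float],
    bw_method: str | float = "silverman",
    min_prominence: float = 0.5,
    grid_size: int = 512,
) -> list[float]:
    """Dominant hues: prominent local maxima of the hue density estimate.

    A Gaussian KDE (Silverman bandwidth by default) is evaluated on a
    ``grid_size``-point grid over [0, 1] with boundary reflection, so a
    red mode sitting exactly at hue 0 is still detected as a peak.

    ``min_prominence`` is expressed in probability-density units on the
    unit hue axis (a uniform hue distribution has density 1 everywhere):
    a mode must rise at least that far above its saddle to count.  The
    default of 0.5 sits well above the sampling wiggles a featureless
    distribution produces under Silverman bandwidths, so near-uniform
    hues yield no dominant hue.  Results are ordered by density height,
    highest first.
    """
    hues = np.asarray(list(hues), dtype=float)
    if hues.size < 2:
        raise ValueError("need at least 2 hues for a density estimate")
    if np.any((hues < 0) | (hues > 1)):
        raise ValueError("hues must lie in [0, 1]")
    if np.all(hues == hues[0]):
        return [float(hues[0])]

    grid = np.linspace(0.0, 1.0, grid_size)
    density = _reflected_kde(hues, grid, bw_method)

    # reflection makes the density symmetric at 0 and 1, so padding with
    # the mirrored profile lets boundary modes register as true peaks
    pad = grid_size // 8
    padded = np.concatenate([density[1:pad + 1][::-1], density, density[-pad - 1:-1][::-1]])
    peaks, _ = signal.find_peaks(padded, prominence=min_prominence)
    peaks = peaks - pad
    peaks = peaks[(peaks >= 0) & (peaks < grid_size)]
    order = np.argsort(density[peaks])[::-1]
    return [float(grid[i]) for i in peaks[order]]


@dataclass(frozen=True)
class GroupColourTable:
    """Colour summaries of one group (phenotype x depth) plus derived counts.

    ``n_matching`` counts samples whose phenotype call equals the donor
    phenotype; the diversity index counts distinct rounded hues among
    *all* samples of the group.
    """

    label: str
    hues: tuple = ()
    saturations: tuple = ()
    values: tuple = ()
    donor_phenotype: str | None = None
    phenotypes: tuple = ()
    hue_precision: int = DEFAULT_HUE_DECIMALS
    _counts: tuple | None = field(default=None, repr=False)

    @classmethod
    def from_summaries(
        cls,
        label: str,
        summaries: pd.DataFrame,
        donor_phenotype: str | None = None,
        hue_precision: int = DEFAULT_HUE_DECIMALS,
    ) -> "GroupColourTable":
        """Build from a pipeline report (only rows with status == "ok")."""
        ok = summaries[summaries["status"] == "ok"]
        return cls(
            label=label,
            hues=tuple(ok["hue"]),
            saturations=tuple(ok["saturation"]),
            values=tuple(ok["value"]),
            donor_phenotype=donor_phenotype,
            phenotypes=tuple(ok["phenotype"]),
            hue_precision=hue_precision,
        )

    @classmethod
    def from_counts(
        cls, label: str, n_samples: int, n_matching: int, n_hues: int
    ) -> "GroupColourTable":
        """Build from printed counts alone (no per-sample colours)."""
        if not (0 <= n_matching <= n_samples and 1 <= n_hues <= n_samples):
            raise ValueError("inconsistent counts")
        return cls(label=label, _counts=(n_samples, n_matching, n_hues))

    @property
    def n_samples(self) -> int:
        return self._counts[0] if self._counts else len(self.hues)

    @property
    def n_matching(self) -> int:
        if self._counts:
            return self._counts[1]
        if self.donor_phenotype is None:
            raise ValueError(f"group {self.label!r} has no donor phenotype")
        return sum(p == self.donor_phenotype for p in self.phenotypes)

    @property
    def n_distinct_hues(self) -> int:
        if self._counts:
            return self._counts[2]
        return count_distinct_hues(self.hues, self.hue_precision)

    @property
    def diversity(self) -> float:
        return diversity_index(self.n_distinct_hues, self.n_samples)

    @property
    def match_rate(self) -> float:
        return match_rate(self.n_matching, self.n_samples)


def compare_groups(
    pairs: Iterable[tuple[GroupColourTable, GroupColourTable]],
    min_prominence: float = 0.5,
) -> pd.DataFrame:
    """Pairwise comparison report between group colour tables.

    For each (a, b) pair: Wilcoxon rank-sum tests on saturation and on
    brightness with signed mean shifts (b minus a), the Yates
    chi-squared test on match/non-match counts, both diversity indices,
    and each group's dominant hues.  Count-only groups get the count
    statistics; groups without per-sample colours skip the distribution
    tests.  Empty groups are skipped with a warning.
    """
    rows = []
    for a, b in pairs:
        if a.n_samples == 0 or b.n_samples == 0:
            warnings.warn(
                f"skipping pair ({a.label}, {b.label}): empty group",
                DegenerateDataWarning,
                stacklevel=2,
            )
            continue
        row: dict = {
            "group_a": a.label,
            "group_b": b.label,
            "n_a": a.n_samples,
            "n_b": b.n_samples,
            "diversity_a": a.diversity,
            "diversity_b": b.diversity,
        }
        if a.saturations and b.saturations:
            for field_name, xa, xb in (
                ("saturation", a.saturations, b.saturations),
                ("value", a.values, b.values),
            ):
                stat, p = wilcoxon_rank_sum(xa, xb)
                row[f"wilcoxon_{field_name}_u"] = stat
                row[f"wilcoxon_{field_name}_p"] = p
                row[f"mean_{field_name}_shift"] = float(np.mean(xb) - np.mean(xa))
            row["dominant_hues_a"] = ";".join(
                f"{h:.4f}" for h in dominant_hues(a.hues, min_prominence=min_prominence)
            )
            row["dominant_hues_b"] = ";".join(
                f"{h:.4f}" for h in dominant_hues(b.hues, min_prominence=min_prominence)
            )
        try:
            table = ContingencyTable2x2(
                a.n_matching, a.n_samples - a.n_matching,
                b.n_matching, b.n_samples - b.n_matching,
            )
            row["match_rate_a"] = a.match_rate
            row["match_rate_b"] = b.match_rate
            row["chi2_yates"], row["chi2_p"] = chi2_yates(table)
        except ValueError:
            pass  # no donor phenotype or degenerate marginals: skip the test
        rows.append(row)
    return pd.DataFrame(rows)
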