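"""Published count table from the depth-conditioning graft experiment.

Pearls were produced from grafts of green- and red-phenotype donor
oysters conditioned at two depths (4 m subsurface vs 30 m deep).  For
every donor-phenotype x depth group the published table reports the
number of pearls harvested, the number whose colour phenotype matches
the donor's, and the number of distinct hues among them.  These counts
are the input of the statistics layer when no raw images are available:
diversity indices, colour-match rates and the Yates chi-squared
contingency tests all recompute directly from them.
"""

from __future__ import annotations

import pandas as pd

from .stats import ContingencyTable2x2, GroupColourTable

__all__ = ["pearl_count_table", "pearl_count_groups", "depth_contingency_tables"]

_ROWS = [
    # donor phenotype, depth, n_pearls, n_matching, n_hues
    ("green", "4m", 197, 132, 84),
    ("green", "30m", 166, 66, 98),
    ("green", "total", 363, 198, 138),
    ("red", "4m", 143, 84, 103),
    ("red", "30m", 163, 118, 112),
    ("red", "total", 306, 202, 185),
]


def pearl_count_table() -> pd.DataFrame:
    """The published counts as a tidy DataFrame."""
    return pd.DataFrame(
        _ROWS, columns=["donor", "depth", "n_pearls", "n_matching", "n_hues"]
    )


def pearl_count_groups() -> dict[str, GroupColourTable]:
    """Count-only group tables keyed ``"<donor>_<depth>"``."""
    return {
        f"{donor}_{depth}": GroupColourTable.from_counts(
            f"{donor}_{depth}", n_pearls, n_matching, n_hues
        )
        for donor, depth, n_pearls, n_matching, n_hues in _ROWS
    }


def depth_contingency_tables() -> dict[str, ContingencyTable2x2]:
    """Match/non-match x condition 2x2 tables for the published comparisons.

    Keys: ``green_by_depth`` and ``red_by_depth`` (4 m vs 30 m within a
    donor phenotype), ``donors_at_30m`` (green vs red at 30 m) and
    ``donors_both_depths`` (green vs red, depths pooled).
    """
    t = {(d, z): (n, m) for d, z, n, m, _ in _ROWS}

    def table(k1, k2) -> ContingencyTable2x2:
        (n1, m1), (n2, m2) = t[k1], t[k2]
        return ContingencyTable2x2(m1, n1 - m1, m2, n2 - m2)

    return {
        "green_by_depth": table(("green", "4m"), ("green", "30m")),
        "red_by_depth": table(("red", "4m"), ("red", "30m")),
        "donors_at_30m": table(("green", "30m"), ("red", "30m")),
        "donors_both_depths": table(("green", "total"), ("red", "total")),
    }
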