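"""Between-group enrichment statistics on UTR features.

Continuous features (G/C content, length, folding energy) are compared
between transcript classes with the two-sample Kolmogorov-Smirnov test;
motif presence flags with Fisher's exact test on 2x2 contingency
tables.  Tables can also be reconstructed from published group
percentages and sizes, for checking reported enrichments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "GroupComparison",
    "ks_compare",
    "fisher_exact",
    "reconstruct_table",
    "group_percentages",
    "benjamini_hochberg",
    "enrichment_report",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (group1 with motif, group1 without, group2 with,
    group2 without)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison of one continuous feature."""

    feature: str
    statistic: float  # KS D in [0, 1]
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


def ks_compare(
    values_a: Sequence[float], values_b: Sequence[float], feature: str = ""
) -> GroupComparison:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Missing values are dropped; the p-value is exact for groups of at
    most 25 observations and asymptotic above.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty after dropping missing values")
    method = "exact" if min(len(a), len(b)) <= 25 else "asymp"
    res = sps.ks_2samp(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        feature=feature,
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=len(a),
        n_b=len(b),
    )


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p: sum of hypergeometric probabilities
    of all tables (at fixed margins) no more probable than the observed
    one.  Degenerate margins give p = 1."""
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        return 1.0
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return float(min(p, 1.0))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconstruct_table(
    pct_a: float, n_a: int, pct_b: float, n_b: int
) -> ContingencyTable:
    """2x2 table from published group percentages and sizes.

    With-motif counts are ``round(pct * n / 100)``, rounding halves away
    from zero.  Published percentages are themselves rounded, so the
    reconstruction can be off by one count when ``pct * n / 100`` sits
    near a half-integer.
    """
    if not (0 <= pct_a <= 100 and 0 <= pct_b <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    a = _round_half_away(pct_a * n_a / 100.0)
    c = _round_half_away(pct_b * n_b / 100.0)
    return ContingencyTable(a, n_a - a, c, n_b - c)


def group_percentages(
    flags_by_group: Mapping[str, Sequence[bool]],
) -> dict[str, float]:
    """Percentage of True flags per group (full precision; empty groups
    map to NaN)."""
    out = {}
    for group, flags in flags_by_group.items():
        flags = list(flags)
        out[group] = 100.0 * sum(flags) / len(flags) if flags else float("nan")
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (opt-in utility)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


CONTINUOUS_FEATURES = ("gc", "length", "dG")
FLAG_FEATURES = (
    "has_ggc_motif",
    "has_gagg_motif",
    "has_urich_motif",
    "has_g4",
    "has_paired_ggagg",
)


def enrichment_report(
    features: pd.DataFrame,
    classes: Mapping[str, str] | pd.Series,
    group_a: str = "dependent",
    group_b: str = "independent",
) -> dict:
    """Full between-class comparison of a UTR feature table.

    Parameters
    ----------
    features:
        Output of :func:`translatome.utr.compute_features`, indexed by
        transcript id.
    classes:
        Transcript id -> class label; only ``group_a`` and ``group_b``
        members enter the comparison.

    Returns a JSON-serializable dict with a KS comparison per continuous
    feature and a Fisher's exact test (with group percentages) per
    presence flag.
    """
    labels = pd.Series(dict(classes))
    common = features.index.intersection(labels.index)
    feats = features.loc[common]
    labels = labels.loc[common]
    in_a = feats[labels == group_a]
    in_b = feats[labels == group_b]
    if len(in_a) == 0 or len(in_b) == 0:
        raise ValueError(
            f"need members of both classes {group_a!r} and {group_b!r} "
            f"(got {len(in_a)} and {len(in_b)})"
        )
    report: dict = {
        "groups": {group_a: int(len(in_a)), group_b: int(len(in_b))},
        "continuous": {},
        "flags": {},
    }
    for feat in CONTINUOUS_FEATURES:
        if feat not in feats.columns or feats[feat].isna().all():
            continue
        cmp = ks_compare(in_a[feat], in_b[feat], feature=feat)
        report["continuous"][feat] = {
            "ks_statistic": cmp.statistic,
            "p_value": cmp.p_value,
            f"median_{group_a}": cmp.median_a,
            f"median_{group_b}": cmp.median_b,
        }
    for feat in FLAG_FEATURES:
        if feat not in feats.columns:
            continue
        fa = in_a[feat].astype(bool)
        fb = in_b[feat].astype(bool)
        table = ContingencyTable(
            int(fa.sum()), int((~fa).sum()), int(fb.sum()), int((~fb).sum())
        )
        pct = group_percentages({group_a: fa.tolist(), group_b: fb.tolist()})
        report["flags"][feat] = {
            "table": [[table.a, table.b], [table.c, table.d]],
            f"pct_{group_a}": pct[group_a],
            f"pct_{group_b}": pct[group_b],
            "p_value": fisher_exact(table),
        }
    return report
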