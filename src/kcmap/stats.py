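"""Descriptive summaries and nonparametric group comparisons.

The analysis layer is deliberately nonparametric: group differences are
tested with the Kruskal-Wallis H test (tie-corrected, chi-square
reference with k-1 df) followed by pairwise Mann-Whitney post hoc
comparisons, with normality screened beforehand by a one-sample
Kolmogorov-Smirnov test against a normal with estimated mean/SD.

Note on the KS test: estimating the parameters from the same sample
makes the nominal KS p-value conservative (the Lilliefors effect); it is
used here as the original analysis used it, as a screen rather than an
exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reference import FEATURE_NAMES

ALPHA = 0.05


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class TestResult:
    """Omnibus Kruskal-Wallis result plus pairwise post hoc tests."""

    feature: str
    h_statistic: float
    p_value: float
    pairwise: tuple[PairwiseResult, ...] = ()


def summarize(features: pd.DataFrame, group_col: str = "group",
              columns: list[str] | None = None) -> pd.DataFrame:
    """Per-group descriptive statistics (mean, sample SD, median, range, n).

    A single-observation group gets SD 0 with ``degenerate_sd=True`` so
    downstream pipelines stay total.
    """
    columns = columns or [c for c in FEATURE_NAMES if c in features.columns]
    if group_col not in features.columns:
        raise ValueError(f"missing group column {group_col!r}")
    rows = []
    for group, sub in features.groupby(group_col, sort=False):
        if sub.empty:
            raise ValueError(f"group {group!r} is empty")
        for col in columns:
            v = sub[col].to_numpy(dtype=float)
            degenerate = v.size == 1
            rows.append(
                {
                    "group": group,
                    "feature": col,
                    "n": v.size,
                    "mean": float(np.mean(v)),
                    "sd": 0.0 if degenerate else float(np.std(v, ddof=1)),
                    "median": float(np.median(v)),
                    "min": float(np.min(v)),
                    "max": float(np.max(v)),
                    "degenerate_sd": degenerate,
                }
            )
    return pd.DataFrame(rows)


def ks_normality(values) -> tuple[float, float]:
    """One-sample KS statistic and asymptotic p against a normal with the
    sample's mean and SD.  Requires n >= 5."""
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("KS normality check requires at least 5 observations")
    mu, sd = v.mean(), v.std(ddof=1)
    if sd == 0:
        return 1.0, 0.0
    res = sps.kstest(v, "norm", args=(mu, sd))
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(values, groups, holm: bool = False) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with pairwise Mann-Whitney post hoc.

    Identical values across all groups yield H=0, p=1 rather than an
    error.  Pairwise p-values are unadjusted by default; ``holm=True``
    applies a Holm step-down correction.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [v[g == lab] for lab in labels]
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least two observations")

    if np.all(v == v[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)

    pairs, raw = [], []
    for (la, sa), (lb, sb) in combinations(zip(labels, samples), 2):
        u, pu = sps.mannwhitneyu(sa, sb, alternative="two-sided")
        pairs.append(((str(la), str(lb)), float(u)))
        raw.append(float(pu))
    if holm:
        from statsmodels.stats.multitest import multipletests
        raw = list(multipletests(raw, method="holm")[1])
    pairwise = tuple(
        PairwiseResult(pair=pair, statistic=stat, p_value=pv)
        for (pair, stat), pv in zip(pairs, raw)
    )
    return TestResult(feature="", h_statistic=float(h), p_value=float(p), pairwise=pairwise)


def test_features(features: pd.DataFrame, group_col: str = "group",
                  columns: list[str] | None = None, holm: bool = False) -> pd.DataFrame:
    """Kruskal-Wallis + post hoc for every feature column; long table with
    one row per feature x comparison (omnibus rows have pair='omnibus')."""
    columns = columns or [c for c in FEATURE_NAMES if c in features.columns]
    rows = []
    for col in columns:
        res = kruskal_wallis(features[col], features[group_col], holm=holm)
        rows.append(
            {"feature": col, "comparison": "omnibus", "statistic": res.h_statistic,
             "p_value": res.p_value, "significant": res.p_value < ALPHA}
        )
        for pw in res.pairwise:
            rows.append(
                {"feature": col, "comparison": f"{pw.pair[0]} vs {pw.pair[1]}",
                 "statistic": pw.statistic, "p_value": pw.p_value,
                 "significant": pw.significant}
            )
    return pd.DataFrame(rows)
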