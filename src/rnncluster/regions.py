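"""Region importance from selected features, plus cohort demographic tests.

A selected nodal feature (degree, clustering, local efficiency) credits
its one region; a selected shortest-path feature credits both endpoint
regions. The resulting integer weight per region — how many selected
significant features touch it — is the proxy for how discriminative (and,
in a patient/control contrast, how abnormal) a region is. Regions never
touched keep weight 0.

Also implemented here: the standard cohort-table tests — Pearson
chi-square (1 df, no continuity correction) on the sex contingency table
and a pooled two-sample t-test on age from summary statistics.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from rnncluster.features import FeatureLayout

__all__ = [
    "load_region_labels",
    "feature_to_regions",
    "region_weights",
    "rank_regions",
    "sex_chisq",
    "age_ttest",
    "CohortSummary",
    "TestResult",
]

TestResult = namedtuple("TestResult", ["statistic", "pvalue"])


def load_region_labels(path=None) -> pd.DataFrame:
    """Region label table: columns index (1-based), abbrev, name.

    Defaults to the bundled 90-region AAL table.
    """
    if path is None:
        src = resources.files("rnncluster.data").joinpath("aal90.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"index", "abbrev", "name"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    return df


def feature_to_regions(index: int, layout: FeatureLayout) -> tuple[int, ...]:
    """Region index (nodal feature) or region pair (shortest-path feature)."""
    _, regions = layout.describe(index)
    return regions


def region_weights(selected, layout: FeatureLayout,
                   labels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-region weights from a selected feature set.

    Returns a DataFrame with columns region (0-based), index (1-based),
    abbrev, name, weight — sorted by descending weight, ties by ascending
    region index. Sum of weights = #nodal selected + 2 * #pair selected.
    """
    weights = np.zeros(layout.n_regions, dtype=int)
    for f in selected:
        for r in feature_to_regions(int(f), layout):
            weights[r] += 1
    if labels is None:
        abbrev = [f"R{r + 1}" for r in range(layout.n_regions)]
        name = abbrev
    else:
        if len(labels) < layout.n_regions:
            raise ValueError(
                f"label table has {len(labels)} rows, need {layout.n_regions}"
            )
        ordered = labels.sort_values("index").reset_index(drop=True)
        abbrev = ordered["abbrev"].tolist()[: layout.n_regions]
        name = ordered["name"].tolist()[: layout.n_regions]
    df = pd.DataFrame({
        "region": np.arange(layout.n_regions),
        "index": np.arange(1, layout.n_regions + 1),
        "abbrev": abbrev,
        "name": name,
        "weight": weights,
    })
    return df.sort_values(
        ["weight", "region"], ascending=[False, True]
    ).reset_index(drop=True)


def rank_regions(table: pd.DataFrame, min_weight: int = 0) -> pd.DataFrame:
    """Regions with weight >= min_weight (inclusive), descending."""
    if min_weight < 0:
        raise ValueError("min_weight must be >= 0")
    out = table[table["weight"] >= min_weight]
    return out.sort_values(
        ["weight", "region"], ascending=[False, True]
    ).reset_index(drop=True)


def sex_chisq(table) -> TestResult:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Rows are groups, columns sex counts. Raises on a zero margin (the
    statistic is undefined there).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 contingency table")
    if np.any(t < 0):
        raise ValueError("cell counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(stat), pvalue=float(p))


def age_ttest(mean1: float, sd1: float, n1: int,
              mean2: float, sd2: float, n2: int) -> TestResult:
    """Pooled-variance two-sample t-test from summary statistics."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=True)
    return TestResult(statistic=float(t), pvalue=float(p))


@dataclass(frozen=True)
class CohortSummary:
    """Group sizes, sex counts and age summaries of a two-group cohort."""

    n_group1: int
    n_group2: int
    sex_table: tuple  # ((m1, f1), (m2, f2))
    age_mean1: float
    age_sd1: float
    age_mean2: float
    age_sd2: float

    def __post_init__(self) -> None:
        t = np.asarray(self.sex_table)
        if t.shape != (2, 2) or np.any(t < 0):
            raise ValueError("sex_table must be a nonnegative 2x2 table")
        if t[0].sum() != self.n_group1 or t[1].sum() != self.n_group2:
            raise ValueError("sex counts inconsistent with group sizes")

    def sex_test(self) -> TestResult:
        return sex_chisq(self.sex_table)

    def age_test(self) -> TestResult:
        return age_ttest(self.age_mean1, self.age_sd1, self.n_group1,
                         self.age_mean2, self.age_sd2, self.n_group2)
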