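"""Cohort-level statistics: paired approach comparisons (two-sided Wilcoxon
signed-rank), tracer-effect tests (two-sided Mann-Whitney U), and mean/SD
summary tables per metric, side and approach.

Raw two-sided p-values are reported against a 0.05 threshold; no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import KidneyMetricRecord

__all__ = ["ComparisonResult", "wilcoxon_paired", "mann_whitney_u",
           "summarize_cohort", "records_to_frame"]

METRIC_COLUMNS = ("dsc", "vd_percent", "ahd_mm")


@dataclass
class ComparisonResult:
    metric: str
    side: str
    approach_a: str
    approach_b: str
    test: str
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def wilcoxon_paired(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Exact null distribution for n <= 25 (no ties/zeros), normal approximation
    otherwise.  Zero differences are discarded (Wilcoxon's original rule).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.all(a == b):
        raise ValueError("all paired differences are zero; test is degenerate")
    res = stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox",
                         correction=False, method="auto")
    return float(res.pvalue)


def mann_whitney_u(group1, group2) -> float:
    """Two-sided Mann-Whitney U (rank-sum) p-value for two independent groups;
    exact for small tie-free samples, tie-corrected normal approximation
    otherwise."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="auto")
    return float(res.pvalue)


def records_to_frame(records: list[KidneyMetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def summarize_cohort(records: list[KidneyMetricRecord],
                     reference_approach: str | None = None,
                     alpha: float = 0.05, pool_sides: bool = False) -> dict:
    """Mean and sample SD per metric/side/approach plus pairwise Wilcoxon
    p-values against a designated reference approach.

    Returns ``{"summary": DataFrame, "comparisons": [ComparisonResult, ...]}``.
    Cells with a single record get SD = NaN (flagged, not imputed); pairs are
    matched on (case_id, side) for the signed-rank tests.  With
    ``pool_sides=True`` left and right kidneys are tested jointly (side label
    "both") instead of separately.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no metric records to summarize")
    if pool_sides:
        df = df.assign(case_id=df["case_id"] + ":" + df["side"], side="both")
    summary = (df.groupby(["approach", "side"])[list(METRIC_COLUMNS)]
                 .agg(["mean", "std", "count"]))
    comparisons: list[ComparisonResult] = []
    approaches = sorted(df["approach"].unique())
    if reference_approach is not None and reference_approach in approaches:
        ref = df[df["approach"] == reference_approach]
        for other in approaches:
            if other == reference_approach:
                continue
            oth = df[df["approach"] == other]
            for side in sorted(df["side"].unique()):
                merged = pd.merge(ref[ref["side"] == side], oth[oth["side"] == side],
                                  on=["case_id", "side"], suffixes=("_ref", "_oth"))
                if len(merged) < 2:
                    continue
                for metric in METRIC_COLUMNS:
                    a = merged[f"{metric}_ref"].to_numpy()
                    b = merged[f"{metric}_oth"].to_numpy()
                    if np.all(a == b):
                        continue
                    comparisons.append(ComparisonResult(
                        metric=metric, side=side,
                        approach_a=reference_approach, approach_b=other,
                        test="wilcoxon_paired",
                        p_value=wilcoxon_paired(a, b), n=len(merged)))
    out = {"summary": summary, "comparisons": comparisons, "alpha": alpha}
    out["significant"] = [c for c in comparisons if c.p_value < alpha]
    return out
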