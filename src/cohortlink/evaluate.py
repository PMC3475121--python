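"""Evaluation statistics for the linkage.

Three kinds of quantity are computed:

* linkage performance against a known ground truth (sensitivity, positive
  predictive value, and a per-stage attribution table) — only meaningful for
  simulated cohorts, where true identity is known;
* completeness estimation: a Wald binomial interval on an externally observed
  pregnancy rate, scaled to a target population, giving the *expected* range
  of matchable women;
* representativeness comparisons between matched and non-matched women:
  odds ratios from 2x2 tables (Woolf log intervals), chi-squared tests for
  categorical variables, and Mann-Whitney rank-sum tests for ages.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import GroundTruth, MatchDecision

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "LinkagePerformance",
    "odds_ratio",
    "expected_match_range",
    "score_linkage",
    "compare_groups",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) = exposed/unexposed in group 1, (c, d) in group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    ci_low: float | None
    ci_high: float | None
    confidence: float

    def rounded(self) -> float:
        """Odds ratio rounded for reporting: 2 decimals, 1 decimal when >= 8."""
        return round(self.oddsratio, 1 if self.oddsratio >= 8 else 2)


def odds_ratio(t: ContingencyTable2x2, confidence: float = 0.95) -> OddsRatioResult:
    """Cross-product odds ratio (a*d)/(b*c) with a Woolf (log) interval.

    The interval needs all four cells positive; with a zero cell the point
    estimate is still returned (when defined) with no interval.
    """
    if t.b * t.c == 0:
        raise ZeroDivisionError("odds ratio undefined: b*c = 0")
    oddsratio = (t.a * t.d) / (t.b * t.c)
    if min(t.a, t.b, t.c, t.d) == 0:
        return OddsRatioResult(oddsratio, None, None, confidence)
    z = stats.norm.ppf(0.5 + confidence / 2)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_or = math.log(oddsratio)
    return OddsRatioResult(oddsratio, math.exp(log_or - z * se),
                           math.exp(log_or + z * se), confidence)


def expected_match_range(events: int, population: int, target_population: int,
                         confidence: float = 0.95) -> tuple[int, int]:
    """Expected number of matchable women in a target population.

    A Wald normal-approximation interval for the proportion events/population
    is scaled to ``target_population`` and rounded to whole women.  Used to
    judge completeness when no gold standard exists: an observed match count
    below the returned range indicates under-matching.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if not 0 <= events <= population:
        raise ValueError("events must lie in [0, population]")
    if events == 0:
        warnings.warn("zero events: degenerate interval (0, 0)")
        return (0, 0)
    p = events / population
    z = stats.norm.ppf(0.5 + confidence / 2)
    half = z * math.sqrt(p * (1 - p) / population)
    return (round((p - half) * target_population),
            round((p + half) * target_population))


@dataclass
class LinkagePerformance:
    """Linkage quality against ground truth, plus per-criterion attribution
    in the shape of a published criteria table (N, %, cumulative %)."""

    true_positives: int
    false_positives: int
    false_negatives: int
    sensitivity: float | None
    ppv: float | None
    stage_table: pd.DataFrame = field(repr=False, default=None)


def score_linkage(confirmed: list[MatchDecision],
                  truth: GroundTruth) -> LinkagePerformance:
    """Compare confirmed matches with the true identity map."""
    confirmed_pairs = {d.pair.key for d in confirmed}
    true_pairs = truth.pairs()
    tp = len(confirmed_pairs & true_pairs)
    fp = len(confirmed_pairs - true_pairs)
    fn = len(true_pairs - confirmed_pairs)

    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None

    rows = []
    total = len(confirmed)
    seen = 0
    for stage in ("CD4-exact", "CD4-window", "ART-exact", "ART-window", "manual"):
        stage_decisions = [d for d in confirmed if d.stage == stage]
        for criterion in sorted({d.criterion for d in stage_decisions}):
            n = sum(1 for d in stage_decisions if d.criterion == criterion)
            seen += n
            rows.append({
                "stage": stage, "criterion": criterion, "n": n,
                "pct": 100.0 * n / total if total else 0.0,
                "cumulative_pct": 100.0 * seen / total if total else 0.0,
            })
    table = pd.DataFrame(rows, columns=["stage", "criterion", "n", "pct",
                                        "cumulative_pct"])
    return LinkagePerformance(tp, fp, fn, sensitivity, ppv, table)


def compare_groups(frame: pd.DataFrame, group_col: str,
                   variables: dict[str, str],
                   confidence: float = 0.95) -> pd.DataFrame:
    """Compare two groups of women variable by variable.

    ``frame`` holds one row per woman; ``group_col`` is a boolean column
    (True = group 1, e.g. matched).  ``variables`` maps column name to kind:

    * ``"binary"``      — boolean column; reports counts, percentages and the
      odds ratio with its Woolf interval and chi-squared p-value;
    * ``"categorical"`` — reports a chi-squared test over the full table;
    * ``"continuous"``  — reports medians and a Mann-Whitney rank-sum p-value.
    """
    missing = [v for v in variables if v not in frame.columns]
    if missing:
        raise KeyError(f"variables absent from records: {missing}")
    if frame[group_col].dtype != bool:
        raise TypeError(f"{group_col!r} must be boolean")

    g1 = frame[frame[group_col]]
    g2 = frame[~frame[group_col]]
    rows = []
    for name, kind in variables.items():
        row: dict = {"variable": name, "kind": kind,
                     "n1": len(g1), "n2": len(g2)}
        if kind == "binary":
            a, b = int(g1[name].sum()), int((~g1[name]).sum())
            c, d = int(g2[name].sum()), int((~g2[name]).sum())
            row.update({
                "count1": a, "pct1": 100.0 * a / len(g1) if len(g1) else np.nan,
                "count2": c, "pct2": 100.0 * c / len(g2) if len(g2) else np.nan,
            })
            try:
                res = odds_ratio(ContingencyTable2x2(a, b, c, d), confidence)
                row.update({"odds_ratio": res.oddsratio,
                            "ci_low": res.ci_low, "ci_high": res.ci_high})
            except ZeroDivisionError:
                row.update({"odds_ratio": np.nan, "ci_low": np.nan,
                            "ci_high": np.nan})
            if min(a + b, c + d) > 0 and 0 < a + c < a + b + c + d:
                row["p_value"] = stats.chi2_contingency(
                    [[a, b], [c, d]], correction=False).pvalue
            else:
                row["p_value"] = np.nan
        elif kind == "categorical":
            table = pd.crosstab(frame[group_col], frame[name])
            row["p_value"] = (stats.chi2_contingency(table.values).pvalue
                              if table.shape == (2, table.shape[1])
                              and table.shape[1] > 1 else np.nan)
        elif kind == "continuous":
            x, y = g1[name].dropna(), g2[name].dropna()
            row.update({"median1": float(x.median()) if len(x) else np.nan,
                        "median2": float(y.median()) if len(y) else np.nan})
            row["p_value"] = (stats.mannwhitneyu(x, y).pvalue
                              if len(x) and len(y) else np.nan)
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
        rows.append(row)
    return pd.DataFrame(rows)
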