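"""Reporting layer: per-activity RMSE tables and paired t-tests.

Mirrors the reporting conventions of bench validation studies of joint
kinematics: per-trial RMSEs are computed first, then summarised per
activity and condition as mean +- sample standard deviation (n-1
denominator), and conditions are compared with two-sided paired t-tests,
reported both raw and Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import KinematicSignal, signal_rmse

__all__ = [
    "RmseReport",
    "PairedTestResult",
    "trial_rmse_matrix",
    "rmse_table",
    "paired_ttest",
]

CONDITIONS = ("not_optimised", "foom_align", "foom_standalone")
_COMPONENT_LABELS = ("flexion/extension", "ab/adduction", "int/ext rotation")

ALPHA = 0.05  # significance level for reported verdicts


@dataclass(frozen=True)
class RmseReport:
    """Per-activity, per-condition RMSE summary (degrees)."""

    table: pd.DataFrame  # index (activity, condition); columns mean/sd per component + n_trials

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def __str__(self) -> str:
        rows = []
        for (activity, condition), row in self.table.iterrows():
            cells = "  ".join(
                f"{row[f'mean_{i}']:4.1f} ± {row[f'sd_{i}']:3.1f}"
                for i in (1, 2, 3))
            rows.append(f"{activity:<15} {condition:<16} {cells}"
                        f"   (n={int(row['n_trials'])})")
        header = (f"{'activity':<15} {'condition':<16} "
                  + "  ".join(f"{lbl[:10]:>10}" for lbl in _COMPONENT_LABELS))
        return "\n".join([header] + rows)


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test with Bonferroni-corrected p-value."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    p_bonferroni: float
    m_comparisons: int
    significant_raw: bool
    significant_bonferroni: bool
    infinite_statistic: bool = False


def trial_rmse_matrix(pairs: Sequence[tuple[KinematicSignal, KinematicSignal]]
                      ) -> np.ndarray:
    """Per-trial, per-component RMSEs for a list of signal pairs, (n, 3)."""
    if len(pairs) == 0:
        raise ValueError("need at least one trial pair")
    return np.array([signal_rmse(a, b) for a, b in pairs])


def rmse_table(trials: Mapping[tuple[str, str],
                               Sequence[tuple[KinematicSignal, KinematicSignal]]]
               ) -> RmseReport:
    """Summarise per-trial RMSEs as mean +- sd per activity and condition.

    ``trials`` maps (activity, condition) to a list of (signal_a, signal_b)
    pairs sharing a cycle grid. Per-trial RMSEs are computed first, then
    averaged across trials; the spread is the sample (n-1) standard
    deviation, reported as 0 for a single trial (flagged by n_trials = 1).
    """
    if not trials:
        raise ValueError("no trials supplied")
    records = []
    for (activity, condition), pairs in trials.items():
        rmse = trial_rmse_matrix(pairs)
        n = rmse.shape[0]
        mean = rmse.mean(axis=0)
        sd = rmse.std(axis=0, ddof=1) if n > 1 else np.zeros(3)
        rec = {"activity": activity, "condition": condition, "n_trials": n}
        for i in range(3):
            rec[f"mean_{i + 1}"] = mean[i]
            rec[f"sd_{i + 1}"] = sd[i]
        records.append(rec)
    table = pd.DataFrame.from_records(records).set_index(
        ["activity", "condition"]).sort_index()
    return RmseReport(table)


def paired_ttest(before: Sequence[float], after: Sequence[float],
                 m_comparisons: int = 2) -> PairedTestResult:
    """Two-sided paired t-test on per-trial RMSEs, with Bonferroni option.

    The default of two comparisons reflects the usual design: condition A
    vs baseline and condition B vs baseline tested on the same trials.

    Raises
    ------
    ValueError
        If fewer than two pairs are given, lengths differ, or every
        difference is exactly zero (the statistic is undefined).
    """
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("before/after must be 1-D sequences of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test requires at least two pairs")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    d = x - y
    sd_d = float(np.std(d, ddof=1))
    mean_d = float(np.mean(d))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            raise ValueError("all paired differences are exactly zero: "
                             "t statistic undefined")
        # constant nonzero difference: statistic diverges, p -> 0
        t_stat = float("inf") if mean_d > 0 else float("-inf")
        return PairedTestResult(
            t_statistic=t_stat, degrees_of_freedom=df, p_value=0.0,
            p_bonferroni=0.0, m_comparisons=m_comparisons,
            significant_raw=True, significant_bonferroni=True,
            infinite_statistic=True)
    res = stats.ttest_rel(x, y)
    t_stat = float(res.statistic)
    p = float(res.pvalue)
    p_bonf = min(1.0, m_comparisons * p)
    return PairedTestResult(
        t_statistic=t_stat,
        degrees_of_freedom=df,
        p_value=p,
        p_bonferroni=p_bonf,
        m_comparisons=m_comparisons,
        significant_raw=p < ALPHA,
        significant_bonferroni=p_bonf < ALPHA,
    )
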