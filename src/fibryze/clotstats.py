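"""Clot-lysis degradation percentage and significance testing.

The degradation percentage follows the assay formula
``(initial − final) / final × 100`` (division by the *final* dry weight,
as the assay defines it); the more common ``(initial − final) / initial``
convention is available explicitly. Group comparisons use classical
one-way ANOVA computed from sums of squares, followed by pairwise t tests
adjusted by both Bonferroni and Holm step-down, reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClotRecord",
    "AnovaResult",
    "degradation_pct",
    "degradation_table",
    "anova_posthoc",
]

CONVENTIONS = ("as_printed", "fraction_of_initial")


@dataclass(frozen=True)
class ClotRecord:
    """One clot-lysis replicate: dry weights (g) and released cells/mL."""

    group: str
    replicate: int
    initial_weight: float
    final_weight: float
    released_cells: float | None = None

    def __post_init__(self) -> None:
        if self.initial_weight <= 0 or self.final_weight <= 0:
            raise ValueError(
                f"{self.group}/{self.replicate}: weights must be positive"
            )


@dataclass
class AnovaResult:
    """One-way ANOVA with a pairwise post-hoc table.

    ``posthoc`` columns: group_a, group_b, t_stat, p_raw, p_bonferroni,
    reject_bonferroni, p_holm, reject_holm.
    """

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    alpha: float
    posthoc: pd.DataFrame


def degradation_pct(initial_weight, final_weight, convention: str = "as_printed"):
    """Percent clot degradation from dry weights.

    ``as_printed``: (initial − final)/final × 100 (the assay formula);
    ``fraction_of_initial``: (initial − final)/initial × 100. Accepts
    scalars or arrays; a zero denominator is an error.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; use one of {CONVENTIONS}")
    i = np.asarray(initial_weight, dtype=float)
    f = np.asarray(final_weight, dtype=float)
    denom = f if convention == "as_printed" else i
    if np.any(denom == 0):
        raise ZeroDivisionError("zero weight in the denominator")
    out = (i - f) / denom * 100.0
    return float(out) if out.ndim == 0 else out


def degradation_table(records: list[ClotRecord], convention: str = "as_printed") -> pd.DataFrame:
    """Per-replicate degradation percentages as a tidy table."""
    rows = [
        {
            "group": r.group,
            "replicate": r.replicate,
            "initial_weight": r.initial_weight,
            "final_weight": r.final_weight,
            "released_cells": r.released_cells,
            "degradation_pct": degradation_pct(r.initial_weight, r.final_weight, convention),
            "convention": convention,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def _pairwise_t(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    # zero pooled variance: the t statistic is undefined; resolve by means
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def anova_posthoc(
    values_by_group: dict[str, "np.typing.ArrayLike"],
    alpha: float = 0.05,
    welch: bool = False,
    posthoc: bool = True,
) -> AnovaResult:
    """Classical one-way ANOVA plus Bonferroni and Holm pairwise tests.

    The F statistic is computed from between/within sums of squares;
    pairwise comparisons are pooled-variance t tests (Welch by flag),
    with both adjustments reported side by side. When every observation
    is identical the degenerate F = 0, p = 1 path is taken.
    ``posthoc=False`` skips the pairwise table (useful in simulation
    loops that only need the omnibus test).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs at least two values")
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    dfb = len(groups) - 1
    dfw = all_vals.size - len(groups)
    if ssw == 0.0 and ssb == 0.0:
        f_stat, p_value = 0.0, 1.0
    elif ssw == 0.0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = (ssb / dfb) / (ssw / dfw)
        p_value = float(stats.f.sf(f_stat, dfb, dfw))
    columns = ["group_a", "group_b", "t_stat", "p_raw", "p_bonferroni",
               "reject_bonferroni", "p_holm", "reject_holm"]
    if posthoc:
        pairs = list(combinations(sorted(groups), 2))
        t_stats, p_raw = [], []
        for ga, gb in pairs:
            t, p = _pairwise_t(groups[ga], groups[gb], welch)
            t_stats.append(t)
            p_raw.append(p)
        rej_b, p_bonf, _, _ = multipletests(p_raw, alpha=alpha, method="bonferroni")
        rej_h, p_holm, _, _ = multipletests(p_raw, alpha=alpha, method="holm")
        table = pd.DataFrame(
            {
                "group_a": [p[0] for p in pairs],
                "group_b": [p[1] for p in pairs],
                "t_stat": t_stats,
                "p_raw": p_raw,
                "p_bonferroni": p_bonf,
                "reject_bonferroni": rej_b,
                "p_holm": p_holm,
                "reject_holm": rej_h,
            }
        )
    else:
        table = pd.DataFrame(columns=columns)
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=dfb,
        df_within=dfw,
        p_value=float(p_value),
        alpha=alpha,
        posthoc=table,
    )
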