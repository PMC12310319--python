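"""Endorsement tables, paired change tests, and scale reliability."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import BinarySymptomMatrix

__all__ = [
    "PairedChangeResult",
    "endorsement_table",
    "mcnemar",
    "paired_change_table",
    "cronbach_alpha",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, used only at the reporting layer."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PairedChangeResult:
    """McNemar test of a marginal frequency change between two waves.

    b = discordant 1 -> 0 pairs, c = discordant 0 -> 1 pairs.
    """

    b: int
    c: int
    statistic: float
    pvalue: float
    correction: bool


def mcnemar(w1_item, w2_item, correction: bool = False) -> PairedChangeResult:
    """McNemar chi-square from the discordant counts.

    statistic = (b - c)^2 / (b + c), or (|b - c| - 1)^2 / (b + c) with
    the continuity correction; p from chi-square(1).  b + c = 0 gives
    statistic 0 and p = 1.
    """
    x1 = np.asarray(w1_item, dtype=np.int64).ravel()
    x2 = np.asarray(w2_item, dtype=np.int64).ravel()
    if x1.shape != x2.shape:
        raise ValueError("paired vectors must have equal length")
    b = int(np.sum((x1 == 1) & (x2 == 0)))
    c = int(np.sum((x1 == 0) & (x2 == 1)))
    if b + c == 0:
        return PairedChangeResult(b, c, 0.0, 1.0, correction)
    if correction:
        stat = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        stat = (b - c) ** 2 / (b + c)
    return PairedChangeResult(b, c, float(stat), float(chi2.sf(stat, df=1)), correction)


def endorsement_table(
    w1: BinarySymptomMatrix, w2: BinarySymptomMatrix
) -> pd.DataFrame:
    """Per-item endorsement counts and percentages for both waves.

    Percentages are kept at full precision; use ``round_half_up`` when
    formatting for display.
    """
    if w1.values.shape != w2.values.shape or w1.item_labels != w2.item_labels:
        raise ValueError("wave matrices must match in shape and labels")
    n = w1.n
    c1 = w1.values.sum(axis=0)
    c2 = w2.values.sum(axis=0)
    return pd.DataFrame(
        {
            "item": list(w1.item_labels),
            "wave1_count": c1,
            "wave1_pct": 100.0 * c1 / n,
            "wave2_count": c2,
            "wave2_pct": 100.0 * c2 / n,
        }
    )


def paired_change_table(
    w1: BinarySymptomMatrix, w2: BinarySymptomMatrix, correction: bool = False
) -> pd.DataFrame:
    """Endorsement table plus McNemar change tests, with significance
    flags at 0.05 (*) and 0.001 (**)."""
    tab = endorsement_table(w1, w2)
    rows = [
        mcnemar(w1.values[:, j], w2.values[:, j], correction=correction)
        for j in range(w1.p)
    ]
    tab["b_1to0"] = [r.b for r in rows]
    tab["c_0to1"] = [r.c for r in rows]
    tab["chi2"] = [r.statistic for r in rows]
    tab["pvalue"] = [r.pvalue for r in rows]
    tab["sig"] = [
        "**" if r.pvalue < 0.001 else ("*" if r.pvalue < 0.05 else "")
        for r in rows
    ]
    return tab


def cronbach_alpha(m: BinarySymptomMatrix) -> float:
    """Cronbach's alpha (equals KR-20 for binary items):

    alpha = p/(p-1) * (1 - sum of item variances / variance of totals).
    """
    x = np.asarray(m.values, dtype=np.float64)
    n, p = x.shape
    if p < 2:
        raise ValueError("alpha requires at least 2 items")
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance")
    return float(p / (p - 1) * (1.0 - item_var.sum() / total_var))
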