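"""Outcome measures of a simulated breeding scheme.

Rates of genetic gain and pedigree inbreeding, GEBV accuracy and dispersion
bias, and replicate aggregation.  The rate of gain is the difference in mean
C-trait true breeding value between the last and first three-year windows of
the evaluation period divided by the number of years in between; the rate of
inbreeding per generation comes from the regression of ln(1 - F_t) on
generation number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "rate_of_genetic_gain",
    "pedigree_inbreeding",
    "rate_of_inbreeding",
    "accuracy_and_bias",
    "summarize_replicates",
    "MetricsReport",
]


def rate_of_genetic_gain(
    series: dict[int, float] | pd.Series,
    early_years: tuple[int, ...] = (5, 6, 7),
    late_years: tuple[int, ...] = (19, 20, 21),
) -> float:
    """Yearly rate of gain from cohort mean TBV of the C trait.

    ``[(G19+G20+G21) - (G5+G6+G7)] / [(19+20+21) - (5+6+7)]`` at the default
    windows; both windows are configurable for shortened runs.
    """
    s = dict(series)
    missing = [t for t in (*early_years, *late_years) if t not in s]
    if missing:
        raise ValueError(f"G series missing years {missing}")
    num = sum(s[t] for t in late_years) - sum(s[t] for t in early_years)
    den = sum(late_years) - sum(early_years)
    return num / den


def pedigree_inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Wright's inbreeding coefficient for every individual of a pedigree.

    ``sire[i]``/``dam[i]`` are row indices of the parents of individual
    ``i``, or -1 for founders; rows must be sorted so parents precede
    offspring (the simulator's pedigrees are, being in birth order).  Uses
    the ancestor-tracing algorithm of the tabular method (Meuwissen-Luo):
    F_i is the coancestry of the parents, accumulated over the diagonal
    contributions of their common ancestors.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    n = sire.size
    if np.any((sire >= np.arange(n)) & (sire >= 0)) or np.any((dam >= np.arange(n)) & (dam >= 0)):
        raise ValueError("pedigree not sorted: each parent must precede its offspring")
    F = np.zeros(n)
    # coancestry cache between pairs already visited, keyed on (min, max)
    cache: dict[tuple[int, int], float] = {}

    def kinship(a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        if a > b:
            a, b = b, a
        key = (a, b)
        got = cache.get(key)
        if got is not None:
            return got
        if a == b:
            val = 0.5 * (1.0 + kinship(sire[a], dam[a]))
        else:
            # b is the younger: recurse on its parents
            val = 0.5 * (kinship(a, sire[b]) + kinship(a, dam[b]))
        cache[key] = val
        return val

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * n + 1000))
    try:
        for i in range(n):
            F[i] = kinship(sire[i], dam[i])
    finally:
        sys.setrecursionlimit(old_limit)
    return F


def rate_of_inbreeding(
    F_by_year: dict[int, float] | pd.Series,
    years: tuple[int, ...] | range = range(5, 22),
    generation_interval: float = 3.0,
) -> float:
    """Rate of inbreeding in % per generation.

    ``(1 - exp(beta)) * 100`` where beta is the slope of the regression of
    ``ln(1 - F_t)`` on ``t / generation_interval`` over the stated years.
    The default three-year interval is the candidate age of the design.
    """
    s = dict(F_by_year)
    ys = [t for t in years]
    missing = [t for t in ys if t not in s]
    if missing:
        raise ValueError(f"F series missing years {missing}")
    F = np.array([s[t] for t in ys], dtype=np.float64)
    if np.any(F >= 1.0) or np.any(F < 0.0):
        raise ValueError("inbreeding coefficients must lie in [0, 1)")
    x = np.array(ys, dtype=np.float64) / generation_interval
    y = np.log1p(-F)
    if np.ptp(x) == 0 or np.allclose(y, y[0]):
        return 0.0
    beta = np.polyfit(x, y, 1)[0]
    return (1.0 - np.exp(beta)) * 100.0


def accuracy_and_bias(
    yearly_pairs: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, float]:
    """Mean accuracy and dispersion bias over the evaluation years.

    Each element of ``yearly_pairs`` holds ``(gebv, tbv)`` for the 3-year-old
    genotyped candidates of one evaluation year.  Accuracy is the Pearson
    correlation; bias is the slope of the regression of TBV on GEBV (< 1
    means over-dispersed, inflated predictions).  Years with fewer than two
    fish or zero GEBV variance are undefined and reported as NaN.
    """
    accs, slopes = [], []
    for gebv, tbv in yearly_pairs:
        gebv = np.asarray(gebv, dtype=np.float64)
        tbv = np.asarray(tbv, dtype=np.float64)
        if gebv.size < 2 or np.var(gebv) == 0 or np.var(tbv) == 0:
            accs.append(np.nan)
            slopes.append(np.nan)
            continue
        vg = np.var(gebv)
        cov = np.mean((gebv - gebv.mean()) * (tbv - tbv.mean()))
        accs.append(cov / np.sqrt(vg * np.var(tbv)))
        slopes.append(cov / vg)
    if np.all(np.isnan(accs)):
        return float("nan"), float("nan")
    return float(np.nanmean(accs)), float(np.nanmean(slopes))


@dataclass
class MetricsReport:
    """Replicate mean and standard error of every outcome measure."""

    mean: pd.Series
    se: pd.Series
    n_replicates: int
    per_replicate: pd.DataFrame

    @property
    def gain_per_percent_inbreeding(self) -> float:
        return float(self.mean["delta_G"] / self.mean["delta_F_percent"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "se": self.se})


def summarize_replicates(per_replicate: pd.DataFrame) -> MetricsReport:
    """Mean and SE (= sample SD / sqrt(R)) over replicate rows."""
    if len(per_replicate) < 2:
        raise ValueError("need at least two replicates to summarize")
    numeric = per_replicate.select_dtypes(include=[np.number])
    mean = numeric.mean()
    se = numeric.std(ddof=1) / np.sqrt(len(numeric))
    return MetricsReport(mean=mean, se=se, n_replicates=len(numeric), per_replicate=per_replicate)
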