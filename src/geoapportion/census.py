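"""Producer fraction of the total bacterial population and group comparisons.

The producer census divides functional-gene copies by total-16S copies,
assuming one gene copy per producer cell and one 16S copy per cell by
default (both correction factors are exposed as parameters).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SectionComparison:
    """One-way ANOVA with Tukey HSD across intestinal sections."""

    group_means: tuple[float, ...]
    f_statistic: float
    p_value: float
    tukey_pairs: dict[tuple[int, int], float]


def producer_fraction(
    geoa: float,
    total16s: float,
    *,
    geoa_per_cell: float = 1.0,
    s16_per_cell: float = 1.0,
) -> float:
    """Percent of cells carrying the producer gene.

    ``100 * (geoa / geoa_per_cell) / (total16s / s16_per_cell)``.
    Zero total with zero gene copies gives 0%; zero total with positive
    gene copies is undefined and returns NaN.
    """
    if geoa < 0 or total16s < 0:
        raise ValueError("copy numbers must be non-negative")
    if geoa_per_cell <= 0 or s16_per_cell <= 0:
        raise ValueError("per-cell copy numbers must be positive")
    if total16s == 0:
        return 0.0 if geoa == 0 else float("nan")
    producers = geoa / geoa_per_cell
    cells = total16s / s16_per_cell
    return 100.0 * producers / cells


def compartment_summary(values: Sequence[float]) -> dict:
    """Mean, 10/25/75/90th percentiles and outliers for one group of samples.

    Percentiles use inclusive linear interpolation; outliers are the
    points falling outside the 10th-90th percentile band.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    p10, p25, p75, p90 = np.percentile(arr, [10, 25, 75, 90], method="linear")
    outliers = arr[(arr < p10) | (arr > p90)]
    return {
        "mean": float(arr.mean()),
        "p10": float(p10),
        "p25": float(p25),
        "p75": float(p75),
        "p90": float(p90),
        "outliers": outliers.tolist(),
        "n": int(arr.size),
    }


def section_anova(groups: Sequence[Sequence[float]]) -> SectionComparison:
    """Classical one-way ANOVA plus Tukey HSD over intestinal sections.

    Every group needs at least two observations. With identical groups
    the F statistic is 0 and p is 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values; ANOVA degrees of freedom undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        f, p = stats.f_oneway(*arrays)
    # f_oneway returns nan for zero between- and within-group variance
    if not np.isfinite(f):
        if all(np.allclose(a, arrays[0][0]) for a in arrays):
            f, p = 0.0, 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        tukey = stats.tukey_hsd(*arrays)
    pairs: dict[tuple[int, int], float] = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            pairs[(i, j)] = float(tukey.pvalue[i, j])
    return SectionComparison(
        group_means=tuple(float(a.mean()) for a in arrays),
        f_statistic=float(f),
        p_value=float(p),
        tukey_pairs=pairs,
    )


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Returns ``(nan, nan)`` when either vector has zero variance.
    """
    if method != "pearson":
        raise ValueError(f"unsupported method {method!r}")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("inputs must be finite")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


def fraction_table(
    fractions: pd.DataFrame,
    *,
    farm_col: str = "farm",
    compartment_col: str = "compartment",
    value_col: str = "fraction_pct",
) -> pd.DataFrame:
    """Per farm x compartment min-max percent ranges (census summary table).

    Input is a tidy frame of per-sample producer fractions; the output
    has one row per farm and one ``"min-max"`` string column per
    compartment, mirroring the published range format.
    """
    def fmt(series: pd.Series) -> str:
        lo, hi = series.min(), series.max()
        return f"{lo:.3g}-{hi:.3g}%"

    wide = fractions.pivot_table(
        index=farm_col, columns=compartment_col, values=value_col, aggfunc=fmt
    )
    return wide.reset_index()
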