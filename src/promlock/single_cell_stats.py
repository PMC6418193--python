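"""Summary statistics and test conventions for single-cell RNA counts.

Conventions used throughout: squared coefficient of variation (CV^2) with
the sample (n-1) variance, 90% confidence intervals from a two-tailed
Student-t, and two-sample Kolmogorov-Smirnov comparisons with a 0.01
significance threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .transcription_model import ParameterError

__all__ = [
    "CountTable",
    "ConditionSummary",
    "KSResult",
    "summarize",
    "ks_compare",
    "fold_change",
    "relative_means",
]

COUNT_COLUMNS = ["cell_id", "condition", "time_min", "rna_count", "replicate"]


@dataclass(frozen=True)
class CountTable:
    """Cross-sectional single-cell integer RNA counts.

    Backed by a DataFrame with columns cell_id, condition, time_min,
    rna_count and (optional, defaulted) replicate.  Counts must be
    non-negative integers.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        required = {"cell_id", "condition", "time_min", "rna_count"}
        missing = required - set(df.columns)
        if missing:
            raise ParameterError(f"count table missing columns: {sorted(missing)}")
        if "replicate" not in df.columns:
            df["replicate"] = "r1"
        if len(df) == 0:
            raise ParameterError("count table is empty")
        counts = df["rna_count"].to_numpy()
        if not np.issubdtype(np.asarray(counts).dtype, np.integer):
            as_float = np.asarray(counts, dtype=float)
            if np.any(as_float != np.round(as_float)):
                raise ParameterError("rna_count values must be integers")
            counts = as_float.astype(np.int64)
        if np.any(counts < 0):
            raise ParameterError("rna_count values must be >= 0")
        df["rna_count"] = counts.astype(np.int64)
        df["time_min"] = df["time_min"].astype(float)
        object.__setattr__(self, "df", df[COUNT_COLUMNS].reset_index(drop=True))

    @property
    def conditions(self) -> list:
        return list(pd.unique(self.df["condition"]))

    def counts(self, condition, time_min: float | None = None) -> np.ndarray:
        sel = self.df["condition"] == condition
        if time_min is not None:
            sel &= self.df["time_min"] == float(time_min)
        return self.df.loc[sel, "rna_count"].to_numpy()


@dataclass(frozen=True)
class ConditionSummary:
    n_cells: int
    mean: float
    cv2: float  # NaN when the mean is zero (undefined)
    ci90: tuple[float, float]

    @property
    def cv2_defined(self) -> bool:
        return not math.isnan(self.cv2)


@dataclass(frozen=True)
class KSResult:
    d_stat: float
    p_value: float
    distinguishable: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_stat <= 1.0 and 0.0 <= self.p_value <= 1.0):
            raise ParameterError("KS statistic and p-value must lie in [0, 1]")
        if self.distinguishable != (self.p_value < 0.01):
            raise ParameterError("distinguishable flag inconsistent with p < 0.01")


def summarize(counts) -> ConditionSummary:
    """Mean, CV^2 (sample variance over mean squared) and 90% t-CI."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("summarize requires at least 2 observations")
    n = x.size
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    cv2 = var / mean**2 if mean != 0 else math.nan
    sem = math.sqrt(var / n)
    halfwidth = float(stats.t.ppf(0.95, df=n - 1)) * sem
    return ConditionSummary(
        n_cells=n, mean=mean, cv2=cv2, ci90=(mean - halfwidth, mean + halfwidth)
    )


def ks_compare(a, b, alpha: float = 0.01, method: str = "auto") -> KSResult:
    """Two-sample KS test with the p < alpha distinguishability convention.

    ``method`` is "asymp", "exact" or "auto" (exact when both samples have
    fewer than 30 observations, asymptotic otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("ks_compare requires non-empty samples")
    if method == "auto":
        method = "exact" if max(a.size, b.size) < 30 else "asymp"
    if method not in ("exact", "asymp"):
        raise ParameterError(f"unknown KS method {method!r}")
    res = stats.ks_2samp(a, b, method=method)
    p = min(float(res.pvalue), 1.0)
    return KSResult(d_stat=float(res.statistic), p_value=p,
                    distinguishable=p < alpha)


def fold_change(induction: dict) -> float:
    """Mean count at the maximal dose divided by the mean at zero dose."""
    if len(induction) < 2:
        raise ParameterError("fold_change requires at least 2 doses")
    doses = sorted(induction)
    if doses[0] != 0:
        raise ParameterError("fold_change requires a zero-dose condition")
    base = float(np.mean(induction[doses[0]]))
    top = float(np.mean(induction[doses[-1]]))
    if base == 0:
        raise ParameterError("zero-dose mean is zero; fold change undefined")
    return top / base


def relative_means(table: CountTable, reference_condition) -> pd.DataFrame:
    """Per-condition mean and 90% CI divided by the reference-condition mean.

    Rows are pooled across time points and replicates within a condition.
    Returns a DataFrame indexed by condition with columns rel_mean,
    ci90_lo, ci90_hi.
    """
    if reference_condition not in table.conditions:
        raise ParameterError(
            f"reference condition {reference_condition!r} not present"
        )
    ref_mean = float(np.mean(table.counts(reference_condition)))
    if ref_mean <= 0:
        raise ParameterError("reference mean must be > 0")
    rows = {}
    for cond in table.conditions:
        s = summarize(table.counts(cond))
        rows[cond] = {
            "rel_mean": s.mean / ref_mean,
            "ci90_lo": s.ci90[0] / ref_mean,
            "ci90_hi": s.ci90[1] / ref_mean,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "condition"
    return out
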