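"""Cohort-level screening, descriptives, and rank correlations.

Participants are screened with a robust outlier rule: a participant is
excluded when, for any screened variable, their value falls more than
k MADs (median absolute deviation, scaled by the 1.4826 normal-
consistency constant by default, as in R's ``mad()``) from the cohort
median.  The cut is strict
(|deviation| exactly equal to k*MAD is retained), computed in a single
pass on the full cohort, and cohort-wide: a participant flagged on any
variable is dropped from all analyses, with the triggering variables
recorded.

The perception-production analysis itself is three Spearman rank
correlations of labeling consistency against each production measure;
p-values are two-sided via the t approximation with n-2 degrees of
freedom and reported unadjusted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .config import MEASURE_COLUMNS, AnalysisConfig, DEFAULT_MAD_VARIABLES
from .errors import DegenerateDataError, SampleSizeError, SchemaError
from .types import CorrelationResult

__all__ = ["normality_test", "MADScreen", "mad_outlier_filter",
           "descriptive_stats", "spearman", "run_correlation_suite",
           "CORRELATION_PAIRS"]

#: The three tested pairs: labeling consistency against each production measure.
CORRELATION_PAIRS = (
    ("labeling_consistency", "log_contrast_distance"),
    ("labeling_consistency", "log_ellipse_area"),
    ("labeling_consistency", "centering_ratio"),
)


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test: returns (W, p)."""
    x = np.asarray(values, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise SampleSizeError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample; normality test undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


class MADScreen(BaseEstimator):
    """Median-absolute-deviation outlier screen over participant measures.

    ``fit(X)`` computes per-variable medians and MADs on the full cohort;
    ``screen(X)`` returns the cohort table with ``included`` and
    ``exclusion_reasons`` columns.  A transformer-style ``transform``
    returns only the included rows.

    Parameters
    ----------
    variables : tuple of str
        Measures screened (default: boundary width, log contrast
        distance, log ellipse area).
    k : float
        Cut in MAD units (default 2).
    consistency_constant : float
        Multiplier on the raw MAD; the default 1.4826 rescales to a
        normal SD (R's ``mad()`` convention), 1.0 uses the raw MAD.

    Attributes
    ----------
    median_ : dict variable -> cohort median
    mad_ : dict variable -> (scaled) MAD
    """

    def __init__(self, variables: tuple[str, ...] = DEFAULT_MAD_VARIABLES,
                 k: float = 2.0, consistency_constant: float = 1.4826):
        self.variables = variables
        self.k = k
        self.consistency_constant = consistency_constant

    def fit(self, X: pd.DataFrame, y=None):
        missing = [v for v in self.variables if v not in X.columns]
        if missing:
            raise SchemaError(f"measures table missing screened variable(s) {missing}")
        self.median_, self.mad_ = {}, {}
        for v in self.variables:
            vals = X[v].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)):
                raise DegenerateDataError(f"non-finite values in screened variable {v!r}")
            med = float(np.median(vals))
            mad = float(np.median(np.abs(vals - med))) * self.consistency_constant
            if mad == 0 and len(self.variables) > 0:
                raise DegenerateDataError(
                    f"MAD of variable {v!r} is zero; outlier cut undefined")
            self.median_[v] = med
            self.mad_[v] = mad
        return self

    def screen(self, X: pd.DataFrame) -> pd.DataFrame:
        """Annotate the cohort with inclusion flags and per-variable reasons."""
        if not hasattr(self, "median_"):
            raise RuntimeError("MADScreen is not fitted")
        out = X.copy()
        reasons = [[] for _ in range(len(out))]
        for v in self.variables:
            dev = np.abs(out[v].to_numpy(dtype=float) - self.median_[v])
            flag = dev > self.k * self.mad_[v]  # strict: exactly k MADs is retained
            for i in np.flatnonzero(flag):
                reasons[i].append(v)
        out["included"] = [not r for r in reasons]
        out["exclusion_reasons"] = [";".join(r) for r in reasons]
        return out

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        scr = self.screen(X)
        return scr.loc[scr["included"], X.columns]


def mad_outlier_filter(table: pd.DataFrame,
                       variables: tuple[str, ...] = DEFAULT_MAD_VARIABLES,
                       k: float = 2.0,
                       consistency_constant: float = 1.4826) -> pd.DataFrame:
    """Single-pass MAD screen; returns the annotated cohort table.

    An empty ``variables`` list leaves the table unchanged apart from
    the (all-True) inclusion flag.
    """
    if len(variables) == 0:
        out = table.copy()
        out["included"] = True
        out["exclusion_reasons"] = ""
        return out
    return MADScreen(variables=variables, k=k,
                     consistency_constant=consistency_constant).fit(table).screen(table)


def descriptive_stats(table: pd.DataFrame,
                      measures: tuple[str, ...] = MEASURE_COLUMNS) -> pd.DataFrame:
    """Mean, SD (n-1), min and max per measure over included participants."""
    if "included" in table.columns:
        table = table.loc[table["included"]]
    if len(table) < 2:
        raise SampleSizeError("need at least 2 included participants for descriptives")
    rows = []
    for m in measures:
        vals = table[m].to_numpy(dtype=float)
        rows.append({"measure": m, "mean": vals.mean(), "sd": vals.std(ddof=1),
                     "min": vals.min(), "max": vals.max()})
    return pd.DataFrame(rows).set_index("measure")


def spearman(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on ties);
    p uses the t statistic with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise SampleSizeError(f"need at least 4 pairs for a correlation, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant vector; rank correlation undefined")
    res = stats.spearmanr(x, y)
    return CorrelationResult(var_x=var_x, var_y=var_y,
                             rho=float(res.statistic), n=n,
                             p_value=float(res.pvalue))


def run_correlation_suite(table: pd.DataFrame) -> list[CorrelationResult]:
    """The three perception-production correlations on a screened cohort."""
    if "included" in table.columns:
        table = table.loc[table["included"]]
    results = []
    for vx, vy in CORRELATION_PAIRS:
        results.append(spearman(table[vx], table[vy], vx, vy))
    return results


def correlations_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "var_x": r.var_x, "var_y": r.var_y, "rho": r.rho,
        "df": r.df, "n": r.n, "p_value": r.p_value,
    } for r in results])


def normality_report(table: pd.DataFrame,
                     measures: tuple[str, ...] = MEASURE_COLUMNS) -> pd.DataFrame:
    """Shapiro-Wilk W and p for each measure over the full cohort."""
    rows = []
    for m in measures:
        w, p = normality_test(table[m].to_numpy(dtype=float))
        rows.append({"measure": m, "W": w, "p_value": p})
    return pd.DataFrame(rows).set_index("measure")
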