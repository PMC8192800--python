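"""Per-participant acoustic production measures.

Three measures summarise a participant's productions of the two vowels
in (F1, F2) mel space:

* **Vowel contrast distance** — the Euclidean distance between the two
  vowels' mean midpoint formants, natural-log-transformed.  Larger =
  more distinct categories.
* **Area of the ellipse** — the area of the 95 % coverage ellipse of a
  vowel's repeated midpoint tokens, pi * q * sqrt(det S) with S the
  sample covariance (n-1 denominator) and q the chi-square(2) quantile
  at the coverage level (5.991 at 0.95).  The per-participant measure is
  the natural log of the mean of the two per-vowel areas.  Larger =
  more trial-to-trial variability.
* **Centering ratio** — within-utterance self-correction.  Per token,
  d_init is the Euclidean distance of the onset-window formants from the
  per-vowel medians of onset formants, d_mid the analogue at midpoint,
  and centering = d_init - d_mid.  Per vowel the mean centering is
  normalised by the mean initial distance (equivalently, ratio = 1 -
  mean(d_mid)/mean(d_init)); the final measure averages the two vowels.
  1 = complete correction to the median, 0 = none, negative = outward
  drift.

Centering deliberately uses medians where the centroid and ellipse
measures use means; the asymmetry is part of the measure definitions.
Excluded tokens are dropped before any statistic.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .errors import DegenerateDataError, SampleSizeError
from .types import VOWELS, VowelSummary

__all__ = ["contrast_distance", "ellipse_area", "mean_log_ellipse_area",
           "token_centering", "centering_ratio", "vowel_summary",
           "ProductionProfile", "coverage_quantile"]

_MIN_TOKENS_COV = 3


def coverage_quantile(coverage: float = 0.95) -> float:
    """chi-square(2 df) quantile scaling the coverage ellipse (5.991 at 0.95)."""
    if not 0 < coverage < 1:
        raise ValueError(f"coverage must lie in (0, 1), got {coverage}")
    return float(chi2.ppf(coverage, df=2))


def _valid(tokens: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in tokens.columns:
        return tokens.loc[~tokens["excluded"].astype(bool)]
    return tokens


def _vowel_xy(tokens: pd.DataFrame, vowel: str, which: str = "mid") -> np.ndarray:
    sub = tokens.loc[tokens["vowel"] == vowel]
    return sub[[f"f1_{which}", f"f2_{which}"]].to_numpy(dtype=float)


def contrast_distance(tokens: pd.DataFrame) -> float:
    """Log Euclidean distance between the vowels' mean midpoint formants."""
    tokens = _valid(tokens)
    centroids = {}
    for v in VOWELS:
        xy = _vowel_xy(tokens, v)
        if len(xy) < 1:
            raise SampleSizeError(f"no non-excluded tokens for vowel {v}")
        centroids[v] = xy.mean(axis=0)
    dist = float(np.linalg.norm(centroids["EH"] - centroids["AE"]))
    if dist <= 0:
        raise DegenerateDataError("vowel centroids coincide; log distance undefined")
    return math.log(dist)


def ellipse_area(xy: np.ndarray | pd.DataFrame, coverage: float = 0.95) -> float:
    """Area (mel^2) of the coverage ellipse of one vowel's midpoint tokens."""
    if isinstance(xy, pd.DataFrame):
        xy = _vowel_xy(_valid(xy), xy["vowel"].iloc[0]) if "vowel" in xy.columns \
            else xy.to_numpy(dtype=float)
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (f1, f2) values")
    n = len(xy)
    if n < _MIN_TOKENS_COV:
        raise SampleSizeError(f"need at least {_MIN_TOKENS_COV} tokens for a covariance, got {n}")
    S = np.cov(xy, rowvar=False, ddof=1)
    det = float(np.linalg.det(S))
    scale = float(np.trace(S))
    if det <= 0 or (scale > 0 and det < 1e-12 * scale**2):
        raise DegenerateDataError("singular token covariance; ellipse undefined")
    return math.pi * coverage_quantile(coverage) * math.sqrt(det)


def mean_log_ellipse_area(tokens: pd.DataFrame, coverage: float = 0.95) -> float:
    """Natural log of the mean of the two per-vowel ellipse areas."""
    tokens = _valid(tokens)
    areas = [ellipse_area(_vowel_xy(tokens, v), coverage) for v in VOWELS]
    return math.log(0.5 * (areas[0] + areas[1]))


def token_centering(f_init: np.ndarray, f_mid: np.ndarray,
                    median_init: np.ndarray, median_mid: np.ndarray):
    """Per-token (d_init, d_mid, centering) against supplied medians.

    Vectorised: ``f_init``/``f_mid`` are (n, 2) arrays of (f1, f2);
    medians are length-2.  centering = d_init - d_mid is positive when a
    token moved toward the median between onset and midpoint.
    """
    f_init = np.atleast_2d(np.asarray(f_init, dtype=float))
    f_mid = np.atleast_2d(np.asarray(f_mid, dtype=float))
    d_init = np.linalg.norm(f_init - np.asarray(median_init, dtype=float), axis=1)
    d_mid = np.linalg.norm(f_mid - np.asarray(median_mid, dtype=float), axis=1)
    return d_init, d_mid, d_init - d_mid


def vowel_summary(tokens: pd.DataFrame, vowel: str, coverage: float = 0.95,
                  medians: tuple | None = None) -> VowelSummary:
    """Full per-vowel summary: centroid, covariance, ellipse, centering.

    ``medians`` optionally supplies (median_init, median_mid) reference
    points (each length-2) in place of the sample medians — used by
    generator-recovery checks where the true centers are known.
    """
    tokens = _valid(tokens)
    init = _vowel_xy(tokens, vowel, "init")
    mid = _vowel_xy(tokens, vowel, "mid")
    n = len(mid)
    if n < _MIN_TOKENS_COV:
        raise SampleSizeError(
            f"need at least {_MIN_TOKENS_COV} non-excluded tokens for vowel {vowel}, got {n}")
    if medians is None:
        median_init = np.median(init, axis=0)
        median_mid = np.median(mid, axis=0)
    else:
        median_init = np.asarray(medians[0], dtype=float)
        median_mid = np.asarray(medians[1], dtype=float)
    d_init, d_mid, cent = token_centering(init, mid, median_init, median_mid)
    mean_d_init = float(d_init.mean())
    if mean_d_init <= 0:
        raise DegenerateDataError(
            f"mean initial distance is zero for vowel {vowel}; centering ratio undefined")
    ratio = 1.0 - float(d_mid.mean()) / mean_d_init
    try:
        area = ellipse_area(mid, coverage)
    except DegenerateDataError:
        area = float("nan")  # centering is still defined; area is not
    return VowelSummary(
        vowel=vowel, n_tokens=n,
        centroid_mid=tuple(mid.mean(axis=0)),
        cov_mid=np.cov(mid, rowvar=False, ddof=1),
        ellipse_area=area,
        median_init=tuple(median_init), median_mid=tuple(median_mid),
        mean_d_init=mean_d_init, mean_d_mid=float(d_mid.mean()),
        mean_centering=float(cent.mean()),
        centering_ratio_vowel=ratio)


def centering_ratio(tokens: pd.DataFrame, medians: dict | None = None) -> float:
    """Participant-level centering ratio, averaged over the two vowels.

    ``medians`` optionally maps vowel -> (median_init, median_mid) to
    supply known true centers instead of sample medians.
    """
    ratios = []
    for v in VOWELS:
        med = medians.get(v) if medians else None
        ratios.append(vowel_summary(tokens, v, medians=med).centering_ratio_vowel)
    return 0.5 * (ratios[0] + ratios[1])


class ProductionProfile(BaseEstimator):
    """Participant-level production measures as a fitted estimator.

    ``fit(X)`` takes one participant's production token table (DataFrame
    with the production columns) and computes the three measures.

    Parameters
    ----------
    coverage : float
        Coverage probability of the dispersion ellipse (default 0.95).

    Attributes
    ----------
    log_contrast_distance_ : float
    ellipse_areas_ : dict vowel -> area (mel^2)
    log_ellipse_area_ : float
        Natural log of the mean of the two areas.
    centering_ratio_ : float
    summaries_ : dict vowel -> VowelSummary
    n_tokens_ : dict vowel -> non-excluded token count
    n_excluded_ : int
    """

    def __init__(self, coverage: float = 0.95):
        self.coverage = coverage

    def fit(self, X: pd.DataFrame, y=None):
        tokens = X
        self.n_excluded_ = int(tokens["excluded"].sum()) if "excluded" in tokens.columns else 0
        valid = _valid(tokens)
        self.summaries_ = {v: vowel_summary(valid, v, self.coverage) for v in VOWELS}
        self.n_tokens_ = {v: self.summaries_[v].n_tokens for v in VOWELS}
        self.log_contrast_distance_ = contrast_distance(valid)
        # recompute areas directly so degenerate geometry raises here
        self.ellipse_areas_ = {v: ellipse_area(_vowel_xy(valid, v), self.coverage)
                               for v in VOWELS}
        self.log_ellipse_area_ = math.log(
            0.5 * sum(self.ellipse_areas_.values()))
        self.centering_ratio_ = 0.5 * sum(
            s.centering_ratio_vowel for s in self.summaries_.values())
        return self
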