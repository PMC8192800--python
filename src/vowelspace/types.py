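"""Core domain records.

Tabular data flow through the pipeline as pandas DataFrames with the
column contracts documented in :mod:`vowelspace.io`; the dataclasses here
are the typed per-record views and carry the field-level invariants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataValidationError, RangeError

#: The two vowel categories of the contrast, lax /ε/ ("head") and /æ/ ("had").
VOWELS = ("EH", "AE")

#: Identification-task response categories.
RESPONSES = ("HEAD", "HAD")


@dataclass(frozen=True)
class ProductionToken:
    """One vowel utterance, reduced to window-mean formants in mel."""

    participant_id: str
    vowel: str
    trial_index: int
    f1_init: float
    f2_init: float
    f1_mid: float
    f2_mid: float
    duration_ms: float
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.vowel not in VOWELS:
            raise DataValidationError(
                f"vowel must be one of {VOWELS}, got {self.vowel!r}")
        if self.trial_index < 1:
            raise DataValidationError(
                f"trial_index must be a positive integer, got {self.trial_index}")
        for name in ("f1_init", "f2_init", "f1_mid", "f2_mid"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise DataValidationError(
                    f"{name} must be a strictly positive finite formant value, got {v}")
        if not math.isfinite(self.duration_ms) or self.duration_ms < 0:
            raise DataValidationError(
                f"duration_ms must be nonnegative, got {self.duration_ms}")


@dataclass(frozen=True)
class FormantTrack:
    """Per-frame formant estimates in Hz for one utterance."""

    participant_id: str
    vowel: str
    trial_index: int
    frame_times_ms: tuple[float, ...]
    f1_hz: tuple[float, ...]
    f2_hz: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.vowel not in VOWELS:
            raise DataValidationError(
                f"vowel must be one of {VOWELS}, got {self.vowel!r}")
        t = np.asarray(self.frame_times_ms, dtype=float)
        if len(t) == 0:
            raise DataValidationError("track must contain at least one frame")
        if not (len(t) == len(self.f1_hz) == len(self.f2_hz)):
            raise DataValidationError("frame time and formant sequences must have equal lengths")
        if np.any(np.diff(t) <= 0):
            raise DataValidationError("frame_times_ms must be strictly increasing")

    @property
    def duration_ms(self) -> float:
        return float(self.frame_times_ms[-1])


@dataclass(frozen=True)
class IdentificationTrial:
    """One continuum-step labeling response."""

    participant_id: str
    step: int
    response: str

    def validate_step(self, n_steps: int) -> None:
        if not 1 <= self.step <= n_steps:
            raise RangeError(
                f"step {self.step} outside [1, {n_steps}] for participant {self.participant_id}")

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise DataValidationError(
                f"response must be one of {RESPONSES}, got {self.response!r}")
        if self.step < 1:
            raise RangeError(f"step must be >= 1, got {self.step}")


@dataclass(frozen=True)
class ParticipantMeasures:
    """The four participant-level variables of the analysis.

    ``labeling_consistency`` is the psychometric boundary width in
    continuum steps; ``log_contrast_distance`` is the natural log of the
    Euclidean distance in mel between the two vowels' midpoint centroids;
    ``log_ellipse_area`` is the natural log of the mean coverage-ellipse
    area in mel^2; ``centering_ratio`` is dimensionless.
    """

    participant_id: str
    labeling_consistency: float
    log_contrast_distance: float
    log_ellipse_area: float
    centering_ratio: float

    def __post_init__(self) -> None:
        for name in ("labeling_consistency", "log_contrast_distance",
                     "log_ellipse_area", "centering_ratio"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DataValidationError(
                    f"{name} must be finite, got {v} "
                    f"(participant {self.participant_id})")
        if self.labeling_consistency < 0:
            raise DataValidationError("labeling_consistency must be >= 0")
        if self.centering_ratio > 1 + 1e-12:
            raise DataValidationError("centering_ratio cannot exceed 1")


@dataclass(frozen=True)
class VowelSummary:
    """Per-vowel production summary for one participant."""

    vowel: str
    n_tokens: int
    centroid_mid: tuple[float, float]
    cov_mid: np.ndarray
    ellipse_area: float
    median_init: tuple[float, float]
    median_mid: tuple[float, float]
    mean_d_init: float
    mean_d_mid: float
    mean_centering: float
    centering_ratio_vowel: float


@dataclass(frozen=True)
class CorrelationResult:
    """A Spearman rank correlation between two participant measures."""

    var_x: str
    var_y: str
    rho: float
    n: int
    p_value: float

    @property
    def df(self) -> int:
        return self.n - 2
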