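"""Run-level analysis configuration.

Collects the fixed constants of the analysis — the two formant time
windows, the mel formula, ellipse coverage, MAD screening parameters and
the identification-task geometry — in one validated, serialisable object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

from .errors import ConfigError

#: Participant-level measures screened for outliers by default: boundary
#: width, log contrast distance and log ellipse area.  The centering ratio
#: is tested for normality but not screened.
DEFAULT_MAD_VARIABLES: tuple[str, ...] = (
    "labeling_consistency",
    "log_contrast_distance",
    "log_ellipse_area",
)

MEASURE_COLUMNS: tuple[str, ...] = (
    "labeling_consistency",
    "log_contrast_distance",
    "log_ellipse_area",
    "centering_ratio",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable constants of the analysis pipeline.

    Parameters
    ----------
    initial_window_ms : (float, float)
        Absolute time window at vowel onset, default 0-50 ms.
    midpoint_fraction : (float, float)
        Relative window as fractions of token duration, default the
        middle 50 % (0.25-0.75).
    mel_formula_id : str
        ``"htk2595"`` for 2595*log10(1 + f/700) or ``"ln1127"`` for
        1127*ln(1 + f/700) (the same curve up to floating point).
    ellipse_coverage : float
        Coverage probability of the token-dispersion ellipse, default 0.95.
    mad_k : float
        Outlier cut in MAD units, default 2.
    mad_consistency_constant : float
        Multiplier applied to the raw MAD; the default 1.4826 rescales
        the MAD to estimate a normal SD (the convention of R's ``mad()``,
        under which a 2-MAD cut is a 2-sigma cut); set 1.0 for the raw MAD.
    mad_variables : tuple of str
        Measures screened for outliers.
    n_steps : int
        Number of continuum steps in the identification task, default 11.
    reps_per_step : int
        Presentations of each step, default 20.
    overlap_duration_ms : float
        Mean-duration threshold below which a participant's tokens are
        reported as potentially window-overlapping, default 150 ms.
    rng_seed : int or None
        Seed for any stochastic stage (simulation only; the analysis
        itself is deterministic).
    """

    initial_window_ms: tuple[float, float] = (0.0, 50.0)
    midpoint_fraction: tuple[float, float] = (0.25, 0.75)
    mel_formula_id: str = "htk2595"
    ellipse_coverage: float = 0.95
    mad_k: float = 2.0
    mad_consistency_constant: float = 1.4826
    mad_variables: tuple[str, ...] = DEFAULT_MAD_VARIABLES
    n_steps: int = 11
    reps_per_step: int = 20
    overlap_duration_ms: float = 150.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.initial_window_ms
        if not 0 <= lo < hi:
            raise ConfigError(f"initial_window_ms must be well-ordered, got {self.initial_window_ms}")
        flo, fhi = self.midpoint_fraction
        if not 0 <= flo < fhi <= 1:
            raise ConfigError(f"midpoint_fraction must satisfy 0 <= lo < hi <= 1, got {self.midpoint_fraction}")
        if self.mel_formula_id not in ("htk2595", "ln1127"):
            raise ConfigError(f"unknown mel_formula_id: {self.mel_formula_id!r}")
        if not 0 < self.ellipse_coverage < 1:
            raise ConfigError(f"ellipse_coverage must lie in (0, 1), got {self.ellipse_coverage}")
        if self.mad_k <= 0:
            raise ConfigError(f"mad_k must be positive, got {self.mad_k}")
        if self.mad_consistency_constant <= 0:
            raise ConfigError("mad_consistency_constant must be positive")
        unknown = set(self.mad_variables) - set(MEASURE_COLUMNS)
        if unknown:
            raise ConfigError(f"unknown mad_variables: {sorted(unknown)}")
        if self.n_steps < 2:
            raise ConfigError("n_steps must be at least 2")
        if self.reps_per_step < 1:
            raise ConfigError("reps_per_step must be at least 1")
        if self.overlap_duration_ms <= 0:
            raise ConfigError("overlap_duration_ms must be positive")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["initial_window_ms"] = list(self.initial_window_ms)
        d["midpoint_fraction"] = list(self.midpoint_fraction)
        d["mad_variables"] = list(self.mad_variables)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("initial_window_ms", "midpoint_fraction", "mad_variables"):
            if key in d:
                d[key] = tuple(d[key])
        try:
            return cls(**d)
        except TypeError as exc:  # wrong type passed through
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            return cls()
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    def with_(self, **kwargs) -> "AnalysisConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
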