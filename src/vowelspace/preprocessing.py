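"""Mel conversion and time-window reduction of formant tracks.

Formant tracks arrive as per-frame (F1, F2) estimates in Hz.  The
analysis needs only two summaries per token, both in mel: the mean over
an absolute onset window (default 0-50 ms) and the mean over a window
covering the middle 50 % of the token's duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataValidationError, DegenerateDataError
from .types import FormantTrack

__all__ = ["hz_to_mel", "mel_to_hz", "WindowSpec", "window_average",
           "flag_window_overlap", "tracks_to_token_frame"]


def hz_to_mel(f, formula: str = "htk2595"):
    """Convert frequency in Hz to mel.

    ``"htk2595"`` uses 2595*log10(1 + f/700); ``"ln1127"`` uses
    1127*ln(1 + f/700).  The two differ only in floating-point rounding
    (1127 approximates 2595/ln 10 * ... exactly: 2595/log10(e) constant).
    Accepts scalars or arrays; negative input is a domain error.
    """
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0):
        raise DataValidationError("frequency must be nonnegative for mel conversion")
    if formula == "htk2595":
        out = 2595.0 * np.log10(1.0 + arr / 700.0)
    elif formula == "ln1127":
        out = 1127.0 * np.log1p(arr / 700.0)
    else:
        raise DataValidationError(f"unknown mel formula {formula!r}")
    return out if arr.ndim else float(out)


def mel_to_hz(m, formula: str = "htk2595"):
    """Inverse of :func:`hz_to_mel`."""
    arr = np.asarray(m, dtype=float)
    if np.any(arr < 0):
        raise DataValidationError("mel value must be nonnegative")
    if formula == "htk2595":
        out = 700.0 * (10.0 ** (arr / 2595.0) - 1.0)
    elif formula == "ln1127":
        out = 700.0 * np.expm1(arr / 1127.0)
    else:
        raise DataValidationError(f"unknown mel formula {formula!r}")
    return out if arr.ndim else float(out)


@dataclass(frozen=True)
class WindowSpec:
    """The two analysis windows.

    ``initial_ms`` is absolute (default [0, 50] ms from vowel onset);
    ``midpoint_fraction`` is relative to token duration d (default
    [0.25*d, 0.75*d]).  Membership uses closed intervals at both ends.
    """

    initial_ms: tuple[float, float] = (0.0, 50.0)
    midpoint_fraction: tuple[float, float] = (0.25, 0.75)

    def midpoint_ms(self, duration_ms: float) -> tuple[float, float]:
        lo, hi = self.midpoint_fraction
        return (lo * duration_ms, hi * duration_ms)


def window_average(track: FormantTrack, spec: WindowSpec = WindowSpec(),
                   mel_formula: str = "htk2595") -> tuple[float, float, float, float]:
    """Reduce a track to (f1_init, f2_init, f1_mid, f2_mid) in mel.

    Each value is the arithmetic mean of the mel-converted frames whose
    times fall inside the window (closed at both ends).  An empty window
    raises :class:`DegenerateDataError`; callers flag the token excluded.
    """
    t = np.asarray(track.frame_times_ms, dtype=float)
    f1 = hz_to_mel(np.asarray(track.f1_hz, dtype=float), mel_formula)
    f2 = hz_to_mel(np.asarray(track.f2_hz, dtype=float), mel_formula)

    means = []
    for name, (lo, hi) in (("initial", spec.initial_ms),
                           ("midpoint", spec.midpoint_ms(track.duration_ms))):
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            raise DegenerateDataError(
                f"no frames in the {name} window [{lo:g}, {hi:g}] ms for "
                f"participant {track.participant_id} {track.vowel} trial {track.trial_index}")
        means.append((float(f1[mask].mean()), float(f2[mask].mean())))
    (f1i, f2i), (f1m, f2m) = means
    return f1i, f2i, f1m, f2m


def flag_window_overlap(duration_ms: float, spec: WindowSpec = WindowSpec()) -> bool:
    """True iff the midpoint window starts before the initial window ends.

    With the default windows the midpoint window begins at 0.25*d, so
    overlap occurs geometrically for d < 200 ms.  The comparison is
    strict: a token whose midpoint window starts exactly at the initial
    window's end does not overlap.
    """
    if duration_ms <= 0:
        raise DataValidationError(f"duration must be positive, got {duration_ms}")
    mid_start = spec.midpoint_fraction[0] * duration_ms
    return mid_start < spec.initial_ms[1]


def tracks_to_token_frame(tracks, spec: WindowSpec = WindowSpec(),
                          mel_formula: str = "htk2595"):
    """Window-average a sequence of tracks into a production token table.

    Tokens whose windows cannot be averaged (no frames inside a window)
    are retained with ``excluded=True`` and NaN formants, mirroring how
    tracking failures are carried rather than dropped.
    """
    import pandas as pd

    rows = []
    for tr in tracks:
        row = {"participant_id": tr.participant_id, "vowel": tr.vowel,
               "trial_index": tr.trial_index, "duration_ms": tr.duration_ms}
        try:
            f1i, f2i, f1m, f2m = window_average(tr, spec, mel_formula)
            row.update(f1_init=f1i, f2_init=f2i, f1_mid=f1m, f2_mid=f2m, excluded=False)
        except DegenerateDataError:
            row.update(f1_init=np.nan, f2_init=np.nan, f1_mid=np.nan,
                       f2_mid=np.nan, excluded=True)
        rows.append(row)
    cols = ["participant_id", "vowel", "trial_index", "f1_init", "f2_init",
            "f1_mid", "f2_mid", "duration_ms", "excluded"]
    return pd.DataFrame(rows, columns=cols)
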