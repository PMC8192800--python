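"""Synthetic listeners and speakers with known ground truth.

The generator mirrors the study design it emulates: each participant
completes a production probe (45 tokens per vowel) and an identification
probe (an 11-step "head"-"had" continuum, 20 presentations per step).

* **Listeners** respond to step x with HEAD probability
  1/(1 + exp((x - x0_true)/s_true)): a logistic observer whose true
  boundary width is 2*s_true*ln 3.
* **Speakers** draw a per-token onset deviation delta ~ N(0, onset_cov)
  in (F1, F2) mel space; onset formants are onset_mean + delta and
  midpoint formants are onset_mean + (1 - g)*delta + eps with
  eps ~ N(0, mid_noise_cov).  The correction gain g in [0, 1] is the
  generative counterpart of vowel centering: in the noiseless limit the
  population centering ratio equals g.
* **Cohorts** couple listener width and speaker dispersion through a
  Gaussian copula on parameter ranks, enabling both null (coupling = 0)
  and power simulations.

Default parameter ranges are chosen so that a simulated cohort's four
measures span realistic adult-female ranges for the /ε/-/æ/ contrast
(see docs/methods.md); they are study conditions, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, DataValidationError
from .preprocessing import hz_to_mel, mel_to_hz
from .types import VOWELS, FormantTrack

__all__ = ["ContinuumDesign", "make_continuum_design", "ListenerParams",
           "VowelParams", "SpeakerParams", "CohortGroundTruth",
           "simulate_identification", "simulate_speaker", "simulate_tracks",
           "sample_cohort_truth", "simulate_cohort"]

#: Default continuum endpoints (Hz): a female-talker "head" and "had".
DEFAULT_ENDPOINTS = ((630.0, 2300.0), (830.0, 2080.0))


# --------------------------------------------------------------------
# continuum design


@dataclass(frozen=True)
class ContinuumDesign:
    """The identification continuum: per-step (F1, F2) in Hz."""

    steps_hz: tuple[tuple[float, float], ...]

    @property
    def n_steps(self) -> int:
        return len(self.steps_hz)

    def gaps_hz(self) -> np.ndarray:
        """Step-to-step Euclidean distances in Hz."""
        arr = np.asarray(self.steps_hz, dtype=float)
        return np.linalg.norm(np.diff(arr, axis=0), axis=1)


def make_continuum_design(endpoints=DEFAULT_ENDPOINTS, n_full: int = 41,
                          n_select: int = 11, seed: int | None = None) -> ContinuumDesign:
    """Select identification steps from a dense equally spaced continuum.

    A full grid of ``n_full`` equally spaced (F1, F2) points runs between
    the two endpoint vowels.  ``n_select`` steps are chosen so that the
    middle 50 % of the continuum — the region around the likely category
    boundary — is sampled more densely than the endpoint-adjacent
    quarters.  The selection is deterministic; ``seed`` is accepted for
    interface uniformity.
    """
    a = np.asarray(endpoints[0], dtype=float)
    b = np.asarray(endpoints[1], dtype=float)
    if np.allclose(a, b):
        raise ConfigError("continuum endpoints must be distinct")
    if n_select > n_full:
        raise ConfigError(f"cannot select {n_select} steps from a {n_full}-step grid")
    if n_select < 2:
        raise ConfigError("need at least 2 selected steps")

    grid = np.linspace(0.0, 1.0, n_full)
    if n_select == n_full:
        idx = np.arange(n_full)
    else:
        top = n_full - 1
        inner_lo, inner_hi = 0.25 * top, 0.75 * top
        n_inner = min(max(1, round(7 / 11 * n_select)), n_select - 2)
        inner = np.unique(np.round(np.linspace(inner_lo, inner_hi, n_inner)).astype(int))
        rem = n_select - len(inner)
        n_left = (rem + 1) // 2
        n_right = rem - n_left
        left = np.round(np.linspace(0, inner[0], n_left, endpoint=False)).astype(int)
        right = (top - np.round(np.linspace(0, top - inner[-1], n_right,
                                            endpoint=False)).astype(int))[::-1]
        idx = np.unique(np.concatenate([left, inner, right]))
        # fill any collisions from unused grid indices nearest the middle
        if len(idx) < n_select:
            unused = np.setdiff1d(np.arange(n_full), idx)
            order = np.argsort(np.abs(unused - top / 2), kind="stable")
            idx = np.sort(np.concatenate([idx, unused[order][:n_select - len(idx)]]))

    pts = tuple((float(f1), float(f2)) for f1, f2 in
                (a + grid[i] * (b - a) for i in idx))
    arr = np.asarray(pts)
    for dim in range(2):
        d = np.diff(arr[:, dim])
        if not (np.all(d >= 0) or np.all(d <= 0)):
            raise ConfigError("continuum formant values must be monotone")
    return ContinuumDesign(steps_hz=pts)


# --------------------------------------------------------------------
# parameter records


@dataclass(frozen=True)
class ListenerParams:
    """True psychometric parameters of one simulated listener."""

    x0_true: float
    s_true: float
    reps_per_step: int = 20
    n_steps: int = 11

    def __post_init__(self):
        if self.s_true <= 0:
            raise DataValidationError("s_true must be positive")
        if self.reps_per_step < 1:
            raise DataValidationError("reps_per_step must be >= 1")

    @property
    def width_true(self) -> float:
        return 2.0 * np.log(3.0) * self.s_true


def _check_psd(m, name):
    m = np.asarray(m, dtype=float)
    if m.shape != (2, 2) or not np.allclose(m, m.T):
        raise DataValidationError(f"{name} must be a symmetric 2x2 matrix")
    if np.min(np.linalg.eigvalsh(m)) < -1e-9:
        raise DataValidationError(f"{name} must be positive semidefinite")
    return m


@dataclass(frozen=True)
class VowelParams:
    """Generative parameters for one vowel of one speaker (mel units)."""

    onset_mean: tuple[float, float]
    onset_cov: np.ndarray
    gain: float
    mid_noise_cov: np.ndarray
    n_tokens: int = 45
    duration_mean_ms: float = 200.0
    duration_sd_ms: float = 25.0

    def __post_init__(self):
        _check_psd(self.onset_cov, "onset_cov")
        _check_psd(self.mid_noise_cov, "mid_noise_cov")
        if not 0.0 <= self.gain <= 1.0:
            raise DataValidationError(f"gain must lie in [0, 1], got {self.gain}")
        if self.n_tokens < 1:
            raise DataValidationError("n_tokens must be >= 1")


@dataclass(frozen=True)
class SpeakerParams:
    """Per-vowel generative parameters of one simulated speaker."""

    vowels: dict[str, VowelParams]

    def __post_init__(self):
        if set(self.vowels) != set(VOWELS):
            raise DataValidationError(f"speaker must define exactly the vowels {VOWELS}")


@dataclass(frozen=True)
class CohortGroundTruth:
    """A full simulated cohort: per-participant parameters plus metadata."""

    participants: tuple[str, ...]
    listeners: dict[str, ListenerParams]
    speakers: dict[str, SpeakerParams]
    coupling: float = 0.0
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not -1.0 <= self.coupling <= 1.0:
            raise DataValidationError("coupling must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in self.participants:
            li = self.listeners[pid]
            sp = self.speakers[pid]
            row = {"participant_id": pid, "x0_true": li.x0_true,
                   "s_true": li.s_true, "width_true": li.width_true,
                   "coupling": self.coupling, "seed": self.seed}
            for v in VOWELS:
                vp = sp.vowels[v]
                row[f"gain_{v}"] = vp.gain
                row[f"onset_sd_{v}"] = float(np.sqrt(np.trace(vp.onset_cov) / 2))
            rows.append(row)
        return pd.DataFrame(rows)


# --------------------------------------------------------------------
# simulation


def simulate_identification(listener: ListenerParams, participant_id: str = "P01",
                            seed=0) -> pd.DataFrame:
    """Simulate one listener's identification trials (shuffled order)."""
    rng = np.random.default_rng(seed)
    steps = np.repeat(np.arange(1, listener.n_steps + 1), listener.reps_per_step)
    z = (steps - listener.x0_true) / listener.s_true
    p_head = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
    head = rng.random(len(steps)) < p_head
    order = rng.permutation(len(steps))
    return pd.DataFrame({
        "participant_id": participant_id,
        "step": steps[order],
        "response": np.where(head[order], "HEAD", "HAD"),
    })


def simulate_speaker(speaker: SpeakerParams, participant_id: str = "P01",
                     seed=0) -> pd.DataFrame:
    """Simulate one speaker's production tokens (window means, mel)."""
    rng = np.random.default_rng(seed)
    frames = []
    for v in VOWELS:
        vp = speaker.vowels[v]
        n = vp.n_tokens
        mean = np.asarray(vp.onset_mean, dtype=float)
        delta = rng.multivariate_normal(np.zeros(2), vp.onset_cov, size=n,
                                        method="cholesky" if
                                        np.linalg.det(vp.onset_cov) > 0 else "svd")
        eps = rng.multivariate_normal(np.zeros(2), vp.mid_noise_cov, size=n,
                                      method="svd")
        init = mean + delta
        mid = mean + (1.0 - vp.gain) * delta + eps
        dur = rng.normal(vp.duration_mean_ms, vp.duration_sd_ms, size=n)
        dur = np.maximum(dur, 1.0)
        frames.append(pd.DataFrame({
            "participant_id": participant_id, "vowel": v,
            "trial_index": np.arange(1, n + 1),
            "f1_init": init[:, 0], "f2_init": init[:, 1],
            "f1_mid": mid[:, 0], "f2_mid": mid[:, 1],
            "duration_ms": dur, "excluded": False,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_tracks(speaker: SpeakerParams, participant_id: str = "P01",
                    seed=0, frame_step_ms: float = 5.0,
                    frame_noise_hz: float = 0.0) -> list[FormantTrack]:
    """Per-frame tracks matching :func:`simulate_speaker`'s window means.

    Each track holds the token's onset value (in mel) throughout the
    initial window [0, 50] ms, ramps linearly to the midpoint value at
    0.25*duration, and holds it through the rest of the token, so that
    noiseless window averaging recovers the generated window means
    exactly whenever the two windows do not overlap.  Optional Gaussian
    frame noise is added in Hz.  Exists to exercise the preprocessing
    stage, not to model real formant trajectories.
    """
    tokens = simulate_speaker(speaker, participant_id, seed)
    rng = np.random.default_rng([np.random.SeedSequence(seed).entropy % (2**31), 7])
    tracks = []
    for row in tokens.itertuples(index=False):
        d = row.duration_ms
        t = np.arange(0.0, d + 1e-9, frame_step_ms)
        t_a, t_b = 50.0, 0.25 * d
        mel_vals = []
        for fi, fm in ((row.f1_init, row.f1_mid), (row.f2_init, row.f2_mid)):
            if t_b > t_a:
                frac = np.clip((t - t_a) / (t_b - t_a), 0.0, 1.0)
            else:  # overlapping windows: step at the midpoint-window start
                frac = (t >= t_b).astype(float)
            mel_vals.append(fi + frac * (fm - fi))
        f1_hz = mel_to_hz(np.asarray(mel_vals[0]))
        f2_hz = mel_to_hz(np.asarray(mel_vals[1]))
        if frame_noise_hz > 0:
            f1_hz = np.maximum(f1_hz + rng.normal(0, frame_noise_hz, len(t)), 1.0)
            f2_hz = np.maximum(f2_hz + rng.normal(0, frame_noise_hz, len(t)), 1.0)
        tracks.append(FormantTrack(
            participant_id=row.participant_id, vowel=row.vowel,
            trial_index=int(row.trial_index),
            frame_times_ms=tuple(t), f1_hz=tuple(f1_hz), f2_hz=tuple(f2_hz)))
    return tracks


# --------------------------------------------------------------------
# cohort sampling

# study-like population defaults (mel unless noted); see docs/methods.md
_VOWEL_BASE_HZ = {"EH": (630.0, 2300.0), "AE": (830.0, 2080.0)}
_DURATION_MS = {"EH": (179.0, 25.0), "AE": (237.0, 30.0)}
_CENTROID_JITTER_MEL = 25.0
_S_LOGMEAN, _S_LOGSD = -0.1914, 0.285   # lognormal: mean ~0.86, SD ~0.25 steps
_S_CLIP = (0.3, 1.6)
_X0_MEAN, _X0_SD, _X0_CLIP = 6.0, 0.7, (3.0, 9.0)
_SIGMA_RANGE = (15.0, 30.0)             # per-token onset SD per formant
_GAIN_RANGE = (0.0, 0.3)
_MID_NOISE_FRAC = 0.35


def sample_cohort_truth(n_participants: int = 37, coupling: float = 0.0,
                        seed: int = 0, n_tokens: int = 45,
                        reps_per_step: int = 20, n_steps: int = 11) -> CohortGroundTruth:
    """Draw a cohort's ground-truth parameters.

    ``coupling`` is the rank (Spearman) correlation imposed between
    listener boundary width and speaker onset dispersion via a Gaussian
    copula (latent Pearson correlation 2*sin(pi*coupling/6)).
    """
    if not -1.0 <= coupling <= 1.0:
        raise ConfigError("coupling must lie in [-1, 1]")
    rng = np.random.default_rng([int(seed) % (2**31), 0x5EED])
    rho_latent = float(np.clip(2.0 * np.sin(np.pi * coupling / 6.0), -1.0, 1.0))
    cov = np.array([[1.0, rho_latent], [rho_latent, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n_participants, method="svd")
    u_disp = norm.cdf(z[:, 1])

    pad = max(2, len(str(n_participants)))
    pids = tuple(f"P{i + 1:0{pad}d}" for i in range(n_participants))
    listeners, speakers = {}, {}
    for i, pid in enumerate(pids):
        s_true = float(np.clip(np.exp(_S_LOGMEAN + _S_LOGSD * z[i, 0]), *_S_CLIP))
        x0 = float(np.clip(rng.normal(_X0_MEAN, _X0_SD), *_X0_CLIP))
        listeners[pid] = ListenerParams(x0_true=x0, s_true=s_true,
                                        reps_per_step=reps_per_step, n_steps=n_steps)
        sigma = _SIGMA_RANGE[0] + (_SIGMA_RANGE[1] - _SIGMA_RANGE[0]) * u_disp[i]
        gain = float(rng.uniform(*_GAIN_RANGE))
        vowels = {}
        for v in VOWELS:
            base = hz_to_mel(np.asarray(_VOWEL_BASE_HZ[v]))
            mean = base + rng.normal(0.0, _CENTROID_JITTER_MEL, size=2)
            sig_v = sigma * float(np.exp(rng.normal(0.0, 0.08)))
            dur_mean, dur_sd = _DURATION_MS[v]
            vowels[v] = VowelParams(
                onset_mean=(float(mean[0]), float(mean[1])),
                onset_cov=np.eye(2) * sig_v**2,
                gain=gain,
                mid_noise_cov=np.eye(2) * (_MID_NOISE_FRAC * sig_v)**2,
                n_tokens=n_tokens,
                duration_mean_ms=dur_mean, duration_sd_ms=dur_sd)
        speakers[pid] = SpeakerParams(vowels=vowels)
    return CohortGroundTruth(participants=pids, listeners=listeners,
                             speakers=speakers, coupling=coupling, seed=int(seed))


def simulate_cohort(truth: CohortGroundTruth):
    """Materialise a cohort into analysis-ready tables.

    Returns ``(production, identification, truth_table)`` DataFrames in
    the CSV schemas the readers consume.  Deterministic: the same truth
    (including its seed) yields identical tables.
    """
    prod_frames, ident_frames = [], []
    base = int(truth.seed) % (2**31)
    for i, pid in enumerate(truth.participants):
        prod_frames.append(simulate_speaker(
            truth.speakers[pid], pid, seed=[base, i, 1]))
        ident_frames.append(simulate_identification(
            truth.listeners[pid], pid, seed=[base, i, 2]))
    production = pd.concat(prod_frames, ignore_index=True)
    identification = pd.concat(ident_frames, ignore_index=True)
    return production, identification, truth.to_frame()
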