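"""Calibration simulations: parameter recovery and test size.

These routines run the pipeline's estimators over many simulated
participants or cohorts to measure statistical behaviour: boundary-width
recovery error, and the empirical type-I error of the three
perception-production correlation tests under a fully independent
(coupling = 0) generator.  They use the same generative model and the
same estimators as the main pipeline, but materialise participants as
arrays rather than CSV-shaped tables so that thousands of cohorts stay
cheap.
"""

from __future__ import annotations

import math

import numpy as np

from .cohort import CORRELATION_PAIRS, spearman
from .perception import PsychometricLogistic
from .production import ellipse_area, token_centering
from .simulate import sample_cohort_truth
from .types import VOWELS

__all__ = ["width_recovery", "measure_participant_arrays", "null_rejection_rates"]


def width_recovery(x0_true: float = 6.0, s_true: float = 0.6,
                   reps_per_step: int = 20, n_steps: int = 11,
                   n_seeds: int = 200, seed: int = 0) -> dict:
    """Monte-Carlo recovery of the boundary width for one listener type.

    Returns the mean and SD of the recovered width over ``n_seeds``
    simulated listeners plus the true width 2*s_true*ln 3.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 0xA11])
    steps = np.repeat(np.arange(1, n_steps + 1), reps_per_step).astype(float)
    p_head = 1.0 / (1.0 + np.exp((steps - x0_true) / s_true))
    widths = np.empty(n_seeds)
    est = PsychometricLogistic(n_steps=n_steps)
    for i in range(n_seeds):
        y = (rng.random(len(steps)) < p_head).astype(float)
        widths[i] = est.fit(steps, y).width_
    true_width = 2.0 * s_true * math.log(3.0)
    return {"width_true": true_width, "width_mean": float(widths.mean()),
            "width_sd": float(widths.std(ddof=1)),
            "rel_err": float(widths.mean() / true_width - 1.0)}


def measure_participant_arrays(listener, speaker, rng) -> dict:
    """One participant's four measures from array-level simulation.

    Runs the same estimators as the table pipeline (psychometric ML fit,
    coverage ellipse, median-referenced centering) on directly drawn
    arrays.
    """
    steps = np.repeat(np.arange(1, listener.n_steps + 1),
                      listener.reps_per_step).astype(float)
    p_head = 1.0 / (1.0 + np.exp((steps - listener.x0_true) / listener.s_true))
    y = (rng.random(len(steps)) < p_head).astype(float)
    if y.min() == y.max():  # degenerate responder; re-fit is impossible
        return {}
    width = PsychometricLogistic(n_steps=listener.n_steps).fit(steps, y).width_

    centroids, areas, ratios = {}, [], []
    for v in VOWELS:
        vp = speaker.vowels[v]
        mean = np.asarray(vp.onset_mean)
        L = np.linalg.cholesky(vp.onset_cov + 1e-12 * np.eye(2))
        Ln = np.linalg.cholesky(vp.mid_noise_cov + 1e-12 * np.eye(2))
        delta = rng.standard_normal((vp.n_tokens, 2)) @ L.T
        eps = rng.standard_normal((vp.n_tokens, 2)) @ Ln.T
        init = mean + delta
        mid = mean + (1.0 - vp.gain) * delta + eps
        centroids[v] = mid.mean(axis=0)
        areas.append(ellipse_area(mid))
        d_init, d_mid, _ = token_centering(
            init, mid, np.median(init, axis=0), np.median(mid, axis=0))
        ratios.append(1.0 - d_mid.mean() / d_init.mean())
    dist = float(np.linalg.norm(centroids["EH"] - centroids["AE"]))
    return {
        "labeling_consistency": width,
        "log_contrast_distance": math.log(dist),
        "log_ellipse_area": math.log(0.5 * sum(areas)),
        "centering_ratio": 0.5 * sum(ratios),
    }


def null_rejection_rates(n_cohorts: int = 2000, n_participants: int = 31,
                         alpha: float = 0.05, seed: int = 0) -> dict:
    """Empirical type-I error of the three correlation tests.

    Simulates ``n_cohorts`` independent cohorts with coupling = 0 (so
    perception and production parameters share no dependence), runs the
    full measure pipeline per participant and the three Spearman tests
    per cohort, and returns the fraction of cohorts with p < alpha for
    each tested pair.
    """
    rejections = {pair: 0 for pair in CORRELATION_PAIRS}
    n_done = 0
    base = int(seed) % (2**31)
    for c in range(n_cohorts):
        child = (base * 1000003 + c) % (2**31)
        truth = sample_cohort_truth(n_participants, coupling=0.0, seed=child)
        rng = np.random.default_rng([base, c, 0xDA7A])
        rows = [measure_participant_arrays(truth.listeners[pid],
                                           truth.speakers[pid], rng)
                for pid in truth.participants]
        rows = [r for r in rows if r]
        if len(rows) < 4:
            continue
        cols = {k: np.array([r[k] for r in rows]) for k in rows[0]}
        for vx, vy in CORRELATION_PAIRS:
            res = spearman(cols[vx], cols[vy], vx, vy)
            if res.p_value < alpha:
                rejections[(vx, vy)] += 1
        n_done += 1
    return {"n_cohorts": n_done, "alpha": alpha,
            "rates": {f"{vx}~{vy}": rejections[(vx, vy)] / n_done
                      for vx, vy in CORRELATION_PAIRS}}
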