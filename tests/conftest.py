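import numpy as np
import pandas as pd
import pytest

from vowelspace.config import AnalysisConfig
from vowelspace.simulate import (VowelParams, SpeakerParams,
                                 sample_cohort_truth, simulate_cohort)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-participant simulated cohort (tables + ground truth)."""
    truth = sample_cohort_truth(n_participants=8, coupling=0.0, seed=11)
    production, identification, truth_df = simulate_cohort(truth)
    return truth, production, identification, truth_df


def make_speaker(gain=0.0, sigma=20.0, noise_sd=0.0, n_tokens=45,
                 eh_mean=(740.0, 1640.0), ae_mean=(880.0, 1550.0)):
    """Speaker with isotropic onset dispersion and optional midpoint noise (mel)."""
    vowels = {}
    for v, mean, dur in (("EH", eh_mean, 179.0), ("AE", ae_mean, 237.0)):
        vowels[v] = VowelParams(
            onset_mean=mean, onset_cov=np.eye(2) * sigma**2, gain=gain,
            mid_noise_cov=np.eye(2) * noise_sd**2, n_tokens=n_tokens,
            duration_mean_ms=dur, duration_sd_ms=10.0)
    return SpeakerParams(vowels=vowels)


def tokens_frame(f_init, f_mid, vowel="EH", participant_id="P01", start_trial=1):
    """Build a production token frame from (n, 2) init/mid arrays."""
    f_init = np.atleast_2d(np.asarray(f_init, dtype=float))
    f_mid = np.atleast_2d(np.asarray(f_mid, dtype=float))
    n = len(f_init)
    return pd.DataFrame({
        "participant_id": participant_id, "vowel": vowel,
        "trial_index": np.arange(start_trial, start_trial + n),
        "f1_init": f_init[:, 0], "f2_init": f_init[:, 1],
        "f1_mid": f_mid[:, 0], "f2_mid": f_mid[:, 1],
        "duration_ms": 220.0, "excluded": False,
    })
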