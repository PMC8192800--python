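import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from vowelspace.errors import DegenerateDataError, SampleSizeError
from vowelspace.production import (ProductionProfile, centering_ratio,
                                   contrast_distance, coverage_quantile,
                                   ellipse_area, mean_log_ellipse_area,
                                   token_centering, vowel_summary)
from vowelspace.simulate import simulate_speaker

from conftest import make_speaker, tokens_frame

Q95 = float(chi2.ppf(0.95, 2))  # ~5.9915


def _whitened_cloud(n, rng, target_cov=None):
    """Points whose sample covariance is exactly target_cov (default I)."""
    x = rng.standard_normal((n, 2))
    x -= x.mean(axis=0)
    S = np.cov(x, rowvar=False, ddof=1)
    L = np.linalg.cholesky(S)
    x = x @ np.linalg.inv(L).T
    if target_cov is not None:
        x = x @ np.linalg.cholesky(target_cov).T
    return x


class TestContrastDistance:
    def test_hand_computed_centroid_distance(self):
        eh = tokens_frame([[700, 1800]], [[700, 1800]], vowel="EH")
        ae = tokens_frame([[800, 1700]], [[800, 1700]], vowel="AE")
        val = contrast_distance(pd.concat([eh, ae]))
        assert val == pytest.approx(math.log(math.hypot(100, 100)), abs=1e-9)
        assert val == pytest.approx(4.952, abs=1e-3)

    def test_identical_centroids_is_log_domain_error(self):
        eh = tokens_frame([[700, 1800]], [[700, 1800]], vowel="EH")
        ae = tokens_frame([[700, 1800]], [[700, 1800]], vowel="AE")
        with pytest.raises(DegenerateDataError):
            contrast_distance(pd.concat([eh, ae]))

    def test_missing_vowel_is_error(self):
        eh = tokens_frame([[700, 1800]], [[700, 1800]], vowel="EH")
        with pytest.raises(SampleSizeError):
            contrast_distance(eh)

    def test_excluded_tokens_do_not_move_centroids(self):
        eh = tokens_frame([[700, 1800], [700, 1800]], [[700, 1800], [700, 1800]], "EH")
        ae = tokens_frame([[800, 1700]], [[800, 1700]], "AE")
        spoiler = tokens_frame([[5000, 5000]], [[5000, 5000]], "EH", start_trial=10)
        spoiler["excluded"] = True
        a = contrast_distance(pd.concat([eh, ae]))
        b = contrast_distance(pd.concat([eh, ae, spoiler]))
        assert a == b


class TestEllipseArea:
    def test_identity_covariance_closed_form(self, rng=np.random.default_rng(5)):
        xy = _whitened_cloud(50, rng)
        assert ellipse_area(xy) == pytest.approx(math.pi * Q95, rel=1e-10)

    def test_diagonal_covariance_doubles_identity_area(self, rng=np.random.default_rng(6)):
        xy = _whitened_cloud(50, rng, target_cov=np.diag([4.0, 1.0]))
        assert ellipse_area(xy) == pytest.approx(2 * math.pi * Q95, rel=1e-10)

    def test_identical_tokens_degenerate(self):
        with pytest.raises(DegenerateDataError):
            ellipse_area(np.tile([700.0, 1800.0], (5, 1)))

    def test_too_few_tokens(self):
        with pytest.raises(SampleSizeError):
            ellipse_area(np.array([[1.0, 2.0], [3.0, 4.0]]))

    def test_coverage_quantile_value(self):
        assert coverage_quantile(0.95) == pytest.approx(5.991, abs=1e-3)

    def test_mean_log_area_of_two_known_areas(self, rng=np.random.default_rng(7)):
        # per-vowel areas 10 and 30 -> log 20
        frames = []
        for vowel, area in (("EH", 10.0), ("AE", 30.0)):
            scale = area / (math.pi * Q95)
            xy = _whitened_cloud(40, rng, target_cov=np.eye(2) * scale)
            xy += np.array([700.0, 1800.0])
            frames.append(tokens_frame(xy, xy, vowel))
        val = mean_log_ellipse_area(pd.concat(frames))
        assert val == pytest.approx(math.log(20.0), abs=1e-9)

    def test_empirical_coverage_of_95_percent_ellipse(self):
        rng = np.random.default_rng(42)
        cov = np.array([[9.0, 2.0], [2.0, 4.0]])
        xy = rng.multivariate_normal([0, 0], cov, size=10_000)
        S = np.cov(xy, rowvar=False, ddof=1)
        d2 = np.einsum("ij,jk,ik->i", xy - xy.mean(0), np.linalg.inv(S),
                       xy - xy.mean(0))
        assert np.mean(d2 <= Q95) == pytest.approx(0.95, abs=0.01)


class TestCentering:
    def test_token_at_both_medians_is_zero(self):
        d_i, d_m, c = token_centering([[700, 1800]], [[710, 1790]],
                                      [700, 1800], [710, 1790])
        assert (d_i[0], d_m[0], c[0]) == (0.0, 0.0, 0.0)

    def test_three_four_five_inward(self):
        d_i, d_m, c = token_centering([[703, 1804]], [[710, 1790]],
                                      [700, 1800], [710, 1790])
        assert (d_i[0], d_m[0], c[0]) == (5.0, 0.0, 5.0)

    def test_outward_drift_is_negative(self):
        d_i, d_m, c = token_centering([[700, 1800]], [[713, 1794]],
                                      [700, 1800], [710, 1790])
        assert c[0] == -5.0

    def test_no_within_trial_change_gives_zero_ratio(self):
        rng = np.random.default_rng(8)
        frames = []
        for v, mean in (("EH", [700, 1800]), ("AE", [850, 1650])):
            init = mean + rng.normal(0, 20, (10, 2))
            frames.append(tokens_frame(init, init, v))
        assert centering_ratio(pd.concat(frames)) == pytest.approx(0.0, abs=1e-12)

    def test_full_correction_gives_ratio_one(self):
        rng = np.random.default_rng(9)
        frames = []
        for v, mean in (("EH", [700.0, 1800.0]), ("AE", [850.0, 1650.0])):
            init = mean + rng.normal(0, 20, (10, 2))
            mid = np.tile(mean, (10, 1))
            frames.append(tokens_frame(init, mid, v))
        assert centering_ratio(pd.concat(frames)) == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_gain_exact_with_true_centers(self):
        g = 0.5
        speaker = make_speaker(gain=g, sigma=20.0, noise_sd=0.0)
        tokens = simulate_speaker(speaker, seed=4)
        medians = {v: (speaker.vowels[v].onset_mean, speaker.vowels[v].onset_mean)
                   for v in ("EH", "AE")}
        assert centering_ratio(tokens, medians=medians) == pytest.approx(g, abs=1e-12)

    def test_ratio_never_exceeds_one(self):
        rng = np.random.default_rng(10)
        for trial in range(20):
            frames = []
            for v in ("EH", "AE"):
                init = 1000 + rng.normal(0, 30, (8, 2))
                mid = 1000 + rng.normal(0, 30, (8, 2))
                frames.append(tokens_frame(init, mid, v))
            assert centering_ratio(pd.concat(frames)) <= 1.0


class TestInvariances:
    def _profile(self, tokens):
        return ProductionProfile().fit(tokens)

    def test_translation_invariance(self):
        speaker = make_speaker(gain=0.2, sigma=18.0, noise_sd=5.0)
        tokens = simulate_speaker(speaker, seed=21)
        shifted = tokens.copy()
        for c in ("f1_init", "f2_init", "f1_mid", "f2_mid"):
            shifted[c] = shifted[c] + 123.0
        a, b = self._profile(tokens), self._profile(shifted)
        assert b.log_contrast_distance_ == pytest.approx(a.log_contrast_distance_, rel=1e-12)
        assert b.log_ellipse_area_ == pytest.approx(a.log_ellipse_area_, rel=1e-12)
        assert b.centering_ratio_ == pytest.approx(a.centering_ratio_, rel=1e-9)

    def test_rotation_invariance_of_centering(self):
        rng = np.random.default_rng(13)
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        center = np.array([900.0, 1500.0])
        init = center + rng.normal(0, 25, (15, 2))
        mid = center + 0.6 * (init - center) + rng.normal(0, 3, (15, 2))
        d_i, d_m, c = token_centering(init, mid, center, center)
        init_r = center + (init - center) @ R.T
        mid_r = center + (mid - center) @ R.T
        d_i2, d_m2, c2 = token_centering(init_r, mid_r, center, center)
        np.testing.assert_allclose(c2, c, rtol=1e-10)

    def test_profile_counts_excluded_tokens(self):
        speaker = make_speaker(sigma=15.0, n_tokens=10)
        tokens = simulate_speaker(speaker, seed=3)
        tokens.loc[tokens.index[:2], "excluded"] = True
        prof = self._profile(tokens)
        assert prof.n_excluded_ == 2
        assert sum(prof.n_tokens_.values()) == len(tokens) - 2

    def test_vowel_summary_mean_centering_identity(self):
        speaker = make_speaker(gain=0.3, sigma=20.0, noise_sd=4.0)
        tokens = simulate_speaker(speaker, seed=6)
        s = vowel_summary(tokens, "EH")
        assert s.mean_centering == pytest.approx(s.mean_d_init - s.mean_d_mid, abs=1e-12)
        assert s.centering_ratio_vowel <= 1.0
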