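import numpy as np
import pandas as pd
import pytest

from vowelspace.cohort import (MADScreen, descriptive_stats,
                               mad_outlier_filter, normality_report,
                               normality_test, run_correlation_suite,
                               spearman)
from vowelspace.errors import (DegenerateDataError, SampleSizeError,
                               SchemaError)

# frozen 20-value fixture; reference W and p computed independently with
# R 4.3.3 shapiro.test (agreement observed to ~1e-10)
SW_FIXTURE = [4.9104, 5.188, 5.0197, 4.2503, 4.9992, 5.0639, 5.2135,
              5.0691, 5.2451, 4.4516, 5.2479, 5.1086, 5.3754, 5.042,
              5.3907, 4.4103, 5.0181, 5.0731, 4.7971, 5.4088]
SW_W_REF, SW_P_REF = 0.8731316083, 0.0133424603


def _cohort(values, var="log_contrast_distance"):
    df = pd.DataFrame({"participant_id": [f"P{i:02d}" for i in range(len(values))],
                       var: values})
    return df, var


class TestNormality:
    def test_matches_reference_implementation(self):
        w, p = normality_test(SW_FIXTURE)
        assert w == pytest.approx(SW_W_REF, abs=1e-6)
        assert p == pytest.approx(SW_P_REF, abs=1e-6)

    def test_constant_sequence_degenerate(self):
        with pytest.raises(DegenerateDataError):
            normality_test([5.0] * 10)

    def test_sample_size_limits(self):
        with pytest.raises(SampleSizeError):
            normality_test([1.0, 2.0])

    def test_heavy_tails_are_detected(self):
        rng = np.random.default_rng(3)
        rejected = sum(normality_test(rng.standard_cauchy(1000))[1] < 0.05
                       for _ in range(40))
        assert rejected >= 38  # >= 95% of seeds


class TestMADFilter:
    def test_hand_computed_fixture_removes_only_the_outlier(self):
        df, var = _cohort([5.0, 5.1, 4.9, 5.2, 4.8, 9.0])
        out = mad_outlier_filter(df, variables=(var,), k=2.0)
        assert list(out["included"]) == [True] * 5 + [False]
        assert out["exclusion_reasons"].iloc[-1] == var

    def test_fixture_insensitive_to_consistency_constant(self):
        df, var = _cohort([5.0, 5.1, 4.9, 5.2, 4.8, 9.0])
        raw = mad_outlier_filter(df, variables=(var,), k=2.0,
                                 consistency_constant=1.0)
        scaled = mad_outlier_filter(df, variables=(var,), k=2.0,
                                    consistency_constant=1.4826)
        assert list(raw["included"]) == list(scaled["included"])

    def test_zero_mad_names_the_variable(self):
        df, var = _cohort([5.0, 5.0, 5.0, 5.0, 7.0])
        with pytest.raises(DegenerateDataError, match=var):
            mad_outlier_filter(df, variables=(var,))

    def test_empty_variable_list_is_identity(self):
        df, var = _cohort([1.0, 2.0, 3.0])
        out = mad_outlier_filter(df, variables=())
        assert out["included"].all()
        pd.testing.assert_frame_equal(out[df.columns], df)

    def test_boundary_deviation_exactly_k_mad_is_retained(self):
        # median 5, raw MAD 1 -> cutoff 2; the value 7 sits exactly on it
        df, var = _cohort([4.0, 5.0, 6.0, 7.0, 3.0])
        out = mad_outlier_filter(df, variables=(var,), k=2.0,
                                 consistency_constant=1.0)
        assert out["included"].all()

    def test_missing_variable_is_schema_error(self):
        df, _ = _cohort([1.0, 2.0, 3.0])
        with pytest.raises(SchemaError):
            mad_outlier_filter(df, variables=("labeling_consistency",))

    def test_frozen_screen_is_idempotent(self):
        rng = np.random.default_rng(5)
        df, var = _cohort(np.r_[rng.normal(5, 0.2, 28), 9.0, 1.0])
        screen = MADScreen(variables=(var,)).fit(df)
        once = screen.transform(df)
        twice = screen.transform(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_multi_variable_exclusion_is_cohort_wide(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(20)],
            "a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20)})
        df.loc[0, "a"] = 50.0
        df.loc[1, "b"] = -50.0
        out = mad_outlier_filter(df, variables=("a", "b"))
        assert not out.loc[0, "included"] and not out.loc[1, "included"]
        assert out.loc[0, "exclusion_reasons"] == "a"
        assert out.loc[1, "exclusion_reasons"] == "b"


class TestDescriptives:
    def test_two_value_hand_case(self):
        df = pd.DataFrame({"x": [1.0, 3.0]})
        out = descriptive_stats(df, measures=("x",))
        row = out.loc["x"]
        assert row["mean"] == 2.0 and row["sd"] == pytest.approx(np.sqrt(2))
        assert row["min"] == 1.0 and row["max"] == 3.0

    def test_constant_has_zero_sd(self):
        df = pd.DataFrame({"x": [2.0, 2.0, 2.0]})
        assert descriptive_stats(df, measures=("x",)).loc["x", "sd"] == 0.0

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.normal(size=12)})
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(descriptive_stats(df, ("x",)),
                                      descriptive_stats(shuffled, ("x",)))

    def test_only_included_participants_counted(self):
        df = pd.DataFrame({"x": [1.0, 3.0, 100.0],
                           "included": [True, True, False]})
        assert descriptive_stats(df, ("x",)).loc["x", "max"] == 3.0


class TestSpearman:
    def test_perfect_monotone_is_one(self):
        r = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r.rho == pytest.approx(1.0, abs=1e-12)

    def test_reversed_is_minus_one(self):
        r = spearman([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert r.rho == pytest.approx(-1.0, abs=1e-12)

    def test_matches_closed_form_on_tie_free_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 11))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            d = np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))
            rho_formula = 1 - 6 * np.sum(d.astype(float)**2) / (n * (n**2 - 1))
            assert spearman(x, y).rho == pytest.approx(rho_formula, abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman(x, y)
        assert spearman(np.exp(x), y).rho == pytest.approx(base.rho, abs=1e-12)
        assert spearman(x, y**3).rho == pytest.approx(base.rho, abs=1e-12)
        assert spearman(np.exp(x), y**3).p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_pairs(self):
        with pytest.raises(SampleSizeError):
            spearman([1, 2, 3], [3, 2, 1])


class TestCorrelationSuite:
    def _measures(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "participant_id": [f"P{i:02d}" for i in range(n)],
            "labeling_consistency": rng.uniform(0.9, 3.1, n),
            "log_contrast_distance": rng.uniform(4.6, 5.5, n),
            "log_ellipse_area": rng.uniform(8.2, 9.6, n),
            "centering_ratio": rng.uniform(-0.1, 0.3, n)})

    def test_exactly_three_pairs_with_consistency_on_the_left(self):
        res = run_correlation_suite(self._measures(12))
        assert [r.var_x for r in res] == ["labeling_consistency"] * 3
        assert {r.var_y for r in res} == {"log_contrast_distance",
                                          "log_ellipse_area", "centering_ratio"}
        assert all(r.df == 10 for r in res)

    def test_small_cohort_errors(self):
        with pytest.raises(SampleSizeError):
            run_correlation_suite(self._measures(3))

    def test_normality_report_covers_all_measures(self):
        rep = normality_report(self._measures(25))
        assert len(rep) == 4 and ((rep["W"] > 0) & (rep["W"] <= 1)).all()
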