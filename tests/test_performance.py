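"""Performance measures: concordance, binormal AUC, Brier decomposition,
recalibration and calibration curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.special import expit
from scipy.stats import norm

from predhet import (
    GroupStats,
    MeasurementSpec,
    binormal_auc,
    brier,
    brier_decomposition,
    calibration_curve,
    calibration_in_the_large,
    concordance,
    delta_auc,
    expected_delta_brier,
    fit_logistic,
    linear_predictor,
    recalibrate,
)


def brute_force_concordance(y, s):
    """O(n^2) pair-counting oracle with half credit for ties."""
    num = tot = 0.0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            tot += 1
            if s[i] > s[j]:
                num += 1
            elif s[i] == s[j]:
                num += 0.5
    return num / tot


class TestConcordance:
    def test_perfect_separation(self):
        assert concordance(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_all_ties(self):
        assert concordance(np.array([0, 1, 0, 1]), np.full(4, 0.3)) == 0.5

    def test_against_brute_force_small_example(self):
        y = np.array([0, 1, 0, 1, 1])
        s = np.array([0.2, 0.1, 0.3, 0.5, 0.5])
        expected = brute_force_concordance(y, s)  # = 4/6
        assert expected == pytest.approx(4 / 6)
        assert concordance(y, s) == pytest.approx(expected)

    def test_against_brute_force_random(self, rng):
        y = rng.integers(0, 2, size=60).astype(float)
        s = rng.choice([0.1, 0.4, 0.4, 0.7, 0.9], size=60)
        assert concordance(y, s) == pytest.approx(brute_force_concordance(y, s))

    @pytest.mark.parametrize("transform", [np.exp, lambda s: 3.0 * s - 7.0])
    def test_invariant_under_increasing_transforms(self, rng, transform):
        y = rng.integers(0, 2, size=200).astype(float)
        s = rng.normal(size=200)
        assert concordance(y, transform(s)) == pytest.approx(concordance(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            concordance(np.ones(5), np.arange(5.0))


class TestBinormalAUC:
    def test_no_separation(self):
        s = GroupStats(0.0, 0.0, 1.0, 1.0, 10, 10)
        assert binormal_auc(s) == pytest.approx(0.5)

    def test_unit_standardized_difference(self):
        # mean difference equal to sqrt(var1+var0) gives Phi(1)
        s = GroupStats(np.sqrt(2.0), 0.0, 1.0, 1.0, 10, 10)
        assert binormal_auc(s) == pytest.approx(norm.cdf(1.0))

    def test_swap_complementarity(self):
        s = GroupStats(1.3, 0.2, 0.8, 1.1, 40, 60)
        assert binormal_auc(s) + binormal_auc(s.swapped()) == pytest.approx(1.0)

    def test_matches_empirical_concordance_under_binormality(self, rng):
        # exact binormal sampling: X|Y=1 ~ N(1, 1), X|Y=0 ~ N(0, 1)
        n = 100_000
        x1 = rng.normal(1.0, 1.0, size=n)
        x0 = rng.normal(0.0, 1.0, size=n)
        y = np.concatenate([np.ones(n), np.zeros(n)])
        x = np.concatenate([x1, x0])
        emp = concordance(y, x)
        approx = binormal_auc(GroupStats.from_sample(y, x))
        assert approx == pytest.approx(emp, abs=0.005)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            binormal_auc(GroupStats(1.0, 0.0, 0.0, 0.0, 5, 5))


class TestDeltaAUC:
    BASE = GroupStats(mean1=0.58, mean0=-0.58, var1=0.66, var0=0.66, n1=50, n0=50)

    def test_identity_spec_changes_nothing(self):
        assert delta_auc(self.BASE, MeasurementSpec.identity()) == pytest.approx(0.0)

    def test_random_error_reduces_discrimination(self):
        spec = MeasurementSpec.nondifferential(err_var=1.0)
        assert delta_auc(self.BASE, spec) < 0

    def test_case_shift_can_improve_discrimination(self):
        # psi1 > psi0 with mean1 > mean0 widens the case/noncase contrast
        spec = MeasurementSpec(psi0=0.0, psi1=1.0)
        assert delta_auc(self.BASE, spec) > 0

    def test_systematic_error_no_effect_beyond_noise(self):
        # pure psi/theta changes rescale both classes: AUC unchanged
        spec = MeasurementSpec.nondifferential(psi=5.0, theta=2.0, err_var=0.0)
        assert delta_auc(self.BASE, spec) == pytest.approx(0.0, abs=1e-12)


class TestBrier:
    def test_perfect_predictions(self):
        y = np.array([0.0, 1.0, 1.0])
        assert brier(y, y) == 0.0

    def test_uninformative_predictions(self):
        assert brier(np.array([0.0, 1.0]), np.array([0.5, 0.5])) == pytest.approx(0.25)

    def test_hand_computed_example(self):
        parts = brier_decomposition(np.array([1.0, 0.0]), np.array([0.8, 0.4]))
        assert parts.total == pytest.approx(0.10)
        assert parts.calibration_term == pytest.approx(-0.10)
        assert parts.refinement_term == pytest.approx(0.20)

    @given(
        y=arrays(np.int_, st.integers(1, 30), elements=st.integers(0, 1)),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_decomposition_identity(self, y, seed):
        # (y-p)^2 = (y-p)(1-2p) + p(1-p) pointwise for y in {0,1}
        p = np.random.default_rng(seed).random(len(y))
        parts = brier_decomposition(y, p)
        assert abs(parts.total - brier(y, p)) < 1e-12
        assert abs(
            parts.calibration_term + parts.refinement_term - parts.total
        ) < 1e-12

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            brier(np.array([0.0, 1.0]), np.array([0.5, 1.2]))

    def test_in_sample_calibration_term_near_zero(self, rng):
        # ML fit is weakly calibrated in its own sample
        x = rng.normal(size=20_000)
        y = (rng.random(20_000) < expit(x)).astype(float)
        fit = fit_logistic(y, x)
        p = expit(linear_predictor(fit, x))
        parts = brier_decomposition(y, p)
        assert parts.calibration_term == pytest.approx(0.0, abs=0.005)


class TestExpectedDeltaBrier:
    def test_identical_refinement(self):
        p = np.array([0.2, 0.7])
        assert expected_delta_brier(p, p) == 0.0

    def test_arithmetic_example(self):
        out = expected_delta_brier(np.array([0.5, 0.5]), np.array([0.9, 0.1]))
        assert out == pytest.approx(0.25 - 0.09)

    def test_less_extreme_predictions_lose_accuracy(self, rng):
        p_x = rng.random(1000)
        p_w = 0.5 + 0.5 * (p_x - 0.5)  # shrunk toward 0.5
        assert expected_delta_brier(p_w, p_x) > 0


class TestRecalibration:
    def make_sample(self, rng, n=4000):
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(1.2 * x)).astype(float)
        fit = fit_logistic(y, x)
        return y, linear_predictor(fit, x)

    def test_in_sample_weak_calibration(self, rng):
        y, lp = self.make_sample(rng)
        res = recalibrate(y, lp)
        assert res.slope == pytest.approx(1.0, abs=1e-6)
        assert res.intercept == pytest.approx(0.0, abs=1e-6)

    def test_slope_halves_when_lp_doubles(self, rng):
        y, lp = self.make_sample(rng)
        assert recalibrate(y, 2 * lp).slope == pytest.approx(
            recalibrate(y, lp).slope / 2, abs=1e-8
        )

    def test_constant_lp_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            recalibrate(np.array([0.0, 1.0]), np.zeros(2))

    def test_citl_zero_in_sample(self, rng):
        y, lp = self.make_sample(rng)
        assert calibration_in_the_large(y, lp) == pytest.approx(0.0, abs=1e-6)

    def test_citl_shift_equivariance(self, rng):
        y, lp = self.make_sample(rng)
        base = calibration_in_the_large(y, lp)
        assert calibration_in_the_large(y, lp + 0.7) == pytest.approx(
            base - 0.7, abs=1e-8
        )

    def test_citl_negative_when_risk_overestimated(self, rng):
        y, lp = self.make_sample(rng)
        assert calibration_in_the_large(y, lp + 1.0) < 0


class TestCalibrationCurve:
    def test_perfect_binary_predictions(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        curve = calibration_curve(y, y, n_bins=2)
        assert curve == [(0.0, 0.0, 2), (1.0, 1.0, 2)]

    def test_bin_counts_sum_to_n(self, rng):
        p = rng.random(1000)
        y = (rng.random(1000) < p).astype(float)
        curve = calibration_curve(y, p, n_bins=10)
        assert sum(c[2] for c in curve) == 1000
        assert all(0.0 <= c[1] <= 1.0 for c in curve)

    def test_well_calibrated_deciles(self, rng):
        n = 50_000
        x = rng.normal(size=n)
        p = expit(1.4 * x)
        y = (rng.random(n) < p).astype(float)
        curve = calibration_curve(y, p, n_bins=10)
        assert len(curve) == 10
        assert max(abs(mp - frac) for mp, frac, _ in curve) < 0.03

    def test_degenerate_support_collapses_with_warning(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        with pytest.warns(UserWarning, match="collapsed"):
            curve = calibration_curve(y, np.full(4, 0.5), n_bins=4)
        assert curve == [(0.5, 0.5, 4)]

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            calibration_curve(np.array([0.0, 1.0]), np.array([0.2, 0.8]), n_bins=1)


class TestStandaloneEvaluation:
    def test_round_trip_through_delimited_text(self, tmp_path, rng):
        import pandas as pd
        from predhet import evaluate_predictions, evaluate_predictions_table

        x = rng.normal(size=3000)
        y = (rng.random(3000) < expit(1.2 * x)).astype(float)
        fit = fit_logistic(y, x)
        lp = linear_predictor(fit, x)
        path = tmp_path / "preds.csv"
        pd.DataFrame({"y": y, "lp": lp}).to_csv(path, index=False)
        from_file = evaluate_predictions_table(path, lp_col="lp", prediction_col=None)
        direct = evaluate_predictions(y, lp=lp)
        assert from_file == pytest.approx(direct)
        assert direct["slope"] == pytest.approx(1.0, abs=1e-6)
        assert direct["citl"] == pytest.approx(0.0, abs=1e-6)
        assert direct["brier"] == pytest.approx(
            direct["brier_calibration"] + direct["brier_refinement"], abs=1e-12
        )

    def test_probability_input_matches_lp_input(self, rng):
        from predhet import evaluate_predictions

        lp = rng.normal(size=500)
        y = (rng.random(500) < expit(lp)).astype(float)
        a = evaluate_predictions(y, lp=lp)
        b = evaluate_predictions(y, p=expit(lp))
        assert b["c"] == pytest.approx(a["c"])
        assert b["slope"] == pytest.approx(a["slope"], abs=1e-6)

    def test_exactly_one_input_required(self):
        from predhet import evaluate_predictions

        with pytest.raises(ValueError, match="exactly one"):
            evaluate_predictions(np.array([0.0, 1.0]))

    def test_missing_column_named(self, tmp_path):
        import pandas as pd
        from predhet import evaluate_predictions_table

        path = tmp_path / "bad.csv"
        pd.DataFrame({"outcome": [0, 1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="'y'"):
            evaluate_predictions_table(path)
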