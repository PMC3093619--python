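"""Aggregation, Weibull fitting, PSE extraction, dB conversion, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compadapt import (
    ObserverParams,
    ResponseTable,
    StaircaseConfig,
    aggregate,
    analyze_trials,
    angle_to_curvature,
    bootstrap_ci,
    curvature_to_angle,
    fit_weibull,
    from_db,
    pse_from_fit,
    run_block,
    side_averaged_pse,
    to_db,
)
from compadapt.psychometrics import PsychometricFit, _fit_counts
from conftest import fixed_effect


def trials_frame(intensities, responses, side="left"):
    n = len(intensities)
    return pd.DataFrame(
        {
            "session": ["s"] * n,
            "condition": ["c"] * n,
            "compound_side": [side] * n,
            "staircase": [0] * n,
            "trial": range(1, n + 1),
            "intensity": intensities,
            "response": responses,
            "seed": [0] * n,
        }
    )


def weibull_counts(alpha, beta, x, n_per_level, lapse=0.0):
    """Deterministic pseudo-counts from an exact Weibull curve."""
    p = lapse / 2 + (1 - lapse) * (1 - np.exp(-((x / alpha) ** beta)))
    y = np.round(n_per_level * p).astype(int)
    return x, np.full_like(y, n_per_level), y


def logistic_trials(pse, slope, levels, n_per_level, rng, side):
    """Binomial trials from a logistic observer with a known PSE."""
    rows_i, rows_r = [], []
    for x in levels:
        p = 1.0 / (1.0 + math.exp(-slope * (x - pse)))
        k = rng.binomial(n_per_level, p)
        rows_i += [x] * n_per_level
        rows_r += ["compound"] * k + ["component"] * (n_per_level - k)
    return trials_frame(rows_i, rows_r, side)


class TestAggregate:
    def test_counts_preserve_totals(self, plaid_observer, plaid_staircase, rng):
        block = run_block(
            "c", plaid_observer, fixed_effect(0.05), plaid_staircase, rng
        )
        table = aggregate(block, "left")
        assert table.total_trials == 200
        assert np.all(np.diff(table.intensity) > 0)

    def test_single_trial(self):
        table = aggregate(trials_frame([0.4], ["compound"]))
        assert table.total_trials == 1 and table.n_compound[0] == 1

    def test_duplication_doubles_counts(self):
        t = trials_frame([0.4, 0.4, 0.5], ["compound", "component", "compound"])
        once = aggregate(t)
        twice = aggregate(pd.concat([t, t], ignore_index=True))
        np.testing.assert_array_equal(twice.n_total, 2 * once.n_total)
        np.testing.assert_array_equal(twice.n_compound, 2 * once.n_compound)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="no trials"):
            aggregate(trials_frame([0.4], ["compound"], side="left"), "right")

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            ResponseTable(np.array([0.4]), np.array([3]), np.array([2]))


class TestFitWeibull:
    def test_recovers_known_parameters_from_clean_data(self):
        x = np.linspace(0.1, 1.2, 12)
        xx, n, y = weibull_counts(0.5, 3.0, x, 20_000)
        fit = _fit_counts(xx, n, y, lapse=0.0)
        assert fit.converged
        assert fit.alpha == pytest.approx(0.5, rel=0.01)
        assert fit.beta == pytest.approx(3.0, rel=0.01)

    def test_symmetric_data_cross_half_at_centre(self):
        x0 = 0.5
        x = np.array([x0 - 0.2, x0 - 0.1, x0, x0 + 0.1, x0 + 0.2])
        p = np.array([0.08, 0.27, 0.50, 0.73, 0.92])
        n = np.full(5, 1000)
        fit = _fit_counts(x, n, np.round(n * p).astype(int), lapse=0.0)
        assert pse_from_fit(fit) == pytest.approx(x0, rel=0.02)

    def test_intensity_scaling_rescales_alpha_only(self):
        x = np.linspace(0.1, 1.2, 10)
        xx, n, y = weibull_counts(0.5, 3.0, x, 5000)
        base = _fit_counts(xx, n, y, lapse=0.0)
        k = 7.5
        scaled = _fit_counts(k * xx, n, y, lapse=0.0)
        assert scaled.alpha == pytest.approx(k * base.alpha, rel=1e-3)
        assert scaled.beta == pytest.approx(base.beta, rel=1e-3)

    def test_all_identical_responses_flagged(self):
        x = np.array([0.3, 0.4, 0.5])
        n = np.array([10, 10, 10])
        fit = _fit_counts(x, n, np.zeros(3, dtype=int), lapse=0.01)
        assert not fit.converged
        with pytest.raises(ValueError):
            pse_from_fit(fit)

    def test_least_squares_cross_check(self):
        x = np.linspace(0.1, 1.2, 12)
        xx, n, y = weibull_counts(0.5, 3.0, x, 5000)
        mle = _fit_counts(xx, n, y, lapse=0.0, method="mle")
        ls = _fit_counts(xx, n, y, lapse=0.0, method="ls")
        assert ls.alpha == pytest.approx(mle.alpha, rel=0.02)
        assert ls.beta == pytest.approx(mle.beta, rel=0.05)

    def test_fit_weibull_on_response_table(self):
        x = np.linspace(0.2, 0.8, 8)
        xx, n, y = weibull_counts(0.45, 4.0, x, 2000)
        table = ResponseTable(xx, y, n)
        fit = fit_weibull(table, lapse=0.0)
        assert fit.alpha == pytest.approx(0.45, rel=0.02)


class TestPSE:
    def test_closed_form_alpha_one_beta_one(self):
        fit = PsychometricFit(alpha=1.0, beta=1.0, lapse=0.0, converged=True,
                              n_trials=100)
        assert pse_from_fit(fit) == pytest.approx(math.log(2), rel=1e-12)

    def test_large_beta_approaches_alpha(self):
        fit = PsychometricFit(alpha=1.0, beta=1e6, lapse=0.0, converged=True,
                              n_trials=100)
        assert pse_from_fit(fit) == pytest.approx(1.0, abs=1e-5)

    @pytest.mark.parametrize("alpha,beta,lapse", [(0.5, 3.0, 0.0), (0.7, 2.0, 0.01)])
    def test_curve_crosses_half_at_the_pse(self, alpha, beta, lapse):
        fit = PsychometricFit(alpha, beta, lapse, True, 100)
        assert abs(fit.predict(pse_from_fit(fit)) - 0.5) < 1e-6


class TestDecibels:
    def test_identity(self):
        assert to_db(0.42, 0.42) == 0.0

    def test_doubling_is_about_six_db(self):
        assert to_db(0.84, 0.42) == pytest.approx(6.0206, abs=1e-4)

    @settings(deadline=None, derandomize=True)
    @given(
        c=st.floats(0.01, 0.98),
        db=st.floats(-20.0, 20.0),
    )
    def test_round_trip_and_monotonicity(self, c, db):
        c_adapt = from_db(db, c)
        assert to_db(c_adapt, c) == pytest.approx(db, abs=1e-9)
        assert to_db(c_adapt + 0.01, c) > to_db(c_adapt, c)

    def test_nonpositive_contrast_rejected(self):
        with pytest.raises(ValueError):
            to_db(0.0, 0.42)
        with pytest.raises(ValueError):
            to_db(0.42, -0.1)


class TestSideAveraging:
    def test_fixed_bias_cancels_exactly_in_the_average(self, rng):
        """Bias +b on one side and -b on the other leaves the mean PSE at
        the bias-free value."""
        pse, b = 0.55, 0.06
        levels = np.linspace(0.35, 0.75, 9)
        left = logistic_trials(pse + b, 30.0, levels, 60, rng, "left")
        right = logistic_trials(pse - b, 30.0, levels, 60, rng, "right")
        est = side_averaged_pse(left, right)
        assert est.pse_left - est.pse_right == pytest.approx(2 * b, abs=0.02)
        assert est.pse_mean == pytest.approx(pse, abs=0.01)
        assert not est.partial

    def test_identical_sides_average_to_either(self, rng):
        levels = np.linspace(0.35, 0.75, 9)
        left = logistic_trials(0.5, 30.0, levels, 60, rng, "left")
        right = left.assign(compound_side="right")
        est = side_averaged_pse(left, right)
        assert est.pse_mean == pytest.approx(est.pse_left, rel=1e-12)

    def test_one_unusable_side_marks_partial(self, rng):
        levels = np.linspace(0.35, 0.75, 9)
        left = logistic_trials(0.5, 30.0, levels, 60, rng, "left")
        right = trials_frame([0.5] * 10, ["compound"] * 10, "right")
        est = side_averaged_pse(left, right)
        assert est.partial and np.isfinite(est.pse_mean)


class TestBootstrap:
    def test_step_observer_yields_degenerate_interval(self, rng):
        """A deterministic responder pins the PSE between two staircase
        levels, so the bootstrap CI is at most one step wide."""
        cfg = StaircaseConfig.default_plaid()
        obs = ObserverParams.default_plaid(psychometric_slope=1e9, lapse_rate=0.0)
        block = run_block("c", obs, fixed_effect(0.0503), cfg, rng)
        left = block[block["compound_side"] == "left"]
        right = block[block["compound_side"] == "right"]
        est = bootstrap_ci(left, right, n_resamples=200,
                           rng=np.random.default_rng(0))
        lo, hi = est.ci95
        assert hi - lo <= cfg.step_size + 1e-9

    def test_single_resample_gives_a_point_interval(self, rng):
        levels = np.linspace(0.35, 0.75, 9)
        left = logistic_trials(0.5, 30.0, levels, 30, rng, "left")
        right = logistic_trials(0.5, 30.0, levels, 30, rng, "right")
        est = bootstrap_ci(left, right, n_resamples=1,
                           rng=np.random.default_rng(0))
        assert est.ci95[0] == est.ci95[1]

    def test_estimates_invariant_to_row_order(self, rng):
        levels = np.linspace(0.35, 0.75, 9)
        left = logistic_trials(0.52, 30.0, levels, 40, rng, "left")
        right = logistic_trials(0.50, 30.0, levels, 40, rng, "right")
        trials = pd.concat([left, right], ignore_index=True)
        shuffled = trials.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = analyze_trials(trials, 0.42, "contrast", 100,
                           np.random.default_rng(9))
        b = analyze_trials(shuffled, 0.42, "contrast", 100,
                           np.random.default_rng(9))
        assert a == b

    def test_zero_effect_interval_contains_zero(
        self, plaid_observer, plaid_staircase
    ):
        rng = np.random.default_rng(77)
        block = run_block("null", plaid_observer, fixed_effect(0.0),
                          plaid_staircase, rng)
        row = analyze_trials(block, 0.42, "contrast", 300,
                             np.random.default_rng(78))
        assert row["ci_lo"] <= 0.0 <= row["ci_hi"]


def test_curvature_coordinate_is_invertible():
    for angle in (100.0, 140.0, 60.0):
        assert curvature_to_angle(angle_to_curvature(angle)) == angle
    assert angle_to_curvature(100.0) == 80.0
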