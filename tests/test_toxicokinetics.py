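"""Depuration kinetics, growth correction, steady-state times and BAF."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import exponential_depuration
from daphtk.toxicokinetics import (
    baf,
    complete_tk_fit,
    detect_plateau,
    fit_depuration,
    growth_correct,
    growth_rate,
    mean_log_baf_l5,
    time_to_ss,
)


class TestFitDepuration:
    def test_exact_exponential(self):
        fit = fit_depuration(exponential_depuration(0.1))
        assert fit.k2 == pytest.approx(0.1, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_collinear_matches_two_point_analytic_slope(self):
        # (0,100), (10,100/e) plus a collinear midpoint: slope must be the
        # two-point closed form ln(c1/c0)/(t1-t0) exactly
        df = exponential_depuration(0.1, times=(0.0, 5.0, 10.0))
        fit = fit_depuration(df)
        analytic = -(math.log(100 / math.e) - math.log(100.0)) / 10.0
        assert fit.k2 == pytest.approx(analytic, abs=1e-14)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            fit_depuration(exponential_depuration(0.1, times=(0.0, 24.0)))

    def test_rising_series_flagged_invalid(self):
        df = exponential_depuration(-0.05)
        fit = fit_depuration(df)
        assert not fit.valid

    def test_exclusions_recorded(self):
        df = exponential_depuration(0.1, times=(0.0, 24.0, 48.0, 72.0, 96.0))
        fit = fit_depuration(df, exclusions=[96.0])
        assert fit.excluded_points == [(96.0, "user exclusion")]
        assert fit.n_points == 4

    def test_recovery_median_error_within_15pct(self):
        # paper-schedule synthetic series, lognormal CV 15%, 200 seeds
        from daphtk.synthetic import SyntheticTKParams, gen_tk_series

        errors = []
        for seed in range(200):
            series = gen_tk_series(
                SyntheticTKParams(k2=0.05, kg=0.0, noise_cv=0.15, seed=seed)
            )
            fit = fit_depuration(series)
            errors.append(abs(fit.k2 - 0.05) / 0.05)
        assert np.median(errors) <= 0.15


class TestPlateau:
    def test_pure_exponential_no_flags(self):
        df = exponential_depuration(0.08, times=(0.0, 24.0, 48.0, 72.0, 96.0))
        assert detect_plateau(df) == []

    def test_elimination_resistant_floor_flags_tail(self):
        # exponential decay onto a residue floor at 10% of C0
        times = (0.0, 24.0, 48.0, 96.0, 144.0, 192.0)
        c0, k2, floor = 100.0, 0.08, 10.0
        df = pd.DataFrame(
            {
                "chemical_id": "X",
                "phase": "depuration",
                "time_h": times,
                "cd_ug_per_kg": [floor + (c0 - floor) * np.exp(-k2 * t) for t in times],
                "replicate": 1,
            }
        )
        flagged_times = [t for t, _ in detect_plateau(df)]
        assert 192.0 in flagged_times

    def test_short_series_no_flags(self):
        df = exponential_depuration(0.1, times=(0.0, 24.0, 48.0))
        assert detect_plateau(df) == []


class TestGrowth:
    def test_constant_weight(self):
        kg = growth_rate([(0.0, 3.0), (24.0, 3.0), (48.0, 3.0)])
        assert kg == pytest.approx(0.0, abs=1e-15)

    def test_exact_exponential_growth(self):
        pts = [(t, 3.0 * math.exp(0.01 * t)) for t in (0.0, 24.0, 48.0, 72.0)]
        assert growth_rate(pts) == pytest.approx(0.01, rel=1e-12)

    def test_noisy_recovery_within_20pct(self):
        rng_errors = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            sigma = math.sqrt(math.log(1.01))
            pts = [
                (t, 3.0 * math.exp(0.01 * t) * rng.lognormal(-sigma**2 / 2, sigma))
                for t in np.arange(0.0, 217.0, 24.0)
            ]
            rng_errors.append(abs(growth_rate(pts) - 0.01) / 0.01)
        assert np.median(rng_errors) <= 0.20

    @pytest.mark.parametrize(
        "k2,kg,expected,valid",
        [(0.05, 0.0, 0.05, True), (0.05, 0.01, 0.04, True), (0.01, 0.02, -0.01, False)],
    )
    def test_growth_correct(self, k2, kg, expected, valid):
        k2g, ok = growth_correct(k2, kg)
        assert k2g == pytest.approx(expected)
        assert ok is valid


class TestTimeToSteadyState:
    def test_printed_half_lives(self):
        assert time_to_ss(0.0059, 0.5) == pytest.approx(117.0, abs=0.5)
        assert time_to_ss(0.25, 0.5) == pytest.approx(2.8, abs=0.05)

    def test_t95_closed_form(self):
        assert time_to_ss(0.1, 0.95) == pytest.approx(29.957322735539897, rel=1e-12)

    @given(k=st.floats(1e-4, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_t95_over_t50_is_ln20_over_ln2(self, k):
        ratio = time_to_ss(k, 0.95) / time_to_ss(k, 0.5)
        assert ratio == pytest.approx(math.log(20) / math.log(2), rel=1e-9)

    @given(k1=st.floats(1e-3, 1.0), k2=st.floats(1e-3, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_higher_k_shorter_t95(self, k1, k2):
        lo, hi = sorted((k1, k2))
        assert time_to_ss(hi, 0.95) <= time_to_ss(lo, 0.95)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            time_to_ss(0.1, 1.0)


class TestBAF:
    def test_bnt_printed_mean_log_baf(self):
        # printed BNT levels: 50 mg/kg at 4.7 ug/L and 150 mg/kg at 12 ug/L,
        # 1.5% lipid normalized to 5% -> mean log BAF*_L5% = 4.58
        results = [baf(50_000.0, 4.7), baf(150_000.0, 12.0)]
        assert results[1].log_baf_l5 == pytest.approx(4.62, abs=0.005)
        assert mean_log_baf_l5(results) == pytest.approx(4.58, abs=0.005)

    def test_reference_lipid_is_identity(self):
        res = baf(1000.0, 2.0, f_lipid=0.05)
        assert res.baf_l5 == pytest.approx(res.baf)

    def test_zero_body_burden(self):
        assert baf(0.0, 2.0).baf == 0.0

    def test_zero_cw_rejected(self):
        with pytest.raises(ZeroDivisionError):
            baf(100.0, 0.0)


class TestRoundTrip:
    def test_synthetic_series_recovers_k2g(self, clean_tk_series):
        # noise-free generation at (k2=0.05, kg=0.01) -> exact recovery
        fit = complete_tk_fit(clean_tk_series)
        assert fit.k2 == pytest.approx(0.05, rel=1e-9)
        assert fit.kg == pytest.approx(0.01, rel=1e-9)
        assert fit.k2g == pytest.approx(0.04, rel=1e-9)
        assert fit.k_for_ss == "k2g"
        assert fit.t50 == pytest.approx(math.log(2) / 0.04, rel=1e-9)
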