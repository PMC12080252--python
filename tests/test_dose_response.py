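"""OECD-211 validity, inhibition, 4PL fitting, bootstrap CIs and CTLBB."""

import numpy as np
import pandas as pd
import pytest

from daphtk.dose_response import (
    ctlbb,
    ecx_ci,
    ecx_from_params,
    fit_4pl,
    percent_inhibition,
    validity_check,
)
from daphtk.synthetic import SyntheticDRParams, gen_reproduction


def make_records(controls, treated=None, dead_controls=0):
    rows = [
        dict(chemical_id="C", conc_ug_per_L=0.0, replicate=i + 1,
             offspring=o, parent_dead=i < dead_controls)
        for i, o in enumerate(controls)
    ]
    if treated:
        for conc, offs in treated:
            for j, o in enumerate(offs):
                rows.append(
                    dict(chemical_id="C", conc_ug_per_L=conc, replicate=j + 1,
                         offspring=o, parent_dead=False)
                )
    return pd.DataFrame(rows)


def exact_4pl_records(params=(0.0, 100.0, np.log10(5.0), 1.2),
                      concs=(0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0),
                      n_rep=2):
    bottom, top, logec50, hill = params
    rows = []
    for c in concs:
        inh = bottom + (top - bottom) / (1 + 10 ** ((logec50 - np.log10(c)) * hill))
        for r in range(n_rep):
            rows.append(dict(conc_ug_per_L=c, replicate=r + 1, inhibition_pct=inh))
    return pd.DataFrame(rows)


class TestValidity:
    def test_healthy_controls_valid(self):
        rng = np.random.default_rng(0)
        controls = np.rint(68 * rng.lognormal(0, 0.08, 10)).astype(int)
        rep = validity_check(make_records(list(controls)))
        assert rep.valid and not rep.reasons

    def test_parent_mortality_fails(self):
        rep = validity_check(make_records([70] * 10, dead_controls=2))
        assert not rep.valid and "parent mortality" in rep.reasons

    def test_mean_exactly_60_fails_strict(self):
        rep = validity_check(make_records([60] * 10))
        assert not rep.valid and "control mean offspring" in rep.reasons

    def test_no_controls_rejected(self):
        with pytest.raises(ValueError):
            validity_check(make_records([], treated=[(1.0, [5])]))


class TestInhibition:
    def test_control_mean_maps_to_zero(self):
        df = make_records([70, 70], treated=[(1.0, [70])])
        out = percent_inhibition(df)
        assert out["inhibition_pct"].iloc[0] == 0.0

    @pytest.mark.parametrize("offspring,expected", [(0, 100.0), (35, 50.0), (105, -50.0)])
    def test_arithmetic_and_no_clipping(self, offspring, expected):
        df = make_records([70, 70], treated=[(1.0, [offspring])])
        assert percent_inhibition(df)["inhibition_pct"].iloc[0] == pytest.approx(expected)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_inhibition(make_records([0, 0], treated=[(1.0, [5])]))


class TestFit4PL:
    def test_exact_recovery_on_noise_free_data(self):
        true = (0.0, 100.0, np.log10(5.0), 1.2)
        fit = fit_4pl(exact_4pl_records(true))
        assert fit.converged
        assert np.allclose(fit.params, true, rtol=1e-6, atol=1e-6)

    def test_ec50_is_inflection_when_symmetric(self):
        fit = fit_4pl(exact_4pl_records())
        assert fit.ecx[50.0].estimate == pytest.approx(5.0, rel=1e-6)

    def test_monotone_ecx_ordering(self):
        fit = fit_4pl(exact_4pl_records())
        assert fit.ecx[10.0].estimate < fit.ecx[20.0].estimate < fit.ecx[50.0].estimate

    def test_requires_five_concentrations(self):
        with pytest.raises(ValueError):
            fit_4pl(exact_4pl_records(concs=(1.0, 2.0, 4.0, 8.0)))

    def test_replicate_order_invariance(self):
        df = exact_4pl_records()
        shuffled = df.sample(frac=1.0, random_state=3)
        a = fit_4pl(df).ecx[50.0].estimate
        b = fit_4pl(shuffled).ecx[50.0].estimate
        assert b == pytest.approx(a, rel=1e-9)

    def test_unit_rescaling_rescales_ecx_linearly(self):
        df = exact_4pl_records()
        df2 = df.assign(conc_ug_per_L=df["conc_ug_per_L"] * 1000.0)
        a = fit_4pl(df).ecx[50.0].estimate
        b = fit_4pl(df2).ecx[50.0].estimate
        assert b == pytest.approx(1000.0 * a, rel=1e-6)

    def test_extrapolation_flagged_outside_tested_range(self):
        # EC50 = 5 but highest tested concentration is only 2 -> extrapolated
        fit = fit_4pl(exact_4pl_records(concs=(0.05, 0.1, 0.25, 0.5, 1.0, 2.0)))
        assert fit.ecx[50.0].extrapolated

    def test_ec50_recovery_median_error_under_10pct(self):
        # 200 seeded simulated experiments at CV 10%, 6 levels x 10 replicates
        true_ec50 = 5.0
        errors = []
        for seed in range(200):
            params = SyntheticDRParams(
                control_cv=0.10, log10_ec50=np.log10(true_ec50), seed=seed
            )
            records = gen_reproduction(params)
            fit = fit_4pl(percent_inhibition(records))
            if fit.converged:
                est = fit.ecx[50.0].estimate
                errors.append(abs(est - true_ec50) / true_ec50)
        assert len(errors) >= 190
        assert np.median(errors) <= 0.10


class TestBootstrapCI:
    def test_zero_noise_interval_degenerate(self):
        df = exact_4pl_records(n_rep=3)
        fit = fit_4pl(df)
        est = ecx_ci(fit, df, 50.0, n_boot=50, seed=0)
        assert est.ci_high - est.ci_low <= 1e-6 * est.estimate

    def test_same_seed_identical_intervals(self):
        records = gen_reproduction(SyntheticDRParams(seed=11))
        inh = percent_inhibition(records)
        fit = fit_4pl(inh)
        a = ecx_ci(fit, inh, 50.0, n_boot=100, seed=5)
        b = ecx_ci(fit, inh, 50.0, n_boot=100, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_interval_brackets_estimate(self):
        records = gen_reproduction(SyntheticDRParams(seed=21))
        inh = percent_inhibition(records)
        fit = fit_4pl(inh)
        est = ecx_ci(fit, inh, 10.0, n_boot=100, seed=2)
        assert est.ci_low <= est.estimate <= est.ci_high


class TestCTLBB:
    def test_null_slope_identity(self):
        assert ctlbb(3.7e-4, 5.9, m=0.0, delta_c=0.0) == pytest.approx(3.7e-4)

    def test_transcribed_formula_oracle(self):
        # oracle: 10**(log10(1e-4) + 0.94*5.9 + 0.352) evaluated independently
        assert ctlbb(1e-4, 5.9) == pytest.approx(79.06786279998254, rel=1e-12)

    def test_study_magnitudes_within_chronic_baseline_band(self):
        # EC10 0.1-15 ug/L, MW 217-268 g/mol, log Kow 5.2-6.9: CTLBB must land
        # inside the 0.36-137 umol/g octanol range typical of chronic narcosis
        cases = [(15.0, 217.27, 5.2), (3.0, 218.25, 5.9), (0.8, 234.32, 6.0),
                 (0.1, 268.31, 6.9)]
        for ec10_ug, mw, log_kow in cases:
            ec10_mmol = ec10_ug / mw / 1000.0
            assert 0.36 <= ctlbb(ec10_mmol, log_kow) <= 137.0

    def test_nonpositive_ec10_rejected(self):
        with pytest.raises(ValueError):
            ctlbb(0.0, 5.0)


def test_ecx_from_params_outside_span_is_nan():
    assert np.isnan(ecx_from_params((20.0, 100.0, 0.0, 1.0), 10.0))
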