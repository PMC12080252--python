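"""OECD-211 reproduction-test analysis for Daphnia magna.

Covers the full chain from raw offspring counts to effect concentrations:

* validity checks against the OECD-211 criteria (parent mortality < 10 %,
  control mean offspring > 60, control CV < 15 %; strict inequalities),
* per-replicate percent inhibition of reproduction relative to the control
  mean,
* a four-parameter logistic (4PL, variable slope) fit of inhibition against
  log10 exposure concentration, with analytic ECx inversion,
* percentile bootstrap confidence intervals for ECx by case-resampling of
  replicates within each concentration,
* the critical target lipid body burden (CTLBB) from the chronic target
  lipid model.

ECx here means the concentration at which the fitted inhibition equals x %
on the absolute scale (not x % of the bottom–top span), so EC50 coincides
with the curve midpoint only when bottom = 0 and top = 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

REPRODUCTION_COLUMNS = [
    "chemical_id", "conc_ug_per_L", "replicate", "offspring", "parent_dead",
]

#: Default box constraints for the 4PL asymptotes, in % inhibition.
DEFAULT_BOTTOM_BOUNDS = (-20.0, 20.0)
DEFAULT_TOP_BOUNDS = (80.0, 120.0)
HILL_BOUNDS = (1e-3, 20.0)

#: Chronic target lipid model constants: universal slope and the
#: polycyclic-aromatic class correction.
TLM_SLOPE = -0.94
TLM_DELTA_C_PAH = 0.352


@dataclass(frozen=True)
class ValidityReport:
    """OECD-211 validity assessment of a reproduction test's controls."""

    parent_mortality_pct: float
    control_mean_offspring: float
    control_cv_pct: float
    valid: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class EcxEstimate:
    estimate: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    extrapolated: bool = False
    unstable: bool = False


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters and derived effect concentrations.

    ``params`` is (bottom %, top %, log10_ec50, hill slope) for the model
    y = bottom + (top − bottom) / (1 + 10^((log10_ec50 − x)·hill)) on
    x = log10(concentration).  ``ecx`` maps the effect level x (e.g. 10,
    20, 50) to an :class:`EcxEstimate` in the concentration's input units.
    """

    params: tuple[float, float, float, float]
    ecx: dict[float, EcxEstimate]
    converged: bool
    n_boot: int = 0
    seed: Optional[int] = None
    r2: float = float("nan")
    conc_range: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def bottom(self) -> float:
        return self.params[0]

    @property
    def top(self) -> float:
        return self.params[1]

    @property
    def log10_ec50_param(self) -> float:
        return self.params[2]

    @property
    def hill(self) -> float:
        return self.params[3]


def read_reproduction_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REPRODUCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reproduction table missing columns: {sorted(missing)}")
    return df


def _controls(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["conc_ug_per_L"] == 0]


def validity_check(records: pd.DataFrame) -> ValidityReport:
    """Check the OECD-211 validity criteria on the control replicates.

    All three inequalities are strict, as the guideline states them:
    parent mortality < 10 %, mean live offspring per surviving mother > 60,
    CV of live offspring in controls < 15 %.
    """
    controls = _controls(records)
    if controls.empty:
        raise ValueError("no control records (conc_ug_per_L == 0)")
    dead = controls["parent_dead"].astype(bool)
    mortality = 100.0 * dead.mean()
    alive = controls.loc[~dead, "offspring"].to_numpy(dtype=float)
    mean_off = float(np.mean(alive)) if alive.size else 0.0
    cv = (
        100.0 * float(np.std(alive, ddof=1)) / mean_off
        if alive.size > 1 and mean_off > 0
        else 0.0
    )
    reasons = []
    if not mortality < 10.0:
        reasons.append("parent mortality")
    if not mean_off > 60.0:
        reasons.append("control mean offspring")
    if not cv < 15.0:
        reasons.append("control offspring CV")
    return ValidityReport(
        parent_mortality_pct=float(mortality),
        control_mean_offspring=mean_off,
        control_cv_pct=float(cv),
        valid=not reasons,
        reasons=reasons,
    )


def percent_inhibition(records: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate reproduction inhibition (%) relative to the control mean.

    inhibition = 100·(1 − offspring / control_mean).  Negative values
    (stimulation above the control mean) are kept, not clipped.  Returns the
    treated records (conc > 0) with an ``inhibition_pct`` column added.
    """
    controls = _controls(records)
    if controls.empty:
        raise ValueError("no control records (conc_ug_per_L == 0)")
    alive = controls.loc[~controls["parent_dead"].astype(bool), "offspring"]
    control_mean = float(alive.mean())
    if not control_mean > 0:
        raise ZeroDivisionError("control mean offspring is zero")
    treated = records[records["conc_ug_per_L"] > 0].copy()
    treated["inhibition_pct"] = 100.0 * (
        1.0 - treated["offspring"].astype(float) / control_mean
    )
    return treated


def _fpl(x: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - x) * hill))


def ecx_from_params(
    params: Sequence[float], x_pct: float
) -> float:
    """Invert the fitted 4PL analytically at absolute inhibition x %.

    Returns the concentration (linear scale, input units) where the fitted
    curve crosses y = x_pct; NaN if x_pct is outside (bottom, top).
    """
    bottom, top, log_ec50, hill = params
    if not (bottom < x_pct < top):
        return float("nan")
    ratio = (top - bottom) / (x_pct - bottom) - 1.0
    if ratio <= 0:
        return float("nan")
    return float(10.0 ** (log_ec50 - np.log10(ratio) / hill))


def _fit_core(
    x: np.ndarray,
    y: np.ndarray,
    bottom_bounds: tuple[float, float],
    top_bounds: tuple[float, float],
    p0: Optional[Sequence[float]] = None,
) -> Optional[np.ndarray]:
    lo = [bottom_bounds[0], top_bounds[0], x.min() - 3.0, HILL_BOUNDS[0]]
    hi = [bottom_bounds[1], top_bounds[1], x.max() + 3.0, HILL_BOUNDS[1]]
    if p0 is None:
        p0 = [
            float(np.clip(y.min(), *bottom_bounds)),
            float(np.clip(y.max(), *top_bounds)),
            float(np.median(x)),
            1.0,
        ]
    p0 = np.clip(np.asarray(p0, dtype=float), lo, hi)
    try:
        popt, _ = curve_fit(
            _fpl, x, y, p0=p0, bounds=(lo, hi), maxfev=5000, method="trf"
        )
    except (RuntimeError, ValueError):
        return None
    return popt


def fit_4pl(
    data: pd.DataFrame,
    ecx_levels: Sequence[float] = (10.0, 20.0, 50.0),
    bottom_bounds: tuple[float, float] = DEFAULT_BOTTOM_BOUNDS,
    top_bounds: tuple[float, float] = DEFAULT_TOP_BOUNDS,
) -> DoseResponseFit:
    """Fit the variable-slope 4PL to per-replicate inhibition data.

    ``data`` needs columns ``conc_ug_per_L`` (> 0) and ``inhibition_pct``
    (controls enter only through the control mean used to compute
    inhibition; conc = 0 cannot appear in a log10 fit).  Requires at least
    5 distinct non-zero concentrations.  ECx estimates falling outside the
    tested concentration range are flagged ``extrapolated``.
    """
    treated = data[data["conc_ug_per_L"] > 0]
    conc = treated["conc_ug_per_L"].to_numpy(dtype=float)
    y = treated["inhibition_pct"].to_numpy(dtype=float)
    n_levels = np.unique(conc).size
    if n_levels < 5:
        raise ValueError(
            f"need >= 5 distinct non-zero concentrations, got {n_levels}"
        )
    x = np.log10(conc)
    popt = _fit_core(x, y, bottom_bounds, top_bounds)
    if popt is None:
        return DoseResponseFit(
            params=(np.nan,) * 4, ecx={}, converged=False,
            conc_range=(float(conc.min()), float(conc.max())),
        )
    resid = y - _fpl(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    lo_c, hi_c = float(conc.min()), float(conc.max())
    ecx = {}
    for level in ecx_levels:
        est = ecx_from_params(popt, float(level))
        ecx[float(level)] = EcxEstimate(
            estimate=est,
            extrapolated=bool(np.isnan(est) or est < lo_c or est > hi_c),
        )
    return DoseResponseFit(
        params=tuple(float(v) for v in popt),
        ecx=ecx,
        converged=True,
        r2=r2,
        conc_range=(lo_c, hi_c),
    )


def ecx_ci(
    fit: DoseResponseFit,
    data: pd.DataFrame,
    x_pct: float,
    n_boot: int = 1000,
    seed: int = 0,
    bottom_bounds: tuple[float, float] = DEFAULT_BOTTOM_BOUNDS,
    top_bounds: tuple[float, float] = DEFAULT_TOP_BOUNDS,
    max_fail_frac: float = 0.2,
) -> EcxEstimate:
    """Percentile bootstrap 97.5–2.5 % confidence interval for an ECx.

    Replicates are case-resampled with replacement within each concentration
    — the controls (conc = 0) included, when ``data`` carries them with an
    ``offspring`` column, so that the uncertainty of the control mean
    propagates into the resampled inhibition values.  The 4PL is refit
    (warm-started at the original parameters) and the ECx recomputed; the
    interval is the 2.5/97.5 percentile of the bootstrap distribution.
    Deterministic for a fixed seed.  If more than ``max_fail_frac`` of
    refits fail (non-convergence or ECx undefined), the interval is flagged
    unstable.
    """
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    treated = data[data["conc_ug_per_L"] > 0]
    rng = np.random.default_rng(seed)
    controls = None
    if "offspring" in data.columns and (data["conc_ug_per_L"] == 0).any():
        ctrl = data[data["conc_ug_per_L"] == 0]
        if "parent_dead" in ctrl.columns:
            ctrl = ctrl[~ctrl["parent_dead"].astype(bool)]
        controls = ctrl["offspring"].to_numpy(dtype=float)
    resample_counts = controls is not None and "offspring" in treated.columns
    groups = [
        (
            np.log10(float(c)),
            grp["offspring"].to_numpy(dtype=float)
            if resample_counts
            else grp["inhibition_pct"].to_numpy(dtype=float),
        )
        for c, grp in treated.groupby("conc_ug_per_L", sort=True)
    ]
    p0 = np.asarray(fit.params, dtype=float)
    boots = np.empty(n_boot)
    boots.fill(np.nan)
    for b in range(n_boot):
        if resample_counts:
            cm = controls[rng.integers(0, controls.size, controls.size)].mean()
            if cm <= 0:
                continue
        xs, ys = [], []
        for logc, vals in groups:
            idx = rng.integers(0, vals.size, vals.size)
            xs.append(np.full(vals.size, logc))
            sampled = vals[idx]
            if resample_counts:
                sampled = 100.0 * (1.0 - sampled / cm)
            ys.append(sampled)
        xb = np.concatenate(xs)
        yb = np.concatenate(ys)
        popt = _fit_core(xb, yb, bottom_bounds, top_bounds, p0=p0)
        if popt is not None:
            boots[b] = ecx_from_params(popt, x_pct)
    ok = boots[np.isfinite(boots)]
    fail_frac = 1.0 - ok.size / n_boot
    point = fit.ecx.get(float(x_pct))
    estimate = point.estimate if point else ecx_from_params(fit.params, x_pct)
    if ok.size == 0:
        return EcxEstimate(estimate=estimate, unstable=True)
    lo, hi = np.percentile(ok, [2.5, 97.5])
    # the interval must bracket the point estimate
    lo = float(min(lo, estimate))
    hi = float(max(hi, estimate))
    return EcxEstimate(
        estimate=estimate,
        ci_low=lo,
        ci_high=hi,
        extrapolated=point.extrapolated if point else False,
        unstable=bool(fail_frac > max_fail_frac),
    )


def ctlbb(
    ec10_mmol_per_l: float,
    log_kow: float,
    m: float = TLM_SLOPE,
    delta_c: float = TLM_DELTA_C_PAH,
) -> float:
    """Critical target lipid body burden (µmol/g octanol) from chronic EC10.

    The target lipid model relates a chemical's effect concentration to a
    species-specific critical concentration in organism lipid via the
    universal slope m:

        log10 EC10 [mmol/L] = m·log K_OW + log10 CTLBB − Δc

    inverted here as CTLBB = 10^(log10 EC10 − m·log K_OW + Δc), with the
    chronic universal slope m = −0.94 and the polycyclic-aromatic class
    correction Δc = 0.352 by default.
    """
    if ec10_mmol_per_l <= 0:
        raise ValueError(f"ec10 must be > 0, got {ec10_mmol_per_l}")
    return float(10.0 ** (np.log10(ec10_mmol_per_l) - m * log_kow + delta_c))
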