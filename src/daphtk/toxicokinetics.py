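"""One-compartment toxicokinetics for Daphnia magna body-burden series.

The depuration rate constant k2 is the slope of ln(body burden) against time
during the depuration phase; it is independent of the uptake route and is
therefore the preferred bioaccumulation metric when uptake occurs via both
water and diet.  Growth dilutes body burdens, so the growth rate constant kg
(slope of ln wet weight vs time) is subtracted to give the growth-corrected
depuration constant k2g = k2 − kg.  Times to 50 % and 95 % of steady state
follow the first-order forms t = −ln(1 − f)/k.  The kinetic bioaccumulation
factor BAF* = C_D(end of uptake)/C_W is lipid-normalized to a reference 5 %
lipid content from the organism's actual lipid fraction (1.5 % for
D. magna): BAF*_L5% = BAF* × 0.05/f_lipid.

The uptake rate constant k1 is deliberately not estimated here: with
simultaneous aqueous and dietary exposure the uptake flux is not
identifiable from body burdens alone.  k1 exists only as a generation
parameter of the synthetic module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BODY_BURDEN_COLUMNS = [
    "chemical_id", "phase", "time_h", "cd_ug_per_kg", "replicate",
]

#: Actual lipid fraction assumed for D. magna and the 5 % reference.
DEFAULT_F_LIPID = 0.015
REFERENCE_F_LIPID = 0.05


@dataclass
class TKFit:
    """Depuration-kinetics fit results.

    ``k2`` (h⁻¹) is minus the OLS slope of ln C_D vs time; ``kg`` the growth
    rate constant; ``k2g = k2 − kg``.  ``t50``/``t95`` are times to 50/95 %
    steady state computed from ``k_for_ss`` (which of k2/k2g was used is
    recorded).  ``valid`` is False when the fitted slope is non-negative or
    growth exceeds elimination.
    """

    k2: float
    k2_se: float
    r2: float
    n_points: int
    kg: float = 0.0
    k2g: Optional[float] = None
    t50: Optional[float] = None
    t95: Optional[float] = None
    k_for_ss: Optional[str] = None
    valid: bool = True
    flags: list[str] = field(default_factory=list)
    excluded_points: list[tuple[float, str]] = field(default_factory=list)


@dataclass(frozen=True)
class BAFResult:
    """Kinetic bioaccumulation factor and its lipid-normalized form."""

    baf: float
    baf_l5: float
    log_baf_l5: float
    f_lipid: float
    steady_state_reached: bool = False


def read_body_burden_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BODY_BURDEN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"body-burden table missing columns: {sorted(missing)}")
    return df


def _loglinear_slope(time_h: np.ndarray, values: np.ndarray):
    if np.any(values <= 0):
        raise ValueError("all values must be > 0 for a log-space fit")
    res = stats.linregress(time_h, np.log(values))
    return res


def fit_depuration(
    series: pd.DataFrame,
    exclusions: Sequence[float] = (),
) -> TKFit:
    """Estimate k2 from the depuration-phase body burdens.

    All retained replicate points are pooled into one OLS fit of ln C_D on
    time (h); k2 = −slope.  ``exclusions`` lists time points (h) to drop —
    e.g. a trailing plateau — and every exclusion is recorded on the fit so
    the decision stays auditable.  Requires >= 3 retained points.
    """
    dep = series[series["phase"] == "depuration"]
    excluded = [
        (float(t), "user exclusion") for t in exclusions
        if (dep["time_h"] == t).any()
    ]
    dep = dep[~dep["time_h"].isin(list(exclusions))]
    t = dep["time_h"].to_numpy(dtype=float)
    cd = dep["cd_ug_per_kg"].to_numpy(dtype=float)
    if t.size < 3:
        raise ValueError(f"need >= 3 retained depuration points, got {t.size}")
    res = _loglinear_slope(t, cd)
    k2 = -float(res.slope)
    fit = TKFit(
        k2=k2,
        k2_se=float(res.stderr),
        r2=float(res.rvalue) ** 2,
        n_points=int(t.size),
        excluded_points=excluded,
    )
    if k2 <= 0:
        fit.valid = False
        fit.flags.append("non-positive k2 (no net elimination)")
    return fit


def detect_plateau(
    series: pd.DataFrame,
    tail_window: int = 2,
    tol: float = 0.20,
    tol_slope: float = 0.005,
) -> list[tuple[float, str]]:
    """Suggest trailing depuration points that look like an elimination plateau.

    Working backwards from the last time point (at most ``tail_window``
    points, always leaving >= 3 for a fit), a point is flagged when both
    (a) removing it and any already-flagged later points changes the fitted
    k2 by more than ``tol`` (relative), and (b) the local log-slope into the
    point is shallower than ``-tol_slope`` (h⁻¹) — i.e. elimination has
    effectively stopped.  Returns suggestions only; exclusion requires an
    explicit user decision (see :func:`fit_depuration`).
    """
    dep = series[series["phase"] == "depuration"]
    grouped = dep.groupby("time_h")["cd_ug_per_kg"].mean().sort_index()
    times = grouped.index.to_numpy(dtype=float)
    means = grouped.to_numpy(dtype=float)
    if times.size < 4:
        return []
    t_all = dep["time_h"].to_numpy(dtype=float)
    cd_all = dep["cd_ug_per_kg"].to_numpy(dtype=float)
    k2_full = -float(_loglinear_slope(t_all, cd_all).slope)
    if k2_full <= 0:
        return []
    suggestions: list[tuple[float, str]] = []
    dropped: set[float] = set()
    for i in range(times.size - 1, max(times.size - 1 - tail_window, 2), -1):
        t_i = float(times[i])
        local_slope = (math.log(means[i]) - math.log(means[i - 1])) / (
            times[i] - times[i - 1]
        )
        candidate = dropped | {t_i}
        keep = ~np.isin(t_all, list(candidate))
        if keep.sum() < 3:
            break
        k2_red = -float(_loglinear_slope(t_all[keep], cd_all[keep]).slope)
        rel_change = abs(k2_red - k2_full) / k2_full
        if rel_change > tol and local_slope >= -tol_slope:
            suggestions.append(
                (t_i, f"plateau suspected: local slope {local_slope:.4g} /h, "
                      f"k2 shifts {100 * rel_change:.0f}% on removal")
            )
            dropped.add(t_i)
        else:
            break
    return sorted(suggestions)


def growth_rate(weights: pd.DataFrame | Sequence[tuple[float, float]]) -> float:
    """Growth rate constant kg (h⁻¹): slope of ln(wet weight) vs time."""
    if isinstance(weights, pd.DataFrame):
        t = weights["time_h"].to_numpy(dtype=float)
        w = weights["wet_weight_mg"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(weights), dtype=float)
        t, w = arr[:, 0], arr[:, 1]
    if t.size < 3:
        raise ValueError(f"need >= 3 weight points, got {t.size}")
    res = _loglinear_slope(t, w)
    return float(res.slope)


def growth_correct(k2: float, kg: float) -> tuple[float, bool]:
    """Growth-corrected depuration constant k2g = k2 − kg.

    Returns ``(k2g, valid)``; a negative k2g (growth faster than apparent
    elimination) is returned but flagged invalid.
    """
    if k2 <= 0:
        raise ValueError(f"k2 must be > 0, got {k2}")
    k2g = k2 - kg
    return k2g, k2g > 0


def time_to_ss(k: float, fraction: float) -> float:
    """Time (h) to reach a given fraction of steady state: t = −ln(1−f)/k.

    t50 = ln(2)/k and t95 = ln(20)/k are the usual special cases.
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    return -math.log(1.0 - fraction) / k


def complete_tk_fit(
    series: pd.DataFrame,
    exclusions: Sequence[float] = (),
    kg: Optional[float] = None,
    use_k2g_for_ss: bool = True,
) -> TKFit:
    """Full depuration workflow: k2 fit, growth correction, t50/t95.

    If ``kg`` is None and the series carries a ``wet_weight_mg`` column with
    measurements, kg is fitted from it; otherwise kg = 0 (no correction).
    The rate feeding t50/t95 defaults to k2g when it is available and valid
    (``use_k2g_for_ss``), else k2; the choice is recorded in ``k_for_ss``.
    """
    fit = fit_depuration(series, exclusions=exclusions)
    if kg is None:
        if "wet_weight_mg" in series.columns and series["wet_weight_mg"].notna().sum() >= 3:
            wdf = series.loc[
                series["wet_weight_mg"].notna(), ["phase", "time_h", "wet_weight_mg"]
            ].copy()
            # depuration times are phase-relative; shift onto the absolute
            # clock so weights from both phases share one growth line
            up = series.loc[series["phase"] == "uptake", "time_h"]
            uptake_end = float(up.max()) if len(up) else 0.0
            wdf.loc[wdf["phase"] == "depuration", "time_h"] += uptake_end
            kg = growth_rate(wdf[["time_h", "wet_weight_mg"]])
        else:
            kg = 0.0
    fit.kg = float(kg)
    if fit.valid:
        k2g, ok = growth_correct(fit.k2, fit.kg)
        fit.k2g = k2g
        if not ok:
            fit.flags.append("k2g <= 0 (growth exceeds elimination)")
        k_ss = k2g if (use_k2g_for_ss and ok) else fit.k2
        fit.k_for_ss = "k2g" if (use_k2g_for_ss and ok) else "k2"
        fit.t50 = time_to_ss(k_ss, 0.5)
        fit.t95 = time_to_ss(k_ss, 0.95)
    return fit


def baf(
    cd_end: float,
    cw: float,
    f_lipid: float = DEFAULT_F_LIPID,
    steady_state_reached: bool = False,
) -> BAFResult:
    """Kinetic bioaccumulation factor BAF* (L/kg) with lipid normalization.

    BAF* = C_D(end of uptake, µg/kg wet weight) / C_W (µg/L);
    BAF*_L5% = BAF* × 0.05 / f_lipid.  When steady state was not reached
    (``steady_state_reached=False``, the default) the value is a lower-bound
    approximation of the steady-state BAF, not its equivalent.
    """
    if cw <= 0:
        raise ZeroDivisionError("cw must be > 0")
    if cd_end < 0:
        raise ValueError(f"cd_end must be >= 0, got {cd_end}")
    if not 0.0 < f_lipid <= 1.0:
        raise ValueError(f"f_lipid must be in (0, 1], got {f_lipid}")
    b = cd_end / cw
    b5 = b * REFERENCE_F_LIPID / f_lipid
    return BAFResult(
        baf=b,
        baf_l5=b5,
        log_baf_l5=math.log10(b5) if b5 > 0 else float("-inf"),
        f_lipid=f_lipid,
        steady_state_reached=steady_state_reached,
    )


def mean_log_baf_l5(results: Sequence[BAFResult]) -> float:
    """Mean of log10 BAF*_L5% across exposure levels (mean-of-logs)."""
    if not results:
        raise ValueError("no BAF results")
    return float(np.mean([r.log_baf_l5 for r in results]))
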