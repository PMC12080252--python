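"""Seeded synthetic-data generators for the three experimental data streams.

The raw study measurements behind this pipeline are not deposited, so these
generators emulate their structure for testing and demonstration:

* body-burden time series from a one-compartment uptake/depuration model on
  the study sampling schedule (uptake 24–120 h at 24 h intervals, 2
  replicates of pooled animals; depuration at 4 time points within 96 h),
  with growth dilution and multiplicative lognormal measurement noise;
* OECD-211 reproduction counts whose controls meet the validity criteria
  (mean > 60 offspring, CV < 15 %, no mortality by default) and whose
  treated replicates follow a 4PL inhibition curve;
* cross-species (log k2, log BCF_L5%) scatter around a target regression
  line.

All generators are pure functions of (parameters, seed).  Every default is
the corresponding study condition; noise magnitudes are the measurement CVs
reported for comparable data.

Note one deliberate asymmetry: growth dilution enters the uptake curve
through the combined rate constant (k2 + kg), while the analysis side
corrects only the depuration fit (k2g = k2 − kg), mirroring the
experimental procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classification import RegressionLine

DEFAULT_UPTAKE_TIMES_H = (24.0, 48.0, 72.0, 96.0, 120.0)
DEFAULT_DEPURATION_TIMES_H = (24.0, 48.0, 72.0, 96.0)

#: Wet weight of a 10-day-old D. magna at the start of exposure, mg.
DEFAULT_START_WEIGHT_MG = 3.0


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass(frozen=True)
class SyntheticTKParams:
    """One-compartment generation parameters for a body-burden series.

    ``k1`` (L kg⁻¹ h⁻¹) exists only here — the analysis never estimates it
    because uptake via water and diet is not separable.  ``noise_cv`` is the
    measurement CV of the body-burden determinations.
    """

    chemical_id: str = "CHEM"
    k1: float = 100.0
    k2: float = 0.05
    kg: float = 0.005
    cw: float = 5.0
    noise_cv: float = 0.15
    uptake_times_h: tuple[float, ...] = DEFAULT_UPTAKE_TIMES_H
    depuration_times_h: tuple[float, ...] = DEFAULT_DEPURATION_TIMES_H
    n_replicates: int = 2
    start_weight_mg: float = DEFAULT_START_WEIGHT_MG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0 or self.kg < 0 or self.cw <= 0:
            raise ValueError("rates and cw must be positive (kg >= 0)")
        for sched in (self.uptake_times_h, self.depuration_times_h):
            if any(b <= a for a, b in zip(sched, sched[1:])):
                raise ValueError("sampling schedules must be strictly increasing")

    def uptake_mean(self, t: float) -> float:
        """Model mean body burden (µg/kg) at uptake time t (h)."""
        k_tot = self.k2 + self.kg
        return self.k1 / k_tot * self.cw * (1.0 - math.exp(-k_tot * t)) * 1000.0

    def depuration_mean(self, dt: float) -> float:
        """Model mean body burden at time dt (h) after uptake ends."""
        c_end = self.uptake_mean(self.uptake_times_h[-1])
        return c_end * math.exp(-self.k2 * dt)


@dataclass(frozen=True)
class SyntheticDRParams:
    """Generation parameters for an OECD-211 reproduction dataset.

    Defaults give controls that pass the validity criteria by construction
    (mean 75 offspring, CV 10 %, no parent mortality).
    """

    chemical_id: str = "CHEM"
    control_mean: float = 75.0
    control_cv: float = 0.10
    bottom: float = 0.0
    top: float = 100.0
    log10_ec50: float = math.log10(5.0)
    hill: float = 1.2
    conc_ug_per_l: tuple[float, ...] = (0.5, 1.0, 2.5, 5.0, 10.0, 25.0)
    n_replicates: int = 10
    n_controls: int = 10
    mortality_p: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conc_ug_per_l) < 5:
            raise ValueError("need >= 5 exposure concentrations")
        if self.control_mean <= 0 or self.control_cv < 0:
            raise ValueError("invalid control parameters")

    def inhibition(self, conc: float) -> float:
        """True 4PL inhibition (%) at a concentration (µg/L)."""
        x = math.log10(conc)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** ((self.log10_ec50 - x) * self.hill)
        )


def gen_tk_series(params: SyntheticTKParams) -> pd.DataFrame:
    """Generate a body-burden time series on the study sampling schedule.

    Returns a DataFrame in the body-burden CSV dialect (``chemical_id,
    phase, time_h, cd_ug_per_kg, replicate, wet_weight_mg``).  Depuration
    times are measured from the start of the depuration phase; wet weights
    grow exponentially at kg across both phases with the same noise CV.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    t_up_end = params.uptake_times_h[-1]
    for phase, times in (
        ("uptake", params.uptake_times_h),
        ("depuration", params.depuration_times_h),
    ):
        for t in times:
            mean = (
                params.uptake_mean(t)
                if phase == "uptake"
                else params.depuration_mean(t)
            )
            t_abs = t if phase == "uptake" else t_up_end + t
            w_mean = params.start_weight_mg * math.exp(params.kg * t_abs)
            noise_cd = _lognormal_factor(rng, params.noise_cv, params.n_replicates)
            noise_w = _lognormal_factor(rng, params.noise_cv, params.n_replicates)
            for rep in range(params.n_replicates):
                rows.append(
                    {
                        "chemical_id": params.chemical_id,
                        "phase": phase,
                        "time_h": t,
                        "cd_ug_per_kg": mean * noise_cd[rep],
                        "replicate": rep + 1,
                        "wet_weight_mg": w_mean * noise_w[rep],
                    }
                )
    return pd.DataFrame(rows)


def gen_reproduction(params: SyntheticDRParams) -> pd.DataFrame:
    """Generate reproduction records in the OECD-211 CSV dialect.

    Control offspring are rounded lognormal draws at (control_mean,
    control_cv); treated replicates scale a control-like draw by the true
    4PL inhibition; counts are rounded and floored at 0; parent deaths are
    Bernoulli(mortality_p).
    """
    rng = np.random.default_rng(params.seed)
    rows = []

    def draw_counts(mean: float, n: int) -> np.ndarray:
        vals = mean * _lognormal_factor(rng, params.control_cv, n)
        return np.maximum(np.rint(vals), 0).astype(int)

    for rep, count in enumerate(draw_counts(params.control_mean, params.n_controls)):
        rows.append(
            {
                "chemical_id": params.chemical_id,
                "conc_ug_per_L": 0.0,
                "replicate": rep + 1,
                "offspring": int(count),
                "parent_dead": bool(rng.random() < params.mortality_p),
            }
        )
    for conc in params.conc_ug_per_l:
        mean = params.control_mean * (1.0 - params.inhibition(conc) / 100.0)
        mean = max(mean, 0.0)
        counts = draw_counts(mean, params.n_replicates) if mean > 0 else np.zeros(
            params.n_replicates, dtype=int
        )
        for rep, count in enumerate(counts):
            rows.append(
                {
                    "chemical_id": params.chemical_id,
                    "conc_ug_per_L": conc,
                    "replicate": rep + 1,
                    "offspring": int(count),
                    "parent_dead": bool(rng.random() < params.mortality_p),
                }
            )
    return pd.DataFrame(rows)


def sigma_for_r2(slope: float, x_range: tuple[float, float], r2: float) -> float:
    """Residual sd giving an expected R² for a line over uniform x."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    var_x = (x_range[1] - x_range[0]) ** 2 / 12.0
    return math.sqrt(slope**2 * var_x * (1.0 / r2 - 1.0))


def gen_bcf_k2(
    line: RegressionLine,
    sigma: float,
    n: int,
    seed: int = 0,
    x_range: tuple[float, float] = (-2.5, 0.5),
    species_group: str = "daphnia",
) -> pd.DataFrame:
    """Generate (log k2, log BCF_L5%) scatter around a target line.

    x = log10 k2 is uniform over ``x_range`` (h⁻¹ on the linear scale);
    y = slope·x + intercept + N(0, sigma).  Returned in the species-table
    CSV dialect.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], n)
    y = line.slope * x + line.intercept + rng.normal(0.0, sigma, n)
    return pd.DataFrame(
        {
            "species_group": species_group,
            "chemical": [f"synthetic-{i + 1}" for i in range(n)],
            "log_kow": np.nan,
            "log_bcf_l5": y,
            "log_k2": x,
            "bcf_type": "kinetic",
        }
    )


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n deterministic substream seeds (< 2**31) from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
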