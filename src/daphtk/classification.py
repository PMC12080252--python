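"""Bioaccumulation classification from depuration kinetics.

Regulatory B/vB categories (REACH: BCF >= 2000 and 5000 L/kg) are defined on
fish bioconcentration factors.  Because depuration is much faster in small
invertebrates than in fish, the same BCF criteria map onto organism-specific
depuration-rate (k2) thresholds.  This module fits the cross-species
log BCF_L5% vs log k2 (and log K_OW vs log BCF_L5%) regressions, inverts
them at the BCF criteria to obtain k2 thresholds, classifies chemicals from
a measured k2, and tabulates fish-vs-invertebrate concordance quadrants.

The published regression lines ship as named constants so that threshold
arithmetic is reproducible without the underlying literature compilation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SPECIES_COLUMNS = [
    "species_group", "chemical", "log_kow", "log_bcf_l5", "log_k2", "bcf_type",
]
SPECIES_GROUPS = {"fish", "daphnia", "hyalella", "other"}

#: REACH bioaccumulative / very bioaccumulative BCF criteria, L/kg.
BCF_B_CRIT = 2000.0
BCF_VB_CRIT = 5000.0

#: High-accumulation cutoff used for concordance quadrants (log10 BCF_L5%).
LOG_BCF_HIGH = 3.3


@dataclass(frozen=True)
class RegressionLine:
    """An ordinary-least-squares line y = slope·x + intercept."""

    slope: float
    intercept: float
    r2: float = float("nan")
    n: int = 0

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


# Published cross-species log BCF_L5% vs log k2 regressions.
DAPHNIA_BCF_K2_LINE = RegressionLine(slope=-1.41, intercept=2.85, r2=0.90, n=14)
HYALELLA_BCF_K2_LINE = RegressionLine(slope=-1.16, intercept=1.64, r2=0.49, n=25)
FISH_BCF_K2_LINE = RegressionLine(slope=-1.19, intercept=0.66, r2=0.78, n=169)

# Published log K_OW vs log BCF_L5% regressions.
DAPHNIA_KOW_BCF_LINE = RegressionLine(slope=0.86, intercept=-0.80, r2=0.90, n=45)
HYALELLA_KOW_BCF_LINE = RegressionLine(slope=0.72, intercept=-0.33, r2=0.78, n=25)
FISH_KOW_BCF_LINE = RegressionLine(slope=0.58, intercept=-0.15, r2=0.67, n=169)

#: Fish k2 thresholds (h⁻¹) derived by the UK Environment Agency from fish
#: BCF data; used as the fish default in preference to the fish-line
#: inversion (the two nearly coincide).
FISH_K2_B = 0.0059
FISH_K2_VB = 0.0027


@dataclass(frozen=True)
class BThresholds:
    """Organism-specific k2 thresholds for the B and vB categories.

    ``k2_b``/``k2_vb`` (h⁻¹) are the depuration rates at which the
    regression predicts BCF_L5% = 2000 / 5000 L/kg; slower depuration
    (smaller k2) means more accumulation, so k2_vb < k2_b.  ``t50_*`` are
    the corresponding elimination half-lives ln(2)/k2.
    """

    species_group: str
    k2_b: float
    k2_vb: float
    t50_b: float
    t50_vb: float


@dataclass(frozen=True)
class ConcordanceResult:
    both: int
    fish_only: int
    invert_only: int
    neither: int
    agreement_pct: float


def read_species_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SPECIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    bad = set(df["species_group"].unique()) - SPECIES_GROUPS
    if bad:
        raise ValueError(f"unknown species_group values: {sorted(bad)}")
    return df


def fit_loglinear(
    records: pd.DataFrame,
    x_field: str,
    y_field: str,
    exclude_chemicals: Sequence[str] = (),
) -> RegressionLine:
    """OLS regression of ``y_field`` on ``x_field`` over complete records.

    ``exclude_chemicals`` drops named chemicals from the fit (e.g. those
    whose BCF is known to be underestimated because t95 exceeded the uptake
    duration); exclusions are explicit, never inferred.
    """
    df = records
    if exclude_chemicals:
        df = df[~df["chemical"].isin(list(exclude_chemicals))]
    df = df[[x_field, y_field]].dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 complete records, got {len(df)}")
    x = df[x_field].to_numpy(dtype=float)
    y = df[y_field].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: x has zero variance")
    res = stats.linregress(x, y)
    return RegressionLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        n=int(len(df)),
    )


def k2_threshold(line: RegressionLine, bcf_crit: float) -> float:
    """Invert a log BCF_L5% vs log k2 line at a BCF criterion.

    k2 = 10^((log10(bcf_crit) − intercept)/slope), h⁻¹.  Requires a
    negative slope (more depuration, less accumulation).
    """
    if line.slope >= 0:
        raise ValueError(f"inversion requires slope < 0, got {line.slope}")
    if bcf_crit <= 0:
        raise ValueError(f"bcf_crit must be > 0, got {bcf_crit}")
    return float(10.0 ** ((math.log10(bcf_crit) - line.intercept) / line.slope))


def derive_thresholds(
    line: RegressionLine,
    species_group: str,
    bcf_b: float = BCF_B_CRIT,
    bcf_vb: float = BCF_VB_CRIT,
) -> BThresholds:
    """k2 thresholds (and half-lives) for the B and vB criteria."""
    k2_b = k2_threshold(line, bcf_b)
    k2_vb = k2_threshold(line, bcf_vb)
    return BThresholds(
        species_group=species_group,
        k2_b=k2_b,
        k2_vb=k2_vb,
        t50_b=math.log(2.0) / k2_b,
        t50_vb=math.log(2.0) / k2_vb,
    )


FISH_THRESHOLDS = BThresholds(
    species_group="fish",
    k2_b=FISH_K2_B,
    k2_vb=FISH_K2_VB,
    t50_b=math.log(2.0) / FISH_K2_B,
    t50_vb=math.log(2.0) / FISH_K2_VB,
)


def classify_k2(
    k2: float, thresholds: BThresholds
) -> Literal["not_B", "B", "vB"]:
    """Classify a chemical from its depuration rate constant.

    vB if k2 <= k2_vb, else B if k2 <= k2_b, else not_B.  Bounds are
    inclusive: a k2 exactly at a threshold meets the criterion.
    """
    if k2 <= 0:
        raise ValueError(f"k2 must be > 0, got {k2}")
    if k2 <= thresholds.k2_vb:
        return "vB"
    if k2 <= thresholds.k2_b:
        return "B"
    return "not_B"


def concordance(
    pairs: pd.DataFrame | Sequence[tuple[float, float]],
    crit: float = LOG_BCF_HIGH,
) -> ConcordanceResult:
    """Fish-vs-invertebrate accumulation concordance quadrants.

    ``pairs`` holds per-chemical (fish log BCF_L5%, invertebrate
    log BCF_L5%) values, either as a DataFrame with columns
    ``log_bcf_fish``/``log_bcf_invert`` or as a sequence of tuples.  A value
    >= ``crit`` (inclusive) counts as high accumulation on that axis.
    Agreement % = 100·(both + neither)/total.
    """
    if isinstance(pairs, pd.DataFrame):
        fish = pairs["log_bcf_fish"].to_numpy(dtype=float)
        inv = pairs["log_bcf_invert"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        if arr.size == 0:
            raise ValueError("need >= 1 pair")
        fish, inv = arr[:, 0], arr[:, 1]
    if fish.size == 0:
        raise ValueError("need >= 1 pair")
    hf = fish >= crit
    hi = inv >= crit
    both = int(np.sum(hf & hi))
    fish_only = int(np.sum(hf & ~hi))
    invert_only = int(np.sum(~hf & hi))
    neither = int(np.sum(~hf & ~hi))
    total = fish.size
    return ConcordanceResult(
        both=both,
        fish_only=fish_only,
        invert_only=invert_only,
        neither=neither,
        agreement_pct=100.0 * (both + neither) / total,
    )
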