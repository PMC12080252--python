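"""Exposure quality control for passive-dosing tests.

Passive dosing keeps the freely dissolved water concentration (C_W) constant
by buffering losses from a pre-loaded PDMS donor.  These routines summarize
measured C_W across media-change cycles (pooling initial and final samples
per exposure level) and test whether concentrations declined systematically
within cycles — a decline would mean the donor failed to compensate losses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

EXPOSURE_COLUMNS = ["chemical_id", "level_id", "cycle", "stage", "cw_ug_per_L"]


@dataclass(frozen=True)
class ExposureSummary:
    """Per-level pooled summary of measured water concentrations."""

    chemical_id: str
    level_id: str
    n: int
    mean_ug_per_l: float
    sd_ug_per_l: float
    cv_pct: float
    flagged: bool = False
    flag_reason: Optional[str] = None


@dataclass(frozen=True)
class StabilityResult:
    """Outcome of the initial-vs-final concentration decline test.

    ``status`` is ``"ok"`` (testable) or ``"inconclusive"`` (too few
    replicates); ``decline`` is True only when the final mean is below the
    initial mean and the one-sided Welch test is significant at p < 0.05.
    """

    chemical_id: str
    level_id: str
    status: Literal["ok", "inconclusive"]
    decline: bool
    statistic: Optional[float] = None
    p_value: Optional[float] = None
    mean_initial: Optional[float] = None
    mean_final: Optional[float] = None


def read_exposure_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EXPOSURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"exposure table missing columns: {sorted(missing)}")
    if (df["cw_ug_per_L"] < 0).any():
        raise ValueError("cw_ug_per_L must be >= 0")
    return df


def summarize_exposure(measurements: pd.DataFrame) -> list[ExposureSummary]:
    """Summarize measured C_W per (chemical, level): n, mean, sd, CV%.

    All measurements of a level — initial and final, across cycles — are
    pooled, so the mean is the average of every sampling point collected
    over the test.  Levels with fewer than 2 measurements are flagged and
    not summarized.  CV = 100·sd/mean (sample sd, ddof=1).
    """
    out: list[ExposureSummary] = []
    for (chem, level), grp in measurements.groupby(
        ["chemical_id", "level_id"], sort=True
    ):
        cw = grp["cw_ug_per_L"].to_numpy(dtype=float)
        if cw.size < 2:
            out.append(
                ExposureSummary(
                    chemical_id=str(chem),
                    level_id=str(level),
                    n=int(cw.size),
                    mean_ug_per_l=float("nan"),
                    sd_ug_per_l=float("nan"),
                    cv_pct=float("nan"),
                    flagged=True,
                    flag_reason="fewer than 2 measurements",
                )
            )
            continue
        mean = float(np.mean(cw))
        sd = float(np.std(cw, ddof=1))
        cv = 100.0 * sd / mean if mean > 0 else float("nan")
        out.append(
            ExposureSummary(
                chemical_id=str(chem),
                level_id=str(level),
                n=int(cw.size),
                mean_ug_per_l=mean,
                sd_ug_per_l=sd,
                cv_pct=cv,
            )
        )
    return out


def summaries_to_frame(summaries: list[ExposureSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def stability_test(
    measurements: pd.DataFrame,
    level_id: str,
    chemical_id: Optional[str] = None,
    alpha: float = 0.05,
) -> StabilityResult:
    """Test for a systematic decline from initial to final C_W at one level.

    One-sided Welch (unequal-variance) two-sample comparison of final vs
    initial concentrations; only a loss threatens the dosing system, so the
    alternative is "final < initial".  Requires >= 2 measurements in each
    stage, otherwise the result is inconclusive rather than a flag.
    """
    df = measurements[measurements["level_id"].astype(str) == str(level_id)]
    if chemical_id is not None:
        df = df[df["chemical_id"].astype(str) == str(chemical_id)]
    chem = str(df["chemical_id"].iloc[0]) if len(df) else (chemical_id or "")
    initial = df.loc[df["stage"] == "initial", "cw_ug_per_L"].to_numpy(float)
    final = df.loc[df["stage"] == "final", "cw_ug_per_L"].to_numpy(float)
    if initial.size < 2 or final.size < 2:
        return StabilityResult(
            chemical_id=chem, level_id=str(level_id),
            status="inconclusive", decline=False,
        )
    mean_i, mean_f = float(np.mean(initial)), float(np.mean(final))
    if np.ptp(initial) == 0 and np.ptp(final) == 0 and mean_i == mean_f:
        # identical degenerate samples: no decline, t undefined
        return StabilityResult(
            chemical_id=chem, level_id=str(level_id), status="ok",
            decline=False, statistic=0.0, p_value=1.0,
            mean_initial=mean_i, mean_final=mean_f,
        )
    t, p = stats.ttest_ind(final, initial, equal_var=False, alternative="less")
    decline = bool(mean_f < mean_i and p < alpha)
    return StabilityResult(
        chemical_id=chem, level_id=str(level_id), status="ok",
        decline=decline, statistic=float(t), p_value=float(p),
        mean_initial=mean_i, mean_final=mean_f,
    )
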