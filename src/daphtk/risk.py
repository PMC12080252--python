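"""PNEC derivation, risk quotients and REACH chronic-toxicity flagging.

PNEC = chronic EC10 / AF with a default assessment factor of 100 (a lower
AF of 10 is sometimes used for baseline toxicants).  RQ = measured
environmental concentration / PNEC; RQ > 1 indicates potential risk.  Under
REACH Annex XIII a chemical with chronic EC10 < 10 µg/L is "toxic to
aquatic life".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

DEFAULT_AF = 100.0
REACH_TOXIC_EC10_UG_PER_L = 10.0


@dataclass(frozen=True)
class RiskAssessment:
    chemical_id: str
    ec10_ug_per_l: float
    af: float
    pnec_ug_per_l: float
    reach_toxic: bool
    mec_ug_per_l: Optional[float] = None
    rq: Optional[float] = None
    rq_exceeds: Optional[bool] = None
    pnec_pmol_per_l: Optional[float] = None


def pnec(ec10_ug_per_l: float, af: float = DEFAULT_AF) -> float:
    """Predicted no-effect concentration (µg/L) = EC10 / AF."""
    if ec10_ug_per_l <= 0:
        raise ValueError(f"ec10 must be > 0, got {ec10_ug_per_l}")
    if af < 1:
        raise ValueError(f"assessment factor must be >= 1, got {af}")
    return ec10_ug_per_l / af


def risk_quotient(mec_ug_per_l: float, pnec_ug_per_l: float) -> tuple[float, bool]:
    """Risk quotient MEC/PNEC and whether it exceeds 1 (strict)."""
    if pnec_ug_per_l <= 0:
        raise ZeroDivisionError("pnec must be > 0")
    if mec_ug_per_l < 0:
        raise ValueError(f"mec must be >= 0, got {mec_ug_per_l}")
    rq = mec_ug_per_l / pnec_ug_per_l
    return rq, rq > 1.0


def reach_toxic_flag(ec10_ug_per_l: float) -> bool:
    """True iff chronic EC10 < 10 µg/L (strict), the REACH toxicity cut."""
    if ec10_ug_per_l <= 0:
        raise ValueError(f"ec10 must be > 0, got {ec10_ug_per_l}")
    return ec10_ug_per_l < REACH_TOXIC_EC10_UG_PER_L


def assess(
    chemical_id: str,
    ec10_ug_per_l: float,
    af: float = DEFAULT_AF,
    mec_ug_per_l: Optional[float] = None,
    mw: Optional[float] = None,
) -> RiskAssessment:
    """Full screening assessment for one chemical.

    Molar PNEC (pmol/L) is reported alongside the mass value when the molar
    mass is supplied: pmol/L = (µg/L / MW[g/mol]) × 1e6.
    """
    p = pnec(ec10_ug_per_l, af)
    rq = exceeds = None
    if mec_ug_per_l is not None:
        rq, exceeds = risk_quotient(mec_ug_per_l, p)
    pnec_pmol = (p / mw * 1e6) if mw else None
    return RiskAssessment(
        chemical_id=chemical_id,
        ec10_ug_per_l=ec10_ug_per_l,
        af=af,
        pnec_ug_per_l=p,
        reach_toxic=reach_toxic_flag(ec10_ug_per_l),
        mec_ug_per_l=mec_ug_per_l,
        rq=rq,
        rq_exceeds=exceeds,
        pnec_pmol_per_l=pnec_pmol,
    )
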