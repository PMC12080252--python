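"""Chemical property registry, unit conversions and chemical-activity calculations.

Concentrations are handled internally in nmol/L because the chemical-activity
framework (effective activity EA = ECx / S_L) and the target lipid model are
molar; mass units (µg/L) are converted at the I/O boundary.

The effective activity of a chemical is its effect concentration divided by
its subcooled liquid solubility S_L — the hypothetical solubility the liquid
form of a solid chemical would have at the test temperature.  Narcosis
(baseline, membrane-perturbation) toxicity occupies a characteristic activity
band: roughly 0.01–0.1 for acute endpoints and 0.001–0.01 for chronic
endpoints.  An activity well below the band suggests a specific mode of
action; one above it suggests the chemical is less potent than baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import pandas as pd

#: Default test temperature (K) for subcooled-solubility calculations.
DEFAULT_TEST_TEMPERATURE_K = 293.15

#: Entropy-of-fusion constant of Walden's rule, ΔS_fus/R, used in the
#: standard subcooled-liquid-solubility approximation.
WALDEN_FUSION_CONSTANT = 6.79

#: Inclusive baseline-toxicity activity bands by endpoint type.
ACTIVITY_BANDS: dict[str, tuple[float, float]] = {
    "chronic": (0.001, 0.01),
    "acute": (0.01, 0.1),
}

Endpoint = Literal["acute", "chronic"]
Band = Literal["below", "baseline", "above"]


@dataclass(frozen=True)
class Chemical:
    """One test chemical and the physicochemical properties the pipeline needs.

    Parameters
    ----------
    id : short token used to join tables (e.g. ``"BNT"``).
    name : free-text chemical name.
    mw : molar mass, g/mol (> 0).
    sw : water solubility, nmol/L (>= 0).
    log_kow : log10 octanol–water partition coefficient.
    tm : melting point, K (> 0).
    pka : acid dissociation constant, optional.
    """

    id: str
    name: str
    mw: float
    sw: float
    log_kow: float
    tm: float
    pka: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"mw must be > 0, got {self.mw}")
        if self.sw < 0:
            raise ValueError(f"sw must be >= 0, got {self.sw}")
        if self.tm <= 0:
            raise ValueError(f"tm must be > 0 K, got {self.tm}")


@dataclass(frozen=True)
class ActivityResult:
    """Effective chemical activity of an effect concentration.

    ``ea = ecx / s_l`` (both nmol/L); ``band`` locates the activity relative
    to the configured baseline-toxicity range of the endpoint.  ``at_bound``
    is set when the activity sits exactly on a band bound (bounds are
    inclusive, so such ties still report a band).
    """

    chemical_id: str
    s_l: float
    ea: float
    endpoint: Endpoint
    band: Band
    at_bound: bool = False


def to_molar(conc_ug_per_l: float, mw: float) -> float:
    """Convert a mass concentration (µg/L) to molar (nmol/L).

    nmol/L = µg/L / (g/mol) × 1000.
    """
    if mw <= 0:
        raise ValueError(f"mw must be > 0, got {mw}")
    if conc_ug_per_l < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_ug_per_l}")
    return conc_ug_per_l / mw * 1000.0


def to_mass(conc_nmol_per_l: float, mw: float) -> float:
    """Convert a molar concentration (nmol/L) back to mass (µg/L)."""
    if mw <= 0:
        raise ValueError(f"mw must be > 0, got {mw}")
    if conc_nmol_per_l < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_nmol_per_l}")
    return conc_nmol_per_l * mw / 1000.0


def subcooled_solubility(
    sw: float, tm: float, t: float = DEFAULT_TEST_TEMPERATURE_K
) -> float:
    """Subcooled liquid solubility S_L (nmol/L) of a solid chemical.

    For a chemical that is solid at the test temperature (``tm > t``) the
    crystal lattice depresses solubility; the liquid-state solubility is
    recovered with the standard entropy-of-fusion correction

        S_L = S_W · exp(6.79 · (T_M / T − 1))

    For a chemical that is liquid at the test temperature (``tm <= t``),
    S_L = S_W.
    """
    if sw < 0:
        raise ValueError(f"sw must be >= 0, got {sw}")
    if tm <= 0 or t <= 0:
        raise ValueError(f"temperatures must be > 0 K, got tm={tm}, t={t}")
    if tm <= t:
        return sw
    return sw * math.exp(WALDEN_FUSION_CONSTANT * (tm / t - 1.0))


def effective_activity(
    ecx: float,
    s_l: float,
    endpoint: Endpoint = "chronic",
    chemical_id: str = "",
    bands: Optional[dict[str, tuple[float, float]]] = None,
) -> ActivityResult:
    """Effective activity EA = ECx / S_L, with baseline-band interpretation.

    Both ``ecx`` and ``s_l`` are nmol/L.  Band bounds are inclusive on both
    ends; an activity exactly at a bound is reported in the band with
    ``at_bound=True``.
    """
    if s_l <= 0:
        raise ZeroDivisionError("s_l must be > 0 to compute an activity")
    if ecx < 0:
        raise ValueError(f"ecx must be >= 0, got {ecx}")
    band_table = ACTIVITY_BANDS if bands is None else bands
    if endpoint not in band_table:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    lo, hi = band_table[endpoint]
    ea = ecx / s_l
    if ea < lo:
        band: Band = "below"
    elif ea > hi:
        band = "above"
    else:
        band = "baseline"
    return ActivityResult(
        chemical_id=chemical_id,
        s_l=s_l,
        ea=ea,
        endpoint=endpoint,
        band=band,
        at_bound=(ea == lo or ea == hi),
    )


def load_chemicals(path: str | Path) -> dict[str, Chemical]:
    """Read a chemical registry CSV into ``Chemical`` objects keyed by id.

    Expected header: ``id,name,mw,sw_ug_per_L,log_kow,tm_K,pka`` — water
    solubility is given in µg/L in the file and converted to nmol/L here.
    Missing pka is allowed as an empty field.
    """
    df = pd.read_csv(path)
    required = {"id", "name", "mw", "sw_ug_per_L", "log_kow", "tm_K"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chemical table missing columns: {sorted(missing)}")
    registry: dict[str, Chemical] = {}
    for row in df.itertuples(index=False):
        pka = getattr(row, "pka", None)
        if pka is not None and pd.isna(pka):
            pka = None
        chem = Chemical(
            id=str(row.id),
            name=str(row.name),
            mw=float(row.mw),
            sw=to_molar(float(row.sw_ug_per_L), float(row.mw)),
            log_kow=float(row.log_kow),
            tm=float(row.tm_K),
            pka=None if pka is None else float(pka),
        )
        registry[chem.id] = chem
    return registry
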