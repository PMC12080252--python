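"""Bundled small data files.

``chemicals_synthetic.csv`` is a synthetic stand-in chemical registry: the
molar masses follow from the chemicals' structures, the log K_OW values are
consistent with the study range (5.2–6.9) and toxicity ordering, but the
water solubilities and melting points are plausible placeholders, not
measured values.  Analyses that depend on S_W or T_M (activities, molar
PNECs) are therefore demonstrative when run from this file.
"""

from importlib.resources import files
from pathlib import Path


def data_path(name: str) -> Path:
    """Absolute path of a bundled data file."""
    return Path(str(files(__package__) / name))
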