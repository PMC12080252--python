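import numpy as np
import pandas as pd
import pytest

from daphtk import synthetic


@pytest.fixture
def clean_tk_series() -> pd.DataFrame:
    """Noise-free body-burden series with k2 = 0.05, kg = 0.01."""
    params = synthetic.SyntheticTKParams(k2=0.05, kg=0.01, noise_cv=0.0, seed=0)
    return synthetic.gen_tk_series(params)


@pytest.fixture
def reproduction_records() -> pd.DataFrame:
    """Seeded synthetic OECD-211 dataset passing validity by construction."""
    return synthetic.gen_reproduction(synthetic.SyntheticDRParams(seed=7))


def exponential_depuration(k2: float, times=(0.0, 24.0, 48.0, 72.0), c0: float = 100.0):
    """Exact first-order decay series in the body-burden table dialect."""
    return pd.DataFrame(
        {
            "chemical_id": "X",
            "phase": "depuration",
            "time_h": list(times),
            "cd_ug_per_kg": [c0 * np.exp(-k2 * t) for t in times],
            "replicate": 1,
        }
    )
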