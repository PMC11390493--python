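import numpy as np
import pandas as pd
import pytest

from cpet_entropy.io_cpet import CpetRecord, PubertalStatus, Sex
from cpet_entropy.synthetic import CellSpec, simulate_record


@pytest.fixture(scope="session")
def default_spec():
    return CellSpec(sex=Sex.male, pubertal=PubertalStatus.early, seed=20240911)


@pytest.fixture(scope="session")
def default_record(default_spec):
    """One seeded default synthetic record with its ground truth."""
    return simulate_record(default_spec, 0)


def make_record(
    n=120,
    dt=1.0,
    vo2=2000.0,
    vco2=None,
    hr=150.0,
    participant_id="p0",
    **meta,
):
    """Hand-built record with constant or per-breath channel values."""
    time = np.arange(1, n + 1) * dt
    as_arr = lambda v: np.full(n, float(v)) if np.isscalar(v) else np.asarray(v, float)
    vo2 = as_arr(vo2)
    vco2 = as_arr(vco2 if vco2 is not None else 0.9 * vo2)
    breaths = pd.DataFrame(
        {
            "time": time,
            "vo2": vo2,
            "vco2": vco2,
            "ve": np.full(n, 50.0),
            "rr": np.full(n, 30.0),
            "vt": np.full(n, 1.2),
            "hr": as_arr(hr),
        }
    )
    return CpetRecord(participant_id=participant_id, breaths=breaths, **meta)


@pytest.fixture
def flat_record():
    return make_record()
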