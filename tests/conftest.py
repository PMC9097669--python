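import numpy as np
import pandas as pd
import pytest

from fertrial import reference as ref
from fertrial import simulate as sim


@pytest.fixture(scope="session")
def products():
    return ref.products()


@pytest.fixture(scope="session")
def treatments():
    return ref.treatments()


@pytest.fixture(scope="session")
def prices():
    return ref.prices()


@pytest.fixture()
def balanced_frame():
    """A deterministic balanced 2 x 8 x 3 grain-yield trial."""
    design = sim.balanced_design()
    effects = sim.default_grain_yield_effects()
    return sim.generate_trial(design, effects, seed=42)


@pytest.fixture()
def small_frame():
    """A tiny 2 soils x 3 treatments x 2 blocks layout with known values."""
    rows = []
    rng = np.random.default_rng(7)
    for soil, soil_off in (("Vertisol", -0.5), ("Cambisol", 0.5)):
        for trt, trt_off in (("T1", 0.0), ("T2", 1.0), ("T3", 2.0)):
            for block in (1, 2):
                rows.append({
                    "soil": soil, "treatment": trt, "block": block,
                    "season": "pooled",
                    "GY": 5.0 + soil_off + trt_off + 0.1 * block
                          + rng.normal(0, 0.2),
                })
    return pd.DataFrame(rows)


def write_csv(path, frame):
    frame.to_csv(path, index=False)
    return path
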