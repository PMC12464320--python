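import numpy as np
import pandas as pd
import pytest

import dropast as da


@pytest.fixture(scope="session")
def default_sim_tables():
    """Three replicates at the default study conditions, fixed seed."""
    cfg = da.SimulationConfig(seed=11)
    return cfg, da.simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_image_set():
    """Four synthetic frames (~200 droplets) with ground truth."""
    cfg = da.ImageConfig(n_images=4, seed=3)
    images, manifest = da.generate_droplet_images(cfg)
    return cfg, images, manifest


def make_table(rows, replicate_id="rep1", unit=""):
    return da.CountTable(
        replicate_id=replicate_id,
        data=pd.DataFrame(rows, columns=["concentration", "n_total", "n_positive"]),
        unit=unit,
    )


@pytest.fixture
def simple_tables():
    """Three hand-written replicates on a shared grid."""
    rows = lambda shift: [
        (0.0, 1000, 95 + shift),
        (6.0, 1000, 50 + shift),
        (10.0, 1000, 20 + shift),
        (16.0, 1000, 0),
    ]
    return [make_table(rows(s), f"rep{i+1}") for i, s in enumerate((0, 2, -2))]
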