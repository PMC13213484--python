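import numpy as np
import pandas as pd
import pytest

import morphoprint as mp


@pytest.fixture(scope="session")
def small_config():
    """A compact screen with two shared-signature compounds and one disjoint."""
    naff = 60
    sig_a = mp.PhenotypeSignature("sigA", np.arange(naff), np.full(naff, 5.0))
    sig_b = mp.PhenotypeSignature("sigB", np.arange(naff, 2 * naff), np.full(naff, 5.0))
    return mp.SimulationConfig(
        n_features=300,
        n_wells=96,
        sites_per_well=9,
        seed=11,
        signatures=[sig_a, sig_b],
        compounds=[
            mp.CompoundSpec("A1", "sigA"),
            mp.CompoundSpec("A2", "sigA"),
            mp.CompoundSpec("B1", "sigB"),
            mp.CompoundSpec("inert_named"),
        ],
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    return mp.simulate_screen(small_config)


@pytest.fixture(scope="session")
def small_result(small_config):
    return mp.run_screen(small_config)


@pytest.fixture()
def vehicle_profiles():
    """Five DMSO well profiles with known median 3 and MAD 1 on one feature."""
    rows = []
    for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0]):
        rows.append(
            {
                "compound": "DMSO",
                "concentration_uM": 0.0,
                "role": "vehicle",
                "cell_count": 100.0,
                "feat_a": v,
                "feat_b": 10.0 + v,
                "feat_c": 7.0,  # zero dispersion
            }
        )
    return pd.DataFrame(rows, index=[f"A{i + 1:02d}" for i in range(5)])
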