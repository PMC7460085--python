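from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fametraj.simulate import (
    ParameterTable,
    load_reference_parameters,
    mean_profiles,
    simulate_profiles,
)

PUBLISHED_LABELS = [
    "12:0", "14:0", "14:1n-5", "15:0", "16:0", "16:1n-7", "16:1n-9", "16:2n-4",
    "16:2n-6", "17:0", "17:1n-7", "17:1n-9", "17:2n-5", "18:0", "18:1n-7", "18:1n-9",
    "18:2n-6", "18:3n-3", "20:0", "20:1n-9", "20:2n-9", "22:0",
]


@pytest.fixture(scope="session")
def ref_params() -> ParameterTable:
    return load_reference_parameters()


@pytest.fixture(scope="session")
def cell_mean_profiles(ref_params):
    """One profile per design cell built from the published group means."""
    return mean_profiles(ref_params)


@pytest.fixture(scope="session")
def sim_profiles(ref_params):
    """One seeded triplicate simulation of the full factorial design."""
    return simulate_profiles(ref_params, n_rep=3, seed=20260901)


def make_shift_params(opposed: bool, sd_frac: float = 0.05) -> ParameterTable:
    """Parameter table with host-specific composition shifts along temperature.

    The LD host trades oleic for linoleic acid as temperature rises; the SL
    host does the opposite when ``opposed`` (the mirrored generator) or the
    same when not.  Used to test trajectory-divergence classification
    against a known generating direction.
    """
    base = {"16:0": 5.0, "18:0": 1.0, "16:1n-7": 0.5, "18:1n-9": 6.0, "18:2n-6": 9.0, "18:3n-3": 0.4}
    slopes = {"16:0": 0.0, "18:0": 0.0, "16:1n-7": -0.01, "18:1n-9": -0.15, "18:2n-6": 0.15, "18:3n-3": 0.01}
    rows = []
    for host, sign in (("LD", 1.0), ("SL", -1.0 if opposed else 1.0)):
        for temp in (10.0, 18.0, 25.0):
            for fa, mu in base.items():
                mean = mu + sign * slopes[fa] * (temp - 17.5)
                assert mean > 0
                rows.append(
                    {
                        "host": host,
                        "temperature_C": temp,
                        "salinity_psu": 23.5,
                        "fatty_acid": fa,
                        "mean_ug_per_g": mean,
                        "sd_ug_per_g": sd_frac * mean,
                        "flag": "ok",
                    }
                )
    return ParameterTable(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(90210)
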