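import numpy as np
import pandas as pd
import pytest

from thermospectrum import Collation, GrowthRecord, StrainCurve


def make_strain(sid, points, respiration="unknown", trophic="unknown"):
    """Strain curve from a list of (temperature, rate) pairs."""
    return StrainCurve(
        sid,
        [GrowthRecord(sid, t, r) for t, r in points],
        respiration=respiration,
        trophic=trophic,
    )


@pytest.fixture
def small_collation():
    """Three strains with distinct T_opt on both sides of 50 °C."""
    return Collation(
        [
            make_strain("a", [(10, 0.01), (20, 0.05), (30, 0.02)]),
            make_strain("b", [(30, 0.02), (42, 0.08), (55, 0.01)]),
            make_strain("c", [(60, 0.005), (70, 0.03), (80, 0.01)]),
        ]
    )


@pytest.fixture
def collation_frame():
    """Raw table for loader tests: one invalid (non-positive rate) row."""
    return pd.DataFrame(
        {
            "strain_id": ["s1", "s1", "s2"],
            "temperature_C": [20.0, 30.0, 25.0],
            "rate": [0.02, -0.01, 0.05],
            "respiration": ["aerobe", "aerobe", "anaerobe"],
            "trophic": ["heterotroph", "heterotroph", "autotroph"],
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
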