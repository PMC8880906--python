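import numpy as np
import pytest

from trefoil_themes import structure_motif as sm
from trefoil_themes import synthetic_data as sd


@pytest.fixture(scope="session")
def btl():
    """Noise-free βTL structure with the planted water."""
    return sd.generate_btl_structure(0.0, dry=False, seed=1)


@pytest.fixture(scope="session")
def btl_dry():
    return sd.generate_btl_structure(0.0, dry=True, seed=1)


@pytest.fixture(scope="session")
def btl_motif(btl):
    return sm.extract_motif(
        btl.structure, btl.motif_segments, source_id="btl",
        donor_residues=btl.donor_positions,
    )


@pytest.fixture(scope="session")
def helix_decoy():
    return sd.generate_decoy_structure(36, "helix", seed=2)


@pytest.fixture(scope="session")
def coil_decoy():
    return sd.generate_decoy_structure(60, "random_coil", seed=3)


@pytest.fixture(scope="session")
def scenario_exact():
    """Planted-theme scenario with zero theme divergence."""
    return sd.generate_theme_scenario(sd.ScenarioParams(theme_divergence=0.0), seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
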