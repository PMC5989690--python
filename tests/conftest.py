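import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ala9():
    from fbgmfcc.structure import build_peptide
    return build_peptide(["A"] * 9)


@pytest.fixture(scope="session")
def helix12():
    from fbgmfcc.structure import build_peptide
    return build_peptide(["A"] * 12, geometry="helical")


@pytest.fixture()
def tripeptide_distorted():
    """A-G-A peptide with a small seeded distortion (breaks the symmetry
    of the ideal build without breaking bonds)."""
    from fbgmfcc.structure import build_peptide
    s = build_peptide(["A", "G", "A"])
    rng = np.random.default_rng(42)
    s.set_positions(s.positions() + 0.05 * rng.normal(size=(s.n_atoms, 3)))
    return s


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix()
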