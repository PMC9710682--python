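import numpy as np
import pytest

from molpatch.fixtures import FixtureSpec, make_structure, write_ala_asp_pdb
from molpatch.surface import SurfaceParams, compute_point_cloud


@pytest.fixture(scope="session")
def params():
    return SurfaceParams()


@pytest.fixture(scope="session")
def single_atom_model():
    return make_structure(
        FixtureSpec(kind="single_atom", n_residues=1, hydrophobic_pattern="H")
    )


@pytest.fixture(scope="session")
def hph_model():
    """Two hydrophobic pseudo-residues separated by a hydrophilic one, far apart."""
    return make_structure(
        FixtureSpec(kind="pseudo_chain", n_residues=3, hydrophobic_pattern="HPH", spacing=20.0)
    )


@pytest.fixture(scope="session")
def hhh_model():
    """Three tightly packed hydrophobic pseudo-residues: one connected patch."""
    return make_structure(
        FixtureSpec(kind="pseudo_chain", n_residues=3, hydrophobic_pattern="HHH", spacing=2.0)
    )


@pytest.fixture(scope="session")
def shell_model():
    """A central atom fully enclosed by a tight shell of 30 atoms."""
    return make_structure(
        FixtureSpec(kind="shell", n_residues=31, hydrophobic_pattern="H" * 31, spacing=2.0)
    )


@pytest.fixture()
def ala_asp_pdb(tmp_path):
    return write_ala_asp_pdb(tmp_path / "ala_asp.pdb")


@pytest.fixture(scope="session")
def cloud_cache(params):
    """Memoised point clouds keyed by model identity (session-scoped speed-up)."""
    cache = {}

    def get(model):
        key = id(model)
        if key not in cache:
            cache[key] = compute_point_cloud(model, params)
        return cache[key]

    return get
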