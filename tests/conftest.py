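import numpy as np
import pytest

from ringweld import fixtures
from ringweld.model_core import BeadKind, Structure


@pytest.fixture(scope="session")
def ring_spec():
    return fixtures.RingSpec()


@pytest.fixture(scope="session")
def reference_ring(ring_spec):
    return fixtures.make_reference_ring(ring_spec)


@pytest.fixture(scope="session")
def split_system(ring_spec):
    """Default toy assembly system: two half-rings at 5 nm with a lipid bath."""
    return fixtures.make_assembly_system(
        ring_spec, fixtures.PlugSpec(), separation=5.0, seed=0
    )


@pytest.fixture()
def single_protomer_bead():
    """One protomer bead in a cubic box — a harmonic-well workhorse."""

    def make():
        return Structure(
            bead_ids=[0],
            kinds=[int(BeadKind.protomer_bead)],
            protomer_index=[0],
            molecule_index=[0],
            leaflet=[0],
            names=np.array(["OC1"], dtype=object),
            coords=[[5.0, 5.0, 0.0]],
            box=[10.0, 10.0, 10.0],
        )

    return make
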