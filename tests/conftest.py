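import numpy as np
import pytest

import membranekit as mk

PM_OUTER = {"POPC": 0.40, "POPE": 0.10, "PPCS": 0.15, "GM3": 0.10, "CHOL": 0.25}
PM_INNER = {"POPC": 0.10, "POPE": 0.40, "POPS": 0.15, "PIP2": 0.10, "CHOL": 0.25}


@pytest.fixture(scope="session")
def pm_composition():
    return mk.CompositionSpec(outer=dict(PM_OUTER), inner=dict(PM_INNER))


@pytest.fixture(scope="session")
def pm_frame(pm_composition):
    """The 1500-lipid plasma-membrane build (asymmetric, seeded)."""
    template = mk.generate_template_bilayer(750, apl=53.3, seed=0)
    return mk.exchange_lipids(template, pm_composition, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def simple_leaflet_frame(positions_xy, species, box, leaflet="outer", box_z=100.0):
    """Hand-built single-leaflet frame with reduced beads at given positions."""
    from membranekit.synth import _leaflet_molecules

    labels = np.asarray(species, dtype=object)
    mols = _leaflet_molecules(np.asarray(positions_xy, dtype=float), labels, leaflet, box_z)
    return mk.MembraneFrame.from_molecules(mols, box=np.array([box[0], box[1], box_z]))
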