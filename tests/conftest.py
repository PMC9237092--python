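import numpy as np
import pytest

from mbrkit.structure import Frame
from mbrkit.synth import (HelixSpec, MembraneModelSpec, build_ideal_helix,
                          make_membrane)


@pytest.fixture(scope="session")
def ideal_helix():
    """15-residue canonical alpha-helix backbone."""
    return build_ideal_helix(HelixSpec("A" * 15))


@pytest.fixture(scope="session")
def extended_chain():
    return build_ideal_helix(HelixSpec("A" * 15, phi=180.0, psi=180.0))


@pytest.fixture(scope="session")
def flat_membrane():
    """Noise-free two-leaflet phosphate lattice (z = +/-20 A)."""
    return make_membrane(MembraneModelSpec(jitter_sd=0.0), seed=1)


def make_point_frame(coords, elements=None, res_ids=None, chain="A"):
    """Minimal frame from bare coordinates for geometric unit tests."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    elements = np.full(n, "C") if elements is None else np.asarray(elements)
    res_ids = np.arange(1, n + 1) if res_ids is None else np.asarray(res_ids)
    return Frame(elements, elements, res_ids, np.full(n, "UNK"),
                 np.full(n, chain), coords)
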