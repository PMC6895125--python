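"""Shared fixtures: calibrated synthetic morphologies and preset models.

Session-scoped because input-resistance calibration and model assembly are
the expensive steps; every test that only reads from a model can share them.
"""

import numpy as np
import pytest

from dendrinh.morphology import (Morphology, SwcNode, Structure, discretize,
                                 generate_synthetic_morphology)
from dendrinh.model import preset_cell_model


@pytest.fixture(scope="session")
def pvi_morph():
    return generate_synthetic_morphology("PVI", seed=1)


@pytest.fixture(scope="session")
def gc_morph():
    return generate_synthetic_morphology("GC", seed=1)


@pytest.fixture(scope="session")
def pvi_seg(pvi_morph):
    return discretize(pvi_morph)


@pytest.fixture(scope="session")
def gc_seg(gc_morph):
    return discretize(gc_morph)


@pytest.fixture(scope="session")
def pvi_passive(pvi_seg):
    return preset_cell_model(pvi_seg, "PVI", passive_only=True)


@pytest.fixture(scope="session")
def gc_passive(gc_seg):
    return preset_cell_model(gc_seg, "GC", passive_only=True)


@pytest.fixture(scope="session")
def pvi_active(pvi_seg):
    return preset_cell_model(pvi_seg, "PVI")


@pytest.fixture(scope="session")
def gc_active(gc_seg):
    return preset_cell_model(gc_seg, "GC")


@pytest.fixture(scope="session")
def pvi_spiking(pvi_seg):
    return preset_cell_model(pvi_seg, "PVI", spiking=True)


@pytest.fixture(scope="session")
def gc_spiking(gc_seg):
    return preset_cell_model(gc_seg, "GC", spiking=True)


def straight_cable(n_nodes: int, spacing_um: float, radius_um: float,
                   soma_radius_um: float = 5.0) -> Morphology:
    """Unbranched soma + dendrite chain along +y (helper for cable oracles)."""
    nodes = [SwcNode(1, Structure.SOMA, 0, 0, 0, soma_radius_um, None)]
    for i in range(n_nodes):
        nodes.append(SwcNode(i + 2, Structure.DENDRITE,
                             0.0, (i + 1) * spacing_um, 0.0, radius_um,
                             i + 1))
    return Morphology(nodes)
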