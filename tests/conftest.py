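import numpy as np
import pytest

from bgcausal import RegionSet, StudyDesign
from bgcausal.synthdata import CouplingSpec, GroundTruthGraph, generate_study


@pytest.fixture
def two_regions() -> RegionSet:
    return RegionSet(("X", "Y"))


@pytest.fixture
def small_design() -> StudyDesign:
    return StudyDesign(n_subjects=2, blocks_per_condition=1, block_length=60)


@pytest.fixture
def small_study(small_design):
    """A 2-subject, 2-condition toy study with one planted linear link."""
    regions = RegionSet(("X", "Y", "Z"))
    link = CouplingSpec("X", "Y", 1, "linear", 0.6)
    graphs = {
        "motor": GroundTruthGraph((link,), "motor"),
        "resting": GroundTruthGraph((link,), "resting"),
    }
    return generate_study(small_design, graphs, region_set=regions, seed=7)


def ar1_channels(n: int, n_channels: int, coeff: float, seed: int) -> np.ndarray:
    """Independent AR(1) channels via the synthetic generator."""
    from bgcausal.synthdata import generate_block

    regions = RegionSet(tuple(f"R{i}" for i in range(n_channels)))
    return generate_block(regions, [], n, autocorr=coeff, seed=seed)
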