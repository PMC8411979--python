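import numpy as np
import pytest

from bpval import geometry
from bpval.synthetic import PairSpec, build_duplex, build_pair


@pytest.fixture(scope="session")
def standards():
    return geometry.standard_bases()


@pytest.fixture(scope="session")
def ideal_gc_pair():
    """A coplanar G-C pair with all six simple parameters at zero."""
    return build_pair(PairSpec(category="DNA-DNA", pair_type="G-C"))


@pytest.fixture(scope="session")
def gc_duplex():
    """Four stacked ideal G-C pairs (B-form rise/twist)."""
    return build_duplex(4, specs=[PairSpec(category="DNA-DNA", pair_type="G-C")] * 4,
                        rise=3.4, twist=36.0)


def measure_pair(structure):
    """Simple parameters of a two-residue pair structure (purine first)."""
    res_i, res_j = structure.residues
    frame_i = geometry.base_frame(res_i)
    frame_j = geometry.base_frame(res_j)
    return geometry.simple_parameters(frame_i, frame_j,
                                      res_i.atom("C1'").position,
                                      res_j.atom("C1'").position)


@pytest.fixture(scope="session")
def measure():
    return measure_pair
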