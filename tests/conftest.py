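import numpy as np
import pytest

import tol2sites as t

STUDY_FEATURE_SPEC = [
    ("sv40_polyA", 0.10, 0.64),
    ("ampR", 0.25, 0.50),
    ("ori", 0.15, 0.50),
    ("backbone", 0.50, 0.50),
]


@pytest.fixture(scope="session")
def study_plasmid() -> t.TargetPlasmid:
    """A 4-kb synthetic stand-in for the circular target plasmid, with a
    64 %-AT SV40 polyA segment and three 50 %-AT features."""
    return t.make_target_plasmid(4000, STUDY_FEATURE_SPEC, seed=7)


@pytest.fixture(scope="session")
def tiled_plasmid() -> t.TargetPlasmid:
    """2 kb, four equal features tiling the whole circle (null-model fixture)."""
    spec = [(f"f{i}", 0.25, 0.5) for i in range(1, 5)]
    return t.make_target_plasmid(2000, spec, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
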