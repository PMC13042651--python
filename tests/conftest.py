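"""Shared fixtures: all inputs are generated programmatically, no data files."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from segremodel.core import SegmentSpec
from segremodel.fixtures import FixtureSpec, make_paired_sheet, make_toy_protein

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helix_fixture():
    """Coil-flanked 12-residue ideal alpha helix (single chain)."""
    return make_toy_protein(FixtureSpec(blocks=(("C", 4), ("H", 12), ("C", 4)),
                                        seed=1))


@pytest.fixture(scope="session")
def sheet_fixture():
    """Two 8-residue antiparallel ideal strands (chains A and B)."""
    return make_paired_sheet(8, seed=2)


@pytest.fixture(scope="session")
def scaffold():
    """Helix-coil-helix scaffold whose middle 12 residues are the design
    segment used across backbone/sequence/evaluation tests."""
    structure, gt = make_toy_protein(
        FixtureSpec(blocks=(("H", 10), ("C", 12), ("H", 10)), seed=3))
    return structure


@pytest.fixture(scope="session")
def scaffold_spec_h():
    return SegmentSpec("A", 11, 22, "H")


@pytest.fixture(scope="session")
def scaffold_spec_e():
    return SegmentSpec("A", 11, 22, "E")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
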