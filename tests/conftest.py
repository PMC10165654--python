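"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from mwnuc import core_md as cm
from mwnuc import synthetic as syn


@pytest.fixture(scope="session")
def mw_params():
    return cm.MWParams()


@pytest.fixture(scope="session")
def cubic_lattice():
    return syn.build_lattice(syn.LatticeSpec(polymorph="cubic-diamond",
                                             cells=(3, 3, 3), density=0.98))


@pytest.fixture(scope="session")
def hex_lattice():
    return syn.build_lattice(syn.LatticeSpec(polymorph="hexagonal-diamond",
                                             cells=(3, 3, 3), density=0.98))


@pytest.fixture(scope="session")
def liquid_270():
    """Equilibrated mW liquid at the warm training state point."""
    return syn.generate_liquid(216, 0.98, 270.9, seed=5)


@pytest.fixture(scope="session")
def liquid_218():
    """Deeply supercooled mW liquid (biased-sampling state point)."""
    return syn.generate_liquid(216, 0.99, 218.0, seed=11)


@pytest.fixture(scope="session")
def random_small_config():
    """30 random particles in a periodic box large enough for the cutoff."""
    rng = np.random.default_rng(0)
    return cm.Configuration(rng.uniform(0, 12, (30, 3)), [12.0, 12.0, 12.0])


@pytest.fixture(scope="session")
def small_corpus(liquid_270):
    """A dozen decorrelated mW liquid snapshots with reference labels."""
    from mwnuc import nnp

    mw = cm.MWPotential()
    cfg = cm.draw_velocities(liquid_270, 270.9, 3)
    st = cm.make_state(cfg)
    out = []
    for k in range(12):
        st = cm.integrate_nvt(st, 400, 4.0, 270.9, damping=0.5, seed=20 + k)
        snap = st.config.copy()
        snap.velocities = None
        U, F, W = mw.evaluate(snap)
        out.append(nnp.CorpusEntry(snap, U, F, W, (0.98, 270.9)))
    return out
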