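import numpy as np
import pytest

from ionlayer import (
    CutoffScheme,
    LatticeSpec,
    SimBox,
    Trajectory,
    build_headgroups,
    build_lattice,
    builtin_forcefield,
)


@pytest.fixture(scope="session")
def li_ff():
    return builtin_forcefield("li_tip3p")


@pytest.fixture
def small_headgroups():
    lat = build_lattice(LatticeSpec(4, 3, spacing=0.497))
    return build_headgroups(lat, height=0.5, seed=7)


@pytest.fixture
def default_cutoffs():
    return CutoffScheme(0.30, 0.42, 0.59)


@pytest.fixture
def tiny_trajectory():
    """Three ions + two headgroup carbons over two frames in a slab box."""
    box = SimBox(6.0, 6.0, 6.0)
    frames = np.array(
        [
            [[1.0, 1.0, 0.5], [3.0, 3.0, 0.5],
             [1.0, 1.0, 0.8], [3.0, 3.0, 1.0], [5.0, 5.0, 5.0]],
            [[1.0, 1.0, 0.5], [3.0, 3.0, 0.5],
             [1.1, 1.0, 0.8], [3.0, 3.1, 1.0], [5.0, 5.0, 4.0]],
        ]
    )
    labels = ["C", "C", "Ca2+", "Ca2+", "Ca2+"]
    return Trajectory(frames, labels, box, dt_out=10.0)
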