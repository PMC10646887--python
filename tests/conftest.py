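import numpy as np
import pytest

from mdbind.core import Frame, Topology, Trajectory


@pytest.fixture
def water_topology():
    """Three-atom water-like topology with one donor/acceptor oxygen."""
    return Topology(
        elements=["O", "H", "H"],
        bonds=[(0, 1), (0, 2)],
        charges=[-0.8, 0.4, 0.4],
        epsilon=[0.15, 0.0, 0.0],
        rmin_half=[1.7, 0.2, 0.2],
        donor=np.array([1, 0, 0], bool),
        acceptor=np.array([1, 0, 0], bool),
        groups={"WAT": frozenset({0, 1, 2})},
    )


@pytest.fixture
def ten_atom_topology():
    rng = np.random.default_rng(42)
    return Topology(
        elements=["C", "N", "O", "C", "N", "O", "C", "N", "O", "C"],
        masses=rng.uniform(1.0, 20.0, 10),
        charges=rng.uniform(-0.5, 0.5, 10),
        epsilon=np.full(10, 0.1),
        rmin_half=np.full(10, 1.8),
        groups={
            "NP": frozenset({0, 1}),
            "FR": frozenset({2, 3, 4, 5}),
            "LIG": frozenset({4, 5, 6}),
        },
    )


def make_trajectory(coords_per_frame, topology, box=None):
    frames = [
        Frame(np.asarray(c, dtype=float), box=box, time=float(t))
        for t, c in enumerate(coords_per_frame)
    ]
    return Trajectory(frames=frames, topology=topology)


@pytest.fixture
def harmonic_umbrella_set():
    """Session-scoped umbrella sampling run on a known harmonic potential."""
    from mdbind import synthetic as syn

    potential = syn.Potential1D.harmonic(2.0, 5.0)
    return syn.generate_umbrella_set(
        potential,
        centers=5.0 + np.arange(11) - 5.0,
        samples_per_window=10_000,
        seed=2024,
    )
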