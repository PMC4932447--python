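"""Shared fixtures: toy segments with hand-computable statistics, small
constructs, and a small harmonic network used across test modules."""

import numpy as np
import pytest

from ecdyn.traj_model import AtomRecord, TrajectorySegment, alpha_synuclein_sequence


def make_atoms(n, chain_id="A", name="CA", element="C"):
    return [AtomRecord(i, name, element, i + 1, "ALA", chain_id)
            for i in range(n)]


@pytest.fixture(scope="session")
def alpha_seq():
    return alpha_synuclein_sequence()


@pytest.fixture
def correlated_pair_segment():
    """Two atoms translating together along x; deviations ±(1,0,0,1,0,0)."""
    atoms = make_atoms(2)
    coords = np.array([[[0, 0, 0], [1, 0, 0]],
                       [[2, 0, 0], [3, 0, 0]]], dtype=float)
    return TrajectorySegment(coords, atoms, frame_interval=1.0)


@pytest.fixture
def anticorrelated_pair_segment():
    """Two atoms moving oppositely along x; deviations ±(1,0,0,-1,0,0)."""
    atoms = make_atoms(2)
    coords = np.array([[[1, 0, 0], [-1, 0, 0]],
                       [[-1, 0, 0], [1, 0, 0]]], dtype=float)
    return TrajectorySegment(coords, atoms, frame_interval=1.0)


def random_segment(rng, n_frames=12, n_atoms=5, chains=("A",), spread=0.3):
    """A generic random-walk-free random trajectory for property tests."""
    n_per = n_atoms // len(chains) or 1
    atoms = []
    for c in chains:
        base = len(atoms)
        for i in range(n_per):
            atoms.append(AtomRecord(base + i, "CA", "C", i + 1, "ALA", c))
    base_coords = rng.uniform(-1, 1, size=(len(atoms), 3))
    coords = base_coords[None] + spread * rng.standard_normal(
        (n_frames, len(atoms), 3))
    return TrajectorySegment(coords, atoms, frame_interval=1.0)


@pytest.fixture(scope="session")
def small_dimer_construct():
    from ecdyn.construct_builder import ConstructSpec, assemble_construct

    seq = alpha_synuclein_sequence()[:20]
    return assemble_construct(ConstructSpec(
        kind="dimer", sequence=seq, dimer_arrangement="HH1"))


@pytest.fixture(scope="session")
def chain_network():
    """A 12-site single-chain block/linker network with known covariance."""
    from ecdyn.construct_builder import ConstructSpec, assemble_construct
    from ecdyn.synthetic_dynamics import (
        BlockPlan, BlockSpec, model_from_construct)

    seq = alpha_synuclein_sequence()[:12]
    model = assemble_construct(ConstructSpec(kind="monomer", sequence=seq))
    plan = BlockPlan(
        blocks=(BlockSpec("A", 1, 5, "rigid-block"),
                BlockSpec("A", 6, 8, "linker"),
                BlockSpec("A", 9, 12, "rigid-block")),
        k_block=500.0, k_linker=50.0, cutoff=1.0)
    return model_from_construct(model, plan, friction=10.0)
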