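import numpy as np
import pytest

from camstates.structure_io import AtomRecord, Ensemble, Topology
from camstates.synthetic_data import SyntheticConfig, build_backbone, default_state_plan


def chain_ensemble(coords_per_residue: np.ndarray) -> Ensemble:
    """Wrap (n_res, 5, 3) backbone coordinates as a single-frame ensemble."""
    atoms, serial = [], 1
    names = ("N", "CA", "C", "O", "CB")
    elems = ("N", "C", "C", "O", "C")
    for r in range(coords_per_residue.shape[0]):
        for name, elem in zip(names, elems):
            atoms.append(AtomRecord(serial, name, elem, "ALA", r + 1, "A"))
            serial += 1
    return Ensemble(Topology(atoms), coords_per_residue.reshape(1, -1, 3))


@pytest.fixture
def ideal_helix():
    """Single-frame 12-residue ideal alpha-helix."""
    return chain_ensemble(build_backbone([(-57.0, -47.0)] * 12))


@pytest.fixture
def extended_chain():
    """Single-frame 12-residue extended chain (no H-bond partners)."""
    return chain_ensemble(build_backbone([(-120.0, 120.0)] * 12))


@pytest.fixture
def frozen_config():
    """Noise-free, wobble-free single-state config (deterministic geometry)."""
    return SyntheticConfig(
        n_frames=4,
        coord_noise_sd=0.0,
        lobe_wobble_deg=0.0,
        planted_states=default_state_plan(1),
        seed=7,
    )


@pytest.fixture
def small_default_config():
    """Default study conditions at a reduced frame count for unit tests."""
    return SyntheticConfig(n_frames=80, seed=5)
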