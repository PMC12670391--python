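import numpy as np
import pytest

from pfklab.core import BeadStructure


def make_structure(n_residues, chain_id="A", resname="GLY", name="BB",
                   coords=None, spacing=0.35, start_resnum=1):
    """Linear bead chain, one bead per residue."""
    n = n_residues
    if coords is None:
        coords = np.zeros((n, 3))
        coords[:, 2] = spacing * np.arange(n)
    return BeadStructure(
        particle_ids=np.arange(1, n + 1),
        names=np.array([name] * n),
        residue_names=np.array([resname] * n),
        residue_numbers=np.arange(start_resnum, start_resnum + n),
        chain_ids=np.array([chain_id] * n),
        coords=np.asarray(coords, dtype=float),
        masses=np.full(n, 72.0),
        radii=np.full(n, 0.235),
    )


def merge_structures(*structures):
    return BeadStructure(
        particle_ids=np.arange(
            1, 1 + sum(s.n_particles for s in structures)),
        names=np.concatenate([s.names for s in structures]),
        residue_names=np.concatenate([s.residue_names for s in structures]),
        residue_numbers=np.concatenate(
            [s.residue_numbers for s in structures]),
        chain_ids=np.concatenate([s.chain_ids for s in structures]),
        coords=np.concatenate([s.coords for s in structures]),
        masses=np.concatenate([s.masses for s in structures]),
        radii=np.concatenate([s.radii for s in structures]),
    )


@pytest.fixture
def monomer_780():
    """Toy monomer numbered 1..780, mirroring full-length numbering."""
    return make_structure(780)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
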