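import numpy as np
import pytest

from topoddg.structure_io import Atom, Structure

# Residue heavy-atom rosters for the hand-built fixtures.
_RESIDUE_ATOMS = {
    "ALA": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")],
    "GLY": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")],
    "SER": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OG", "O")],
}


def make_structure(residues, partition=None, sid="FIX"):
    """Build a structure from (chain, res_seq, res_name, center) tuples.

    Each residue's atoms are placed at small fixed offsets around its
    center so distances between residues are controlled by the centers.
    """
    offsets = {
        "N": np.array([-0.7, 0.6, 0.0]),
        "CA": np.zeros(3),
        "C": np.array([0.8, 0.5, 0.0]),
        "O": np.array([1.0, 1.4, 0.3]),
        "CB": np.array([0.2, -1.0, 0.9]),
        "OG": np.array([0.3, -1.9, 1.6]),
    }
    atoms = []
    for chain, res_seq, res_name, center in residues:
        for name, element in _RESIDUE_ATOMS[res_name]:
            atoms.append(
                Atom(
                    element=element,
                    coords=np.asarray(center, dtype=float) + offsets[name],
                    chain=chain,
                    res_seq=str(res_seq),
                    res_name=res_name,
                    name=name,
                    b_factor=20.0,
                )
            )
    return Structure(sid, atoms, partition or {})


@pytest.fixture
def toy_two_residue_complex():
    """One ALA per chain, CA–CA distance 8 Å along x."""
    return make_structure(
        [("A", 1, "ALA", (0, 0, 0)), ("B", 1, "ALA", (8, 0, 0))],
        partition={"A": "P1", "B": "P2"},
    )


@pytest.fixture
def equilateral_distance():
    return np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])


@pytest.fixture(scope="session")
def toy_dimer():
    from topoddg.synthetic import ToyDimerConfig, make_toy_dimer

    return make_toy_dimer(ToyDimerConfig(residues_per_chain=20, interface_contacts=5, seed=3))


def random_cloud(seed, n_min=4, n_max=12, scale=2.0):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    return rng.uniform(0.0, scale, size=(n, 3)), rng
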