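import numpy as np
import pytest

import hingeflex as hf


@pytest.fixture(scope="session")
def toy_hinge():
    return hf.make_toy_hinge()


@pytest.fixture(scope="session")
def duplex18():
    return hf.build_bdna_duplex("ATGCATGCATGCATGCAT")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def central_difference_forces(energy_fn, positions, eps=1e-5):
    """Independent numerical gradient oracle: -dE/dr by central differences."""
    positions = np.asarray(positions, dtype=float)
    out = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for ax in range(3):
            pp = positions.copy()
            pm = positions.copy()
            pp[i, ax] += eps
            pm[i, ax] -= eps
            out[i, ax] = -(energy_fn(pp) - energy_fn(pm)) / (2 * eps)
    return out


def helix_pdb_text(n_residues=20, chain="A", start_res=1):
    """A toy alpha-helical CA trace written as PDB text, with the coordinate
    list returned alongside for independent comparison."""
    coords = []
    lines = []
    serial = 1
    for j in range(n_residues):
        x = 2.3 * np.cos(np.deg2rad(100.0 * j))
        y = 2.3 * np.sin(np.deg2rad(100.0 * j))
        z = 1.5 * j
        coords.append((x, y, z))
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA {chain}{start_res + j:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n", np.array(coords)
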