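import numpy as np
import pytest

from ensavg.structure_io import Atom, Structure


def ca_structure(xs, label="toy", chain="A", res_name="ALA"):
    """CA-only structure from an (n, 3) coordinate array, residues 1..n."""
    xs = np.asarray(xs, float)
    atoms = [Atom(chain, i + 1, res_name, "CA", "C", tuple(x))
             for i, x in enumerate(xs)]
    return Structure(atoms=atoms, label=label)


def cb_structure(pairs, label="toy"):
    """Structure with one CA+CB per residue from [(ca_xyz, cb_xyz), ...]."""
    atoms = []
    for i, (ca, cb) in enumerate(pairs):
        atoms.append(Atom("A", i + 1, "ALA", "CA", "C", tuple(ca)))
        atoms.append(Atom("A", i + 1, "ALA", "CB", "C", tuple(cb)))
    return Structure(atoms=atoms, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def line_structure():
    """10 CA atoms along x, 3.8 Å apart (collinear on purpose)."""
    return ca_structure([[3.8 * i, 0.0, 0.0] for i in range(10)])


@pytest.fixture
def folded_structure(rng):
    """Non-degenerate 8-residue CA trace used across geometry tests."""
    from ensavg.synthetic import ToySpec, make_toy_native
    return make_toy_native(ToySpec(n_residues=8, seed=99))
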