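import numpy as np
import pytest

from omtkit.structio import Atom, Ensemble, Frame


def make_frame(coords, index=1, names=None, chain="A", resseq_per_atom=None):
    """Build a Frame from an (n, 3) coordinate array with simple metadata."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = names or [f"C{i+1}" for i in range(n)]
    resseqs = resseq_per_atom or [1] * n
    atoms = [
        Atom(serial=i + 1, name=names[i], resname="GLY", chain=chain,
             resseq=resseqs[i], xyz=coords[i], element=names[i][0])
        for i in range(n)
    ]
    return Frame(index=index, atoms=atoms)


def random_rigid(rng):
    """A random proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def square_frame():
    """Four atoms at the corners of a unit-ish cross, centroid at origin."""
    return make_frame([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]],
                      names=["N", "CA", "C", "O"], resseq_per_atom=[1, 1, 2, 2])


@pytest.fixture
def tiny_ensemble(square_frame):
    f2 = make_frame([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]],
                    index=2, names=["N", "CA", "C", "O"], resseq_per_atom=[1, 1, 2, 2])
    return Ensemble(frames=[square_frame, f2])
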