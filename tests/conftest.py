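import numpy as np
import pytest

from mdinfonet import synthetic as syn
from mdinfonet.trajio import AtomRecord, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_gaussian_traj():
    """Uncorrelated 10-residue Gaussian ensemble, 200 frames."""
    traj, gt = syn.gen_gaussian_traj(
        syn.GaussianTrajSpec(n_res=10, n_frames=200, sigma=0.4, seed=7))
    return traj


@pytest.fixture
def blocked_gaussian_traj():
    """20 residues with a rho=0.9 correlated block far from the rest."""
    spec = syn.GaussianTrajSpec(
        n_res=20, n_frames=3000, sigma=0.5, seed=11,
        blocks=[syn.CorrelationBlock(residues=[2, 3, 4], rho=0.9)])
    return syn.gen_gaussian_traj(spec)


def make_traj(coords, names=None, elements=None, res_ids=None,
              res_names=None, chain="A"):
    """Hand-build a Trajectory from (frames, atoms, 3) coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    names = names or ["CA"] * n
    elements = elements or [nm[0] for nm in names]
    res_ids = res_ids if res_ids is not None else list(range(1, n + 1))
    res_names = res_names or ["ALA"] * n
    atoms = [AtomRecord(serial=i + 1, name=names[i], element=elements[i],
                        res_name=res_names[i], res_id=res_ids[i], chain=chain)
             for i in range(n)]
    return Trajectory(atoms=atoms, coords=coords)


@pytest.fixture
def make_trajectory():
    return make_traj


def random_rigid_motion(rng):
    """A random proper rotation + translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(2**31)))).as_matrix()
    t = rng.normal(scale=5.0, size=3)
    return R, t
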