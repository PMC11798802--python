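import numpy as np
import pytest

from ensemblepharm.structure_io import ConformationEnsemble, SiteDefinition


def make_toy_ensemble(n_frames=2, jitter=0.0, seed=0, transform=None):
    """Tiny two-residue protein fragment (GLY backbone + ASP) replicated
    across frames, optionally jittered and rigidly moved per frame."""
    rng = np.random.default_rng(seed)
    atoms = [
        # (element, name, res_id, res_name)
        ("N", "N", 10, "GLY"), ("C", "CA", 10, "GLY"),
        ("C", "C", 10, "GLY"), ("O", "O", 10, "GLY"),
        ("N", "N", 11, "ASP"), ("C", "CA", 11, "ASP"),
        ("C", "C", 11, "ASP"), ("O", "O", 11, "ASP"),
        ("C", "CB", 11, "ASP"), ("C", "CG", 11, "ASP"),
        ("O", "OD1", 11, "ASP"), ("O", "OD2", 11, "ASP"),
    ]
    base = np.array([
        [0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.2, 1.3, 0.0], [1.6, 2.4, 0.0],
        [3.5, 1.3, 0.1], [4.3, 2.5, 0.2], [5.8, 2.3, 0.2], [6.5, 3.3, 0.4],
        [3.9, 3.8, 1.3], [4.5, 5.1, 1.8], [5.7, 5.3, 1.9], [3.8, 6.1, 2.2],
    ])
    coords = np.stack([
        base + rng.normal(scale=jitter, size=base.shape)
        for _ in range(n_frames)])
    if transform is not None:
        for f in range(1, n_frames):
            coords[f] = transform(coords[f], f)
    el, nm, rid, rnm = zip(*atoms)
    return ConformationEnsemble(
        coords=coords, elements=np.array(el), atom_names=np.array(nm),
        res_ids=np.array(rid), res_names=np.array(rnm),
        chain_ids=np.array(["A"] * len(atoms)))


@pytest.fixture
def toy_ensemble():
    return make_toy_ensemble(n_frames=2)


@pytest.fixture
def toy_site():
    return SiteDefinition(mode="residue_list", residues=[("A", 10), ("A", 11)])


def random_rigid(rng):
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(rng=rng)
    t = rng.uniform(-10, 10, size=3)
    return lambda x: rot.apply(x) + t


def kabsch_oracle_rmsd(mobile, target):
    """Closed-form Kabsch RMSD, written directly from the SVD construction
    (independent of the package's superposition code path)."""
    P = mobile - mobile.mean(axis=0)
    Q = target - target.mean(axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = (R @ P.T).T
    return float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
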