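import numpy as np
import pytest

import helixcheck as hx


@pytest.fixture(scope="session")
def helix10():
    return hx.build_ideal_helix(10, -60.0, -45.0)


@pytest.fixture(scope="session")
def helix20():
    return hx.build_ideal_helix(20, -60.0, -45.0)


@pytest.fixture(scope="session")
def two_chain_complex():
    """Backbone-only two-helix complex, chains A and B, crossing at 47°."""
    return hx.build_bundle([20, 20], 47.0, separation=7.0)


@pytest.fixture(scope="session")
def talos30():
    return hx.synth_talos_records(30, n_tail=8, seed=11, angle_sigma=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_dihedral(p0, p1, p2, p3):
    """Independent torsion formulation: plane normals + signed acos."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return float(ang)


def brute_force_kabsch_rmsd(ref, mob):
    """Independent SVD Kabsch: returns minimum RMSD of mob onto ref."""
    ref = np.asarray(ref, float)
    mob = np.asarray(mob, float)
    q = ref - ref.mean(axis=0)
    p = mob - mob.mean(axis=0)
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return float(np.sqrt(np.mean(np.sum((p @ r.T - q) ** 2, axis=1))))
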