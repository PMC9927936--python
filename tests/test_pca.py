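import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gpcrtraj import (
    BWTable,
    MOUSE_ETAR_BW,
    extracellular_half_selection,
    fit_pca,
    planted_motion_trajectory,
    project,
    select_atoms,
    superpose,
)
from gpcrtraj.pca import rmsd
from conftest import simple_trajectory


def _horn_quaternion_rmsd(ref, mov):
    """Closed-form least-squares RMSD via Horn's quaternion method —
    an oracle independent of the SVD/Kabsch route used by superpose."""
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    M = mov_c.T @ ref_c
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(K)[-1]
    sq = (ref_c**2).sum() + (mov_c**2).sum() - 2.0 * lam_max
    return float(np.sqrt(max(sq, 0.0) / ref.shape[0]))


@pytest.fixture(scope="module")
def random_traj():
    rng = np.random.default_rng(12)
    coords = rng.uniform(-10, 10, (15, 12, 3))
    return simple_trajectory(coords)


def test_superpose_identity_is_noop(random_traj):
    fit = select_atoms(random_traj)
    aligned = superpose(random_traj, random_traj.frame(0), fit)
    assert rmsd(aligned.coords[0], random_traj.coords[0]) < 1e-9


def test_superpose_removes_rigid_motion(random_traj):
    # every frame is a rigidly moved copy of the reference conformation
    ref_coords = random_traj.coords[0]
    rng = np.random.default_rng(4)
    moved = random_traj.with_coords(
        np.stack([
            Rotation.random(rng=rng).apply(ref_coords) + rng.uniform(-30, 30, 3)
            for _ in range(10)
        ])
    )
    aligned = superpose(moved, random_traj.frame(0), select_atoms(random_traj))
    for t in range(10):
        assert rmsd(aligned.coords[t], ref_coords) < 1e-9


def test_superpose_matches_quaternion_oracle(random_traj):
    rng = np.random.default_rng(3)
    perturbed = random_traj.with_coords(
        random_traj.coords + rng.normal(0, 0.8, random_traj.coords.shape)
    )
    fit = select_atoms(random_traj)
    ref = random_traj.frame(0)
    aligned = superpose(perturbed, ref, fit)
    for t in range(random_traj.n_frames):
        got = rmsd(aligned.coords[t], random_traj.coords[0])
        oracle = _horn_quaternion_rmsd(random_traj.coords[0], perturbed.coords[t])
        assert got == pytest.approx(oracle, abs=1e-9)
        # least-squares: fitted RMSD never exceeds the unfitted one
        assert got <= rmsd(perturbed.coords[t], random_traj.coords[0]) + 1e-12


def test_superpose_rejects_degenerate_fit_set():
    coords = np.zeros((2, 3, 3))
    coords[:, :, 0] = [0.0, 1.0, 2.0]  # collinear atoms
    traj = simple_trajectory(coords)
    with pytest.raises(ValueError, match="collinear|degenerate"):
        superpose(traj, traj.frame(0), select_atoms(traj))
    with pytest.raises(ValueError, match="at least 3"):
        superpose(traj, traj.frame(0), select_atoms(traj, residue_id=[1, 2]))


def test_fit_pca_single_planted_motion():
    traj, dirs, amps = planted_motion_trajectory(
        n_frames=500, variances=(2.5,), n_atoms=20, seed=1
    )
    model = fit_pca(traj, select_atoms(traj))
    assert model.eigenvalues[0] == pytest.approx(np.var(amps[:, 0], ddof=1), rel=1e-9)
    assert model.eigenvalues[1] < 1e-10 * model.eigenvalues[0]
    assert abs(dirs[0] @ model.components[0]) > 0.999999


def test_fit_pca_degenerate_inputs():
    frames = np.repeat(np.random.default_rng(0).uniform(-5, 5, (1, 8, 3)), 6, axis=0)
    traj = simple_trajectory(frames)
    model = fit_pca(traj, select_atoms(traj))
    assert np.all(model.eigenvalues < 1e-18)
    with pytest.raises(ValueError, match="at least 2"):
        fit_pca(simple_trajectory(frames[:1]), select_atoms(traj))


def test_eigenvalue_sum_conserves_total_variance(random_traj):
    model = fit_pca(random_traj, select_atoms(random_traj))
    X = random_traj.coords.reshape(random_traj.n_frames, -1)
    total = np.var(X, axis=0, ddof=1).sum()
    assert model.eigenvalues.sum() == pytest.approx(total, rel=1e-9)


def test_fit_pca_cross_checked_against_sklearn(random_traj):
    from sklearn.decomposition import PCA as SkPCA

    model = fit_pca(random_traj, select_atoms(random_traj))
    X = random_traj.coords.reshape(random_traj.n_frames, -1)
    sk = SkPCA().fit(X)
    k = sk.explained_variance_.size
    assert np.allclose(model.eigenvalues[:k], sk.explained_variance_, atol=1e-9)


def test_projection_completeness_and_zero_mean(random_traj):
    model = fit_pca(random_traj, select_atoms(random_traj))
    proj = project(model, random_traj)
    assert np.allclose(proj.mean(axis=0), 0.0, atol=1e-9)
    recon = model.mean_coords + proj @ model.components
    assert np.max(np.abs(recon - random_traj.coords.reshape(15, -1))) < 1e-6
    mean_traj = random_traj.with_coords(
        np.broadcast_to(
            model.mean_coords.reshape(1, -1, 3), (1, random_traj.n_atoms, 3)
        ).copy()
    )
    assert np.allclose(project(model, mean_traj), 0.0, atol=1e-9)
    with pytest.raises(ValueError, match="out of range"):
        project(model, random_traj, [10_000])


def test_projection_separates_planted_clusters():
    rng = np.random.default_rng(6)
    base = rng.uniform(-8, 8, (10, 3))
    direction = np.zeros(30)
    direction[::3] = 1.0
    direction /= np.linalg.norm(direction)
    labels = rng.random(200) < 0.5
    offsets = np.where(labels, 4.0, -4.0)  # planted separation 8 along one axis
    flat = base.reshape(-1) + offsets[:, None] * direction
    coords = flat.reshape(200, 10, 3) + rng.normal(0, 0.05, (200, 10, 3))
    traj = simple_trajectory(coords)
    model = fit_pca(traj, select_atoms(traj))
    pc1 = project(model, traj, [0])[:, 0]
    gap = abs(pc1[labels].mean() - pc1[~labels].mean())
    assert gap == pytest.approx(8.0, rel=0.05)
    assert (pc1[labels] > 0).all() != (pc1[~labels] > 0).all()


def test_pca_equivariant_under_global_rigid_motion(random_traj):
    model = fit_pca(random_traj, select_atoms(random_traj))
    rot = Rotation.from_euler("xyz", [30, -20, 75], degrees=True)
    moved = random_traj.with_coords(
        np.stack([rot.apply(f) + [3.0, -7.0, 1.0] for f in random_traj.coords])
    )
    model2 = fit_pca(moved, select_atoms(moved))
    assert np.allclose(model.eigenvalues, model2.eigenvalues, atol=1e-9)


def test_extracellular_half_selection_midpoint_rule(small_synthetic):
    _, traj, _ = small_synthetic
    toy = BWTable(
        anchors={6: 321},
        helix_ranges={6: (296, 329)},
        extracellular_is_cterm={6: True},
    )
    sel = extracellular_half_selection(toy, traj, helices=(6,))
    residues = {traj.topology[i].residue_id for i in sel}
    assert 329 in residues and 296 not in residues
    assert residues == set(range((296 + 329) // 2, 330))
    assert len(extracellular_half_selection(toy, traj, helices=())) == 0
    with pytest.raises(ValueError, match="helix 5"):
        extracellular_half_selection(toy, traj, helices=(5,))


def test_extracellular_half_honours_published_cut(small_synthetic):
    # TM6 cytoplasmic half ends at 6.47 (C318) -> extracellular half starts at W319
    _, traj, _ = small_synthetic
    sel = extracellular_half_selection(MOUSE_ETAR_BW, traj, helices=(6,))
    residues = sorted(traj.topology[i].residue_id for i in sel)
    assert residues[0] == 319 and residues[-1] == 331
    # selection contains only CA atoms of the named helices
    full = extracellular_half_selection(MOUSE_ETAR_BW, traj)
    for i in full:
        rec = traj.topology[i]
        assert rec.atom_name == "CA"
        lo2, hi2 = MOUSE_ETAR_BW.helix_ranges[2]
        lo6, hi6 = MOUSE_ETAR_BW.helix_ranges[6]
        lo7, hi7 = MOUSE_ETAR_BW.helix_ranges[7]
        assert (lo2 <= rec.residue_id <= hi2 or lo6 <= rec.residue_id <= hi6
                or lo7 <= rec.residue_id <= hi7)
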