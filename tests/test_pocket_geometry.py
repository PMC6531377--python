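"""RMSF/B-factor, spatial distribution, pocket volume, state projection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from gpcrdyn import (Topology, TrajectoryEnsemble, compute_rmsf,
                     pocket_volume, rmsf_to_bfactor, spatial_distribution,
                     state_projection)
from gpcrdyn.synthetic_data import ToyReceptorSpec, gen_toy_trajectory


def _point_cloud_topology(n, ligand_first=False):
    lig = np.zeros(n, dtype=bool)
    if ligand_first:
        lig[0] = True
    return Topology(
        atom_names=np.array([f"C{i}" for i in range(n)], dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        res_ids=np.arange(1, n + 1),
        res_names=np.array(["LIG" if m else "ALA" for m in lig], dtype=object),
        chains=np.array(["A"] * n, dtype=object),
        ligand_mask=lig)


# --- RMSF / B-factor ------------------------------------------------------

def test_static_trajectory_zero_rmsf():
    coords = np.repeat(np.random.default_rng(0).normal(
        size=(1, 20, 3)), 10, axis=0)
    ens = TrajectoryEnsemble(runs=[coords])
    rmsf = compute_rmsf(ens, np.arange(20))
    np.testing.assert_allclose(rmsf, 0.0, atol=1e-10)


def test_isotropic_jitter_rmsf_matches_chi_expectation(toy_jitter_fixture):
    fix = toy_jitter_fixture
    heavy = np.nonzero(~fix.topology.ligand_mask)[0]
    rmsf = compute_rmsf(fix.ensemble, heavy, align_selection=heavy)
    expected = fix.metadata["expected_rmsf"]       # sigma * sqrt(3)
    assert float(rmsf.mean()) == pytest.approx(expected, rel=0.03)
    bfac = rmsf_to_bfactor(float(rmsf.mean()))
    assert bfac == pytest.approx((8 * np.pi ** 2 / 3) * expected ** 2,
                                 rel=0.06)


def test_rigid_body_motion_removed_by_superposition():
    rng = np.random.default_rng(1)
    base = rng.normal(scale=4.0, size=(25, 3))
    frames = []
    for _ in range(30):
        rot = Rotation.random(random_state=rng).as_matrix()
        frames.append(base @ rot.T + rng.normal(scale=10.0, size=3))
    ens = TrajectoryEnsemble(runs=[np.stack(frames)])
    rmsf = compute_rmsf(ens, np.arange(25))
    assert float(rmsf.max()) < 1e-6


def test_bfactor_closed_form_and_scaling():
    assert rmsf_to_bfactor(1.0) == pytest.approx(26.3189, abs=1e-3)
    assert rmsf_to_bfactor(0.0) == 0.0
    assert rmsf_to_bfactor(2.0) == pytest.approx(4 * rmsf_to_bfactor(1.0))
    with pytest.raises(ValueError):
        rmsf_to_bfactor(-0.1)


def test_empty_selection_rejected():
    ens = TrajectoryEnsemble(runs=[np.zeros((5, 4, 3))])
    with pytest.raises(ValueError, match="selection"):
        compute_rmsf(ens, np.array([], dtype=int))


def test_flexibility_ranking_reproduced_exactly():
    # ten distinct per-residue sigma levels -> Spearman 1.0 on mean RMSF
    sigmas = [0.1, 0.18, 0.27, 0.38, 0.5, 0.63, 0.77, 0.92, 1.08, 1.25]
    spec = ToyReceptorSpec(helix_count=2, residues_per_helix=5,
                           per_atom_sigma=sigmas, n_runs=2,
                           frames_per_run=500, seed=17)
    fix = gen_toy_trajectory(spec)
    top = fix.topology
    heavy = np.nonzero(~top.ligand_mask)[0]
    rmsf = compute_rmsf(fix.ensemble, heavy, align_selection=heavy)
    per_res = [float(rmsf[top.res_ids[heavy] == r].mean())
               for r in range(1, 11)]
    rho, _ = spearmanr(sigmas, per_res)
    assert rho == pytest.approx(1.0)


# --- spatial distribution -------------------------------------------------

def _sdf_system(track_positions):
    """4 static alignment atoms + 1 tracked atom moving as prescribed."""
    n_frames = len(track_positions)
    align = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]])
    coords = np.empty((n_frames, 5, 3))
    coords[:, :4, :] = align
    coords[:, 4, :] = track_positions
    return TrajectoryEnsemble(runs=[coords])


def test_static_atom_occupies_single_voxel():
    ens = _sdf_system([[5.2, 5.2, 5.2]] * 8)
    grid = spatial_distribution(ens, np.array([4]), np.arange(4))
    assert grid.counts.max() == 8
    assert (grid.counts > 0).sum() == 1
    assert grid.n_outside == 0


def test_alternating_atom_splits_between_two_voxels():
    pos = [[5.2, 5.2, 5.2], [8.7, 5.2, 5.2]] * 5
    grid = spatial_distribution(_sdf_system(pos), np.array([4]),
                                np.arange(4))
    occupied = np.sort(grid.counts[grid.counts > 0])
    np.testing.assert_array_equal(occupied, [5, 5])


def test_gaussian_cloud_mass_within_four_sigma():
    rng = np.random.default_rng(2)
    pos = rng.normal(loc=5.0, scale=1.0, size=(4000, 3))
    grid = spatial_distribution(_sdf_system(pos), np.array([4]),
                                np.arange(4), grid_spacing=0.5)
    centers = (np.stack(np.meshgrid(
        *[grid.origin[k] + grid.spacing * (np.arange(grid.counts.shape[k])
                                           + 0.5) for k in range(3)],
        indexing="ij"), axis=-1))
    d = np.linalg.norm(centers - np.array([5.0, 5.0, 5.0]), axis=-1)
    frac_inside = grid.counts[d <= 4.0].sum() / grid.counts.sum()
    assert frac_inside >= 0.99


def test_degenerate_alignment_rejected():
    ens = _sdf_system([[1.0, 1, 1]] * 4)
    with pytest.raises(ValueError, match="alignment"):
        spatial_distribution(ens, np.array([4]), np.array([0]))


# --- pocket volume --------------------------------------------------------

def test_empty_box_volume_exact(single_atom_topology):
    v = pocket_volume(single_atom_topology, np.zeros((1, 3)),
                      ligand_res_id=1, prune=False)
    assert v.volume == 1728.0
    assert v.retained_points == 1728


def test_single_sphere_deletion_matches_analytic():
    top = _point_cloud_topology(2, ligand_first=True)
    frame = np.zeros((2, 3))
    v = pocket_volume(top, frame, ligand_res_id=1, prune=False,
                      radii_table={"C": 3.0})
    deleted = 1728.0 - v.volume
    analytic = 4.0 / 3.0 * np.pi * 27.0      # 113.097
    assert deleted == pytest.approx(analytic, rel=0.15)


def test_fully_occluded_box_zero():
    # a wall of overlapping giant spheres leaves nothing
    top = _point_cloud_topology(28, ligand_first=True)
    rng = np.random.default_rng(3)
    frame = np.vstack([[0.0, 0, 0], rng.uniform(-4, 4, size=(27, 3))])
    v = pocket_volume(top, frame, ligand_res_id=1, prune=False,
                      radii_table={"C": 12.0})
    assert v.volume == 0.0


def test_volume_monotone_under_atom_addition():
    rng = np.random.default_rng(4)
    for _ in range(50):
        n = int(rng.integers(2, 7))
        pos = rng.uniform(-6, 6, size=(n, 3))
        top_small = _point_cloud_topology(n, ligand_first=True)
        top_big = _point_cloud_topology(n + 1, ligand_first=True)
        frame_small = np.vstack([[0.0, 0, 0], pos[:-1]])
        frame_big = np.vstack([[0.0, 0, 0], pos])
        v1 = pocket_volume(top_small, frame_small, ligand_res_id=1,
                           prune=False)
        v2 = pocket_volume(top_big, frame_big, ligand_res_id=1, prune=False)
        assert v2.volume <= v1.volume


def test_grid_refinement_consistency(single_atom_topology):
    v1 = pocket_volume(single_atom_topology, np.zeros((1, 3)),
                       ligand_res_id=1, prune=False, spacing=0.5)
    assert v1.volume == pytest.approx(1728.0)
    top = _point_cloud_topology(2, ligand_first=True)
    analytic = 4.0 / 3.0 * np.pi * 27.0
    errs = []
    for spacing in (1.0, 0.5):
        v = pocket_volume(top, np.zeros((2, 3)), ligand_res_id=1,
                          prune=False, spacing=spacing,
                          radii_table={"C": 3.0})
        errs.append(abs((1728.0 - v.volume) - analytic))
    assert errs[1] < errs[0]


def test_invalid_grid_parameters_rejected(single_atom_topology):
    with pytest.raises(ValueError):
        pocket_volume(single_atom_topology, np.zeros((1, 3)),
                      ligand_res_id=1, spacing=0.0)
    with pytest.raises(ValueError):
        pocket_volume(single_atom_topology, np.zeros((1, 3)),
                      ligand_res_id=1, box=-1.0)


def test_core_pruning_drops_disconnected_pockets():
    # a solid dividing wall at x=0 separates the core half from the far half
    n_wall = 13 * 13
    top = _point_cloud_topology(n_wall + 1, ligand_first=True)
    yy, zz = np.meshgrid(np.arange(-6, 7), np.arange(-6, 7))
    wall = np.stack([3.0 * np.ones(n_wall), yy.ravel(), zz.ravel()], axis=1)
    frame = np.vstack([[0.0, 0, 0], wall])
    free = pocket_volume(top, frame, ligand_res_id=1, prune=False,
                         radii_table={"C": 1.0})
    pruned = pocket_volume(top, frame, ligand_res_id=1, prune=True,
                           radii_table={"C": 1.0})
    assert pruned.volume < free.volume


# --- state projection -----------------------------------------------------

def _ca_topology(n):
    return Topology(
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        res_ids=np.arange(1, n + 1),
        res_names=np.array(["ALA"] * n, dtype=object),
        chains=np.array(["A"] * n, dtype=object),
        ligand_mask=np.zeros(n, dtype=bool))


def test_fixed_geometry_single_occupied_bin():
    top = _ca_topology(4)
    frame = np.array([[0.0, 0, 0], [8.0, 0, 0], [0, 9.0, 0], [0, 0, 7.0]])
    ens = TrajectoryEnsemble(runs=[np.repeat(frame[None], 6, axis=0)])
    proj = state_projection(top, ens, (1, 2), (1, 3))
    assert (proj.hist > 0).sum() == 1
    assert proj.hist.max() == 6
    np.testing.assert_allclose(proj.d_a, 8.0)
    np.testing.assert_allclose(proj.d_b, 9.0)


def test_two_state_toggling_gives_bimodal_map():
    top = _ca_topology(3)
    near = np.array([[0.0, 0, 0], [8.0, 0, 0], [0, 9.0, 0]])
    far = np.array([[0.0, 0, 0], [12.0, 0, 0], [0, 9.0, 0]])
    run = np.concatenate([np.repeat(near[None], 6, axis=0),
                          np.repeat(far[None], 2, axis=0)])
    proj = state_projection(top, TrajectoryEnsemble(runs=[run]),
                            (1, 2), (1, 3))
    occupied = np.sort(proj.hist[proj.hist > 0])
    np.testing.assert_array_equal(occupied, [2, 6])   # 75/25 state split


def test_distances_invariant_under_global_rotation():
    top = _ca_topology(3)
    frame = np.array([[0.0, 0, 0], [8.0, 0, 0], [0, 9.0, 0]])
    rot = Rotation.from_euler("xyz", [0.3, 0.9, -1.2]).as_matrix()
    ens_a = TrajectoryEnsemble(runs=[np.repeat(frame[None], 4, axis=0)])
    ens_b = TrajectoryEnsemble(
        runs=[np.repeat((frame @ rot.T)[None], 4, axis=0)])
    pa = state_projection(top, ens_a, (1, 2), (1, 3))
    pb = state_projection(top, ens_b, (1, 2), (1, 3))
    np.testing.assert_allclose(pa.d_a, pb.d_a, atol=1e-9)
    np.testing.assert_allclose(pa.d_b, pb.d_b, atol=1e-9)


def test_missing_calpha_rejected():
    top = _point_cloud_topology(3)      # atoms named C0..C2, no CA
    ens = TrajectoryEnsemble(runs=[np.zeros((3, 3, 3))])
    with pytest.raises(ValueError, match="C-alpha"):
        state_projection(top, ens, (1, 2), (1, 3))
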