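"""Contact gates, occupancy statistics, distances and interaction energy."""

import numpy as np
import pytest

from gpcrdyn import (NonbondedParams, Topology, TrajectoryEnsemble,
                     contact_occupancy, detect_hbond_frame, detect_vdw_frame,
                     interaction_energy, mean_contact_distance)
from gpcrdyn.contacts import COULOMB_CONSTANT


def _two_group_topology(lig_atoms, res_atoms):
    """Ligand residue 2 + protein residue 1 from (name, element) lists."""
    names = [a[0] for a in res_atoms] + [a[0] for a in lig_atoms]
    elems = [a[1] for a in res_atoms] + [a[1] for a in lig_atoms]
    n_res, n_lig = len(res_atoms), len(lig_atoms)
    return Topology(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elems, dtype=object),
        res_ids=np.array([1] * n_res + [2] * n_lig),
        res_names=np.array(["ALA"] * n_res + ["LIG"] * n_lig, dtype=object),
        chains=np.array(["A"] * (n_res + n_lig), dtype=object),
        ligand_mask=np.array([False] * n_res + [True] * n_lig))


def _hbond_frame(n_o_dist: float, angle_deg: float):
    """Ligand donor N(+H) against a residue acceptor O at given geometry.

    The hydrogen sits 1.0 A from the donor, positioned in the xy plane so
    the donor-H-acceptor angle is exactly ``angle_deg`` (solved by
    bisection on the H direction).
    """
    from scipy.optimize import brentq
    top = _two_group_topology([("N1", "N"), ("HN1", "H")], [("O", "O")])
    acceptor = np.array([0.0, 0.0, 0.0])
    donor = np.array([n_o_dist, 0.0, 0.0])

    def angle_at_h(alpha):
        h = donor + np.array([-np.cos(alpha), np.sin(alpha), 0.0])
        v1, v2 = donor - h, acceptor - h
        c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return np.degrees(np.arccos(np.clip(c, -1, 1))) - angle_deg

    alpha = brentq(angle_at_h, 1e-9, np.pi / 2)
    h = donor + np.array([-np.cos(alpha), np.sin(alpha), 0.0])
    frame = np.stack([acceptor, donor, h])
    return top, frame


@pytest.mark.parametrize("dist,angle,expected", [
    (2.9, 165.0, True),     # canonical hydrogen bond
    (3.6, 179.0, False),    # distance gate fails regardless of angle
    (3.2, 110.0, False),    # angle gate fails
    (3.4, 121.0, True),     # just inside both gates
])
def test_hbond_distance_and_angle_gates(dist, angle, expected):
    top, frame = _hbond_frame(dist, angle)
    assert detect_hbond_frame(top, frame, 1, ligand_res_id=2) is expected


def test_hbond_missing_hydrogen_requires_inference_flag():
    # heavy-atom-only structure: neither partner can donate
    top = _two_group_topology([("N1", "N")], [("O", "O")])
    frame = np.array([[0.0, 0, 0], [3.0, 0, 0]])
    with pytest.raises(ValueError, match="hydrogen"):
        detect_hbond_frame(top, frame, 1, ligand_res_id=2)
    assert detect_hbond_frame(top, frame, 1, ligand_res_id=2,
                              infer_missing_h=True)


@pytest.mark.parametrize("dist,expected", [(3.99, True), (4.01, False)])
def test_vdw_carbon_carbon_boundary(dist, expected):
    top = _two_group_topology([("C1", "C")], [("CB", "C")])
    frame = np.array([[0.0, 0, 0], [dist, 0.0, 0.0]])
    assert detect_vdw_frame(top, frame, 1, ligand_res_id=2) is expected


def test_residue_without_carbons_never_vdw_contacts():
    top = _two_group_topology([("C1", "C")], [("O", "O"), ("N", "N")])
    frame = np.zeros((3, 3))
    frame[2] = [0.5, 0, 0]
    assert not detect_vdw_frame(top, frame, 1, ligand_res_id=2)


def test_contact_detection_invariant_under_rigid_transform():
    from scipy.spatial.transform import Rotation
    top, frame = _hbond_frame(2.9, 165.0)
    rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
    moved = frame @ rot.T + np.array([5.0, -3.0, 8.0])
    assert detect_hbond_frame(top, moved, 1, ligand_res_id=2)


# --- occupancy ------------------------------------------------------------

def test_scheduled_occupancy_and_sustained_rule(toy_contact_fixture):
    fix = toy_contact_fixture
    top, ens = fix.topology, fix.ensemble
    frames_per_run = fix.metadata["frames_per_run"]
    hb = contact_occupancy(top, ens, 2, "hbond")
    assert hb.occupancy == pytest.approx(0.45, abs=1.0 / frames_per_run)
    assert hb.sustained                       # 0.45 > 0.40
    vd41 = contact_occupancy(top, ens, 4, "vdw")
    assert vd41.occupancy == pytest.approx(0.41, abs=1.0 / frames_per_run)
    assert vd41.sustained                     # 0.41 > 0.40
    vd39 = contact_occupancy(top, ens, 7, "vdw")
    assert vd39.occupancy == pytest.approx(0.39, abs=1.0 / frames_per_run)
    assert not vd39.sustained                 # 0.39 fails the strict rule


def test_exact_forty_percent_is_not_sustained():
    from gpcrdyn.contacts import ContactRecord
    assert not ContactRecord(1, "vdw", 0.40, 3.0, 3.0, 100).sustained
    assert ContactRecord(1, "vdw", 0.401, 3.0, 3.0, 1000).sustained


def test_zero_contact_residue_still_reports_distances(toy_contact_fixture):
    fix = toy_contact_fixture
    rec = contact_occupancy(fix.topology, fix.ensemble, 9, "vdw")
    assert rec.occupancy == 0.0
    assert not rec.sustained
    assert np.isnan(rec.mean_distance_contact)
    assert rec.mean_distance_all > 0.0


def test_unknown_residue_rejected(toy_contact_fixture):
    fix = toy_contact_fixture
    with pytest.raises(KeyError):
        contact_occupancy(fix.topology, fix.ensemble, 999, "vdw")


def test_occupancy_pooling_equals_frame_weighted_mean(toy_contact_fixture):
    fix = toy_contact_fixture
    top = fix.topology
    per_run = []
    weights = []
    for run in fix.ensemble.runs:
        sub = TrajectoryEnsemble(runs=[run])
        per_run.append(contact_occupancy(top, sub, 2, "hbond").occupancy)
        weights.append(run.shape[0])
    pooled = contact_occupancy(top, fix.ensemble, 2, "hbond").occupancy
    assert pooled == pytest.approx(np.average(per_run, weights=weights))


# --- mean distances -------------------------------------------------------

def test_static_geometry_mean_distance():
    top = _two_group_topology([("C1", "C")], [("CB", "C")])
    frame = np.array([[0.0, 0, 0], [3.0, 0.0, 0.0]])
    ens = TrajectoryEnsemble(runs=[np.repeat(frame[None], 5, axis=0)])
    assert mean_contact_distance(top, ens, 1, "vdw",
                                 ligand_res_id=2) == pytest.approx(3.0)


def test_half_populated_distances_average():
    top = _two_group_topology([("C1", "C")], [("CB", "C")])
    near = np.array([[0.0, 0, 0], [2.8, 0.0, 0.0]])
    far = np.array([[0.0, 0, 0], [3.2, 0.0, 0.0]])
    run = np.stack([near, far, near, far])
    ens = TrajectoryEnsemble(runs=[run])
    assert mean_contact_distance(top, ens, 1, "vdw",
                                 ligand_res_id=2) == pytest.approx(3.0)


def test_two_state_distance_offset_recovered():
    top = _two_group_topology([("C1", "C")], [("CB", "C")])
    mk = lambda d: TrajectoryEnsemble(
        runs=[np.repeat(np.array([[[0.0, 0, 0], [d, 0.0, 0.0]]]), 6, axis=0)])
    d_a = mean_contact_distance(top, mk(4.5), 1, "vdw", ligand_res_id=2)
    d_b = mean_contact_distance(top, mk(3.0), 1, "vdw", ligand_res_id=2)
    assert d_a - d_b == pytest.approx(1.5)


def test_empty_frame_set_rejected():
    top = _two_group_topology([("C1", "C")], [("CB", "C")])
    ens = TrajectoryEnsemble(runs=[np.zeros((2, 2, 3))])
    ens.runs[0] = np.zeros((0, 2, 3))  # degenerate, bypassing validation
    with pytest.raises(ValueError):
        mean_contact_distance(top, ens, 1, "vdw", ligand_res_id=2)


# --- interaction energy ---------------------------------------------------

def _energy_system(r, qa, qb, sigma=0.0, eps=0.0):
    top = _two_group_topology([("C1", "C")], [("CB", "C")])
    frame = np.array([[0.0, 0, 0], [r, 0.0, 0.0]])
    ens = TrajectoryEnsemble(runs=[np.repeat(frame[None], 3, axis=0)])
    params = NonbondedParams(charges={0: qa, 1: qb},
                             lj_sigma={0: sigma, 1: sigma},
                             lj_eps={0: eps, 1: eps})
    return top, ens, params


def test_coulomb_hand_value():
    # two +1e charges at 3 A, LJ off: 332.0636/3 = 110.688 kcal/mol
    top, ens, params = _energy_system(3.0, 1.0, 1.0)
    mean, sd = interaction_energy(top, ens, params, np.array([1]),
                                  np.array([0]))
    assert mean == pytest.approx(COULOMB_CONSTANT / 3.0, abs=1e-6)
    assert sd == pytest.approx(0.0, abs=1e-9)


def test_lj_zero_at_r_equal_sigma():
    top, ens, params = _energy_system(3.4, 0.0, 0.0, sigma=3.4, eps=0.2)
    mean, _ = interaction_energy(top, ens, params, np.array([1]),
                                 np.array([0]))
    assert mean == pytest.approx(0.0, abs=1e-9)


def test_doubling_charges_quadruples_coulomb():
    top, ens, p1 = _energy_system(3.0, 1.0, 1.0)
    _, _, p2 = _energy_system(3.0, 2.0, 2.0)
    e1, _ = interaction_energy(top, ens, p1, np.array([1]), np.array([0]))
    e2, _ = interaction_energy(top, ens, p2, np.array([1]), np.array([0]))
    assert e2 == pytest.approx(4.0 * e1)


def test_coulomb_antisymmetric_under_sign_flip():
    top, ens, p1 = _energy_system(3.0, 1.0, 1.0)
    _, _, p2 = _energy_system(3.0, 1.0, -1.0)
    e1, _ = interaction_energy(top, ens, p1, np.array([1]), np.array([0]))
    e2, _ = interaction_energy(top, ens, p2, np.array([1]), np.array([0]))
    assert e2 == pytest.approx(-e1)


def test_energy_invariant_under_rigid_transform():
    from scipy.spatial.transform import Rotation
    top, ens, params = _energy_system(3.0, 1.0, -0.5, sigma=3.0, eps=0.15)
    rot = Rotation.from_euler("zyx", [1.0, 0.3, -0.7]).as_matrix()
    moved = TrajectoryEnsemble(
        runs=[ens.runs[0] @ rot.T + np.array([2.0, -1.0, 4.0])])
    e1, _ = interaction_energy(top, ens, params, np.array([1]), np.array([0]))
    e2, _ = interaction_energy(top, moved, params, np.array([1]),
                               np.array([0]))
    assert e2 == pytest.approx(e1, rel=1e-9)


def test_missing_parameters_listed():
    top, ens, _ = _energy_system(3.0, 1.0, 1.0)
    incomplete = NonbondedParams(charges={0: 1.0}, lj_sigma={0: 1.0},
                                 lj_eps={0: 0.0})
    with pytest.raises(ValueError, match=r"\[1\]"):
        interaction_energy(top, ens, incomplete, np.array([1]), np.array([0]))
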