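"""Ligand-receptor contacts, occupancy statistics and interaction energy.

Two contact kinds are detected frame by frame:

* **hydrogen bond** — heteroatom (N/O) pair within 3.5 A *and* a
  donor-H-acceptor angle of at least 120 deg;
* **van der Waals** — any ligand carbon within 4.0 A of any residue carbon.

A contact present in strictly more than 40% of the analysis snapshots
(pooled over all runs) is a *sustained* contact.  Snapshot pooling mirrors
aggregating the replicas of an ensemble into one trajectory before counting.

A simple nonbonded interaction energy (Coulomb + Lennard-Jones with
user-supplied parameters, no cutoff) supports per-residue energy tables;
it makes no attempt to reproduce any particular force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traj_io import Topology, TrajectoryEnsemble

__all__ = [
    "ContactRecord",
    "NonbondedParams",
    "SUSTAINED_THRESHOLD",
    "HBOND_DIST_CUTOFF",
    "HBOND_ANGLE_CUTOFF",
    "VDW_DIST_CUTOFF",
    "COULOMB_CONSTANT",
    "detect_hbond_frame",
    "detect_vdw_frame",
    "contact_occupancy",
    "mean_contact_distance",
    "interaction_energy",
]

SUSTAINED_THRESHOLD = 0.40       # strictly greater-than
HBOND_DIST_CUTOFF = 3.5          # A, heavy-atom N/O distance
HBOND_ANGLE_CUTOFF = 120.0       # deg, donor-H-acceptor
VDW_DIST_CUTOFF = 4.0            # A, carbon-carbon
COULOMB_CONSTANT = 332.0636      # kcal*A/(mol*e^2)
_H_BOND_LENGTH = 1.2             # A, H considered bonded to its donor


@dataclass
class ContactRecord:
    res_id: int
    kind: str                        # "hbond" | "vdw" | "any"
    occupancy: float
    mean_distance_contact: float     # over in-contact frames (nan if none)
    mean_distance_all: float         # over all analysis frames
    n_frames: int

    @property
    def sustained(self) -> bool:
        return self.occupancy > SUSTAINED_THRESHOLD


@dataclass
class NonbondedParams:
    """Per-atom charges (e) and Lennard-Jones parameters (sigma A, eps kcal/mol)."""

    charges: dict[int, float] = field(default_factory=dict)
    lj_sigma: dict[int, float] = field(default_factory=dict)
    lj_eps: dict[int, float] = field(default_factory=dict)
    combining_rule: str = "lorentz-berthelot"
    coulomb_k: float = COULOMB_CONSTANT

    def validate(self, atoms: np.ndarray) -> None:
        missing = [int(a) for a in atoms
                   if int(a) not in self.charges
                   or int(a) not in self.lj_sigma
                   or int(a) not in self.lj_eps]
        if missing:
            raise ValueError(f"missing nonbonded parameters for atoms "
                             f"{missing}")
        if any(self.lj_eps[int(a)] < 0 for a in atoms):
            raise ValueError("LJ epsilon must be >= 0")
        if self.combining_rule not in ("lorentz-berthelot", "geometric"):
            raise ValueError("combining rule must be lorentz-berthelot or "
                             "geometric")


# ---------------------------------------------------------------------------
# Per-frame detection
# ---------------------------------------------------------------------------

def _pair_min_distance(frame: np.ndarray, idx_a: np.ndarray,
                       idx_b: np.ndarray) -> float:
    d = np.linalg.norm(frame[idx_a][:, None, :] - frame[idx_b][None, :, :],
                       axis=-1)
    return float(d.min()) if d.size else np.inf


def _hetero_indices(top: Topology, res_id: int) -> np.ndarray:
    idx = top.atoms_of_residue(res_id)
    return idx[np.isin(top.elements[idx], ("N", "O"))]


def _carbon_indices(top: Topology, res_id: int) -> np.ndarray:
    idx = top.atoms_of_residue(res_id)
    return idx[top.elements[idx] == "C"]


def _hydrogens_of(top: Topology, frame: np.ndarray, donor: int) -> np.ndarray:
    """Hydrogens covalently associated with a donor heavy atom (<= 1.2 A),
    searched within the donor's residue."""
    idx = top.atoms_of_residue(int(top.res_ids[donor]))
    hyd = idx[top.elements[idx] == "H"]
    if hyd.size == 0:
        return hyd
    d = np.linalg.norm(frame[hyd] - frame[donor], axis=-1)
    return hyd[d <= _H_BOND_LENGTH]


def detect_hbond_frame(top: Topology, frame: np.ndarray, res_id: int,
                       ligand_res_id: int | None = None,
                       infer_missing_h: bool = False) -> bool:
    """Is there a ligand-residue hydrogen bond in this frame?

    Gate: heavy-atom N/O distance <= 3.5 A AND donor-H-acceptor angle
    >= 120 deg, where either partner may donate.  A heavy atom's hydrogens
    are those of its own residue within covalent range.  If a candidate
    donor carries no hydrogen: with ``infer_missing_h`` the ideal placement
    (H on the donor-acceptor axis, angle 180 deg) is assumed, i.e. the
    distance gate alone decides; otherwise detection fails loudly.
    """
    lig = ligand_res_id if ligand_res_id is not None else _default_ligand(top)
    a_idx = _hetero_indices(top, lig)
    b_idx = _hetero_indices(top, res_id)
    for ai in a_idx:
        for bi in b_idx:
            r = float(np.linalg.norm(frame[ai] - frame[bi]))
            if r > HBOND_DIST_CUTOFF:
                continue
            evaluable = False
            for donor, acceptor in ((ai, bi), (bi, ai)):
                hyd = _hydrogens_of(top, frame, int(donor))
                if hyd.size == 0:
                    continue             # cannot donate without a hydrogen
                evaluable = True
                v1 = frame[donor] - frame[hyd]        # H -> donor
                v2 = frame[acceptor] - frame[hyd]     # H -> acceptor
                cosang = np.einsum("ij,ij->i", v1, v2) / (
                    np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1))
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if np.any(ang >= HBOND_ANGLE_CUTOFF):
                    return True
            if not evaluable:
                # neither partner carries a hydrogen: the angle cannot be
                # measured for this in-range pair
                if infer_missing_h:
                    return True          # ideal H placement: angle 180 deg
                raise ValueError(
                    f"neither atom {int(ai)} nor {int(bi)} has a hydrogen; "
                    "enable infer_missing_h to assume ideal placement")
    return False


def detect_vdw_frame(top: Topology, frame: np.ndarray, res_id: int,
                     ligand_res_id: int | None = None) -> bool:
    """Is the residue in van der Waals contact with the ligand (any
    carbon-carbon pair within 4.0 A)?  Residues without carbons never are."""
    lig = ligand_res_id if ligand_res_id is not None else _default_ligand(top)
    ca = _carbon_indices(top, lig)
    cb = _carbon_indices(top, res_id)
    if ca.size == 0 or cb.size == 0:
        return False
    return _pair_min_distance(frame, ca, cb) <= VDW_DIST_CUTOFF


def _default_ligand(top: Topology) -> int:
    lig = top.ligand_res_ids
    if len(lig) != 1:
        raise ValueError(f"expected exactly one ligand residue, found {lig}; "
                         "pass ligand_res_id explicitly")
    return lig[0]


# ---------------------------------------------------------------------------
# Occupancy & distances
# ---------------------------------------------------------------------------

def _contact_atom_sets(top: Topology, res_id: int, lig: int, kind: str
                       ) -> tuple[np.ndarray, np.ndarray]:
    if kind == "hbond":
        return _hetero_indices(top, lig), _hetero_indices(top, res_id)
    if kind == "vdw":
        return _carbon_indices(top, lig), _carbon_indices(top, res_id)
    if kind == "any":
        lig_idx = top.atoms_of_residue(lig)
        res_idx = top.atoms_of_residue(res_id)
        heavy = top.heavy_mask()
        return lig_idx[heavy[lig_idx]], res_idx[heavy[res_idx]]
    raise ValueError(f"unknown contact kind {kind!r}")


def contact_occupancy(top: Topology, ens: TrajectoryEnsemble, res_id: int,
                      kind: str, ligand_res_id: int | None = None,
                      infer_missing_h: bool = False) -> ContactRecord:
    """Occupancy of one ligand-residue contact over the pooled analysis window.

    ``kind`` is "hbond", "vdw", or "any" (in contact when either kind is);
    occupancy = in-contact frames / total analysis frames, runs pooled.
    The sustained flag applies the strict >40% rule.  Mean minimum distance
    between the contact-defining atom sets is reported both over in-contact
    frames and over all frames.
    """
    lig = ligand_res_id if ligand_res_id is not None else _default_ligand(top)
    if res_id not in top.residue_ids:
        raise KeyError(f"residue {res_id} not in topology")
    coords = ens.analysis_coords()
    n = coords.shape[0]
    flags = np.zeros(n, dtype=bool)
    for f in range(n):
        if kind in ("hbond", "any"):
            flags[f] = detect_hbond_frame(top, coords[f], res_id, lig,
                                          infer_missing_h)
        if kind in ("vdw", "any") and not flags[f]:
            flags[f] = detect_vdw_frame(top, coords[f], res_id, lig)
    set_a, set_b = _contact_atom_sets(top, res_id, lig, kind)
    dmin = np.array([_pair_min_distance(coords[f], set_a, set_b)
                     for f in range(n)])
    occ = float(flags.mean())
    mean_contact = float(dmin[flags].mean()) if flags.any() else float("nan")
    return ContactRecord(res_id, kind, occ, mean_contact,
                         float(dmin.mean()), n)


def mean_contact_distance(top: Topology, ens: TrajectoryEnsemble, res_id: int,
                          kind: str = "any",
                          ligand_res_id: int | None = None) -> float:
    """Mean over analysis frames of the minimum distance between the
    contact-defining atom sets of the ligand and one residue (A)."""
    lig = ligand_res_id if ligand_res_id is not None else _default_ligand(top)
    coords = ens.analysis_coords()
    if coords.shape[0] == 0:
        raise ValueError("empty analysis frame set")
    set_a, set_b = _contact_atom_sets(top, res_id, lig, kind)
    dmin = np.array([_pair_min_distance(coords[f], set_a, set_b)
                     for f in range(coords.shape[0])])
    return float(dmin.mean())


# ---------------------------------------------------------------------------
# Interaction energy
# ---------------------------------------------------------------------------

def interaction_energy(top: Topology, ens: TrajectoryEnsemble,
                       params: NonbondedParams,
                       group_a: np.ndarray, group_b: np.ndarray
                       ) -> tuple[float, float]:
    """Mean +- SD (kcal/mol) of the nonbonded group-group energy per frame.

    Per frame:  sum over pairs of  k q_i q_j / r  +  4 eps [(s/r)^12 - (s/r)^6]
    with Lorentz-Berthelot (or geometric) combining; no distance cutoff —
    intended for compact toy systems and per-residue energy tables.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    params.validate(np.concatenate([group_a, group_b]))
    qa = np.array([params.charges[int(i)] for i in group_a])
    qb = np.array([params.charges[int(i)] for i in group_b])
    sa = np.array([params.lj_sigma[int(i)] for i in group_a])
    sb = np.array([params.lj_sigma[int(i)] for i in group_b])
    ea = np.array([params.lj_eps[int(i)] for i in group_a])
    eb = np.array([params.lj_eps[int(i)] for i in group_b])
    if params.combining_rule == "lorentz-berthelot":
        sig = (sa[:, None] + sb[None, :]) / 2.0
    else:
        sig = np.sqrt(sa[:, None] * sb[None, :])
    eps = np.sqrt(ea[:, None] * eb[None, :])
    qq = qa[:, None] * qb[None, :]

    coords = ens.analysis_coords()
    energies = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        r = np.linalg.norm(coords[f, group_a][:, None, :]
                           - coords[f, group_b][None, :, :], axis=-1)
        if np.any(r < 1e-9):
            raise ValueError("overlapping atoms between the two groups")
        sr6 = (sig / r) ** 6
        energies[f] = (params.coulomb_k * qq / r
                       + 4.0 * eps * (sr6 ** 2 - sr6)).sum()
    return float(energies.mean()), float(energies.std())
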