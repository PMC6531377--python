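"""Synthetic trajectory ensembles and work samples with known ground truth.

Every analysis stage in this package is validated against data whose
statistical structure is known exactly:

* **Coupled torsions** — pairs of angles drawn from a bivariate angular
  model with von Mises marginals and cosine-of-difference coupling,

      p(ti, tj)  proportional to  exp[km cos ti + km cos tj + kc cos(ti - tj)]

  whose density is evaluable in closed form, so the mutual information of a
  coupled pair can be computed by dense quadrature (:func:`oracle_mi`) and
  compared with the histogram estimator.  ``kc = 0`` gives exact
  independence.  Sampling is exact rejection sampling from the product of
  the marginals (acceptance factor ``exp(kc (cos(ti - tj) - 1))``).

* **Toy receptor trajectories** — a small poly-helical "receptor" plus a
  ligand with named atoms.  Atoms jitter isotropically with a prescribed
  per-axis sigma (expected 3D RMSF = sigma * sqrt(3)), and ligand-residue
  contacts are switched on/off frame by frame so that scheduled contact
  occupancies are realized exactly (up to rounding) by construction.

* **Work samples** — per-window Gaussian forward/reverse work obeying the
  Crooks fluctuation symmetry, for which the window free energy has the
  closed form dG = mu_w - sigma_w^2 / 2 (reduced units, k_B T = 1).

The ensembles emulate the study design of five independent replicas with
the trailing half of each run used for analysis; they contain no force
field, solvent, membrane or integrator — only the statistical features the
estimators consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .traj_io import (Topology, TrajectoryEnsemble, write_topology,
                      write_trajectory)
from .torsion_stats import TorsionSeries

__all__ = [
    "TorsionModelSpec",
    "ToyReceptorSpec",
    "WorkSampleSpec",
    "ToyFixture",
    "gen_coupled_torsions",
    "oracle_mi",
    "oracle_marginal_entropy",
    "gen_toy_trajectory",
    "gen_bar_samples",
    "write_toy_fixture",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class TorsionModelSpec:
    """Ground-truth model for an ensemble of coupled torsion angles."""

    n_residues: int = 10
    torsions_per_residue: int = 1
    coupling_edges: list[tuple[int, int, float]] = field(default_factory=list)
    marginal_concentration: float = 1.0       # km >= 0
    n_runs: int = 5
    frames_per_run: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if self.marginal_concentration < 0:
            raise ValueError("marginal concentration must be >= 0")
        seen: set[int] = set()
        for i, j, kc in self.coupling_edges:
            if kc < 0:
                raise ValueError("coupling strength must be >= 0")
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues):
                raise ValueError(f"coupling edge ({i},{j}) out of range")
            if i == j:
                raise ValueError("self-coupling is not supported")
            if i in seen or j in seen:
                raise ValueError("each residue may appear in at most one "
                                 "coupling edge (pairwise model)")
            seen |= {i, j}
        if min(self.n_residues, self.torsions_per_residue,
               self.n_runs, self.frames_per_run) < 1:
            raise ValueError("counts must be positive")


@dataclass
class ToyReceptorSpec:
    """Geometry + noise model for the toy receptor/ligand trajectory."""

    helix_count: int = 2
    residues_per_helix: int = 6
    ligand_atom_names: list[str] = field(
        default_factory=lambda: ["N1", "O1", "C1", "C2"])
    # per-axis fluctuation amplitude(s), Angstrom: one value for all atoms,
    # or one per receptor residue (ligand atoms then stay noise-free)
    per_atom_sigma: float | list[float] = 0.2
    contact_schedule: list[tuple[int, str, float]] = field(default_factory=list)
    n_runs: int = 5
    frames_per_run: int = 200
    window: float = 1.0                       # schedule realized inside window
    seed: int = 0

    def validate(self) -> None:
        names = self.ligand_atom_names
        if not any(n.startswith("N") for n in names):
            raise ValueError("ligand must include a primary-amine-like N atom")
        if not any(n.startswith("O") for n in names):
            raise ValueError("ligand must include a hydroxyl-like O atom")
        n_res = self.helix_count * self.residues_per_helix
        sigmas = np.atleast_1d(np.asarray(self.per_atom_sigma, dtype=float))
        if np.any(sigmas < 0):
            raise ValueError("sigma must be >= 0")
        if sigmas.size not in (1, n_res):
            raise ValueError("per_atom_sigma must be scalar or one value "
                             "per receptor residue")
        for res, kind, occ in self.contact_schedule:
            if kind not in ("hbond", "vdw"):
                raise ValueError(f"unknown contact kind {kind!r}")
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"occupancy {occ} outside [0, 1]")
            if not 1 <= res <= n_res:
                raise ValueError(f"scheduled residue {res} not in receptor")
        if not 0.0 < self.window <= 1.0:
            raise ValueError("window fraction must be in (0, 1]")


@dataclass
class WorkSampleSpec:
    """Gaussian Crooks-consistent work samples for the BAR estimator.

    Per window w:  W_f ~ N(mu_w, sigma_w^2);  Crooks symmetry then fixes
    W_r ~ N(sigma_w^2 - mu_w, sigma_w^2)  and  dG_w = mu_w - sigma_w^2/2
    (reduced units).
    """

    mu: list[float] = field(default_factory=lambda: [1.0])
    sigma: list[float] = field(default_factory=lambda: [1.0])
    samples_per_window: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if len(self.mu) != len(self.sigma):
            raise ValueError("mu and sigma lists must have equal length")
        if any(s < 0 for s in self.sigma):
            raise ValueError("sigma must be >= 0")
        if self.samples_per_window < 1:
            raise ValueError("need at least one sample per window")

    @property
    def n_windows(self) -> int:
        return len(self.mu)

    def true_window_dg(self) -> np.ndarray:
        return np.asarray(self.mu) - np.asarray(self.sigma) ** 2 / 2.0

    def true_total_dg(self) -> float:
        return float(self.true_window_dg().sum())


# ---------------------------------------------------------------------------
# Coupled torsion ensembles
# ---------------------------------------------------------------------------

def _sample_coupled_pair(rng: np.random.Generator, n: int, km: float,
                         kc: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact rejection sampling of n draws from the bivariate angular model."""
    out_i = np.empty(n)
    out_j = np.empty(n)
    filled = 0
    while filled < n:
        batch = max(2 * (n - filled), 1000)
        ti = rng.vonmises(0.0, km, size=batch)
        tj = rng.vonmises(0.0, km, size=batch)
        accept = rng.random(batch) < np.exp(kc * (np.cos(ti - tj) - 1.0))
        ti, tj = ti[accept], tj[accept]
        take = min(ti.size, n - filled)
        out_i[filled:filled + take] = ti[:take]
        out_j[filled:filled + take] = tj[:take]
        filled += take
    return out_i, out_j


def _to_degrees(theta: np.ndarray) -> np.ndarray:
    deg = np.degrees(theta)
    deg[deg >= 180.0] = -180.0
    return deg


def gen_coupled_torsions(spec: TorsionModelSpec) -> list[TorsionSeries]:
    """Draw a torsion ensemble with the spec's pairwise coupling structure.

    Torsion 0 of residue *i* couples to torsion 0 of residue *j* for every
    edge (i, j, kc); all other torsions are independent von Mises draws with
    the marginal concentration.  Identical seeds reproduce bit-identical
    output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_runs * spec.frames_per_run
    run_lengths = tuple([spec.frames_per_run] * spec.n_runs)
    km = spec.marginal_concentration

    angles = {}
    coupled: set[tuple[int, int]] = set()
    for i, j, kc in spec.coupling_edges:
        ti, tj = _sample_coupled_pair(rng, n_total, km, kc)
        angles[(i, 0)] = ti
        angles[(j, 0)] = tj
        coupled |= {(i, 0), (j, 0)}
    for res in range(spec.n_residues):
        for t in range(spec.torsions_per_residue):
            if (res, t) not in coupled:
                angles[(res, t)] = rng.vonmises(0.0, km, size=n_total)

    out = []
    for res in range(spec.n_residues):
        for t in range(spec.torsions_per_residue):
            name = "chi%d" % (t + 1)
            out.append(TorsionSeries(res + 1, name,
                                     _to_degrees(angles[(res, t)]),
                                     run_lengths=run_lengths))
    return out


def _pair_density_grid(km: float, kc: float, n_grid: int
                       ) -> tuple[np.ndarray, float]:
    """Unnormalized density on an n_grid x n_grid midpoint grid + cell area."""
    if km < 0 or kc < 0:
        raise ValueError("concentrations must be >= 0")
    edges = np.linspace(-np.pi, np.pi, n_grid + 1)
    mid = (edges[:-1] + edges[1:]) / 2.0
    ti = mid[:, None]
    tj = mid[None, :]
    logp = km * np.cos(ti) + km * np.cos(tj) + kc * np.cos(ti - tj)
    dens = np.exp(logp - logp.max())
    cell = (2.0 * np.pi / n_grid) ** 2
    z = dens.sum() * cell
    if not np.isfinite(z) or z <= 0:
        raise ValueError("density is not normalizable")
    return dens / z, cell


def oracle_mi(km: float, kc: float, n_grid: int = 720,
              m_bins: int | None = None) -> float:
    """Mutual information (nats) of the bivariate angular model by quadrature.

    Midpoint rule on an ``n_grid`` x ``n_grid`` grid (refining by 2x moves
    the result by far less than 1e-4 nats for moderate concentrations).
    With ``m_bins`` set, returns instead the MI of the distribution
    *discretized* onto ``m_bins`` equal angular bins — the population
    quantity the histogram estimator converges to; requires
    n_grid % m_bins == 0.
    """
    p, cell = _pair_density_grid(km, kc, n_grid)
    if m_bins is not None:
        if n_grid % m_bins:
            raise ValueError("n_grid must be a multiple of m_bins")
        f = n_grid // m_bins
        p = p.reshape(m_bins, f, m_bins, f).sum(axis=(1, 3)) * cell
        pi = p.sum(axis=1)
        pj = p.sum(axis=0)
        mask = p > 0
        return float((p[mask] * np.log(p[mask]
                                       / np.outer(pi, pj)[mask])).sum())
    # marginal densities: integrate over the other axis
    dx = 2.0 * np.pi / n_grid
    pi = p.sum(axis=1) * dx
    pj = p.sum(axis=0) * dx
    mask = p > 0
    mi = (p[mask] * np.log(p[mask] / np.outer(pi, pj)[mask])).sum() * cell
    return float(mi)


def oracle_marginal_entropy(km: float, n_grid: int = 720,
                            m_bins: int | None = None) -> float:
    """Entropy (nats) of the von Mises marginal, by quadrature.

    With ``m_bins`` set, the discrete entropy of the binned distribution —
    comparable with the histogram estimator at the same bin count.
    """
    if km < 0:
        raise ValueError("concentration must be >= 0")
    dx = 2.0 * np.pi / n_grid
    mid = -np.pi + dx * (np.arange(n_grid) + 0.5)
    logp = km * np.cos(mid)
    p = np.exp(logp - logp.max())
    p /= p.sum() * dx
    if m_bins is not None:
        if n_grid % m_bins:
            raise ValueError("n_grid must be a multiple of m_bins")
        pb = p.reshape(m_bins, n_grid // m_bins).sum(axis=1) * dx
        pb = pb[pb > 0]
        return float(-(pb * np.log(pb)).sum())
    return float(-(p * np.log(p)).sum() * dx)


# ---------------------------------------------------------------------------
# Toy receptor trajectories
# ---------------------------------------------------------------------------

@dataclass
class ToyFixture:
    """A generated toy system: topology, base coordinates, ensemble, truth."""

    topology: Topology
    base_coords: np.ndarray            # (atoms, 3), the noise-free geometry
    ensemble: TrajectoryEnsemble
    metadata: dict


_RES_TEMPLATE = [
    # name, offset (Angstrom) within the residue frame
    ("N",  (-0.5, -0.8, 0.0)),
    ("CA", (0.0, 0.0, 0.0)),
    ("C",  (1.2, 0.7, 0.0)),
    ("O",  (1.3, 1.9, 0.0)),
    ("CB", (-0.8, 1.0, 1.0)),
]

_HELIX_SPACING = 20.0    # Angstrom between helix axes
_RISE = 3.8              # Angstrom between consecutive residues
_CONTACT_DIST = {"hbond": 2.9, "vdw": 3.5}
_AWAY_DIST = 8.0
_HBOND_CUTOFF_NOTE = "in-contact 2.9 A vs 3.5 A gate; out 8.0 A"


def _element_of(name: str) -> str:
    s = name.strip()
    while s and s[0].isdigit():
        s = s[1:]
    return s[:1].upper() or "X"


def gen_toy_trajectory(spec: ToyReceptorSpec) -> ToyFixture:
    """Generate the toy receptor/ligand trajectory ensemble.

    Receptor helices are straight residue stacks; every atom jitters with an
    isotropic per-axis Gaussian of the prescribed sigma (expected 3D
    RMSF = sigma*sqrt(3)).  Each contact-schedule entry claims one ligand
    atom (hydrogen-bond entries use the amine N, then the hydroxyl O, each
    with an explicit hydrogen; van der Waals entries use ligand carbons) and
    that atom is placed inside/outside the geometric contact gate in exactly
    the scheduled fraction of analysis frames, chosen by a seeded
    permutation per run.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_res = spec.helix_count * spec.residues_per_helix

    atom_names: list[str] = []
    elements: list[str] = []
    res_ids: list[int] = []
    res_names: list[str] = []
    ligand_flags: list[bool] = []
    base: list[tuple[float, float, float]] = []

    res = 0
    for h in range(spec.helix_count):
        for k in range(spec.residues_per_helix):
            res += 1
            ox, oz = h * _HELIX_SPACING, k * _RISE
            for name, (dx, dy, dz) in _RES_TEMPLATE:
                atom_names.append(name)
                elements.append(_element_of(name))
                res_ids.append(res)
                res_names.append("ALA")
                ligand_flags.append(False)
                base.append((ox + dx, dy, oz + dz))

    # ligand parked away from the receptor in +y
    lig_id = n_res + 1
    lig_names = list(spec.ligand_atom_names)
    amine_n = next(n for n in lig_names if n.startswith("N"))
    hydroxyl_o = next(n for n in lig_names if n.startswith("O"))
    # explicit hydrogens on the polar ligand atoms (donor geometry)
    lig_names += ["H" + amine_n, "H" + hydroxyl_o]
    for i, name in enumerate(lig_names):
        atom_names.append(name)
        elements.append(_element_of(name))
        res_ids.append(lig_id)
        res_names.append("LIG")
        ligand_flags.append(True)
        base.append((2.0 * i, 30.0, 0.0))

    top = Topology(
        atom_names=np.array(atom_names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_ids=np.array(res_ids, dtype=int),
        res_names=np.array(res_names, dtype=object),
        chains=np.array(["A"] * len(atom_names), dtype=object),
        ligand_mask=np.array(ligand_flags, dtype=bool),
    )
    base_arr = np.asarray(base, dtype=float)
    n_atoms = base_arr.shape[0]

    # assign one ligand atom (and hydrogen, for hbond) per schedule entry
    donors = iter([amine_n, hydroxyl_o])
    carbons = iter([n for n in spec.ligand_atom_names if n.startswith("C")])
    assignments = []   # (res, kind, occ, lig_atom_idx, lig_h_idx | None)
    for entry in spec.contact_schedule:
        res_i, kind, occ = entry
        if kind == "hbond":
            try:
                donor = next(donors)
            except StopIteration:
                raise ValueError("at most two hbond schedule entries "
                                 "(amine N and hydroxyl O donors)") from None
            assignments.append((res_i, kind, occ,
                                top.atom_index(lig_id, donor),
                                top.atom_index(lig_id, "H" + donor)))
        else:
            try:
                carbon = next(carbons)
            except StopIteration:
                raise ValueError("not enough ligand carbon atoms for the vdw "
                                 "schedule") from None
            assignments.append((res_i, kind, occ,
                                top.atom_index(lig_id, carbon), None))

    # schedule realization: within each run, the trailing analysis window and
    # the leading remainder each get round(occ * len) in-contact frames at
    # permuted positions, so occupancy inside the window is exact by design.
    def contact_frames(n_frames: int, occ: float) -> np.ndarray:
        tail = int(np.floor(spec.window * n_frames))
        head = n_frames - tail
        mask = np.zeros(n_frames, dtype=bool)
        for start, length in ((0, head), (head, tail)):
            if length == 0:
                continue
            k = int(round(occ * length))
            perm = rng.permutation(length)[:k]
            mask[start + perm] = True
        return mask

    sigmas = np.atleast_1d(np.asarray(spec.per_atom_sigma, dtype=float))
    if sigmas.size == 1:
        sigma_atom = np.full(n_atoms, float(sigmas[0]))
    else:
        sigma_atom = np.zeros(n_atoms)
        for a in range(n_atoms):
            if not ligand_flags[a]:
                sigma_atom[a] = sigmas[res_ids[a] - 1]

    runs = []
    realized: dict[tuple[int, str], float] = {}
    for _ in range(spec.n_runs):
        jitter = rng.normal(0.0, 1.0,
                            size=(spec.frames_per_run, n_atoms, 3)) \
            * sigma_atom[None, :, None]
        coords = base_arr[None, :, :] + jitter
        for res_i, kind, occ, lig_idx, h_idx in assignments:
            mask = contact_frames(spec.frames_per_run, occ)
            anchor_name = "O" if kind == "hbond" else "CB"
            anchor = top.atom_index(res_i, anchor_name)
            # direction away from the receptor (+y), in/out along it
            for in_contact, dist in ((True, _CONTACT_DIST[kind]),
                                     (False, _AWAY_DIST)):
                sel = mask if in_contact else ~mask
                pos = coords[sel, anchor, :] + np.array([0.0, dist, 0.0])
                coords[sel, lig_idx, :] = pos
                if h_idx is not None:
                    # hydrogen on the donor, pointing at the acceptor (180 deg)
                    coords[sel, h_idx, :] = pos + np.array([0.0, -1.0, 0.0])
            n_tail = int(np.floor(spec.window * spec.frames_per_run))
            got = float(mask[spec.frames_per_run - n_tail:].mean())
            key = (res_i, kind)
            realized[key] = realized.get(key, 0.0) + got / spec.n_runs
        runs.append(coords)

    meta = {
        "per_atom_sigma": (float(sigmas[0]) if sigmas.size == 1
                           else [float(s) for s in sigmas]),
        "expected_rmsf": (float(sigmas[0] * np.sqrt(3.0))
                          if sigmas.size == 1
                          else [float(s * np.sqrt(3.0)) for s in sigmas]),
        "rmsf_convention": "per-axis sigma; expected 3D RMSF = sigma*sqrt(3)",
        "contact_geometry": _HBOND_CUTOFF_NOTE,
        "scheduled_occupancy": {f"{r}:{k}": occ
                                for r, k, occ in spec.contact_schedule},
        "realized_occupancy": {f"{r}:{k}": v for (r, k), v in realized.items()},
        "ligand_res_id": lig_id,
        "n_runs": spec.n_runs,
        "frames_per_run": spec.frames_per_run,
        "window": spec.window,
        "seed": spec.seed,
    }
    ens = TrajectoryEnsemble(runs=runs, window=spec.window)
    return ToyFixture(top, base_arr, ens, meta)


def write_toy_fixture(fix: ToyFixture, out_dir: str | Path) -> dict[str, str]:
    """Write a toy fixture to disk: PDB + per-run trajectories + YAML truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    pdb = out / "topology.pdb"
    write_topology(pdb, fix.topology, fix.base_coords)
    paths["topology"] = str(pdb)
    run_paths = []
    for i, run in enumerate(fix.ensemble.runs):
        p = out / f"run{i}.traj"
        write_trajectory(p, run)
        run_paths.append(str(p))
    paths["runs"] = run_paths
    meta = out / "metadata.yaml"
    with open(meta, "w") as fh:
        yaml.safe_dump(fix.metadata, fh, sort_keys=True)
    paths["metadata"] = str(meta)
    return paths


# ---------------------------------------------------------------------------
# BAR work samples
# ---------------------------------------------------------------------------

def gen_bar_samples(spec: WorkSampleSpec
                    ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-window (forward, reverse) work samples, reduced units.

    Forward work is N(mu_w, sigma_w^2); the reverse work is drawn from
    N(sigma_w^2 - mu_w, sigma_w^2), the unique Gaussian consistent with the
    Crooks fluctuation theorem, so each window's true free energy is
    mu_w - sigma_w^2/2 and the true total is their sum.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = []
    for mu, sigma in zip(spec.mu, spec.sigma):
        wf = rng.normal(mu, sigma, size=spec.samples_per_window)
        wr = rng.normal(sigma ** 2 - mu, sigma, size=spec.samples_per_window)
        out.append((wf, wr))
    return out
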