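"""Flexibility maps, ligand density, pocket volume and state projections.

* RMSF per atom about the ensemble-average structure, after least-squares
  superposition of every frame onto that average (iterated to
  self-consistency); the thermal B-factor follows as B = (8 pi^2 / 3) RMSF^2.
* Spatial distribution function: frames superposed on a rigid selection,
  selected atoms binned on a 3D grid — the time-averaged density cloud of,
  e.g., the agonist's amine nitrogen and hydroxyl oxygen.
* Binding-site volume: a 12x12x12 A box of 1 A voxels centred on the ligand
  centroid; voxels clashing with any receptor atom's van der Waals sphere
  are deleted and voxels disconnected from a central core sphere are pruned
  (6-connectivity region growing).
* Activation-state projection: per-frame C-alpha distance pairs (TM3-TM6,
  TM3-TM7) histogrammed in 2D, with optional crystal-structure reference
  markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .traj_io import Topology, TrajectoryEnsemble

__all__ = [
    "DensityGrid",
    "VolumeResult",
    "StateProjection",
    "BONDI_RADII",
    "superpose_frames",
    "compute_rmsf",
    "rmsf_to_bfactor",
    "spatial_distribution",
    "pocket_volume",
    "pocket_volume_series",
    "state_projection",
]

#: Bondi van der Waals radii (A) for clash detection, configurable per call.
BONDI_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
_DEFAULT_RADIUS = 1.70


@dataclass
class DensityGrid:
    origin: np.ndarray               # (3,) A, corner of voxel (0,0,0)
    spacing: float                   # A
    counts: np.ndarray               # (nx, ny, nz) occupancy counts
    n_frames: int
    n_outside: int = 0               # tracked-atom positions off the grid

    def occupancy(self) -> np.ndarray:
        total = self.counts.sum() + self.n_outside
        return self.counts / total if total else self.counts.astype(float)

    def write_text(self, path) -> None:
        """Plain-text volumetric dump: header then one count per line in
        C order (x fastest last)."""
        with open(path, "w") as fh:
            fh.write("gpcrdyn-grid 1\n")
            fh.write("origin %.6f %.6f %.6f\n" % tuple(self.origin))
            fh.write("spacing %.6f\n" % self.spacing)
            fh.write("shape %d %d %d\n" % self.counts.shape)
            fh.write("frames %d outside %d\n" % (self.n_frames, self.n_outside))
            np.savetxt(fh, self.counts.reshape(-1, 1), fmt="%d")


@dataclass
class VolumeResult:
    retained_points: int
    volume: float                    # A^3 = retained * spacing^3
    spacing: float
    box: float
    core_radius: float
    per_frame: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def mean(self) -> float:
        return float(self.per_frame.mean()) if self.per_frame.size \
            else self.volume

    @property
    def sd(self) -> float:
        return float(self.per_frame.std()) if self.per_frame.size else 0.0


@dataclass
class StateProjection:
    d_a: np.ndarray                  # per-frame distance, pair A (A)
    d_b: np.ndarray                  # per-frame distance, pair B (A)
    hist: np.ndarray
    edges_a: np.ndarray
    edges_b: np.ndarray
    markers: list[tuple[str, float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Superposition / RMSF
# ---------------------------------------------------------------------------

def _fit_frame(mobile: np.ndarray, ref: np.ndarray,
               fit_idx: np.ndarray) -> np.ndarray:
    """Least-squares superpose one frame onto ref over fit_idx (Kabsch)."""
    mob_sel = mobile[fit_idx]
    ref_sel = ref[fit_idx]
    mc = mob_sel.mean(axis=0)
    rc = ref_sel.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_sel - rc, mob_sel - mc)
    return rot.apply(mobile - mc) + rc


def superpose_frames(coords: np.ndarray, fit_idx: np.ndarray,
                     ref: np.ndarray | None = None,
                     max_iter: int = 10, tol: float = 1e-8) -> np.ndarray:
    """Superpose every frame onto the ensemble-average structure.

    Starts from the first frame as reference (or an explicit ``ref``),
    alternates fitting and re-averaging until the average converges.
    """
    coords = np.asarray(coords, dtype=float)
    if fit_idx.size < 3:
        raise ValueError("need at least 3 atoms for superposition")
    reference = coords[0] if ref is None else np.asarray(ref, dtype=float)
    fitted = coords
    for _ in range(max_iter):
        fitted = np.stack([_fit_frame(f, reference, fit_idx) for f in coords])
        new_ref = fitted.mean(axis=0)
        if np.max(np.abs(new_ref - reference)) < tol:
            reference = new_ref
            break
        reference = new_ref
    return fitted


def compute_rmsf(ens: TrajectoryEnsemble, selection: np.ndarray,
                 align_selection: np.ndarray | None = None,
                 superpose: bool = True) -> np.ndarray:
    """Per-atom RMSF (A) of the selected atoms over the analysis window.

    The reference is the ensemble-average structure of the pooled runs;
    frames are least-squares superposed onto it over ``align_selection``
    (default: the analysis selection itself) before the fluctuation
    RMSF_i = sqrt(<|x_i - <x_i>|^2>) is taken.  ``superpose=False`` skips
    the fit (useful when frames are already in a common frame).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    coords = ens.analysis_coords()
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 frames for RMSF")
    if superpose:
        fit_idx = selection if align_selection is None \
            else np.asarray(align_selection, dtype=int)
        coords = superpose_frames(coords, fit_idx)
    x = coords[:, selection, :]
    mean = x.mean(axis=0)
    return np.sqrt(((x - mean) ** 2).sum(axis=-1).mean(axis=0))


def rmsf_to_bfactor(rmsf: np.ndarray | float) -> np.ndarray | float:
    """Thermal B-factor (A^2) from RMSF (A):  B = (8 pi^2 / 3) RMSF^2."""
    arr = np.asarray(rmsf, dtype=float)
    if np.any(arr < 0):
        raise ValueError("RMSF must be >= 0")
    out = (8.0 * np.pi ** 2 / 3.0) * arr ** 2
    return float(out) if np.isscalar(rmsf) else out


# ---------------------------------------------------------------------------
# Spatial distribution function
# ---------------------------------------------------------------------------

def spatial_distribution(ens: TrajectoryEnsemble, tracked_atoms: np.ndarray,
                         align_selection: np.ndarray,
                         grid_spacing: float = 1.0,
                         padding: float = 5.0) -> DensityGrid:
    """Time-averaged density of tracked atoms on a 3D grid.

    Frames are superposed on ``align_selection`` (a rigid part of the
    receptor); tracked-atom positions are binned at ``grid_spacing``.  The
    grid covers the tracked cloud with ``padding`` A margins; positions off
    the grid are tallied in ``n_outside``.
    """
    tracked = np.asarray(tracked_atoms, dtype=int)
    align = np.asarray(align_selection, dtype=int)
    if tracked.size == 0:
        raise ValueError("no tracked atoms")
    if align.size < 3:
        raise ValueError("alignment selection needs >= 3 atoms")
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    coords = superpose_frames(ens.analysis_coords(), align)
    pos = coords[:, tracked, :].reshape(-1, 3)
    lo = pos.min(axis=0) - padding
    hi = pos.max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / grid_spacing).astype(int), 1)
    idx = np.floor((pos - lo) / grid_spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, tuple(idx[inside].T), 1)
    return DensityGrid(origin=lo, spacing=grid_spacing, counts=counts,
                       n_frames=coords.shape[0],
                       n_outside=int((~inside).sum()))


# ---------------------------------------------------------------------------
# Pocket volume
# ---------------------------------------------------------------------------

def pocket_volume(top: Topology, frame: np.ndarray,
                  ligand_res_id: int | None = None,
                  center: np.ndarray | None = None,
                  spacing: float = 1.0, box: float = 12.0,
                  core_radius: float = 4.0, prune: bool = True,
                  radii_table: dict[str, float] | None = None
                  ) -> VolumeResult:
    """Open volume of the binding-site box in one frame (A^3).

    A ``box`` x ``box`` x ``box`` A grid of voxel centres placed at integer
    multiples of the spacing from the ligand centroid (or an explicit
    ``center``); an even voxel count extends one half-voxel farther on the
    negative side.
    A voxel is deleted when its centre lies within the van der Waals radius
    of any receptor (non-ligand) atom.  With ``prune`` the surviving voxels
    disconnected (6-connectivity) from the core sphere of ``core_radius``
    at the box centre are discarded as outside pockets.
    Volume = retained voxels x spacing^3.
    """
    if spacing <= 0 or box <= 0:
        raise ValueError("spacing and box must be positive")
    radii = BONDI_RADII if radii_table is None else radii_table
    if center is None:
        lig = ligand_res_id if ligand_res_id is not None else \
            _one_ligand(top)
        lig_idx = top.atoms_of_residue(lig)
        center = frame[lig_idx].mean(axis=0)
        exclude = set(int(i) for i in lig_idx)
    else:
        center = np.asarray(center, dtype=float)
        exclude = set(int(i) for i in
                      (top.atoms_of_residue(ligand_res_id)
                       if ligand_res_id is not None else []))

    n = int(round(box / spacing))
    # grid points at integer multiples of the spacing from the box centre
    # (even counts extend one half-voxel farther on the negative side)
    axis = spacing * (np.arange(n) - n // 2)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1) + center    # (n,n,n,3)

    keep = np.ones((n, n, n), dtype=bool)
    half_diag = box * np.sqrt(3) / 2.0
    max_r = max(radii.values()) if radii else _DEFAULT_RADIUS
    for a in range(top.n_atoms):
        if a in exclude:
            continue
        pos = frame[a]
        if np.linalg.norm(pos - center) > half_diag + max_r:
            continue
        r = radii.get(str(top.elements[a]), _DEFAULT_RADIUS)
        d2 = ((pts - pos) ** 2).sum(axis=-1)
        keep &= d2 > r * r

    if prune and keep.any():
        labels, _ = ndimage.label(keep)   # default structure = 6-connectivity
        core = (((pts - center) ** 2).sum(axis=-1)
                <= core_radius * core_radius) & keep
        good = np.unique(labels[core])
        good = good[good != 0]
        keep &= np.isin(labels, good)

    retained = int(keep.sum())
    return VolumeResult(retained, retained * spacing ** 3, spacing, box,
                        core_radius)


def pocket_volume_series(top: Topology, ens: TrajectoryEnsemble,
                         ligand_res_id: int | None = None,
                         **kwargs) -> VolumeResult:
    """Per-frame pocket volumes pooled over all analysis frames (mean +- SD)."""
    coords = ens.analysis_coords()
    vols = np.array([pocket_volume(top, coords[f], ligand_res_id,
                                   **kwargs).volume
                     for f in range(coords.shape[0])])
    last = pocket_volume(top, coords[-1], ligand_res_id, **kwargs)
    return VolumeResult(last.retained_points, float(vols.mean()),
                        last.spacing, last.box, last.core_radius,
                        per_frame=vols)


def _one_ligand(top: Topology) -> int:
    lig = top.ligand_res_ids
    if len(lig) != 1:
        raise ValueError("pocket_volume needs a unique ligand residue or an "
                         "explicit center")
    return lig[0]


# ---------------------------------------------------------------------------
# Activation-state projection
# ---------------------------------------------------------------------------

def state_projection(top: Topology, ens: TrajectoryEnsemble,
                     pair_a: tuple[int, int], pair_b: tuple[int, int],
                     bin_width: float = 0.25,
                     markers: list[tuple[str, float, float]] | None = None
                     ) -> StateProjection:
    """Project the ensemble onto two C-alpha distances (A).

    ``pair_a`` and ``pair_b`` are residue-id pairs (e.g. the TM3-TM6 and
    TM3-TM7 probes R102-E228 and R102-Y288); per-frame distances are
    histogrammed on a 2D grid of ``bin_width``.  ``markers`` annotates
    reference points such as crystal-structure distances.
    """
    coords = ens.analysis_coords()

    def ca(res: int) -> int:
        idx = top.calpha_indices([res])
        if idx.size == 0:
            raise ValueError(f"residue {res} has no C-alpha atom")
        return int(idx[0])

    ia, ja = (ca(r) for r in pair_a)
    ib, jb = (ca(r) for r in pair_b)
    d_a = np.linalg.norm(coords[:, ia] - coords[:, ja], axis=-1)
    d_b = np.linalg.norm(coords[:, ib] - coords[:, jb], axis=-1)
    lo_a = np.floor(d_a.min() / bin_width) * bin_width
    hi_a = np.ceil(d_a.max() / bin_width) * bin_width + bin_width / 2
    lo_b = np.floor(d_b.min() / bin_width) * bin_width
    hi_b = np.ceil(d_b.max() / bin_width) * bin_width + bin_width / 2
    edges_a = np.arange(lo_a, hi_a + bin_width, bin_width)
    edges_b = np.arange(lo_b, hi_b + bin_width, bin_width)
    hist, _, _ = np.histogram2d(d_a, d_b, bins=(edges_a, edges_b))
    return StateProjection(d_a, d_b, hist, edges_a, edges_b,
                           markers or [])
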