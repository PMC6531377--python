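"""Topology / trajectory ensemble I/O and analysis-window management.

The package analyses multi-run molecular-dynamics ensembles (several
independent replicas of the same system).  Analyses are restricted to the
trailing fraction of every run independently — the convention of discarding
the first half of each replica as equilibration and keeping the "last half"
as the production window.

Topologies are PDB files (read and written through :mod:`biotite`); coordinate
series use a documented plain-text dialect so that fixtures stay small,
diffable and platform independent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Topology",
    "TrajectoryEnsemble",
    "RegionSet",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "select_analysis_frames",
    "load_region_fixture",
    "A2AR_REGIONS",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Atom/residue bookkeeping for one molecular system.

    Parallel arrays over atoms; residues are ordered by (chain, residue id).
    ``ligand_mask`` marks atoms belonging to ligand (HETATM) residues.
    """

    atom_names: np.ndarray          # (A,) str
    elements: np.ndarray            # (A,) str, e.g. "C", "N"
    res_ids: np.ndarray             # (A,) int, author numbering (1-based)
    res_names: np.ndarray           # (A,) str
    chains: np.ndarray              # (A,) str
    ligand_mask: np.ndarray         # (A,) bool
    bw_labels: dict[int, str] = field(default_factory=dict)  # res_id -> "3.50"

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for arr in (self.elements, self.res_ids, self.res_names,
                    self.chains, self.ligand_mask):
            if len(arr) != n:
                raise ValueError("topology arrays must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residue_ids(self) -> list[int]:
        """Ordered unique residue ids (order of first appearance)."""
        seen: dict[int, None] = {}
        for r in self.res_ids:
            seen.setdefault(int(r), None)
        return list(seen)

    def atoms_of_residue(self, res_id: int) -> np.ndarray:
        """Indices of the atoms belonging to one residue."""
        idx = np.nonzero(self.res_ids == res_id)[0]
        if idx.size == 0:
            raise KeyError(f"residue {res_id} not in topology")
        return idx

    def atom_index(self, res_id: int, atom_name: str) -> int:
        idx = np.nonzero((self.res_ids == res_id)
                         & (self.atom_names == atom_name))[0]
        if idx.size == 0:
            raise KeyError(f"atom {atom_name} of residue {res_id} not found")
        return int(idx[0])

    def calpha_indices(self, res_ids: list[int] | None = None) -> np.ndarray:
        mask = (self.atom_names == "CA") & ~self.ligand_mask
        if res_ids is not None:
            mask &= np.isin(self.res_ids, res_ids)
        return np.nonzero(mask)[0]

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    @property
    def ligand_res_ids(self) -> list[int]:
        return sorted({int(r) for r in self.res_ids[self.ligand_mask]})


@dataclass
class TrajectoryEnsemble:
    """A multi-run coordinate ensemble in Angstrom.

    ``runs`` is a list of (frames, atoms, 3) float arrays, one per replica.
    ``window`` is the trailing fraction of every run used for analysis
    (0.5 emulates keeping the last 100 ns of 200 ns runs).
    """

    runs: list[np.ndarray]
    window: float = 1.0

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("ensemble needs at least one run")
        n_atoms = self.runs[0].shape[1]
        for r in self.runs:
            if r.ndim != 3 or r.shape[2] != 3:
                raise ValueError("run arrays must have shape (frames, atoms, 3)")
            if r.shape[1] != n_atoms:
                raise ValueError("all runs must share the atom count")
        if not 0.0 < self.window <= 1.0:
            raise ValueError("window fraction must be in (0, 1]")

    @property
    def n_atoms(self) -> int:
        return self.runs[0].shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def window_frames(self, run: int) -> np.ndarray:
        """The analysis frames of one run (trailing ``floor(window*frames)``)."""
        arr = self.runs[run]
        k = int(np.floor(self.window * arr.shape[0]))
        if k < 1:
            raise ValueError("analysis window empty for run %d" % run)
        return arr[arr.shape[0] - k:]

    def analysis_coords(self) -> np.ndarray:
        """All analysis frames pooled over runs: (F, atoms, 3)."""
        return np.concatenate([self.window_frames(i)
                               for i in range(self.n_runs)], axis=0)

    def analysis_counts(self) -> list[int]:
        """Per-run analysis-frame counts (run boundaries for torsion series)."""
        return [self.window_frames(i).shape[0] for i in range(self.n_runs)]


@dataclass
class RegionSet:
    """A named residue set (extracellular, intracellular, binding site ...).

    ``parts`` optionally keeps named sub-lists (individual loops) so that
    per-loop subtotals can be reported alongside region totals.
    """

    name: str
    res_ids: list[int]
    parts: dict[str, list[int]] = field(default_factory=dict)

    def __contains__(self, res_id: int) -> bool:
        return res_id in self.res_ids

    def __len__(self) -> int:
        return len(self.res_ids)


# ---------------------------------------------------------------------------
# PDB topology I/O (biotite-backed)
# ---------------------------------------------------------------------------

def read_topology(path: str | Path,
                  ligand_res_names: list[str] | None = None
                  ) -> tuple[Topology, np.ndarray]:
    """Read a PDB topology; returns (Topology, coordinates of the model).

    Ligand residues are those stored as HETATM records, or any residue whose
    name is listed in ``ligand_res_names``.  Insertion codes are rejected:
    author numbering must be unambiguous.
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    ins = arr.ins_code
    if np.any(ins != ""):
        raise ValueError("insertion codes are unsupported; renumber the PDB")
    ligand = np.asarray(arr.hetero, dtype=bool).copy()
    if ligand_res_names:
        ligand |= np.isin(arr.res_name, ligand_res_names)
    elements = np.array([e.capitalize() if e else _guess_element(n)
                         for e, n in zip(arr.element, arr.atom_name)])
    top = Topology(
        atom_names=np.asarray(arr.atom_name, dtype=object),
        elements=np.asarray(elements, dtype=object),
        res_ids=np.asarray(arr.res_id, dtype=int),
        res_names=np.asarray(arr.res_name, dtype=object),
        chains=np.asarray(arr.chain_id, dtype=object),
        ligand_mask=ligand,
    )
    return top, np.asarray(arr.coord, dtype=float)


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name[1:]
    return name[:1].upper()


def write_topology(path: str | Path, top: Topology, coords: np.ndarray,
                   bfactors: np.ndarray | None = None) -> None:
    """Write a Topology + one coordinate frame as PDB.

    ``bfactors`` (per atom, A^2) fills the B-factor column — used to export
    flexibility heat maps for structure viewers.
    """
    n = top.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = np.asarray(top.atom_names, dtype="U6")
    arr.element = np.asarray([e.upper() for e in top.elements], dtype="U2")
    arr.res_id = np.asarray(top.res_ids, dtype=int)
    arr.res_name = np.asarray(top.res_names, dtype="U5")
    arr.chain_id = np.asarray(top.chains, dtype="U4")
    arr.hetero = np.asarray(top.ligand_mask, dtype=bool)
    if bfactors is not None:
        arr.set_annotation("b_factor", np.asarray(bfactors, dtype=float))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Plain-text trajectory dialect
# ---------------------------------------------------------------------------
# Line 1:  "gpcrdyn-traj 1"            (magic + version)
# Line 2:  "<n_atoms> <n_frames>"
# Then n_frames blocks of n_atoms lines "x y z" (Angstrom, %.6f).

_TRAJ_MAGIC = "gpcrdyn-traj 1"


def write_trajectory(path: str | Path, coords: np.ndarray) -> None:
    """Write one run (frames, atoms, 3) in the plain-text dialect."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("expected (frames, atoms, 3) coordinates")
    n_frames, n_atoms, _ = coords.shape
    with open(path, "w") as fh:
        fh.write(f"{_TRAJ_MAGIC}\n{n_atoms} {n_frames}\n")
        np.savetxt(fh, coords.reshape(-1, 3), fmt="%.6f")


def read_trajectory(path: str | Path) -> np.ndarray:
    """Read one run from the plain-text dialect -> (frames, atoms, 3)."""
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _TRAJ_MAGIC:
            raise ValueError(f"not a gpcrdyn trajectory file: {path!s}")
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("malformed trajectory header")
        n_atoms, n_frames = (int(x) for x in header)
        flat = np.loadtxt(io.StringIO(fh.read()), dtype=float, ndmin=2)
    if flat.shape != (n_frames * n_atoms, 3):
        raise ValueError(
            f"trajectory body has {flat.shape[0]} rows, "
            f"expected {n_frames * n_atoms}")
    return flat.reshape(n_frames, n_atoms, 3)


def select_analysis_frames(ens: TrajectoryEnsemble,
                           window: float = 0.5) -> TrajectoryEnsemble:
    """Restrict the ensemble to the trailing ``window`` fraction of each run.

    Selection is per run, never across concatenated runs, so replica
    boundaries cannot bleed into each other.  The frame count kept per run is
    ``floor(window * frames)``, taken from the tail.
    """
    if not 0.0 < window <= 1.0:
        raise ValueError("window fraction must be in (0, 1]")
    out_runs = []
    for i, arr in enumerate(ens.runs):
        k = int(np.floor(window * arr.shape[0]))
        if k < 1:
            raise ValueError(f"window {window} empties run {i}")
        out_runs.append(arr[arr.shape[0] - k:].copy())
    return TrajectoryEnsemble(runs=out_runs, window=1.0)


# ---------------------------------------------------------------------------
# Region fixtures (adenosine A2A receptor)
# ---------------------------------------------------------------------------
# Residue ranges in author numbering; ranges inclusive on both ends.
# "extracellular"/"intracellular" are the loop regions (loops plus the top or
# bottom two helical turns) used for torsional-entropy totals; "ec_region" is
# the broader extracellular surface used as allosteric pathway sources;
# "gprotein_interface" is the sink set; "binding_site" the orthosteric pocket.

def _expand(*items: int | tuple[int, int]) -> list[int]:
    out: list[int] = []
    for it in items:
        if isinstance(it, tuple):
            out.extend(range(it[0], it[1] + 1))
        else:
            out.append(it)
    return out


A2AR_REGIONS: dict[str, RegionSet] = {
    "extracellular": RegionSet(
        "extracellular",
        _expand((64, 78), (137, 178), (254, 271)),
        parts={"ECL1": _expand((64, 78)),
               "ECL2": _expand((137, 178)),
               "ECL3": _expand((254, 271))}),
    "intracellular": RegionSet(
        "intracellular",
        _expand((30, 43), (104, 121), (208, 230)),
        parts={"ICL1": _expand((30, 43)),
               "ICL2": _expand((104, 121)),
               "ICL3": _expand((208, 230))}),
    "gprotein_interface": RegionSet(
        "gprotein_interface",
        _expand(102, (105, 114), 200, 203, 204, (207, 211), 231, 234, 235)),
    "binding_site": RegionSet(
        "binding_site",
        _expand(60, (81, 86), 89, 153, 156, 159, 162, 166, 170, 171,
                239, 242, 243, 246, 263, (267, 271))),
    "ec_region": RegionSet(
        "ec_region",
        _expand((6, 10), (68, 83), (145, 176), (256, 272))),
}

#: Ballesteros-Weinstein labels for the activation-state projection residues.
A2AR_BW_LABELS = {102: "3.50", 228: "6.30", 288: "7.53", 246: "6.48",
                  52: "2.50", 91: "3.39"}


def load_region_fixture(receptor: str = "A2AR") -> list[RegionSet]:
    """Built-in region definitions for a supported receptor.

    For the adenosine A2A receptor this returns the extracellular and
    intracellular loop regions, the orthosteric binding-site residues, the
    G-protein-interface residues and the extracellular surface residues.
    """
    if receptor.upper() != "A2AR":
        raise KeyError(f"no region fixture for receptor {receptor!r}")
    return [RegionSet(r.name, list(r.res_ids), dict(r.parts))
            for r in A2AR_REGIONS.values()]
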