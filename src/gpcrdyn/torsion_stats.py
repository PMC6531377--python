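"""Torsion-angle statistics: first-order Gibbs entropy and mutual information.

Conformational entropy is estimated in internal (torsion) coordinates, which
fluctuates far less than Cartesian estimates; bond and angle degrees of
freedom are neglected as their contributions are comparatively small.  For
every torsion the marginal (first-order) entropy is the Gibbs entropy of the
binned angle distribution,

    S_raw = - sum_k p_k ln p_k            (nats, i.e. units of k_B)

with a Miller-Madow correction for finite sampling,

    S = S_raw + (M_occ - 1) / (2 N)

where M_occ is the number of occupied bins and N the sample count.  Pairwise
mutual information uses the same estimator on the joint M x M histogram:

    MI = S(a) + S(b) - S(a, b)

The Miller-Madow terms largely cancel the positive plug-in bias of MI for
independent torsions; residual negative estimates are clamped to zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .traj_io import RegionSet, Topology, TrajectoryEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "TorsionSeries",
    "EntropyResult",
    "MIMatrix",
    "dihedral",
    "extract_torsions",
    "entropy_first_order",
    "region_entropy",
    "mutual_information_pair",
    "mi_matrix",
]

DEFAULT_BINS = 30  # 12-degree bins over [-180, 180)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TorsionSeries:
    """One torsion's angle series over the analysis window, degrees [-180, 180).

    ``run_lengths`` keeps the per-run frame counts so replica boundaries are
    never lost, though the histogram estimators pool all samples.
    """

    res_id: int
    name: str                      # "phi", "psi", "chi1", ...
    angles: np.ndarray             # (N,) degrees
    run_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size and (self.angles.min() < -180.0
                                 or self.angles.max() >= 180.0):
            raise ValueError("angles must lie in [-180, 180)")
        if self.run_lengths and sum(self.run_lengths) != self.angles.size:
            raise ValueError("run lengths do not sum to series length")

    @property
    def n(self) -> int:
        return self.angles.size


@dataclass
class EntropyResult:
    res_id: int
    name: str
    raw: float          # plug-in Gibbs entropy, nats (k_B units)
    corrected: float    # raw + undersampling correction
    correction: float
    m_occupied: int
    n: int


@dataclass
class MIMatrix:
    """Symmetric residue-pair mutual information (nats).

    ``pairs`` maps frozenset({res_i, res_j}) -> MI; ``attained_by`` records
    which torsion pair attained the residue-level value.
    """

    pairs: dict[frozenset, float]
    attained_by: dict[frozenset, tuple[str, str]]

    def get(self, i: int, j: int) -> float:
        return self.pairs.get(frozenset((i, j)), 0.0)

    def residues(self) -> set[int]:
        out: set[int] = set()
        for key in self.pairs:
            out |= set(key)
        return out


# ---------------------------------------------------------------------------
# Torsion extraction
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle (degrees, [-180, 180)) for stacked coordinates.

    Implements the standard atan2 formulation; inputs may be (3,) or (F, 3).
    Returns NaN where the central atoms are colinear (undefined dihedral).
    """
    p0, p1, p2, p3 = (np.atleast_2d(np.asarray(p, dtype=float))
                      for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(n1, n2), b1 / b1n[:, None])
        ang = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=-1) < 1e-10) | \
          (np.linalg.norm(n2, axis=-1) < 1e-10)
    ang[bad] = np.nan
    # map +180 exactly onto -180 to stay inside the half-open interval
    ang[ang >= 180.0] = -180.0
    return ang


_BACKBONE = ("N", "CA", "C")


def _residue_torsion_defs(top: Topology, which: str) -> list[tuple[int, str, tuple[int, int, int, int]]]:
    """(res_id, torsion_name, atom index quadruple) for each defined torsion."""
    defs = []
    res_ids = [r for r in top.residue_ids if r not in set(top.ligand_res_ids)]
    by_res = {r: top.atoms_of_residue(r) for r in res_ids}

    def find(res: int, name: str) -> int | None:
        for idx in by_res[res]:
            if top.atom_names[idx] == name:
                return int(idx)
        return None

    for pos, res in enumerate(res_ids):
        if which in ("backbone", "both"):
            prev_res = res_ids[pos - 1] if pos > 0 else None
            next_res = res_ids[pos + 1] if pos + 1 < len(res_ids) else None
            n, ca, c = (find(res, a) for a in _BACKBONE)
            # phi: C(i-1) - N - CA - C
            if prev_res is not None:
                c_prev = find(prev_res, "C")
                if None not in (c_prev, n, ca, c):
                    defs.append((res, "phi", (c_prev, n, ca, c)))
                else:
                    logger.info("residue %d: phi skipped (missing atoms)", res)
            # psi: N - CA - C - N(i+1)
            if next_res is not None:
                n_next = find(next_res, "N")
                if None not in (n, ca, c, n_next):
                    defs.append((res, "psi", (n, ca, c, n_next)))
                else:
                    logger.info("residue %d: psi skipped (missing atoms)", res)
        if which in ("sidechain", "both"):
            # chi1: N - CA - CB - CG (or first gamma-position heavy atom)
            n, ca, cb = find(res, "N"), find(res, "CA"), find(res, "CB")
            cg = None
            for gname in ("CG", "CG1", "OG", "OG1", "SG"):
                cg = find(res, gname)
                if cg is not None:
                    break
            if None not in (n, ca, cb, cg):
                defs.append((res, "chi1", (n, ca, cb, cg)))
    return defs


def extract_torsions(top: Topology, ens: TrajectoryEnsemble,
                     which: str = "both") -> list[TorsionSeries]:
    """Compute per-residue torsion series over the ensemble's analysis window.

    ``which`` selects backbone (phi/psi), sidechain (chi1) or both.  Terminal
    residues lacking phi or psi are skipped with a log record; frames with an
    undefined (colinear) dihedral are dropped from that torsion's series.
    """
    if which not in ("backbone", "sidechain", "both"):
        raise ValueError("which must be backbone, sidechain or both")
    defs = _residue_torsion_defs(top, which)
    counts = ens.analysis_counts()
    coords = ens.analysis_coords()
    out = []
    for res, name, (a, b, c, d) in defs:
        ang = dihedral(coords[:, a], coords[:, b], coords[:, c], coords[:, d])
        bad = np.isnan(ang)
        if bad.any():
            logger.warning("torsion %s of residue %d: %d undefined frames "
                           "excluded", name, res, int(bad.sum()))
            ang = ang[~bad]
            out.append(TorsionSeries(res, name, ang, run_lengths=()))
        else:
            out.append(TorsionSeries(res, name, ang,
                                     run_lengths=tuple(counts)))
    return out


# ---------------------------------------------------------------------------
# Entropy & mutual information estimators
# ---------------------------------------------------------------------------

def _angle_bin_index(angles: np.ndarray, m: int) -> np.ndarray:
    idx = np.floor((np.asarray(angles, dtype=float) + 180.0)
                   * (m / 360.0)).astype(np.int64)
    # guard against roundoff at the right edge
    return np.clip(idx, 0, m - 1)


def _plugin_entropy(counts: np.ndarray, n: int) -> tuple[float, int]:
    p = counts[counts > 0] / n
    s = float(-(p * np.log(p)).sum())
    return (s if s != 0.0 else 0.0), int(p.size)


def entropy_first_order(series: TorsionSeries,
                        m_bins: int = DEFAULT_BINS,
                        correction: str = "miller-madow") -> EntropyResult:
    """First-order torsional entropy of one angle series (k_B units).

    Histogram over ``m_bins`` equal bins of [-180, 180); plug-in Gibbs
    entropy plus the chosen undersampling correction ("miller-madow" adds
    (M_occ - 1)/(2N); "none" disables it).
    """
    if series.n == 0:
        raise ValueError("empty torsion series")
    if series.n < m_bins:
        warnings.warn(f"only {series.n} samples for {m_bins} bins; entropy "
                      "will be strongly undersampled", stacklevel=2)
    counts = np.bincount(_angle_bin_index(series.angles, m_bins),
                         minlength=m_bins)
    raw, m_occ = _plugin_entropy(counts, series.n)
    if correction == "miller-madow":
        corr = (m_occ - 1) / (2.0 * series.n)
    elif correction == "none":
        corr = 0.0
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return EntropyResult(series.res_id, series.name, raw, raw + corr,
                         corr, m_occ, series.n)


def region_entropy(results: list[EntropyResult], region: RegionSet
                   ) -> tuple[float, dict[str, float]]:
    """Total corrected torsional entropy of a residue region (k_B units).

    Sums the corrected per-torsion entropies over every torsion of every
    region residue; returns (total, per-part subtotals) where parts are the
    region's named loops.  Residues of the region with no torsion result at
    all raise, listing the missing ids.
    """
    by_res: dict[int, float] = {}
    for r in results:
        by_res[r.res_id] = by_res.get(r.res_id, 0.0) + r.corrected
    missing = [i for i in region.res_ids if i not in by_res]
    if missing:
        raise ValueError(f"region {region.name!r}: no torsion results for "
                         f"residues {missing}")
    total = float(sum(by_res[i] for i in region.res_ids))
    subtotals = {part: float(sum(by_res[i] for i in ids if i in by_res))
                 for part, ids in region.parts.items()}
    return total, subtotals


def mutual_information_pair(a: TorsionSeries, b: TorsionSeries,
                            m_bins: int = DEFAULT_BINS,
                            correction: str = "miller-madow"
                            ) -> tuple[float, float]:
    """Mutual information between two torsions (nats).

    MI = S(a) + S(b) - S(a,b) with the same histogram estimator and
    undersampling correction applied to every term; the joint uses an
    m_bins x m_bins grid.  Returns (clamped MI, raw MI): negative estimates
    are clamped to 0 but the raw value is retained.
    """
    if a.n != b.n:
        raise ValueError("torsion series lengths differ")
    n = a.n
    ia = _angle_bin_index(a.angles, m_bins)
    ib = _angle_bin_index(b.angles, m_bins)
    ca = np.bincount(ia, minlength=m_bins)
    cb = np.bincount(ib, minlength=m_bins)
    cj = np.bincount(ia * m_bins + ib, minlength=m_bins * m_bins)
    sa, ma = _plugin_entropy(ca, n)
    sb, mb = _plugin_entropy(cb, n)
    sj, mj = _plugin_entropy(cj, n)
    if correction == "miller-madow":
        sa += (ma - 1) / (2.0 * n)
        sb += (mb - 1) / (2.0 * n)
        sj += (mj - 1) / (2.0 * n)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    raw_mi = sa + sb - sj
    return max(raw_mi, 0.0), raw_mi


def mi_matrix(series: list[TorsionSeries],
              pairs: list[tuple[int, int]] | None = None,
              m_bins: int = DEFAULT_BINS,
              aggregate: str = "max") -> MIMatrix:
    """Residue-level MI for the requested residue pairs.

    Residue-level MI aggregates over all (torsion of i, torsion of j)
    combinations; ``aggregate`` is "max" (default), "sum" or "mean".  The
    matrix is symmetric; the attaining torsion pair is recorded.
    """
    if aggregate not in ("max", "sum", "mean"):
        raise ValueError("aggregate must be max, sum or mean")
    by_res: dict[int, list[TorsionSeries]] = {}
    for s in series:
        by_res.setdefault(s.res_id, []).append(s)
    if pairs is None:
        ids = sorted(by_res)
        pairs = [(ids[i], ids[j]) for i in range(len(ids))
                 for j in range(i + 1, len(ids))]
    out: dict[frozenset, float] = {}
    attained: dict[frozenset, tuple[str, str]] = {}
    for i, j in pairs:
        if i not in by_res or j not in by_res:
            raise KeyError(f"residue pair ({i}, {j}) has no torsion series")
        vals = []
        for si in by_res[i]:
            for sj in by_res[j]:
                mi, _ = mutual_information_pair(si, sj, m_bins=m_bins)
                vals.append((mi, (si.name, sj.name)))
        if aggregate == "max":
            best = max(vals, key=lambda v: v[0])
        elif aggregate == "sum":
            best = (sum(v[0] for v in vals), ("sum", "sum"))
        else:
            best = (sum(v[0] for v in vals) / len(vals), ("mean", "mean"))
        key = frozenset((i, j))
        out[key] = float(best[0])
        attained[key] = best[1]
    return MIMatrix(out, attained)
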