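"""Config-driven orchestration over one or more receptor states.

A run config (YAML or dict) names the states to analyse — each either a
topology + trajectory-run file set, or a synthetic toy-receptor spec — plus
region definitions, stage toggles and parameters.  ``run`` executes the
enabled stages per state, writes TSV/JSON artifacts and a machine-readable
manifest, and returns everything in memory; ``compare_states`` joins
per-state metrics into a delta report (stateB - stateA), the form used to
contrast inactive/active-intermediate/G-protein-bound ensembles.

Outputs carry no timestamps, so identical inputs give byte-identical
artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .traj_io import (RegionSet, TrajectoryEnsemble, load_region_fixture,
                      read_topology, read_trajectory, select_analysis_frames,
                      write_topology)
from .torsion_stats import (entropy_first_order, extract_torsions, mi_matrix,
                            region_entropy)
from .allosteer import assemble_pipelines, build_graph, enumerate_pathways
from .contacts import contact_occupancy
from .pocket_geometry import (compute_rmsf, pocket_volume_series,
                              rmsf_to_bfactor, state_projection)
from .free_energy import WindowWork, bar_total
from .synthetic_data import ToyReceptorSpec, gen_toy_trajectory

logger = logging.getLogger(__name__)

__all__ = ["run", "compare_states", "load_config", "read_work_table"]

_FLOAT_FMT = "%.10g"

_DEFAULTS = {
    "window": 0.5,
    "bins": 30,
    "proximity_cutoff": 5.0,
    "proximity_occupancy": 0.75,
    "grid_spacing": 1.0,
    "box": 12.0,
    "core_radius": 4.0,
    "torsions": "backbone",
    "infer_missing_h": True,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _validate(cfg: dict) -> dict:
    cfg = dict(cfg)
    params = {**_DEFAULTS, **cfg.get("params", {})}
    for key in ("proximity_cutoff", "grid_spacing", "box", "core_radius"):
        if params[key] <= 0:
            raise ValueError(f"parameter {key!r} must be positive, got "
                             f"{params[key]}")
    if not 0.0 < params["window"] <= 1.0:
        raise ValueError("parameter 'window' must be in (0, 1]")
    if int(params["bins"]) < 2:
        raise ValueError("parameter 'bins' must be >= 2")
    if not cfg.get("states"):
        raise ValueError("config defines no states")
    for name, state in cfg["states"].items():
        if "synthetic" not in state:
            for key in ("topology", "runs"):
                if key not in state:
                    raise ValueError(f"state {name!r} missing {key!r}")
                paths = state[key] if key == "runs" else [state[key]]
                for p in paths:
                    if not Path(p).exists():
                        raise ValueError(f"state {name!r}: path {p} does "
                                         "not exist")
    cfg["params"] = params
    return cfg


def _regions_from_config(cfg: dict) -> dict[str, RegionSet]:
    spec = cfg.get("regions", {})
    if isinstance(spec, str):
        return {r.name: r for r in load_region_fixture(spec)}
    return {name: RegionSet(name, list(ids)) for name, ids in spec.items()}


def _load_state(name: str, state_cfg: dict, window: float, seed: int):
    if "synthetic" in state_cfg:
        syn = dict(state_cfg["synthetic"])
        syn.setdefault("seed", seed)
        syn.setdefault("window", window)
        sched = [tuple(e) for e in syn.pop("contact_schedule", [])]
        fix = gen_toy_trajectory(ToyReceptorSpec(contact_schedule=sched,
                                                 **syn))
        return fix.topology, fix.ensemble, fix.metadata
    top, _ = read_topology(state_cfg["topology"],
                           state_cfg.get("ligand_res_names"))
    runs = [read_trajectory(p) for p in state_cfg["runs"]]
    ens = TrajectoryEnsemble(runs=runs, window=window)
    return top, ens, {}


def read_work_table(path: str | Path) -> list[WindowWork]:
    """Read a work-sample table (TSV: window, direction, work[, units])."""
    df = pd.read_csv(path, sep="\t")
    need = {"window", "direction", "work"}
    if not need.issubset(df.columns):
        raise ValueError(f"work table needs columns {sorted(need)}")
    units = str(df["units"].iloc[0]) if "units" in df.columns else "reduced"
    out = []
    for win in sorted(df["window"].unique()):
        sub = df[df["window"] == win]
        fwd = sub[sub["direction"] == "forward"]["work"].to_numpy()
        rev = sub[sub["direction"] == "reverse"]["work"].to_numpy()
        out.append(WindowWork(int(win), fwd, rev, units=units))
    return out


# ---------------------------------------------------------------------------
# Stage execution
# ---------------------------------------------------------------------------

def _stage_entropy(top, ens, regions, params, out_dir, state):
    series = extract_torsions(top, ens, which=params["torsions"])
    results = [entropy_first_order(s, m_bins=int(params["bins"]))
               for s in series]
    df = pd.DataFrame([{"res_id": r.res_id, "torsion": r.name,
                        "S_raw": r.raw, "S_corrected": r.corrected,
                        "correction": r.correction, "M_occ": r.m_occupied,
                        "N": r.n} for r in results])
    df.to_csv(out_dir / f"{state}_entropy.tsv", sep="\t", index=False,
              float_format=_FLOAT_FMT)
    region_rows = []
    totals = {}
    present = set(r.res_id for r in results)
    for rset in regions.values():
        usable = RegionSet(rset.name,
                           [i for i in rset.res_ids if i in present],
                           {k: [i for i in v if i in present]
                            for k, v in rset.parts.items()})
        if not usable.res_ids:
            continue
        total, parts = region_entropy(results, usable)
        totals[rset.name] = total
        region_rows.append({"region": rset.name, "part": "total",
                            "S_total": total,
                            "n_residues": len(usable.res_ids)})
        for part, val in parts.items():
            region_rows.append({"region": rset.name, "part": part,
                                "S_total": val,
                                "n_residues": len(usable.parts[part])})
    if region_rows:
        pd.DataFrame(region_rows).to_csv(out_dir / f"{state}_region_entropy.tsv",
                                         sep="\t", index=False,
                                         float_format=_FLOAT_FMT)
    return {"series": series, "per_torsion": results,
            "region_totals": totals}


def _stage_mi(top, ens, params, out_dir, state, series):
    mi = mi_matrix(series, m_bins=int(params["bins"]))
    rows = [{"res_i": min(k), "res_j": max(k), "mi": v,
             "torsion_i": mi.attained_by[k][0],
             "torsion_j": mi.attained_by[k][1]}
            for k, v in sorted(mi.pairs.items(), key=lambda kv: sorted(kv[0]))]
    pd.DataFrame(rows).to_csv(out_dir / f"{state}_mi.tsv", sep="\t",
                              index=False, float_format=_FLOAT_FMT)
    return mi


def _stage_allosteer(top, ens, mi, regions, params, out_dir, state):
    rg = build_graph(top, ens, mi,
                     proximity_cutoff=params["proximity_cutoff"],
                     proximity_occupancy=params["proximity_occupancy"])
    sources = regions.get("ec_region") or regions.get("extracellular")
    sinks = regions.get("gprotein_interface") or regions.get("intracellular")
    via = regions.get("binding_site")
    if sources is None or sinks is None:
        raise ValueError("allosteer stage needs source (ec_region/"
                         "extracellular) and sink (gprotein_interface/"
                         "intracellular) regions")
    paths = enumerate_pathways(rg, sources, sinks, via)
    rows = [{"source": p.source, "sink": p.sink,
             "residues": "-".join(map(str, p.residues)),
             "total_mi": p.total_mi, "total_cost": p.total_cost}
            for p in paths]
    pd.DataFrame(rows).to_csv(out_dir / f"{state}_pathways.tsv", sep="\t",
                              index=False, float_format=_FLOAT_FMT)
    pipelines = assemble_pipelines(paths) if paths else []
    prow, hrow = [], []
    for k, pl in enumerate(pipelines):
        prow.append({"pipeline": k, "strength": pl.strength})
        for res, cnt in sorted(pl.hub_counts.items()):
            hrow.append({"pipeline": k, "res_id": res, "hub_count": cnt})
    pd.DataFrame(prow).to_csv(out_dir / f"{state}_pipelines.tsv", sep="\t",
                              index=False)
    pd.DataFrame(hrow).to_csv(out_dir / f"{state}_hubs.tsv", sep="\t",
                              index=False)
    return {"graph": rg, "pathways": paths, "pipelines": pipelines}


def _stage_contacts(top, ens, params, out_dir, state, residues):
    records = []
    for res in residues:
        for kind in ("hbond", "vdw"):
            rec = contact_occupancy(top, ens, res, kind,
                                    infer_missing_h=params["infer_missing_h"])
            records.append(rec)
        records.append(contact_occupancy(
            top, ens, res, "any",
            infer_missing_h=params["infer_missing_h"]))
    df = pd.DataFrame([{"res_id": r.res_id, "kind": r.kind,
                        "occupancy_pct": 100.0 * r.occupancy,
                        "sustained": r.sustained,
                        "mean_distance_contact": r.mean_distance_contact,
                        "mean_distance_all": r.mean_distance_all}
                       for r in records])
    df.to_csv(out_dir / f"{state}_contacts.tsv", sep="\t", index=False,
              float_format=_FLOAT_FMT)
    return records


def _stage_geometry(top, ens, params, out_dir, state, geo_cfg):
    out = {}
    calpha = top.calpha_indices()
    heavy = np.nonzero(top.heavy_mask() & ~top.ligand_mask)[0]
    align = heavy if calpha.size < 3 else calpha
    rmsf = compute_rmsf(ens, heavy, align_selection=align)
    bfac = rmsf_to_bfactor(rmsf)
    pd.DataFrame({"atom_index": heavy,
                  "res_id": top.res_ids[heavy],
                  "atom": top.atom_names[heavy],
                  "rmsf": rmsf, "bfactor": bfac}).to_csv(
        out_dir / f"{state}_rmsf.tsv", sep="\t", index=False,
        float_format=_FLOAT_FMT)
    out["rmsf"] = dict(zip((int(i) for i in heavy), rmsf))
    # per-atom B-factor column for heat-map rendering
    ball = np.zeros(top.n_atoms)
    ball[heavy] = bfac
    write_topology(out_dir / f"{state}_bfactor.pdb", top,
                   ens.analysis_coords().mean(axis=0), bfactors=ball)
    if top.ligand_res_ids:
        vol = pocket_volume_series(top, ens,
                                   spacing=params["grid_spacing"],
                                   box=params["box"],
                                   core_radius=params["core_radius"])
        pd.DataFrame({"frame": np.arange(vol.per_frame.size),
                      "volume": vol.per_frame}).to_csv(
            out_dir / f"{state}_volume.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        out["volume_mean"] = vol.mean
        out["volume_sd"] = vol.sd
    pairs = geo_cfg.get("projection_pairs")
    if pairs:
        proj = state_projection(top, ens, tuple(pairs[0]), tuple(pairs[1]))
        pd.DataFrame({"d_a": proj.d_a, "d_b": proj.d_b}).to_csv(
            out_dir / f"{state}_projection.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        out["projection"] = proj
    return out


def _stage_bar(bar_cfg, out_dir, state):
    windows = read_work_table(bar_cfg["work_table"])
    res = bar_total(windows)
    payload = {
        "total_dg": res.total_dg, "total_se": res.total_se,
        "units": res.units,
        "windows": [{"index": w.index, "dg": w.dg, "se": w.se,
                     "se_reliable": w.se_reliable} for w in res.windows],
    }
    with open(out_dir / f"{state}_bar.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return res


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run(config: dict | str | Path, output_dir: str | Path | None = None
        ) -> dict:
    """Execute the enabled stages for every configured state.

    Writes per-stage TSV/JSON artifacts plus ``manifest.json`` (inputs,
    parameters, package version, seed) into the output directory and
    returns all results in memory, keyed by state.  A stage failure aborts
    with the stage name; a partial manifest records what completed.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    cfg = _validate(cfg)
    params = cfg["params"]
    out_dir = Path(output_dir or cfg.get("output_dir", "gpcrdyn_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", ["entropy", "mi", "allosteer", "contacts",
                                "geometry"])
    regions = _regions_from_config(cfg)

    results: dict[str, dict] = {}
    manifest = {"package": "gpcrdyn", "version": __version__, "seed": seed,
                "params": {k: v for k, v in params.items()},
                "states": {}, "stages": list(stages), "outputs": []}

    def _mark(path: Path):
        manifest["outputs"].append(str(path.name))

    for state_name, state_cfg in cfg["states"].items():
        logger.info("analysing state %s", state_name)
        sres: dict = {}
        stage = "load"
        try:
            top, ens, meta = _load_state(state_name, state_cfg,
                                         params["window"], seed)
            if "synthetic" not in state_cfg:
                ens = select_analysis_frames(ens, params["window"])
            manifest["states"][state_name] = {
                "inputs": {k: v for k, v in state_cfg.items()},
                "n_runs": ens.n_runs, "n_atoms": ens.n_atoms,
                "analysis_frames": ens.analysis_counts(),
            }
            series = None
            if "entropy" in stages or "mi" in stages or "allosteer" in stages:
                stage = "entropy"
                ent = _stage_entropy(top, ens, regions, params, out_dir,
                                     state_name)
                sres["entropy"] = ent
                series = ent["series"]
                _mark(out_dir / f"{state_name}_entropy.tsv")
            if "mi" in stages or "allosteer" in stages:
                stage = "mi"
                sres["mi"] = _stage_mi(top, ens, params, out_dir,
                                       state_name, series)
                _mark(out_dir / f"{state_name}_mi.tsv")
            if "allosteer" in stages:
                stage = "allosteer"
                sres["allosteer"] = _stage_allosteer(
                    top, ens, sres["mi"], regions, params, out_dir,
                    state_name)
                _mark(out_dir / f"{state_name}_pathways.tsv")
            if "contacts" in stages and top.ligand_res_ids:
                stage = "contacts"
                residues = state_cfg.get("contact_residues")
                if residues is None:
                    residues = [r for r in top.residue_ids
                                if r not in top.ligand_res_ids]
                sres["contacts"] = _stage_contacts(top, ens, params, out_dir,
                                                   state_name, residues)
                _mark(out_dir / f"{state_name}_contacts.tsv")
            if "geometry" in stages:
                stage = "geometry"
                sres["geometry"] = _stage_geometry(
                    top, ens, params, out_dir, state_name,
                    state_cfg.get("geometry", {}))
                _mark(out_dir / f"{state_name}_rmsf.tsv")
            if "bar" in stages and "bar" in state_cfg:
                stage = "bar"
                sres["bar"] = _stage_bar(state_cfg["bar"], out_dir,
                                         state_name)
                _mark(out_dir / f"{state_name}_bar.json")
        except Exception as exc:
            manifest["failed"] = {"state": state_name, "stage": stage,
                                  "error": str(exc)}
            with open(out_dir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1, sort_keys=True)
            raise RuntimeError(
                f"stage {stage!r} failed for state {state_name!r}: "
                f"{exc}") from exc
        sres["meta"] = meta
        sres["_topology"] = top
        sres["_ensemble"] = ens
        results[state_name] = sres

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["_manifest"] = manifest
    results["_output_dir"] = str(out_dir)
    return results


def compare_states(results: dict, pairs: list[tuple[str, str]],
                   out_dir: str | Path | None = None) -> dict:
    """Pairwise state deltas (stateB - stateA) across the computed metrics.

    Region entropies, pipeline strengths, sustained-contact occupancies and
    mean distances, pocket volume and per-residue B-factor deltas; contacts
    sustained in only one state are flagged.  States must have been run
    with identical parameters.
    """
    report: dict = {"pairs": []}
    for a, b in pairs:
        for s in (a, b):
            if s not in results:
                raise KeyError(f"state {s!r} not in results")
        ra, rb = results[a], results[b]
        entry: dict = {"stateA": a, "stateB": b}
        ea = ra.get("entropy", {}).get("region_totals", {})
        eb = rb.get("entropy", {}).get("region_totals", {})
        entry["region_entropy_delta"] = {
            k: eb[k] - ea[k] for k in sorted(set(ea) & set(eb))}
        pa = ra.get("allosteer", {}).get("pipelines", [])
        pb = rb.get("allosteer", {}).get("pipelines", [])
        entry["pipeline_strength"] = {
            a: [p.strength for p in pa], b: [p.strength for p in pb],
            "total_delta": (sum(p.strength for p in pb)
                            - sum(p.strength for p in pa))}
        ca = {(r.res_id, r.kind): r for r in ra.get("contacts", [])}
        cb = {(r.res_id, r.kind): r for r in rb.get("contacts", [])}
        rows = []
        for key in sorted(set(ca) | set(cb)):
            rec_a, rec_b = ca.get(key), cb.get(key)
            rows.append({
                "res_id": key[0], "kind": key[1],
                "occupancy_a": rec_a.occupancy if rec_a else float("nan"),
                "occupancy_b": rec_b.occupancy if rec_b else float("nan"),
                "delta_mean_distance":
                    (rec_b.mean_distance_all - rec_a.mean_distance_all)
                    if rec_a and rec_b else float("nan"),
                "sustained_only_in":
                    a if (rec_a and rec_a.sustained
                          and not (rec_b and rec_b.sustained)) else
                    b if (rec_b and rec_b.sustained
                          and not (rec_a and rec_a.sustained)) else "",
            })
        entry["contacts"] = rows
        ga = ra.get("geometry", {})
        gb = rb.get("geometry", {})
        if "volume_mean" in ga and "volume_mean" in gb:
            entry["volume_delta"] = gb["volume_mean"] - ga["volume_mean"]
        if "rmsf" in ga and "rmsf" in gb:
            entry["bfactor_delta"] = {
                int(i): rmsf_to_bfactor(gb["rmsf"][i])
                - rmsf_to_bfactor(ga["rmsf"][i])
                for i in sorted(set(ga["rmsf"]) & set(gb["rmsf"]))}
        report["pairs"].append(entry)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        serializable = json.loads(json.dumps(report, default=str))
        with open(out / "comparison.json", "w") as fh:
            json.dump(serializable, fh, indent=1, sort_keys=True)
    return report
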