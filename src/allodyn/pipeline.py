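"""End-to-end orchestration: one configuration drives every analysis stage.

Stages (in order): superpose -> rmsd/rmsf -> cluster/representatives ->
distances/H-bonds -> CVs/FEL -> DCCM -> energetics -> network/communities/
paths.  All results go to TSV/JSON/PDB files under the output directory and
are registered in a provenance manifest; re-running with the same
configuration and seed reproduces the TSV outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import clustering, correlation, energetics, geometry, network, synthetic
from .errors import AnalysisError, ConfigError, SelectionError, StructureError
from .geometry import AtomRef, TriangleCV
from .trajectory import (
    Ensemble,
    MotifMapping,
    read_ensemble,
    read_structure,
    resolve_selection,
    rmsd_series,
    rmsf_profile,
    superpose,
    write_structure,
)

__all__ = ["default_config", "load_config", "validate_config", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("superpose", "rmsd", "cluster", "distances", "fel", "dccm", "energy", "network")

_FLOAT_FMT = "%.6f"


def default_config() -> dict:
    """Full default configuration, targeting the shipped synthetic toy study.

    Methods-level constants (4.5 A / 75% contact gate, -ln|C| weights, 3.5 A
    hydrogen-bond cutoff, gamma = 0.00542, b = 0.92, 300 K) are pre-filled
    and overridable.
    """
    return {
        # n_receptor_residues defaults to each study preset's own size
        "synthetic": {"kind": "path", "n_receptor_residues": None, "n_frames": 600, "seed": 7},
        "selections": {
            "fit": "chain A and name CA",
            "calpha": "chain A and name CA",
            "nodes": "chain A",
            "receptor": "chain A",
            "partner": "chain P",
        },
        "motif": {"chain": "P", "anchor": 1},
        "distances": [{"name": "D590_R+2", "a": "A:590:OD1", "b": "R+2:NE"}],
        "hbond_cutoff": 3.5,
        "cvs": [
            {"name": "pocket_cofactor", "atoms": ["A:590:CA", "A:579:CA", "A:602:CA"]},
            {"name": "pocket_ligand", "atoms": ["A:585:CA", "A:595:CA", "A:605:CA"]},
        ],
        "fel": {"bins": 40, "temperature": 300.0},
        "clustering": {"k": 3, "seed": 0},
        "dccm": {"replica_mode": "average"},
        "energetics": {
            "stride": 25,
            "eps_interior": 1.0,
            "eps_solvent": 80.0,
            "gamma": 0.00542,
            "b": 0.92,
            "probe": 1.4,
            "n_sphere_points": 240,
        },
        "network": {
            "cutoff": 4.5,
            "min_occupancy": 0.75,
            "neighbor_exclusion": 1,
            "contact_mode": "heavy",
            "log_base": "e",
            "delta": 0.20,
            "source": 602,
            "target": 590,
        },
        "stages": list(ALL_STAGES),
    }


def load_config(path: str | Path) -> dict:
    base = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}

    def merge(dst: dict, src: dict) -> dict:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v
        return dst

    return merge(base, user)


def _load_inputs(config: dict, seed: int | None):
    """Materialise (ensemble, params table, truth-or-None) from the config."""
    if "input" in config and config["input"]:
        inp = config["input"]
        ensemble = read_ensemble(inp["ensemble"])
        params = pd.read_csv(inp["params"], sep="\t") if inp.get("params") else None
        reference = read_structure(inp["reference"]) if inp.get("reference") else None
        return ensemble, params, None, reference
    syn = config.get("synthetic", {})
    kind = syn.get("kind", "path")
    used_seed = seed if seed is not None else syn.get("seed", 0)
    maker = {"path": synthetic.path_study_spec, "communities": synthetic.community_study_spec}
    if kind not in maker:
        raise ConfigError([f"unknown synthetic kind {kind!r}"])
    kwargs = {k: syn[k] for k in ("n_receptor_residues", "n_frames") if syn.get(k) is not None}
    spec, truth, params = maker[kind](seed=used_seed, **kwargs)
    ensemble, truth = synthetic.sample_ensemble(spec, truth)
    return ensemble, params, truth, spec.reference


def validate_config(config: dict, seed: int | None = None) -> list[str]:
    """Fail-fast validation: every referenced residue/atom resolvable, every
    numeric range sane.  Returns the aggregated problem list (empty = valid)."""
    problems: list[str] = []
    net = config.get("network", {})
    if not (0.0 < net.get("min_occupancy", 0.75) <= 1.0):
        problems.append(f"network.min_occupancy {net.get('min_occupancy')} outside (0, 1]")
    if net.get("cutoff", 4.5) <= 0:
        problems.append("network.cutoff must be positive")
    if config.get("hbond_cutoff", 3.5) <= 0:
        problems.append("hbond_cutoff must be positive")
    if config.get("fel", {}).get("temperature", 300.0) <= 0:
        problems.append("fel.temperature must be positive")
    if config.get("clustering", {}).get("k", 3) < 1:
        problems.append("clustering.k must be >= 1")

    try:
        ensemble, params, _, reference = _load_inputs(config, seed)
    except (OSError, KeyError, StructureError, ConfigError, AnalysisError) as exc:
        problems.append(f"inputs: {exc}")
        return problems

    stages = set(config.get("stages", ALL_STAGES))
    motif = None
    mc = config.get("motif")
    if mc and (stages & {"distances", "fel"}):
        try:
            motif = MotifMapping.from_anchor(ensemble.topology, mc["chain"], int(mc["anchor"]))
        except (SelectionError, KeyError) as exc:
            problems.append(f"motif: {exc}")
    needed = {"fit", "calpha"}
    if "network" in stages:
        needed.add("nodes")
    if "energy" in stages:
        needed |= {"receptor", "partner"}
    for key, expr in config.get("selections", {}).items():
        if key not in needed:
            continue
        try:
            resolve_selection(ensemble, expr)
        except SelectionError as exc:
            problems.append(f"selections.{key}: {exc}")
    if "distances" in stages:
        for d in config.get("distances", []):
            for side in ("a", "b"):
                try:
                    AtomRef.parse(d[side]).resolve(ensemble, motif)
                except (SelectionError, KeyError) as exc:
                    problems.append(f"distance {d.get('name', '?')}: {exc}")
    if "fel" in stages:
        for cv in config.get("cvs", []):
            try:
                refs = [AtomRef.parse(a) for a in cv["atoms"]]
                if len(refs) != 3:
                    raise SelectionError("triangle CV needs exactly 3 atoms")
                for ref in refs:
                    ref.resolve(ensemble, motif)
            except (SelectionError, KeyError) as exc:
                problems.append(f"cv {cv.get('name', '?')}: {exc}")
    if "network" in stages:
        for endpoint in ("source", "target"):
            rid = net.get(endpoint)
            if rid is not None:
                hits = {a.residue_id for a in ensemble.topology.atoms if a.residue_id == rid}
                if not hits:
                    problems.append(f"network.{endpoint}: residue {rid} not in topology")
    if "energy" in stages and params is None:
        problems.append("energetics stage enabled but no parameter table available")
    return problems


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=True)


def _node_name(node) -> str:
    return f"{node[0]}:{node[1]}"


def run_pipeline(
    config: dict, out_dir: str | Path, seed: int | None = None, force: bool = False
) -> dict:
    """Run all enabled stages; returns (and writes) the provenance manifest.

    Finished stages recorded in an existing manifest are skipped unless
    ``force`` (or the configuration hash changed).
    """
    problems = validate_config(config, seed)
    if problems:
        raise ConfigError(problems)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode() + str(seed).encode()
    ).hexdigest()[:16]

    manifest_path = out / "manifest.json"
    registry: dict[str, list[str]] = {}
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == cfg_hash:
            registry = {
                stage: files
                for stage, files in old.get("stages", {}).items()
                if all((out / f).exists() for f in files)
            }

    ensemble, params, truth, reference = _load_inputs(config, seed)
    if reference is None:
        reference = ensemble.frame_structure(0, title="reference (frame 0)")
    sel = config["selections"]
    stages = [s for s in config.get("stages", ALL_STAGES) if s in ALL_STAGES]
    motif = None
    if config.get("motif") and set(stages) & {"distances", "fel"}:
        motif = MotifMapping.from_anchor(
            ensemble.topology, config["motif"]["chain"], int(config["motif"]["anchor"])
        )
    t0 = time.time()
    timings: dict[str, float] = {}

    fitted = superpose(ensemble, reference, sel["fit"])

    def done(stage: str) -> bool:
        return stage in registry and not force

    def register(stage: str, files: list[Path]) -> None:
        registry[stage] = [str(f.relative_to(out)) for f in files]
        timings[stage] = round(time.time() - t0, 3)

    if "superpose" in stages and not done("superpose"):
        ref_out = out / "reference.pdb"
        write_structure(reference, ref_out)
        register("superpose", [ref_out])

    if "rmsd" in stages and not done("rmsd"):
        rmsd = rmsd_series(fitted, reference, sel["calpha"])
        rmsf = rmsf_profile(fitted, sel["calpha"])
        idx = resolve_selection(fitted, sel["calpha"])
        labels = [_node_name((fitted.topology.atoms[i].chain_id, fitted.topology.atoms[i].residue_id)) for i in idx]
        f1, f2 = out / "rmsd.tsv", out / "rmsf.tsv"
        _write_tsv(pd.DataFrame({"rmsd_A": rmsd}, index=pd.Index(range(len(rmsd)), name="frame")), f1)
        _write_tsv(pd.DataFrame({"rmsf_A": rmsf}, index=pd.Index(labels, name="residue")), f2)
        register("rmsd", [f1, f2])

    if "cluster" in stages and not done("cluster"):
        cc = config["clustering"]
        result = clustering.kmeans_frames(fitted, sel["calpha"], k=cc.get("k", 3), seed=cc.get("seed", 0))
        f1 = out / "cluster_assignments.tsv"
        _write_tsv(
            pd.DataFrame({"cluster": result.assignments}, index=pd.Index(range(fitted.n_frames), name="frame")),
            f1,
        )
        files = [f1]
        for c in range(result.k):
            rep = clustering.representative_structure(result, fitted, c)
            fp = out / f"representative_cluster{c}.pdb"
            write_structure(rep, fp)
            files.append(fp)
        elbow = clustering.elbow_report(fitted, sel["calpha"], ks=range(1, min(9, fitted.n_frames + 1)), seed=cc.get("seed", 0))
        fe = out / "cluster_elbow.tsv"
        _write_tsv(pd.DataFrame({"inertia": list(elbow.values())}, index=pd.Index(list(elbow.keys()), name="k")), fe)
        files.append(fe)
        register("cluster", files)

    if "distances" in stages and not done("distances"):
        files = []
        occ_rows = []
        for d in config.get("distances", []):
            series = geometry.distance_series(fitted, d["a"], d["b"], motif)
            fp = out / f"distance_{d['name']}.tsv"
            _write_tsv(pd.DataFrame({"distance_A": series}, index=pd.Index(range(len(series)), name="frame")), fp)
            files.append(fp)
            grid, dens = geometry.distance_density(series)
            fd = out / f"density_{d['name']}.tsv"
            _write_tsv(pd.DataFrame({"density": dens}, index=pd.Index(grid, name="distance_A")), fd)
            files.append(fd)
            occ_rows.append(
                {"pair": d["name"], "occupancy": geometry.hbond_occupancy(series, config.get("hbond_cutoff", 3.5))}
            )
        if occ_rows:
            fo = out / "hbond_occupancy.tsv"
            _write_tsv(pd.DataFrame(occ_rows).set_index("pair"), fo)
            files.append(fo)
        register("distances", files)

    cv_series: dict[str, np.ndarray] = {}
    if "fel" in stages and not done("fel"):
        files = []
        for cv in config.get("cvs", []):
            refs = [AtomRef.parse(a) for a in cv["atoms"]]
            tri = TriangleCV(*refs, name=cv["name"])
            cv_series[cv["name"]] = geometry.triangle_area_series(fitted, tri, motif)
            fp = out / f"cv_{cv['name']}.tsv"
            _write_tsv(
                pd.DataFrame({"area_A2": cv_series[cv["name"]]}, index=pd.Index(range(fitted.n_frames), name="frame")),
                fp,
            )
            files.append(fp)
        if len(cv_series) >= 2:
            names = list(cv_series)[:2]
            grid = geometry.fel_2d(
                cv_series[names[0]], cv_series[names[1]],
                bins=config["fel"].get("bins", 40), temperature=config["fel"].get("temperature", 300.0),
            )
            ff = out / "fel_free_energy.tsv"
            fe_mat = grid.free_energy.filled(np.nan)
            _write_tsv(pd.DataFrame(fe_mat), ff)
            fm = out / "fel_meta.json"
            fm.write_text(json.dumps({
                "cv1": names[0], "cv2": names[1],
                "cv1_edges": np.round(grid.cv1_edges, 6).tolist(),
                "cv2_edges": np.round(grid.cv2_edges, 6).tolist(),
                "temperature_K": grid.temperature,
                "n_samples": int(grid.counts.sum()),
            }, indent=1))
            files += [ff, fm]
        register("fel", files)

    corr = None
    if "dccm" in stages and not done("dccm") or "network" in stages and not done("network"):
        corr = correlation.dccm(fitted, sel["calpha"])
    if "dccm" in stages and not done("dccm"):
        labels = [_node_name(n) for n in corr.residue_ids]
        fp = out / "dccm.tsv"
        _write_tsv(pd.DataFrame(corr.matrix, index=labels, columns=labels), fp)
        register("dccm", [fp])

    if "energy" in stages and not done("energy"):
        ec = config["energetics"]
        ff_params = energetics.ForceFieldParameters.from_table(
            params, ensemble.topology,
            eps_interior=ec.get("eps_interior", 1.0), eps_solvent=ec.get("eps_solvent", 80.0),
            gamma=ec.get("gamma", 0.00542), b_offset=ec.get("b", 0.92),
            probe_radius=ec.get("probe", 1.4),
        )
        decomp = energetics.binding_decomposition(
            fitted, sel["receptor"], sel["partner"], ff_params,
            stride=ec.get("stride", 25), n_sphere_points=ec.get("n_sphere_points", 240),
        )
        f1, f2, f3 = out / "energy_totals.tsv", out / "energy_frames.tsv", out / "energy_per_residue.tsv"
        _write_tsv(decomp.summary_table(), f1)
        _write_tsv(decomp.frames, f2)
        _write_tsv(decomp.per_residue, f3)
        register("energy", [f1, f2, f3])

    if "network" in stages and not done("network"):
        nc = config["network"]
        contacts = network.contact_occupancy(
            fitted, sel["nodes"], cutoff=nc.get("cutoff", 4.5),
            min_occupancy=nc.get("min_occupancy", 0.75),
            contact_mode=nc.get("contact_mode", "heavy"),
            neighbor_exclusion=nc.get("neighbor_exclusion", 1),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = network.weight_edges(contacts, corr, log_base=nc.get("log_base", "e"))
        edges = pd.DataFrame(
            [
                {
                    "node_a": _node_name(u), "node_b": _node_name(v),
                    "occupancy": d["occupancy"], "absC": d["absC"], "weight": d["weight"],
                }
                for u, v, d in sorted(g.edges(data=True))
            ]
        )
        f1 = out / "network_edges.tsv"
        _write_tsv(edges.set_index(["node_a", "node_b"]) if len(edges) else edges, f1)
        fg = out / "network.graphml"
        nx.write_graphml(nx.relabel_nodes(g, _node_name), fg)
        files = [f1, fg]
        part = network.detect_communities(g)
        part.connectivity = network.intercommunity_connectivity(g, part)
        f2 = out / "communities.tsv"
        _write_tsv(
            pd.DataFrame(
                {"community": [part.labels[n] for n in sorted(part.labels)]},
                index=pd.Index([_node_name(n) for n in sorted(part.labels)], name="residue"),
            ),
            f2,
        )
        f3 = out / "intercommunity.tsv"
        _write_tsv(
            pd.DataFrame(
                [{"community_a": a, "community_b": b, "n_shortest_paths": c} for (a, b), c in sorted(part.connectivity.items())]
            ).set_index(["community_a", "community_b"])
            if part.connectivity
            else pd.DataFrame(columns=["community_a", "community_b", "n_shortest_paths"]).set_index(["community_a", "community_b"]),
            f3,
        )
        files += [f2, f3]
        if nc.get("source") is not None and nc.get("target") is not None:
            paths = network.suboptimal_paths(g, nc["source"], nc["target"], delta=nc.get("delta", 0.20))
            rows = [
                {
                    "rank": k,
                    "length_raw": p.length,
                    "length_x100": p.length_x100,
                    "n_residues": p.n_residues,
                    "pathway": ",".join(str(n[1]) for n in p.nodes),
                }
                for k, p in enumerate(paths)
            ]
            f4 = out / "paths.tsv"
            _write_tsv(pd.DataFrame(rows).set_index("rank") if rows else pd.DataFrame(columns=["rank"]).set_index("rank"), f4)
            files.append(f4)
        register("network", files)

    manifest = {
        "config_hash": cfg_hash,
        "seed": seed,
        "replica_mode": config.get("dccm", {}).get("replica_mode", "average"),
        "synthetic_truth": {
            "chain_residues": truth.chain_residues,
            "source": truth.source,
            "target": truth.target,
            "community_labels": {str(k): v for k, v in truth.community_labels.items()},
        }
        if truth is not None
        else None,
        "stages": registry,
        "timings_s": timings,
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
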