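"""End-to-end orchestration: simulate -> connectome -> networks -> dynamics
-> associate -> omics -> integrate -> report.

Configuration is a strict YAML/dict tree: unknown keys are errors, so
typos in threshold names fail loudly.  All analysis defaults follow the
study's printed conventions (1-6% module densities, 7.5% partial-network
density, 30 mm centroid exclusion, FDR q = 0.1 for scans and 0.05 for the
phenome network, |r| > 0.2 gate, expression filter bounds 4 / 10000,
soft-threshold power 8).  Every output file is declared in a JSON
manifest; a rerun with the same config and seed is bit-identical apart
from the manifest timestamp.
"""

from __future__ import annotations

import copy
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import connectome as conn_mod
from . import dynamics as dyn_mod
from . import graphs as graph_mod
from . import integration as integ_mod
from . import omics as omics_mod
from . import synth as synth_mod

__all__ = ["DEFAULT_CONFIG", "PipelineConfig", "run_pipeline"]

log = logging.getLogger("phenodyn")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "phenodyn_out",
    "stages": {
        "simulate": True,
        "connectome": True,
        "networks": True,
        "dynamics": True,
        "associate": True,
        "omics": True,
        "integrate": True,
    },
    "sim": {  # desk-scale defaults; see SimConfig for field meanings
        "n_parcels": 120,
        "n_networks": 6,
        "n_sessions": 30,
        "timepoints_per_session": 200,
        "n_genes": 400,
        "n_gene_modules": 5,
        "n_metabolites": 60,
        "n_metab_clusters": 6,
        "n_omics_sessions": 24,
    },
    "connectome": {
        "partial_density": 0.075,
        "partial_tol": 0.001,
        "l2_lambda": 1.0e-4,
    },
    "networks": {
        "densities": [0.01, 0.02, 0.03, 0.04, 0.05, 0.06],
        "exclusion_mm": 30.0,
        "min_module_size": 9,
        "state_density": 0.01,
    },
    "dynamics": {
        "trends": ["linear", "polynomial"],
    },
    "associate": {
        "q": 0.1,
        "min_abs_r": 0.2,
        "min_n": 10,
    },
    "omics": {
        "min_mean": 4.0,
        "max_mean": 10000.0,
        "soft_power": 8,
        "min_module": 30,
        "ap_damping": 0.9,
    },
    "integrate": {
        "s_density": 0.10,
        "n_perm": 200,
        "struct_agreement": 0.7,
        "inter_hemi_weight": 0.15,
        "phenome_q": 0.05,
    },
}


def _sim_field_names() -> set:
    import dataclasses
    return {f.name for f in dataclasses.fields(synth_mod.SimConfig)} - {"seed"}


def _merge_strict(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in (user or {}).items():
        where = f"{path}.{key}" if path else key
        if path == "sim":
            if key not in _sim_field_names():
                raise KeyError(f"unknown configuration key: {where}")
            out[key] = value
            continue
        if key not in defaults:
            raise KeyError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict) and not isinstance(value, dict):
            raise TypeError(f"configuration key {where} must be a mapping")
        if isinstance(defaults[key], dict):
            out[key] = _merge_strict(defaults[key], value, where)
        else:
            out[key] = value
    return out


class PipelineConfig(dict):
    """Validated pipeline configuration (strict keys over DEFAULT_CONFIG)."""

    @classmethod
    def from_dict(cls, user: dict | None) -> "PipelineConfig":
        return cls(_merge_strict(DEFAULT_CONFIG, user or {}))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls.from_dict(user)


def _setup_logging(out: Path, verbose: bool = False) -> None:
    log.setLevel(logging.DEBUG)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setLevel(logging.DEBUG if verbose else logging.INFO)
    sh.setFormatter(fmt)
    log.addHandler(sh)
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(fmt)
    log.addHandler(fh)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


import contextlib


@contextlib.contextmanager
def _stage_guard(name: str):
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: PipelineConfig | dict, verbose: bool = False) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    cfg = PipelineConfig.from_dict(dict(cfg))
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, verbose)
    seed = int(cfg["seed"])
    outputs: list[str] = []
    stages_run: list[str] = []
    timers: dict = {}

    def stage(name):
        return cfg["stages"].get(name, False)

    def emit(name: str):
        outputs.append(name)

    t0 = time.time()
    sim_cfg = synth_mod.SimConfig(**cfg["sim"], seed=seed)
    sessions = truth = genes = metab = behavior = None
    if stage("simulate"):
        log.info("stage simulate")
        t = time.time()
        sessions, truth = synth_mod.gen_parcel_sessions(sim_cfg)
        genes, metab, behavior = synth_mod.gen_omics_and_behavior(sim_cfg, truth)
        simdir = out / "sim"
        for fn in synth_mod.write_dataset(simdir, sessions, truth, genes,
                                          metab, behavior):
            emit(f"sim/{fn}")
        timers["simulate"] = time.time() - t
        stages_run.append("simulate")
    else:
        raise RuntimeError("stage simulate is required as the data source "
                           "for the remaining stages in this run mode")

    mean_full = None
    if stage("connectome"):
        log.info("stage connectome")
        t = time.time()
        fulls = [conn_mod.full_correlation(s) for s in sessions]
        mean_full = conn_mod.mean_connectome(fulls)
        conn_mod.write_connectome_tsv(mean_full, out / "mean_full.tsv")
        emit("mean_full.tsv")
        l2 = conn_mod.partial_l2(sessions[0], lam=cfg["connectome"]["l2_lambda"])
        conn_mod.write_connectome_tsv(l2, out / "session0_partial_l2.tsv")
        emit("session0_partial_l2.tsv")
        try:
            l1 = conn_mod.partial_l1_density(
                sessions[0], target_density=cfg["connectome"]["partial_density"],
                tol=cfg["connectome"]["partial_tol"])
            conn_mod.write_connectome_tsv(l1, out / "session0_partial_l1.tsv")
            emit("session0_partial_l1.tsv")
        except RuntimeError as exc:
            raise RuntimeError(f"stage connectome failed: {exc}") from exc
        timers["connectome"] = time.time() - t
        stages_run.append("connectome")

    partition = None
    if stage("networks"):
        log.info("stage networks")
        t = time.time()
        assignments = {}
        for i, d in enumerate(cfg["networks"]["densities"]):
            g = conn_mod.binarize_at_density(
                mean_full, d, exclusion_mm=cfg["networks"]["exclusion_mm"],
                centroids=truth.centroids)
            assignments[d] = graph_mod.detect_communities(g, seed=seed + i)
        partition = graph_mod.consensus_partition(
            assignments, min_module_size=cfg["networks"]["min_module_size"])
        pd.DataFrame({"parcel_id": np.arange(partition.assignment.size),
                      "module_id": partition.assignment}).to_csv(
            out / "consensus_partition.tsv", sep="\t", index=False)
        emit("consensus_partition.tsv")
        d0 = cfg["networks"]["densities"][1 if len(cfg["networks"]["densities"]) > 1 else 0]
        g0 = conn_mod.binarize_at_density(mean_full, d0)
        hubs = graph_mod.participation_and_hubs(g0, partition)
        hubs.to_csv(out / "hubs.tsv", sep="\t")
        emit("hubs.tsv")
        metrics = {
            "signed_modularity": graph_mod.signed_modularity(mean_full, partition),
            "global_efficiency": graph_mod.global_efficiency(g0),
            "n_modules": partition.n_modules,
        }
        with open(out / "graph_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1)
        emit("graph_metrics.json")
        timers["networks"] = time.time() - t
        stages_run.append("networks")

    summaries = None
    if stage("dynamics"):
        log.info("stage dynamics")
        t = time.time()
        part_for_sum = partition if partition is not None else truth.parcel_partition
        with _stage_guard("dynamics"):
            summaries = dyn_mod.network_summaries(sessions, part_for_sum)
        summaries.to_csv(out / "network_summaries.tsv", sep="\t")
        emit("network_summaries.tsv")
        sim_mat, to_mean = dyn_mod.session_similarity(sessions)
        sim_mat.to_csv(out / "session_similarity.tsv", sep="\t")
        emit("session_similarity.tsv")
        rows = []
        state = truth.state_vector
        for col in summaries.columns:
            if col == "state":
                continue
            y = summaries[col].values
            for kind in cfg["dynamics"]["trends"]:
                res = dyn_mod.trend_test(y, kind=kind)
                rows.append((col, kind, res["coef"], res["t"], res["p"],
                             str(res["order"])))
            st = dyn_mod.state_effect_test(y, state, var=col)
            rows.append((col, "state", st.coef, st.t, st.p, str(st.order)))
        pd.DataFrame(rows, columns=["variable", "test", "coef", "t", "p",
                                    "order"]).to_csv(
            out / "dynamics_tests.tsv", sep="\t", index=False)
        emit("dynamics_tests.tsv")
        timers["dynamics"] = time.time() - t
        stages_run.append("dynamics")

    eigengenes = metab_eig = None
    if stage("omics"):
        log.info("stage omics")
        t = time.time()
        factors = omics_mod.size_factors(genes)
        filtered = omics_mod.filter_genes(
            genes, min_mean=cfg["omics"]["min_mean"],
            max_mean=cfg["omics"]["max_mean"], factors=factors)
        stab = omics_mod.vst(filtered, factors)
        resid = omics_mod.nuisance_regress(
            stab, genes.attrs["rin"].values, n_pcs=3)
        power = cfg["omics"]["soft_power"]
        if not power:
            power, _ = omics_mod.pick_soft_power(
                omics_mod.bicor_matrix(resid.values))
        modules = omics_mod.coexpression_modules(
            resid, power=power, min_module=cfg["omics"]["min_module"])
        modules.membership.to_frame().to_csv(out / "gene_modules.tsv", sep="\t")
        emit("gene_modules.tsv")
        eigengenes = modules.eigengenes
        eigengenes.to_csv(out / "gene_eigengenes.tsv", sep="\t")
        emit("gene_eigengenes.tsv")

        normed = omics_mod.metab_normalize(metab)
        prof = (normed.values - normed.values.mean(axis=1, keepdims=True))
        sd = prof.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        prof = prof / sd
        sim = -np.square(prof[:, None, :] - prof[None, :, :]).sum(axis=2)
        exemplars, labels = omics_mod.affinity_propagation(
            sim, damping=cfg["omics"]["ap_damping"], seed=seed)
        pd.DataFrame({"metabolite": normed.index, "cluster": labels}).to_csv(
            out / "metab_clusters.tsv", sep="\t", index=False)
        emit("metab_clusters.tsv")
        m_eig = {}
        for lab in np.unique(labels):
            block = normed.values[labels == lab]
            scores, _, _ = omics_mod._eigengene(block)
            m_eig[int(lab)] = scores
        metab_eig = pd.DataFrame(m_eig, index=normed.columns).T
        metab_eig.to_csv(out / "metab_eigengenes.tsv", sep="\t")
        emit("metab_eigengenes.tsv")
        timers["omics"] = time.time() - t
        stages_run.append("omics")

    assoc_table = None
    if stage("associate"):
        log.info("stage associate")
        t = time.time()
        if summaries is None:
            raise RuntimeError("stage associate requires stage dynamics")
        win_cols = [c for c in summaries.columns if c.startswith("win:")]
        beh = behavior.drop(columns=["TuesThurs"])
        table_a = beh
        table_b = summaries[win_cols]
        assoc_table = assoc_mod.scan_pairs(
            table_a, table_b, min_abs_r=cfg["associate"]["min_abs_r"],
            q=cfg["associate"]["q"], min_n=cfg["associate"]["min_n"],
            classes_a={c: "behav" for c in table_a.columns},
            classes_b={c: "wincorr" for c in table_b.columns})
        assoc_table.to_csv(out / "associations.tsv", sep="\t", index=False)
        emit("associations.tsv")
        timers["associate"] = time.time() - t
        stages_run.append("associate")

    if stage("integrate"):
        log.info("stage integrate")
        t = time.time()
        struct = synth_mod.gen_structural(
            truth, agreement=cfg["integrate"]["struct_agreement"],
            density=cfg["integrate"]["s_density"], seed=seed + 77,
            inter_hemi_weight=cfg["integrate"]["inter_hemi_weight"],
            within=sim_cfg.within_network_corr,
            between=sim_cfg.between_network_corr)
        overlap = integ_mod.struct_func_overlap(
            mean_full, struct, cfg["networks"]["densities"],
            s_density=cfg["integrate"]["s_density"],
            n_perm=cfg["integrate"]["n_perm"], seed=seed + 78)
        overlap.to_csv(out / "struct_func_overlap.tsv", sep="\t", index=False)
        emit("struct_func_overlap.tsv")
        inter_f = integ_mod.interhemispheric_proportion(
            mean_full, truth.hemisphere_labels, cfg["networks"]["densities"])
        inter_s = integ_mod.interhemispheric_proportion(
            struct, truth.hemisphere_labels, cfg["networks"]["densities"])
        inter = inter_f.merge(inter_s, on="density", how="outer",
                              suffixes=("_functional", "_structural"))
        inter.to_csv(out / "interhemispheric.tsv", sep="\t", index=False)
        emit("interhemispheric.tsv")

        # phenome network across all session-level variable tables
        tables = []
        if summaries is not None:
            win = summaries[[c for c in summaries.columns if c.startswith("win:")]]
            bw = summaries[[c for c in summaries.columns if c.startswith("bw:")]]
            tables.append((win, "wincorr"))
            tables.append((bw, "bwcorr"))
        tables.append((behavior.drop(columns=["TuesThurs"]), "behav"))
        if eigengenes is not None:
            ge = eigengenes.T
            ge.columns = [f"ME{m}" for m in ge.columns]
            tables.append((ge, "wgcna"))
        if metab_eig is not None:
            me = metab_eig.T
            me.columns = [f"MC{m}" for m in me.columns]
            tables.append((me, "metab"))
        frames = []
        for i in range(len(tables)):
            for j in range(i + 1, len(tables)):
                ta, ca = tables[i]
                tb, cb = tables[j]
                res = assoc_mod.scan_pairs(
                    ta, tb, min_abs_r=cfg["associate"]["min_abs_r"],
                    q=cfg["integrate"]["phenome_q"],
                    min_n=cfg["associate"]["min_n"],
                    classes_a={c: ca for c in ta.columns},
                    classes_b={c: cb for c in tb.columns})
                frames.append(res)
        allres = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        if len(allres):
            graph = integ_mod.build_phenome_network(
                allres, q=cfg["integrate"]["phenome_q"], seed=seed + 79)
            graph.nodes.to_csv(out / "phenome_nodes.tsv", sep="\t", index=False)
            graph.edges.to_csv(out / "phenome_edges.tsv", sep="\t", index=False)
            emit("phenome_nodes.tsv")
            emit("phenome_edges.tsv")
            if not graph.is_empty:
                graph.write_graphml(out / "phenome.graphml")
                emit("phenome.graphml")
            with open(out / "phenome_summary.json", "w") as fh:
                json.dump({"n_nodes": len(graph.nodes),
                           "n_edges": len(graph.edges),
                           "modularity": graph.modularity}, fh, indent=1)
            emit("phenome_summary.json")
        timers["integrate"] = time.time() - t
        stages_run.append("integrate")

    manifest = {
        "config": dict(cfg),
        "seed": seed,
        "stages_run": stages_run,
        "outputs": sorted(outputs),
        "timers_s": {k: round(v, 3) for k, v in timers.items()},
        "total_s": round(time.time() - t0, 3),
        "versions": _versions(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    summary = [f"phenodyn pipeline run (seed {seed})",
               f"stages: {', '.join(stages_run)}",
               f"outputs: {len(outputs)} files in {out}"]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    log.info("done in %.1fs", time.time() - t0)
    return manifest


def _versions() -> dict:
    import igraph
    import scipy
    import sklearn
    import statsmodels
    from . import __version__
    return {
        "phenodyn": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
        "igraph": igraph.__version__,
    }
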