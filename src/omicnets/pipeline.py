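"""Desk-scale orchestration: config expansion, staged execution, metadata.

A run config is a YAML mapping with a global ``seed``/``outdir`` and one
block per stage (``synth``, ``prep_expr``, ``prep_meth``, ``ggm``,
``netcompare``, ``enrich``). Any stage parameter may be a list of values, in
which case the config expands to the Cartesian product of concrete runs,
each with a deterministically derived sub-seed. Unknown keys are rejected.

Stages execute serially in dependency order (synth -> prep -> ggm ->
netcompare -> enrich) and write CSV/HDF5 artifacts plus one metadata row per
artifact. Numeric outputs are bit-reproducible under a fixed config and
seed; metadata rows carry wall-clock timestamps (provenance, not results).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import enrich as enrich_mod
from . import ggm as ggm_mod
from . import netcompare as nc
from . import prep_expr as pe
from . import prep_meth as pm
from . import synth as synth_mod
from ._util import derive_seed, subject_of

__all__ = ["RunConfig", "expand_config", "run_pipeline", "load_config", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("synth", "prep_expr", "prep_meth", "ggm", "netcompare", "enrich")

_UPSTREAM = {
    "synth": (),
    "prep_expr": ("synth",),
    "prep_meth": ("synth",),
    "ggm": ("prep_expr", "prep_meth"),
    "netcompare": ("ggm", "synth"),
    "enrich": ("netcompare", "synth"),
}

_SCHEMA: dict[str, dict[str, object]] = {
    "synth": {
        "n_genes": 40,
        "n_tf": 25,
        "probes_per_gene": 3,
        "n_subtypes": 2,
        "n_samples_per_subtype": 120,
        "n_silenced": 4,
        "n_flip_edges": 10,
        "flip_magnitude": 0.35,
        "silencing_magnitude": 0.4,
        "background_density": 0.02,
        "duplicate_fraction": 0.1,
        "missing_rate": 0.02,
        "include_cnv": False,
    },
    "prep_expr": {
        "method": "CPM_TMM",
        "n_min_counts": 5,
        "p_fraction": 0.9,
        "purity_min": 0.0,
        "pseudocount": 1.0,
    },
    "prep_meth": {
        "window_bp": 200,
        "duplicate_policy": "least_missing",
        "m_fraction": 0.2,
        "epsilon": 1e-6,
    },
    "ggm": {
        "lambda1": 0.1,
        "lambda2": 0.1,
        "cv_folds": 5,
    },
    "netcompare": {
        "decile": 0.1,
        "top_k": 40,
        "n_clusters": 2,
    },
    "enrich": {
        "n_sets": 15,
        "set_size": 8,
        "min_overlap": 2,
    },
}


@dataclass
class RunConfig:
    """A validated run configuration (possibly list-valued)."""

    seed: int
    outdir: str
    stages: dict[str, dict[str, object]]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        seed = int(raw.pop("seed", 0))
        outdir = str(raw.pop("outdir", "results"))
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        stages: dict[str, dict[str, object]] = {}
        for stage, defaults in _SCHEMA.items():
            block = dict(raw.get(stage) or {})
            bad = set(block) - set(defaults)
            if bad:
                raise ValueError(f"unknown key(s) in [{stage}]: {sorted(bad)}")
            merged = dict(defaults)
            merged.update(block)
            stages[stage] = merged
        return cls(seed=seed, outdir=outdir, stages=stages)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


@dataclass
class ConcreteRun:
    run_id: str
    seed: int
    outdir: Path
    params: dict[str, dict[str, object]]


def expand_config(config: RunConfig) -> list[ConcreteRun]:
    """Expand list-valued parameters into the Cartesian product of concrete
    runs, in deterministic (stage, key, value-order) order, each with a
    derived 31-bit sub-seed."""
    axes: list[tuple[str, str, list[object]]] = []
    for stage in STAGES:
        for key in sorted(config.stages[stage]):
            val = config.stages[stage][key]
            if isinstance(val, list):
                if not val:
                    raise ValueError(f"empty value list for {stage}.{key}")
                axes.append((stage, key, val))
    combos = list(itertools.product(*[vals for _, _, vals in axes])) or [()]
    runs: list[ConcreteRun] = []
    for i, combo in enumerate(combos):
        params = {stage: dict(block) for stage, block in config.stages.items()}
        for (stage, key, _), val in zip(axes, combo):
            params[stage][key] = val
        run_id = f"run{i:03d}"
        runs.append(
            ConcreteRun(
                run_id=run_id,
                seed=derive_seed(config.seed, i),
                outdir=Path(config.outdir) / run_id,
                params=params,
            )
        )
    return runs


# --------------------------------------------------------------------------
# stage implementations


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.10g")
    return path


class _Meta:
    def __init__(self, run: ConcreteRun):
        self.run = run
        self.rows: list[dict] = []

    def add(self, stage: str, path: Path, params: dict) -> None:
        if not Path(path).exists():
            raise FileNotFoundError(path)
        self.rows.append(
            {
                "run_id": self.run.run_id,
                "stage": stage,
                "params": json.dumps(params, sort_keys=True, default=str),
                "output": str(path),
                "timestamp": datetime.now(timezone.utc).isoformat(),
            }
        )

    def flush(self) -> Path:
        path = self.run.outdir / "metadata.csv"
        df = pd.DataFrame(self.rows)
        header = not path.exists()
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, mode="a", header=header, index=False)
        self.rows = []
        return path


def _subtypes(run: ConcreteRun) -> list[str]:
    n = int(run.params["synth"]["n_subtypes"])
    return [f"S{k + 1}" for k in range(n)]


def _require(run: ConcreteRun, stage: str, paths: list[Path]) -> None:
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(
                f"missing artifact {p}; run the '{stage}' stage first"
            )


def _stage_synth(run: ConcreteRun, meta: _Meta) -> None:
    p = run.params["synth"]
    out = run.outdir / "synth"
    out.mkdir(parents=True, exist_ok=True)
    genes, probes = synth_mod.generate_annotation(
        int(p["n_genes"]), int(p["n_tf"]), int(p["probes_per_gene"]), run.seed
    )
    tf_ids = list(genes.index[genes["is_tf"]])
    rng_idx = derive_seed(run.seed, 1)
    import numpy as np

    rng = np.random.default_rng(rng_idx)
    subtypes = _subtypes(run)
    n_sil = min(int(p["n_silenced"]), len(tf_ids))
    silencing = {
        subtypes[0]: {str(t) for t in rng.choice(tf_ids, size=n_sil, replace=False)}
    }
    flip = None
    if int(p["n_flip_edges"]) > 0 and len(subtypes) >= 2:
        pairs = [(a, b) for a in tf_ids for b in tf_ids if a != b]
        chosen = rng.choice(len(pairs), size=min(int(p["n_flip_edges"]), len(pairs)),
                            replace=False)
        flip = synth_mod.FlipSpec(
            edges=tuple(pairs[i] for i in sorted(chosen)),
            magnitude=float(p["flip_magnitude"]),
            positive_subtype=subtypes[0],
            negative_subtype=subtypes[1],
        )
    precisions, truth = synth_mod.build_subtype_precisions(
        genes,
        n_subtypes=len(subtypes),
        silencing_spec=silencing,
        flip_spec=flip,
        seed=derive_seed(run.seed, 2),
        silencing_magnitude=float(p["silencing_magnitude"]),
        background_density=float(p["background_density"]),
    )
    bundles = synth_mod.simulate_cohort(
        precisions,
        (genes, probes),
        n_samples_per_subtype=int(p["n_samples_per_subtype"]),
        duplicate_fraction=float(p["duplicate_fraction"]),
        missing_rate=float(p["missing_rate"]),
        seed=derive_seed(run.seed, 3),
        include_cnv=bool(p["include_cnv"]),
    )
    genes_path = out / "genes.tsv"
    genes.to_csv(genes_path, sep="\t")
    meta.add("synth", genes_path, p)
    probes_path = out / "probes.tsv"
    probes.to_csv(probes_path, sep="\t")
    meta.add("synth", probes_path, p)
    for s, bundle in bundles.items():
        meta.add("synth", _write_csv(bundle.expression_counts, out / f"{s}_expression_counts.csv"), p)
        meta.add("synth", _write_csv(bundle.methylation_beta, out / f"{s}_methylation_beta.csv"), p)
        meta.add("synth", _write_csv(bundle.purity.to_frame(), out / f"{s}_purity.csv"), p)
        if bundle.cnv is not None:
            meta.add("synth", _write_csv(bundle.cnv, out / f"{s}_cnv.csv"), p)

    net_a, net_b, partition, bip_truth = synth_mod.generate_bipartite_pair(
        n_tf=12, n_genes=40, n_modules=4, planted_module=0,
        delta=1.0, noise_sd=0.1, seed=derive_seed(run.seed, 4),
    )
    meta.add("synth", _write_csv(net_a.weights, out / "bipartite_A.csv"), p)
    meta.add("synth", _write_csv(net_b.weights, out / "bipartite_B.csv"), p)
    part_df = pd.DataFrame(
        sorted(partition.assignments.items()), columns=["node", "module"]
    ).set_index("node")
    meta.add("synth", _write_csv(part_df, out / "partition.csv"), p)

    ep = run.params["enrich"]
    collection, gs_truth = synth_mod.generate_gene_sets(
        universe=list(genes.index),
        query=sorted(silencing[subtypes[0]]) or tf_ids[:3],
        n_sets=int(ep["n_sets"]),
        set_size=int(ep["set_size"]),
        seed=derive_seed(run.seed, 5),
    )
    gmt_path = out / "gene_sets.gmt"
    enrich_mod.write_gmt(collection, gmt_path)
    meta.add("synth", gmt_path, p)

    truth_payload = {
        "silenced_tfs_by_subtype": {s: sorted(v) for s, v in truth.silenced_tfs_by_subtype.items()},
        "flip_cluster_edges": sorted(truth.flip_cluster_edges),
        "planted_module": list(bip_truth.planted_module or ()),
        "enriched_set": gs_truth.enriched_set,
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth_payload, indent=2, sort_keys=True))
    meta.add("synth", truth_path, p)


def _stage_prep_expr(run: ConcreteRun, meta: _Meta) -> None:
    p = run.params["prep_expr"]
    out = run.outdir / "prep_expr"
    synth_dir = run.outdir / "synth"
    genes_path = synth_dir / "genes.tsv"
    _require(run, "synth", [genes_path])
    genes = pd.read_csv(genes_path, sep="\t", index_col=0)
    for s in _subtypes(run):
        counts_path = synth_dir / f"{s}_expression_counts.csv"
        _require(run, "synth", [counts_path])
        counts = pd.read_csv(counts_path, index_col=0)
        purity = pd.read_csv(synth_dir / f"{s}_purity.csv", index_col=0)["purity"]
        mat = pe.ExpressionMatrix(
            values=counts, units="counts", gene_lengths=genes["length_bp"]
        )
        mat = pe.resolve_duplicates_expression(mat)
        mat = pe.filter_purity(mat, purity, float(p["purity_min"]))
        params = pe.ExprFilterParams(
            n_min_counts=int(p["n_min_counts"]),
            p_fraction=float(p["p_fraction"]),
            pseudocount=float(p["pseudocount"]),
        )
        mat, removed = pe.filter_low_expression(mat, params)
        mat = pe.normalize_expression(mat, method=str(p["method"]), params=params)
        mat = pe.log_transform(mat, float(p["pseudocount"]))
        # one vial per subject now: expose subject ids for cross-omic matching
        vals = mat.values.copy()
        vals.columns = [subject_of(c) for c in vals.columns]
        meta.add("prep_expr", _write_csv(vals, out / f"{s}_expression_log.csv"), p)
        removed_df = pd.DataFrame({"gene_id": removed}).set_index("gene_id")
        meta.add("prep_expr", _write_csv(removed_df, out / f"{s}_removed_genes.csv"), p)
    meta.flush()


def _stage_prep_meth(run: ConcreteRun, meta: _Meta) -> None:
    p = run.params["prep_meth"]
    out = run.outdir / "prep_meth"
    synth_dir = run.outdir / "synth"
    _require(run, "synth", [synth_dir / "genes.tsv", synth_dir / "probes.tsv"])
    genes = pd.read_csv(synth_dir / "genes.tsv", sep="\t", index_col=0)
    probes = pd.read_csv(synth_dir / "probes.tsv", sep="\t", index_col=0)
    tf_subset = set(genes.index[genes["is_tf"]])
    mapping = pm.map_probes_to_promoters(
        probes, genes, window_bp=int(p["window_bp"]), gene_subset=tf_subset
    )
    map_rows = [(g, pr) for g in sorted(mapping) for pr in sorted(mapping[g])]
    map_df = pd.DataFrame(map_rows, columns=["gene_id", "probe_id"]).set_index("gene_id")
    meta.add("prep_meth", _write_csv(map_df, out / "promoter_mapping.csv"), p)
    for s in _subtypes(run):
        beta_path = synth_dir / f"{s}_methylation_beta.csv"
        _require(run, "synth", [beta_path])
        beta = pd.read_csv(beta_path, index_col=0)
        mat = pm.MethylationMatrix(values=beta, kind="probe")
        agg, _ = pm.aggregate_promoter_beta(mat, mapping)
        agg = pm.resolve_duplicates_methylation(
            agg, policy=str(p["duplicate_policy"]), seed=run.seed
        )
        agg = pm.filter_and_impute_missing(agg, m_fraction=float(p["m_fraction"]))
        mvals = pm.convert_beta_m(agg, "beta_to_m", epsilon=float(p["epsilon"]))
        npn = pm.nonparanormal_transform(mvals)
        vals = npn.values.copy()
        vals.columns = [subject_of(c) for c in vals.columns]
        meta.add("prep_meth", _write_csv(vals, out / f"{s}_methylation_npn.csv"), p)
    meta.flush()


def _stage_ggm(run: ConcreteRun, meta: _Meta) -> None:
    p = run.params["ggm"]
    out = run.outdir / "ggm"
    out.mkdir(parents=True, exist_ok=True)
    genes = pd.read_csv(run.outdir / "synth" / "genes.tsv", sep="\t", index_col=0)
    tf_ids = set(genes.index[genes["is_tf"]])
    lam1, lam2 = p["lambda1"], p["lambda2"]
    lambdas: tuple[float, float] | str
    lambdas = "auto" if lam1 == "auto" or lam2 == "auto" else (float(lam1), float(lam2))
    for s in _subtypes(run):
        meth_path = run.outdir / "prep_meth" / f"{s}_methylation_npn.csv"
        expr_path = run.outdir / "prep_expr" / f"{s}_expression_log.csv"
        if not meth_path.exists():
            raise FileNotFoundError(
                f"missing artifact {meth_path}; run the 'prep_meth' stage first"
            )
        if not expr_path.exists():
            raise FileNotFoundError(
                f"missing artifact {expr_path}; run the 'prep_expr' stage first"
            )
        meth = pd.read_csv(meth_path, index_col=0)
        expr = pd.read_csv(expr_path, index_col=0)
        expr = expr.loc[[g for g in expr.index if g in tf_ids]]
        shared = [c for c in meth.columns if c in set(expr.columns)]
        net = ggm_mod.fit_partial_correlations(
            meth[shared],
            expr[shared],
            lambdas=lambdas,
            cv_folds=int(p["cv_folds"]),
            seed=run.seed,
        )
        h5_path = out / f"{s}_network.h5"
        ggm_mod.save_network(net, h5_path)
        meta.add("ggm", h5_path, p)
        meta.add("ggm", _write_csv(ggm_mod.self_pair_edges(net), out / f"{s}_self_pairs.csv"), p)
    meta.flush()


def _stage_netcompare(run: ConcreteRun, meta: _Meta) -> None:
    p = run.params["netcompare"]
    out = run.outdir / "netcompare"
    out.mkdir(parents=True, exist_ok=True)
    subtypes = _subtypes(run)
    nets, self_pairs = {}, {}
    for s in subtypes:
        h5_path = run.outdir / "ggm" / f"{s}_network.h5"
        _require(run, "ggm", [h5_path])
        nets[s] = ggm_mod.load_network(h5_path)
        self_pairs[s] = ggm_mod.self_pair_edges(nets[s])
    report = nc.detect_silencing(self_pairs, decile=float(p["decile"]))
    flags = report.flags.copy()
    flags["union"] = flags.any(axis=1)
    meta.add("netcompare", _write_csv(flags, out / "silencing_flags.csv"), p)

    top = nc.top_cross_edges(nets, k=int(p["top_k"]))
    labels, order = nc.cluster_edges(top, n_clusters=int(p["n_clusters"]))
    clustered = top.copy()
    clustered["cluster"] = labels
    clustered["dendrogram_position"] = pd.Series(
        {clustered.index[pos]: rank for rank, pos in enumerate(order)}
    )
    meta.add("netcompare", _write_csv(clustered, out / "edge_clusters.csv"), p)

    net_a = nc.BipartiteNetwork(
        weights=pd.read_csv(run.outdir / "synth" / "bipartite_A.csv", index_col=0),
        condition="A",
    )
    net_b = nc.BipartiteNetwork(
        weights=pd.read_csv(run.outdir / "synth" / "bipartite_B.csv", index_col=0),
        condition="B",
    )
    part_df = pd.read_csv(run.outdir / "synth" / "partition.csv", index_col=0)
    partition = nc.ModulePartition(
        assignments=part_df["module"].to_dict(),
        n_modules=int(part_df["module"].max()) + 1,
    )
    dd = nc.differential_degree(net_a, net_b, partition)
    meta.add("netcompare", _write_csv(dd.genes, out / "diff_degree_genes.csv"), p)
    meta.add("netcompare", _write_csv(dd.tfs, out / "diff_degree_tfs.csv"), p)
    meta.add("netcompare", _write_csv(nc.module_inout_test(dd), out / "module_tests.csv"), p)
    meta.flush()


def _stage_enrich(run: ConcreteRun, meta: _Meta) -> None:
    p = run.params["enrich"]
    out = run.outdir / "enrich"
    out.mkdir(parents=True, exist_ok=True)
    flags_path = run.outdir / "netcompare" / "silencing_flags.csv"
    gmt_path = run.outdir / "synth" / "gene_sets.gmt"
    _require(run, "netcompare", [flags_path])
    _require(run, "synth", [gmt_path])
    flags = pd.read_csv(flags_path, index_col=0)
    query = set(flags.index[flags["union"]])
    genes = pd.read_csv(run.outdir / "synth" / "genes.tsv", sep="\t", index_col=0)
    universe = set(genes.index)
    collection = enrich_mod.read_gmt(gmt_path)
    result = enrich_mod.hypergeometric_ora(
        query, universe, collection, min_overlap=int(p["min_overlap"])
    )
    meta.add("enrich", _write_csv(result, out / "ora_results.csv"), p)
    meta.flush()


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "prep_expr": _stage_prep_expr,
    "prep_meth": _stage_prep_meth,
    "ggm": _stage_ggm,
    "netcompare": _stage_netcompare,
    "enrich": _stage_enrich,
}


def run_pipeline(
    config: RunConfig, stages: list[str] | None = None
) -> pd.DataFrame:
    """Execute the requested stages for every concrete run of ``config``.

    Stages run serially in dependency order; an artifact required by a
    requested stage but absent (its producing stage neither on disk nor in
    this invocation) raises an error naming the stage to run first. Returns
    the combined metadata table."""
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    frames = []
    for run in expand_config(config):
        meta = _Meta(run)
        run.outdir.mkdir(parents=True, exist_ok=True)
        for stage in ordered:
            log.info("run %s: stage %s", run.run_id, stage)
            _STAGE_FUNCS[stage](run, meta)
            meta.flush()
        frames.append(pd.read_csv(run.outdir / "metadata.csv"))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
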