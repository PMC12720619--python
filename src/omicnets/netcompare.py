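"""Comparison statistics across subtype networks.

Covers: decile-based detection of methylation-driven TF silencing, a
Kolmogorov-Smirnov test for lower self-pair weights among cancer-driver TFs,
selection and hierarchical clustering of the strongest cross-omic edges,
per-node paired Wilcoxon edge-shift tests with BH FDR, in-/out-module
differential-degree testing of paired bipartite TF-gene networks with
Bonferroni FWER, differential-targeting gene ranking, and Fisher-exact
annotation-overlap tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .ggm import PartialCorrelationNetwork, edge_block

__all__ = [
    "BipartiteNetwork",
    "ModulePartition",
    "SilencingReport",
    "DiffDegreeResult",
    "detect_silencing",
    "driver_shift_test",
    "top_cross_edges",
    "cluster_edges",
    "per_node_shift_test",
    "differential_degree",
    "module_inout_test",
    "differential_targeting",
    "annotation_overlap_test",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# containers


@dataclass
class BipartiteNetwork:
    """A weighted TF x gene regulatory network for one condition."""

    weights: pd.DataFrame  # TFs in rows, genes in columns
    condition: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights.to_numpy(dtype=float)).all():
            raise ValueError("bipartite network weights must be finite")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights.columns)


@dataclass
class ModulePartition:
    """Assignment of every TF and gene to exactly one of ``n_modules``."""

    assignments: dict[str, int]
    n_modules: int

    def __post_init__(self) -> None:
        seen = set(self.assignments.values())
        if not seen <= set(range(self.n_modules)):
            raise ValueError("module ids must lie in 0..n_modules-1")
        if seen != set(range(self.n_modules)):
            raise ValueError("every module must be nonempty")

    def module_of(self, node: str) -> int:
        return self.assignments[node]


@dataclass
class SilencingReport:
    """Per-subtype decile thresholds and silenced-TF flags."""

    thresholds: dict[str, float]
    flags: pd.DataFrame  # TFs x subtypes, boolean
    union: set[str] = field(default_factory=set)


@dataclass
class DiffDegreeResult:
    """Node-level in-/out-module differential degrees for a network pair.

    ``genes`` and ``tfs`` are tables with columns ``module``, ``in_degree``,
    ``out_degree``; by construction ``in + out`` equals the node's total
    differential degree (sum over all counterpart nodes of the A-B edge
    difference)."""

    genes: pd.DataFrame
    tfs: pd.DataFrame
    n_modules: int


# --------------------------------------------------------------------------
# silencing & driver tests


def detect_silencing(
    self_pair_tables: dict[str, pd.DataFrame], decile: float = 0.10
) -> SilencingReport:
    """Flag TFs whose (M_i, E_i) self-pair weight falls in the lowest decile
    of a subtype's self-pair distribution.

    The threshold ``t_s`` is the linear-interpolation ``decile`` quantile of
    subtype ``s``'s weights and a TF is flagged there iff ``weight <= t_s``
    (ties inclusive). The union over subtypes is reported."""
    if not self_pair_tables:
        raise ValueError("no self-pair tables given")
    if not 0.0 < decile < 1.0:
        raise ValueError("decile must lie in (0, 1)")
    subtypes = sorted(self_pair_tables)
    universe = list(self_pair_tables[subtypes[0]].index)
    for s in subtypes[1:]:
        if list(self_pair_tables[s].index) != universe:
            raise ValueError("all subtypes must share the same TF universe")
    thresholds: dict[str, float] = {}
    flags = pd.DataFrame(False, index=universe, columns=subtypes)
    for s in subtypes:
        w = self_pair_tables[s]["weight"]
        if w.empty:
            raise ValueError(f"empty self-pair table for subtype {s}")
        t = float(np.quantile(w.to_numpy(), decile))
        thresholds[s] = t
        flags[s] = w <= t
    union = set(flags.index[flags.any(axis=1)])
    return SilencingReport(thresholds=thresholds, flags=flags, union=union)


def driver_shift_test(
    self_pair_table: pd.DataFrame, driver_set: set[str]
) -> tuple[float, float]:
    """One-sided two-sample Kolmogorov-Smirnov test that the self-pair
    weights of driver TFs are stochastically smaller than those of the
    remaining TFs. Returns ``(statistic, p)``."""
    weights = self_pair_table["weight"]
    drivers = weights[weights.index.isin(driver_set)]
    others = weights[~weights.index.isin(driver_set)]
    if len(drivers) < 2 or len(others) < 2:
        raise ValueError("need at least 2 TFs in each group")
    method = "exact" if len(drivers) + len(others) <= 25 else "auto"
    # drivers stochastically smaller <=> their empirical CDF lies above
    res = stats.ks_2samp(drivers, others, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# cross-omic edge selection & clustering


def top_cross_edges(
    nets: dict[str, PartialCorrelationNetwork],
    k: int = 200,
    block: str = "ME",
) -> pd.DataFrame:
    """Select the strongest cross-omic edges across subtypes.

    Self pairs (edges linking one TF's two layers) are excluded; remaining
    cross-layer edges are ranked by the mean over subtypes of the absolute
    weight, descending, ties broken lexicographically by (node_i, node_j)
    and logged. Returns the top ``k`` as an edge x subtype weight matrix
    indexed by ``(node_i, node_j)``."""
    if not nets:
        raise ValueError("no networks given")
    subtypes = sorted(nets)
    first = nets[subtypes[0]]
    for s in subtypes[1:]:
        if nets[s].nodes != first.nodes or nets[s].layers != first.layers:
            raise ValueError("all subtype networks must share the same node set")
    tables = {s: edge_block(nets[s], block) for s in subtypes}
    base = tables[subtypes[0]][["node_i", "node_j"]].copy()
    wide = base.copy()
    for s in subtypes:
        wide[s] = tables[s]["weight"].to_numpy()
    wide = wide[wide["node_i"] != wide["node_j"]].copy()
    wide["_score"] = wide[subtypes].abs().mean(axis=1)
    if wide["_score"].duplicated().any():
        log.info("ties in mean |weight| broken lexicographically by node pair")
    wide = wide.sort_values(
        by=["_score", "node_i", "node_j"], ascending=[False, True, True]
    )
    if len(wide) < k:
        log.warning("only %d candidate edges for top-%d selection", len(wide), k)
    out = wide.head(k).set_index(["node_i", "node_j"])[subtypes]
    return out


def cluster_edges(
    edge_matrix: pd.DataFrame, n_clusters: int
) -> tuple[pd.Series, list[int]]:
    """Hierarchically cluster edges by their per-subtype weight vectors
    (average linkage, Euclidean distance) and cut to ``n_clusters``.

    Returns ``(labels, dendrogram leaf order)``; labels are 0-based and
    indexed like ``edge_matrix``."""
    if len(edge_matrix) < 2:
        raise ValueError("need at least 2 edges to cluster")
    if n_clusters > len(edge_matrix):
        raise ValueError("n_clusters exceeds the number of edges")
    z = hierarchy.linkage(edge_matrix.to_numpy(dtype=float), method="average",
                          metric="euclidean")
    raw = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    labels = pd.Series(raw - 1, index=edge_matrix.index, name="cluster")
    order = [int(i) for i in hierarchy.leaves_list(z)]
    return labels, order


# --------------------------------------------------------------------------
# paired edge-shift tests


def _paired_wilcoxon(diffs: np.ndarray, alternative: str) -> tuple[float, float, bool]:
    """Classical paired signed-rank test on a vector of differences; zeros
    dropped, exact null for n <= 25. Returns (stat, p, degenerate_flag)."""
    d = diffs[diffs != 0]
    if d.size == 0:
        return 0.0, 1.0, True
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative=alternative,
                         method=method)
    return float(res.statistic), float(res.pvalue), False


def per_node_shift_test(
    net_a: PartialCorrelationNetwork,
    net_b: PartialCorrelationNetwork,
    source_layer: str = "C",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per source-layer node, a paired Wilcoxon signed-rank test of its
    cross-layer edge weights in network A vs network B (e.g. the edge set
    {(C_i, E_j)}_j between two subtypes), with BH-adjusted q-values across
    nodes. Zero differences are dropped; all-zero nodes get p = 1 and a
    degenerate flag."""
    if net_a.nodes != net_b.nodes or net_a.layers != net_b.layers:
        raise ValueError("both networks must share node sets and layers")
    other = [lab for lab in dict.fromkeys(net_a.layers) if lab != source_layer]
    if len(other) != 1:
        raise ValueError("expected exactly one counterpart layer")
    src_idx = net_a.node_index(source_layer)
    tgt_idx = np.array(net_a.node_index(other[0]))
    rows = []
    for i in src_idx:
        d = net_a.weights[i, tgt_idx] - net_b.weights[i, tgt_idx]
        stat, p, degen = _paired_wilcoxon(d, alternative)
        rows.append((net_a.nodes[i], d[d != 0].size, stat, p, degen))
    out = pd.DataFrame(
        rows, columns=["node", "n_nonzero", "statistic", "p", "degenerate"]
    ).set_index("node")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# --------------------------------------------------------------------------
# differential degree on bipartite networks


def differential_degree(
    net_a: BipartiteNetwork,
    net_b: BipartiteNetwork,
    partition: ModulePartition,
) -> DiffDegreeResult:
    """In-/out-module differential degrees for every gene and TF.

    The differential edge is ``e_A - e_B`` (first network minus second).
    For a gene ``r`` in module ``c``, the in-module differential degree sums
    the differential edges from the TFs assigned to ``c``; the out-module
    degree sums those from all other TFs. TF degrees mirror this over genes.
    ``in + out`` equals the node's total differential degree exactly."""
    if net_a.tf_ids != net_b.tf_ids or net_a.gene_ids != net_b.gene_ids:
        raise ValueError("networks must share identical TF and gene id lists")
    missing = (set(net_a.tf_ids) | set(net_a.gene_ids)) - set(partition.assignments)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    diff = net_a.weights.to_numpy(dtype=float) - net_b.weights.to_numpy(dtype=float)
    tf_mod = np.array([partition.module_of(t) for t in net_a.tf_ids])
    gene_mod = np.array([partition.module_of(g) for g in net_a.gene_ids])

    # per-module column/row sums of the difference matrix
    n_mod = partition.n_modules
    tf_groups = [np.flatnonzero(tf_mod == c) for c in range(n_mod)]
    gene_groups = [np.flatnonzero(gene_mod == c) for c in range(n_mod)]
    per_mod_gene = np.stack([diff[g].sum(axis=0) for g in tf_groups])  # mod x gene
    per_mod_tf = np.stack([diff[:, g].sum(axis=1) for g in gene_groups])  # mod x tf
    total_gene = diff.sum(axis=0)
    total_tf = diff.sum(axis=1)

    gene_in = per_mod_gene[gene_mod, np.arange(len(gene_mod))]
    tf_in = per_mod_tf[tf_mod, np.arange(len(tf_mod))]
    genes = pd.DataFrame(
        {
            "module": gene_mod,
            "in_degree": gene_in,
            "out_degree": total_gene - gene_in,
        },
        index=pd.Index(net_a.gene_ids, name="gene_id"),
    )
    tfs = pd.DataFrame(
        {
            "module": tf_mod,
            "in_degree": tf_in,
            "out_degree": total_tf - tf_in,
        },
        index=pd.Index(net_a.tf_ids, name="tf_id"),
    )
    return DiffDegreeResult(genes=genes, tfs=tfs, n_modules=n_mod)


def module_inout_test(result: DiffDegreeResult) -> pd.DataFrame:
    """Per module and node type, a paired Wilcoxon signed-rank test of the
    in-module vs out-module differential degrees of the module's nodes, with
    Bonferroni FWER across modules (within each node-type family) and mean
    in/out degrees. Modules with fewer than 2 nodes of a type are skipped
    with a flag."""
    rows = []
    for kind, table in (("gene", result.genes), ("tf", result.tfs)):
        for c in range(result.n_modules):
            sub = table[table["module"] == c]
            if len(sub) < 2:
                rows.append((kind, c, len(sub), np.nan, np.nan, np.nan,
                             sub["in_degree"].mean(), sub["out_degree"].mean(), True))
                continue
            d = (sub["in_degree"] - sub["out_degree"]).to_numpy()
            stat, p, degen = _paired_wilcoxon(d, "two-sided")
            rows.append((kind, c, len(sub), stat, p, np.nan,
                         sub["in_degree"].mean(), sub["out_degree"].mean(), degen))
    out = pd.DataFrame(
        rows,
        columns=["kind", "module", "n", "statistic", "p", "p_bonferroni",
                 "mean_in", "mean_out", "degenerate"],
    )
    for kind in ("gene", "tf"):
        mask = (out["kind"] == kind) & out["p"].notna()
        n_tests = int(mask.sum())
        out.loc[mask, "p_bonferroni"] = np.minimum(out.loc[mask, "p"] * n_tests, 1.0)
    return out.set_index(["kind", "module"])


def differential_targeting(
    net_a: BipartiteNetwork,
    net_b: BipartiteNetwork,
    tf_set: set[str],
    top_k: int = 100,
) -> list[str]:
    """Target genes of the ``top_k`` edges from ``tf_set`` with the greatest
    absolute edge-weight difference between the two networks, deduplicated in
    rank order. Identical networks yield an empty list with a warning."""
    if not tf_set:
        raise ValueError("tf_set must not be empty")
    unknown = tf_set - set(net_a.tf_ids)
    if unknown:
        raise ValueError(f"unknown TFs: {sorted(unknown)}")
    tfs = [t for t in net_a.tf_ids if t in tf_set]
    diff = (net_a.weights.loc[tfs] - net_b.weights.loc[tfs]).abs()
    long = diff.stack()
    if (long == 0).all():
        log.warning("networks identical on tf_set: no differential targets")
        return []
    long = long.reset_index()
    long.columns = ["tf", "gene", "absdiff"]
    long = long.sort_values(by=["absdiff", "tf", "gene"],
                            ascending=[False, True, True]).head(top_k)
    genes: list[str] = []
    for g in long["gene"]:
        if g not in genes:
            genes.append(g)
    return genes


# --------------------------------------------------------------------------
# annotation overlap


def annotation_overlap_test(
    member_set: set[str], annotated_set: set[str], universe: set[str]
) -> tuple[float, float]:
    """Fisher's exact test of overlap between a member set (e.g. a cluster's
    TFs) and an annotation (e.g. cancer drivers) within a universe.

    Returns ``(odds ratio, two-sided exact p)``; the odds ratio is the sample
    (cross-product) OR with a Haldane 0.5 correction when a cell is zero."""
    if not universe:
        raise ValueError("universe must not be empty")
    if not member_set <= universe or not annotated_set <= universe:
        raise ValueError("member_set and annotated_set must be subsets of universe")
    a = len(member_set & annotated_set)
    b = len(member_set - annotated_set)
    c = len(annotated_set - member_set)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds = (a * d) / (b * c)
    return float(odds), float(p)
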