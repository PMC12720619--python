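"""Recovery and calibration studies on synthetic cohorts.

Each study simulates data whose planted structure is known, runs the full
analysis path on it, and measures how well the planted truth is recovered.
They are the package's own benchmark of its methods under the study
conditions (sample sizes, effect magnitudes, noise levels) fixed here, and
back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import ggm, netcompare, prep_expr, prep_meth, synth
from ._util import derive_seed

__all__ = [
    "fit_subtype_networks",
    "silencing_recovery_study",
    "flip_cluster_study",
    "module_test_calibration",
    "module_test_power",
    "enrichment_recovery_study",
]

# study-wide estimation setting: a small fixed shrinkage keeps the inverse
# well conditioned at p ~ 100, n = 500 without a per-fit grid search
_STUDY_LAMBDAS = (0.05, 0.05)


def _preprocess_bundle(
    bundle: synth.OmicsBundle,
    genes: pd.DataFrame,
    probes: pd.DataFrame,
    window_bp: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter M-value (nonparanormal) and log-CPM TF-expression layers for
    one bundle, aligned on shared samples."""
    tf_subset = set(genes.index[genes["is_tf"]])
    mapping = prep_meth.map_probes_to_promoters(
        probes, genes, window_bp=window_bp, gene_subset=tf_subset
    )
    mat = prep_meth.MethylationMatrix(values=bundle.methylation_beta, kind="probe")
    agg, _ = prep_meth.aggregate_promoter_beta(mat, mapping)
    agg = prep_meth.resolve_duplicates_methylation(agg, policy="least_missing")
    agg = prep_meth.filter_and_impute_missing(agg, m_fraction=0.2)
    mvals = prep_meth.convert_beta_m(agg, "beta_to_m")
    npn = prep_meth.nonparanormal_transform(mvals)

    expr = prep_expr.ExpressionMatrix(
        values=bundle.expression_counts,
        units="counts",
        gene_lengths=genes["length_bp"],
    )
    expr = prep_expr.resolve_duplicates_expression(expr)
    expr = prep_expr.normalize_expression(expr, method="CPM_TMM")
    expr = prep_expr.log_transform(expr, pseudocount=1.0)
    expr_vals = expr.values.loc[[g for g in expr.values.index if g in tf_subset]]

    shared = [c for c in npn.values.columns if c in set(expr_vals.columns)]
    return npn.values[shared], expr_vals[shared]


def fit_subtype_networks(
    precisions: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
    probes: pd.DataFrame,
    n_samples: int,
    seed: int,
    lambdas: tuple[float, float] = _STUDY_LAMBDAS,
) -> dict[str, ggm.PartialCorrelationNetwork]:
    """Simulate one cohort per subtype and fit its M/E partial-correlation
    network through the full preprocessing chain."""
    bundles = synth.simulate_cohort(
        precisions, (genes, probes), n_samples_per_subtype=n_samples,
        seed=seed, include_cnv=False,
    )
    nets = {}
    for s, bundle in bundles.items():
        meth, expr = _preprocess_bundle(bundle, genes, probes)
        nets[s] = ggm.fit_partial_correlations(meth, expr, lambdas=lambdas)
    return nets


def silencing_recovery_study(
    seed: int,
    n_seeds: int = 20,
    n_tf: int = 50,
    n_silenced: int = 5,
    n_samples: int = 500,
) -> dict[str, float]:
    """Recovery of planted methylation-silenced TFs.

    Per seed: a two-subtype cohort with ``n_silenced`` TFs silenced in the
    first subtype (self-pair partial correlation -0.4) is simulated, both
    networks are fit, and the first-decile silencing detector is applied.
    Returns the pooled fraction of planted TFs recovered by the union flag
    and the fraction of planted self-pairs whose estimated weight is
    negative in the silenced subtype."""
    recovered = planted_total = negative = 0
    for r in range(n_seeds):
        sub_seed = derive_seed(seed, r)
        genes, probes = synth.generate_annotation(
            n_genes=n_tf, n_tf=n_tf, probes_per_gene=2, seed=sub_seed
        )
        rng = np.random.default_rng(sub_seed)
        tf_ids = list(genes.index[genes["is_tf"]])
        silenced = {str(t) for t in rng.choice(tf_ids, size=n_silenced, replace=False)}
        precisions, _ = synth.build_subtype_precisions(
            genes, n_subtypes=2, silencing_spec={"S1": silenced},
            seed=sub_seed, silencing_magnitude=0.4, background_density=0.02,
        )
        nets = fit_subtype_networks(
            precisions, genes, probes, n_samples=n_samples, seed=sub_seed
        )
        tables = {s: ggm.self_pair_edges(net) for s, net in nets.items()}
        report = netcompare.detect_silencing(tables, decile=0.10)
        recovered += len(report.union & silenced)
        planted_total += len(silenced)
        w = tables["S1"]["weight"]
        negative += int((w.loc[sorted(silenced)] < 0).sum())
    return {
        "recovery_fraction": recovered / planted_total,
        "negative_sign_fraction": negative / planted_total,
        "n_seeds": n_seeds,
    }


def flip_cluster_study(
    seed: int,
    n_seeds: int = 20,
    n_tf: int = 50,
    n_flip: int = 12,
    n_samples: int = 500,
    top_k: int = 40,
    ari_threshold: float = 0.8,
) -> dict[str, float]:
    """Recovery of a planted sign-flip edge cluster.

    Per seed: ``n_flip`` cross-omic (M_i, E_j) edges are planted with
    partial correlation +0.35 in one subtype and -0.35 in the other, against
    a background of sign-consistent edges; the top ``top_k`` strongest
    estimated cross edges are clustered (average linkage, Euclidean) into 2
    groups and compared with the planted flip/non-flip labels by adjusted
    Rand index. Returns the fraction of seeds with ARI >= threshold."""
    successes = 0
    aris = []
    for r in range(n_seeds):
        sub_seed = derive_seed(seed, 10_000 + r)
        genes, probes = synth.generate_annotation(
            n_genes=n_tf, n_tf=n_tf, probes_per_gene=2, seed=sub_seed
        )
        rng = np.random.default_rng(sub_seed)
        tf_ids = list(genes.index[genes["is_tf"]])
        pairs = [(a, b) for a in tf_ids for b in tf_ids if a != b]
        chosen = rng.choice(len(pairs), size=n_flip, replace=False)
        flip = synth.FlipSpec(
            edges=tuple(pairs[i] for i in sorted(chosen)),
            magnitude=0.35,
            positive_subtype="S1",
            negative_subtype="S2",
        )
        precisions, truth = synth.build_subtype_precisions(
            genes, n_subtypes=2, flip_spec=flip, seed=sub_seed,
            background_density=0.02, background_magnitude=(0.2, 0.35),
        )
        nets = fit_subtype_networks(
            precisions, genes, probes, n_samples=n_samples, seed=sub_seed
        )
        top = netcompare.top_cross_edges(nets, k=top_k)
        labels, _ = netcompare.cluster_edges(top, n_clusters=2)
        flip_edges = {(m.split(":", 1)[1], e.split(":", 1)[1])
                      for m, e in truth.flip_cluster_edges}
        truth_labels = [int(pair in flip_edges) for pair in top.index]
        ari = adjusted_rand_score(truth_labels, labels.to_numpy())
        aris.append(ari)
        successes += int(ari >= ari_threshold)
    return {
        "success_fraction": successes / n_seeds,
        "mean_ari": float(np.mean(aris)),
        "n_seeds": n_seeds,
    }


def _one_module_run(
    seed: int, delta: float, noise_sd: float
) -> pd.DataFrame:
    net_a, net_b, partition, _ = synth.generate_bipartite_pair(
        n_tf=12, n_genes=40, n_modules=4, planted_module=0,
        delta=delta, noise_sd=noise_sd, seed=seed,
    )
    dd = netcompare.differential_degree(net_a, net_b, partition)
    return netcompare.module_inout_test(dd)


def module_test_calibration(
    seed: int,
    n_replicates: int = 500,
    alpha: float = 0.05,
    noise_sd: float = 0.1,
) -> dict[str, float]:
    """Type-I error of the in-/out-module gene test under no planted effect:
    the fraction of (replicate, module) gene tests with p < alpha."""
    rejections = total = 0
    for r in range(n_replicates):
        tests = _one_module_run(derive_seed(seed, 20_000 + r), delta=0.0,
                                noise_sd=noise_sd)
        p = tests.loc["gene"]["p"].dropna()
        rejections += int((p < alpha).sum())
        total += len(p)
    return {
        "rejection_rate": rejections / total,
        "n_tests": total,
        "alpha": alpha,
    }


def module_test_power(
    seed: int,
    n_replicates: int = 100,
    delta: float = 1.0,
    noise_sd: float = 0.1,
) -> dict[str, float]:
    """Power to single out the planted module: the fraction of replicates in
    which the planted module attains the minimum gene-test p-value."""
    wins = 0
    for r in range(n_replicates):
        tests = _one_module_run(derive_seed(seed, 30_000 + r), delta=delta,
                                noise_sd=noise_sd)
        p = tests.loc["gene"]["p"].dropna()
        if p.loc[0] <= p.min():
            wins += 1
    return {"min_p_fraction": wins / n_replicates, "n_replicates": n_replicates}


def enrichment_recovery_study(
    seed: int,
    n_seeds: int = 50,
    n_universe: int = 1000,
    n_query: int = 60,
    set_size: int = 50,
    overlap_frac: float = 0.6,
) -> dict[str, float]:
    """Fraction of seeds in which the planted enriched set attains the
    smallest BH q-value in the overrepresentation analysis."""
    from . import enrich

    wins = 0
    for r in range(n_seeds):
        sub_seed = derive_seed(seed, 40_000 + r)
        rng = np.random.default_rng(sub_seed)
        universe = [f"g{i:04d}" for i in range(n_universe)]
        query = [str(g) for g in rng.choice(universe, size=n_query, replace=False)]
        collection, truth = synth.generate_gene_sets(
            universe, query, n_sets=20, set_size=set_size,
            enriched_overlap_frac=overlap_frac, seed=sub_seed,
        )
        result = enrich.hypergeometric_ora(
            set(query), set(universe), collection, min_overlap=1
        )
        if len(result) and result["q"].idxmin() == truth.enriched_set:
            wins += 1
    return {"smallest_q_fraction": wins / n_seeds, "n_seeds": n_seeds}
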