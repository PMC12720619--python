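"""Preprocess the expression and methylation layers of one subtype.

Expression: duplicate vials resolved by sequencing depth, low-expressed
genes dropped, CPM normalization on TMM-scaled libraries, log2 transform.
Methylation: probes averaged into promoter values, duplicates resolved by
least missingness, missing values filtered/imputed at the 20% rule, beta
converted to M-values, nonparanormal transform.
"""

from omicnets import (
    ExpressionMatrix,
    ExprFilterParams,
    MethylationMatrix,
    aggregate_promoter_beta,
    build_subtype_precisions,
    convert_beta_m,
    filter_and_impute_missing,
    filter_low_expression,
    generate_annotation,
    log_transform,
    map_probes_to_promoters,
    nonparanormal_transform,
    normalize_expression,
    resolve_duplicates_expression,
    resolve_duplicates_methylation,
    simulate_cohort,
    tmm_factors,
)

genes, probes = generate_annotation(n_genes=30, n_tf=15, probes_per_gene=3, seed=7)
precisions, _ = build_subtype_precisions(genes, n_subtypes=1, seed=7)
bundle = simulate_cohort(
    precisions, (genes, probes), n_samples_per_subtype=60,
    duplicate_fraction=0.2, missing_rate=0.03, seed=7,
)["S1"]

expr = ExpressionMatrix(
    values=bundle.expression_counts, units="counts", gene_lengths=genes["length_bp"]
)
print(f"expression: {expr.values.shape[1]} samples before duplicate resolution")
expr = resolve_duplicates_expression(expr)
print(f"            {expr.values.shape[1]} samples after (greatest depth kept)")
expr, removed = filter_low_expression(
    expr, ExprFilterParams(n_min_counts=5, p_fraction=0.9)
)
print(f"            {len(removed)} low-expressed genes removed")
factors = tmm_factors(expr.values)
expr = normalize_expression(expr, method="CPM_TMM")
expr = log_transform(expr, pseudocount=1.0)
print(f"            TMM factors span [{factors.min():.3f}, {factors.max():.3f}]"
      f" (geometric mean 1); units now {expr.units}")

mapping = map_probes_to_promoters(
    probes, genes, window_bp=200, gene_subset=set(genes.index[genes["is_tf"]])
)
meth = MethylationMatrix(values=bundle.methylation_beta, kind="probe")
agg, _ = aggregate_promoter_beta(meth, mapping)
agg = resolve_duplicates_methylation(agg, policy="least_missing")
kept_before = agg.values.shape[0]
agg = filter_and_impute_missing(agg, m_fraction=0.2)
mvals = convert_beta_m(agg, "beta_to_m")
npn = nonparanormal_transform(mvals)
print(f"methylation: {len(mapping)} TFs with promoter probes; "
      f"{kept_before - agg.values.shape[0]} dropped by the 20% missingness rule")
print(f"             M-value matrix {npn.values.shape}, per-feature SD 1 after "
      "nonparanormal transform")
# Both layers now share one column per subject, ready for network inference.
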