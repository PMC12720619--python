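# Methods

## Model and scope

`omicnets` analyzes regulatory differences between condition groups
("subtypes") from matched omic layers. Two network models are used:

* an **undirected two-layer Gaussian graphical model** over TF promoter
  methylation (M) and TF expression (E) nodes, whose edge weights are
  partial correlations — association conditional on all other nodes; and
* a **weighted bipartite TF–gene regulatory network** per condition, which
  the package consumes as input (or generates synthetically) rather than
  infers: bipartite GRN inference and differential-modularity partitioning
  are upstream methods outside this package's scope, so module partitions
  arrive as data.

The analysis questions are: which TFs show direct epigenetic suppression of
their own expression (strongly negative (M_i, E_i) self pairs); which
cross-omic associations reverse direction between subtypes; and which
modules of the bipartite networks gain or lose connectivity between
conditions.

## Partial-correlation estimator

Features are standardized (so the estimate is invariant to affine
rescaling of any input feature) and stacked; the joint sample correlation
matrix `R` is shrunk per layer pair,

    R*_ij = sqrt((1 - λ_a)(1 - λ_b)) · R_ij   (i in layer a, j in layer b),

with unit diagonal, and weights are `w_ij = -Θ_ij / √(Θ_ii Θ_jj)` with
`Θ = (R*)⁻¹`. Per-layer shrinkage acknowledges that the two omic layers can
need different regularization (methylation features are typically noisier
and more numerous than expression features).

λ is either supplied or selected on the grid {0, 0.05, …, 0.95, 0.99}² by
K-fold (default 5, seeded) held-out Gaussian log-likelihood; ties resolve to
the smallest grid pair, deterministically. A cross-validated selection was
chosen over analytic risk formulas deliberately: it is assumption-light,
easy to audit, and its fold structure is reproducible from the seed. Fits
with `lambda_mode="cv"` are labelled as such in saved networks. At λ=(0,0)
the estimator reduces exactly to direct inversion of the sample correlation
matrix (verified to 1e−8 in the tests at p=6, n=5000); at λ=(1,1) the
network is exactly zero.

Degenerate inputs: a constant feature is an error naming the feature; a
singular shrunk correlation (e.g. p > n at λ=0) is an error instructing a
larger λ. The weight diagonal is fixed at 0 — "self pair" always means the
cross-layer (M_i, E_i) entry, never the matrix diagonal.

## Preprocessing conventions

* **Promoter window**: 0-based, half-open, strand-mirrored — on "+" a probe
  maps iff `tss − w ≤ pos < tss`, on "−" iff `tss < pos ≤ tss + w`, with
  w = 200 bp by default. The convention is arbitrary at the 1 bp level but
  fixed and testable against a brute-force interval scan.
* **Promoter β**: mean over the gene's mapped probes using non-missing
  values per sample; a gene with all mapped probes missing stays missing.
* **Missingness rule**: a feature is removed iff its missing fraction is
  strictly greater than m (default 0.20) — exactly 20 % missing is kept —
  and survivors are mean-imputed. `m = 0` removes any feature with a
  missing entry. The operation is idempotent.
* **β↔M conversion**: `M = log2(β/(1−β))` after clamping β to
  [ε, 1−ε], ε = 1e−6, because the logit is infinite at {0, 1}. Conversion
  refuses missing entries (impute first): order violations raise
  contract errors rather than silently proceeding.
* **Nonparanormal transform**: per feature, average ranks r over n samples
  are mapped through `Φ⁻¹(r/(n+1))` and rescaled to unit sample SD. The
  shrunken-rank form (dividing by n+1) keeps the extremes finite without a
  truncation constant; it is strictly rank-preserving, so any monotone
  marginal distortion of a feature yields identical output.
* **TMM factors**: reference sample = the one whose 75th percentile of
  library-scaled counts is closest to the mean 75th percentile; M (log2
  count ratio) and A (mean log2 abundance) over genes positive in both;
  trim 30 % per M tail and 5 % per A tail; factor = 2^(inverse-variance
  weighted mean of trimmed M); factors rescaled to geometric mean 1.
  Identical libraries give factors of exactly 1, and pure depth scaling of
  one library leaves normalized values of balanced genes equal across
  samples.
* **Low-expression rule**: gene removed iff the number of samples with
  `count < n` is at least `ceil(p·S)`; ties at the threshold resolve toward
  removal, for determinism.
* **Duplicates**: expression keeps the vial with the greatest total count
  (ties: first in column order, logged); methylation offers least-missing,
  seeded-random, or exclude-all policies. Samples with no purity annotation
  are retained with a warning by default (only known-low-purity samples are
  dropped), with an opt-in strict mode.

## Comparison statistics

* **Silencing decile**: per subtype, the threshold is the
  linear-interpolation 0.10 quantile of that subtype's self-pair weights;
  TFs at or below it are flagged (ties inclusive), and the union over
  subtypes is reported. The decile is a relative criterion, so some tail
  noise is flagged by construction even without planted structure.
* **Driver shift**: one-sided two-sample KS with the alternative that
  driver TFs' weights are stochastically smaller; exact null for small
  samples (verified against full permutation enumeration at n=8).
* **Top cross edges**: self pairs excluded; ranking by mean |weight| over
  subtypes, descending, ties broken lexicographically by node pair and
  logged; fewer than K candidates returns all with a warning.
* **Edge clustering**: average-linkage hierarchical clustering on Euclidean
  distance between per-subtype weight vectors; the number of clusters is a
  required parameter (no automatic cut criterion is imposed) and the
  dendrogram leaf order is exported so users can re-cut.
* **Wilcoxon convention**: zero differences are dropped (classical signed
  rank) with the post-drop n recorded; exact null for n ≤ 25, normal
  approximation beyond; all-zero difference vectors return p = 1 with a
  degenerate flag. Per-node edge-shift tests are two-sided by default with
  BH FDR across nodes; the module in/out test is two-sided with Bonferroni
  FWER across modules, separately for the gene and TF families.
* **Differential degree**: computed as first network minus second; callers
  choose the orientation. `in + out` equals the node's total differential
  degree to machine precision by construction, and swapping the networks
  negates all degrees without changing two-sided p-values.
* **Overlap tests and ORA**: odds ratios are sample (cross-product) ORs
  with a Haldane 0.5 correction on zero cells — a conditional-MLE OR would
  differ slightly but the sample OR is the common convention and is
  documented in output headers. ORA p-values are upper hypergeometric
  tails, verified against subset enumeration on small universes; sets
  overlapping the query below `min_overlap` (default 2) are excluded from
  the BH family to avoid singleton-driven hits.
* **Slim collapsing**: every pathway's members merge into its top-level
  ancestor in the child→parent map, so the output contains no
  parent–child pair. Collapsing to broad top-level terms (rather than to
  each leaf's immediate parent) is the only rule that guarantees that
  invariant when parents are themselves sets in the collection.

## Synthetic-data generator

The generator is the package's study design, not a fixture: its defaults
define the conditions under which the recovery claims hold.

* **Latent model**: per subject, `Z ~ N(0, Ω⁻¹)` over M + E nodes. Planted
  structure lives in Ω: a silenced TF has target self-pair partial
  correlation −0.4 in its subtype and 0 elsewhere; flip edges are
  +magnitude (default 0.35) in one named subtype and −magnitude in the
  other; optional background (M_i, E_j) edges, shared across subtypes with
  positive sign, supply the strong sign-consistent edges among which a flip
  cluster must be discovered (and make a 2-cluster cut of the top edges
  identifiable: flip edges look like (+v, −v), background like (v, v)).
* **PD repair**: Ω = I + S with zero-diagonal S; if the minimum eigenvalue
  falls below 0.05, S is scaled uniformly (one factor across subtypes, to
  preserve cross-subtype comparability) to restore it. Uniform scaling
  cannot change planted signs; if it would shrink a planted magnitude below
  0.05 the generator raises an error rather than silently clamping.
* **Observation links**: promoter probes are
  `invlogit(μ_m + σ_m·Z_M + probe offset + noise)` (μ_m = −1, σ_m = 1.2,
  offset SD 0.4, noise SD 0.3), so β marginals are skewed toward low
  methylation; off-promoter probes carry independent baselines. Counts are
  `Poisson(depth · softplus(μ_e + σ_e·Z_E))` with per-sample depth uniform
  in (30, 80) — mean counts in the hundreds, typical of a moderately
  sequenced bulk library after gene-level summarization. CNV is a per-gene
  latent correlated with the expression latent (coupling 0.5) plus a
  segment Gaussian shared by genes within 1 Mb on a chromosome, giving the
  positive (C_i, E_i) skew and the block structure expected of copy-number
  data. These monotone links preserve ranks, so the rank-based
  preprocessing recovers the latent correlation structure approximately —
  the estimated self-pairs are attenuated (≈ −0.3 observed for −0.4
  planted at n = 500) but preserve sign and order.
* **Duplicates and missingness**: duplicate subjects share one latent
  vector and get a second vial with fresh depth and noise plus 10 %
  extra methylation missingness, so duplicate-resolution policies have
  real work to do. Sample ids are `SUBJ<k>-V<j>`; no external barcode
  scheme is emulated.
* **Randomness**: one seed per call, split deterministically per layer via
  independent child streams, so adding a layer (e.g. turning CNV on) does
  not perturb the others. All generators are pure functions of
  (parameters, seed).
* **Bipartite pairs**: baseline N(0,1) weights; condition B adds +δ to the
  in-module edges of the planted module before independent N(0, noise²)
  noise; round-robin module assignment (then shuffled) guarantees nonempty
  modules.

What the generator does **not** emulate: array probe chemistry, tumor
purity acting as a confounder (purity is annotation only), batch effects,
library-preparation biases, count overdispersion beyond Poisson, or
realistic gene-length/expression coupling. Passing recovery tests therefore
demonstrates the correctness and statistical behavior of the analysis
chain under its stated assumptions, not robustness to those real-data
complications.

## Study sizes and calibration results

The bundled studies (also run by `scripts/acceptance.py`) use: 50 TFs with
5 silenced, two subtypes, 500 samples per subtype, 20 seeds for the
silencing and flip-cluster recoveries; 500 replicates (12 TFs × 40 genes,
4 modules) for the module-test type-I rate and 100 for power; 50 seeds for
enrichment recovery (universe 1000, query 60, one planted set with 60 %
query overlap). These sizes make each claim measurable with tight binomial
error while every study stays in the tens of seconds. Recovery networks use
fixed λ = (0.05, 0.05): at p ≈ 100 and n = 500 the sample correlation is
well conditioned and a light fixed shrinkage avoids a per-seed grid search
without changing the ranking of edges.

Observed under these conditions (seed 1): silenced-TF recovery 100 %,
estimated-sign agreement 100 %, flip-cluster ARI 1.0 on all seeds, module
test type-I rate 0.0475 at α = 0.05 (the exact signed-rank null at 10
genes/module makes the achievable level ≈ 0.049), planted-module minimum-p
rate 100 %, planted-enrichment recovery 100 %.

## Pipeline and reproducibility

Stages run serially in dependency order; each artifact appends a metadata
row (run id, stage, parameters, path, timestamp). All numeric artifacts are
bit-reproducible from (config, seed); metadata timestamps are wall-clock
provenance and deliberately not part of the deterministic surface. Strict
config validation rejects unknown keys; list-valued parameters expand to a
Cartesian product of runs with sub-seeds derived through a seed sequence
(stable, collision-free, < 2³¹). Networks are stored in HDF5
(`/nodes`, `/layers`, `/weights`, `/lambdas`) and round-trip weights
bit-exactly. After duplicate resolution the prep stages re-key columns to
subject ids, which is what makes cross-omic sample matching trivial
downstream.

## Known limitations

* The shrinkage estimator's λ grid search optimizes held-out likelihood,
  not edge-recovery; for very small n the selected λ can be large and all
  weights strongly attenuated.
* Silencing is a relative (decile) criterion: it always flags ~10 % of TFs
  per subtype, including pure noise when nothing is planted.
* The bipartite-module Wilcoxon test assumes genes are exchangeable within
  a module under the null; correlated edge noise across TFs would break
  the nominal level.
* ORA treats genes as exchangeable draws; gene-length or expression bias
  in the query is not modeled.
* CNV support covers generation and the per-node shift test surface; the
  pipeline's staged runs fit only M/E networks by default.
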