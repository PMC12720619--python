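"""Seeded synthetic multiomic cohorts and network pairs with planted truth.

The generators here emulate the statistical structure the downstream analyses
assume — matched expression/methylation/CNV layers over shared subjects,
negatively skewed promoter-methylation-to-expression self-pair partial
correlations with subtype-specific "silenced" TFs, a cluster of cross-omic
edges whose signs flip between two subtypes, bipartite TF-gene network pairs
with a planted differentially connected module, and gene-set collections with
one planted enriched set — and return ground-truth labels so that recovery can
be tested.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import spawn_rngs
from .netcompare import BipartiteNetwork, ModulePartition

__all__ = [
    "GenerationError",
    "FlipSpec",
    "OmicsBundle",
    "SyntheticTruth",
    "generate_annotation",
    "build_subtype_precisions",
    "simulate_cohort",
    "generate_bipartite_pair",
    "generate_gene_sets",
]


class GenerationError(RuntimeError):
    """Raised when a requested planted structure cannot be realized."""


# --------------------------------------------------------------------------
# containers


@dataclass
class FlipSpec:
    """A set of cross-omic (methylation-node, expression-node) edges whose
    partial-correlation sign flips between two subtypes.

    ``edges`` holds (tf_id, gene_id) pairs; the partial correlation is
    ``+magnitude`` in ``positive_subtype`` and ``-magnitude`` in
    ``negative_subtype``.
    """

    edges: tuple[tuple[str, str], ...]
    magnitude: float
    positive_subtype: str
    negative_subtype: str


@dataclass
class OmicsBundle:
    """Matched feature x sample matrices for one subtype.

    Columns of every layer are sample ids of the form ``SUBJ<k>-V<j>``;
    layers share subjects but a subject may have extra vials in one layer.
    """

    expression_counts: pd.DataFrame  # genes x samples, nonnegative ints
    methylation_beta: pd.DataFrame  # probes x samples, in [0,1], NaN = missing
    purity: pd.Series  # per expression sample, in [0,1]
    cnv: pd.DataFrame | None = None  # genes x samples
    subtype: str = ""

    def __post_init__(self) -> None:
        beta = self.methylation_beta.to_numpy(dtype=float)
        finite = beta[np.isfinite(beta)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("methylation beta values must lie in [0, 1]")
        if (self.expression_counts.to_numpy() < 0).any():
            raise ValueError("expression counts must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression_counts.columns)


@dataclass
class SyntheticTruth:
    """Planted ground truth attached to a generated object."""

    silenced_tfs_by_subtype: dict[str, set[str]] = field(default_factory=dict)
    flip_cluster_edges: set[tuple[str, str]] = field(default_factory=set)
    true_partial_correlations: dict[str, pd.DataFrame] = field(default_factory=dict)
    planted_module: tuple[int, float] | None = None
    enriched_set: str | None = None


# --------------------------------------------------------------------------
# annotation


def generate_annotation(
    n_genes: int,
    n_tf: int,
    probes_per_gene: int,
    seed: int,
    window_bp: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a gene annotation and a matching CpG probe annotation.

    Genes are placed on two chromosomes with increasing 0-based coordinates.
    For every gene at least one probe falls inside its promoter window
    (``window_bp`` upstream of the TSS, strand aware) and — when
    ``probes_per_gene >= 2`` — at least one falls outside it, so promoter
    mapping is exercised in both directions.

    Returns ``(genes, probes)``: genes indexed by ``gene_id`` with columns
    ``chrom, tss, strand, length_bp, is_tf``; probes indexed by ``probe_id``
    with columns ``chrom, pos``.
    """
    if n_genes < 1 or probes_per_gene < 1:
        raise ValueError("n_genes and probes_per_gene must be positive")
    if not 1 <= n_tf <= n_genes:
        raise ValueError("n_tf must satisfy 1 <= n_tf <= n_genes")
    if window_bp < 1:
        raise ValueError("window_bp must be positive")

    rng = np.random.default_rng(int(seed))
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    chroms, tsss, strands, lengths = [], [], [], []
    pos_cursor = {"chr1": 10_000, "chr2": 10_000}
    for i in range(n_genes):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        pos_cursor[chrom] += int(rng.integers(50_000, 150_000))
        chroms.append(chrom)
        tsss.append(pos_cursor[chrom])
        strands.append("+" if rng.random() < 0.5 else "-")
        lengths.append(int(rng.integers(500, 50_000)))
    tf_idx = rng.choice(n_genes, size=n_tf, replace=False)
    is_tf = np.zeros(n_genes, dtype=bool)
    is_tf[tf_idx] = True
    genes = pd.DataFrame(
        {
            "chrom": chroms,
            "tss": tsss,
            "strand": strands,
            "length_bp": lengths,
            "is_tf": is_tf,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    probe_ids, p_chroms, p_pos = [], [], []
    for i, gid in enumerate(gene_ids):
        tss = tsss[i]
        sign = 1 if strands[i] == "+" else -1
        for j in range(probes_per_gene):
            if j == 0:  # inside the promoter window
                pos = tss - sign * int(rng.integers(1, window_bp + 1))
            elif j == 1:  # outside: the non-promoter side of the TSS
                pos = tss + sign * int(rng.integers(0, 5_000))
            else:
                pos = tss + int(rng.integers(-5_000, 5_000))
            probe_ids.append(f"cg{i:04d}_{j}")
            p_chroms.append(chroms[i])
            p_pos.append(max(pos, 0))
    probes = pd.DataFrame(
        {"chrom": p_chroms, "pos": p_pos},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return genes, probes


# --------------------------------------------------------------------------
# precision matrices

_EIG_FLOOR = 0.05


def _node_names(genes: pd.DataFrame) -> tuple[list[str], list[str]]:
    tf_ids = list(genes.index[genes["is_tf"]])
    gene_ids = list(genes.index)
    return tf_ids, gene_ids


def build_subtype_precisions(
    annotation: pd.DataFrame,
    n_subtypes: int,
    silencing_spec: dict[str, set[str]] | None = None,
    flip_spec: FlipSpec | None = None,
    seed: int = 0,
    silencing_magnitude: float = 0.4,
    background_density: float = 0.0,
    background_magnitude: tuple[float, float] = (0.2, 0.35),
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Build per-subtype precision matrices over M (TF promoter) + E (gene
    expression) latent nodes, with planted partial-correlation structure.

    Nodes are named ``M:<tf_id>`` then ``E:<gene_id>``. Planting targets the
    partial correlation ``rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)``:

    * a TF silenced in subtype ``s`` gets rho(M_i, E_i) = -silencing_magnitude
      there and 0 elsewhere;
    * flip edges get +magnitude in one named subtype and -magnitude in the
      other;
    * optional background (M_i, E_j) edges, shared across subtypes with
      positive sign, provide the consistent strong edges among which a flip
      cluster must be discovered.

    Positive definiteness is enforced by uniformly scaling the off-diagonal
    part so the smallest eigenvalue stays above a floor; if the repair would
    effectively erase a planted edge a :class:`GenerationError` is raised
    rather than silently clamping.
    """
    silencing_spec = silencing_spec or {}
    if n_subtypes < 1:
        raise ValueError("n_subtypes must be positive")
    if not 0 < silencing_magnitude < 1:
        raise ValueError("silencing_magnitude must lie in (0, 1)")
    subtypes = [f"S{k + 1}" for k in range(n_subtypes)]
    for s in silencing_spec:
        if s not in subtypes:
            raise ValueError(f"unknown subtype in silencing_spec: {s!r}")
    if flip_spec is not None:
        if not 0 < flip_spec.magnitude < 1:
            raise ValueError("flip magnitude must lie in (0, 1)")
        for s in (flip_spec.positive_subtype, flip_spec.negative_subtype):
            if s not in subtypes:
                raise ValueError(f"unknown subtype in flip_spec: {s!r}")

    tf_ids, gene_ids = _node_names(annotation)
    tf_set = set(tf_ids)
    for s, tfs in silencing_spec.items():
        missing = set(tfs) - tf_set
        if missing:
            raise ValueError(f"silencing_spec names unknown TFs: {sorted(missing)}")
    nodes = [f"M:{t}" for t in tf_ids] + [f"E:{g}" for g in gene_ids]
    idx = {name: i for i, name in enumerate(nodes)}
    p = len(nodes)

    rng = np.random.default_rng(int(seed))
    planted: set[tuple[int, int]] = set()

    def _pair(mi: str, ej: str) -> tuple[int, int]:
        if f"M:{mi}" not in idx:
            raise ValueError(f"unknown methylation node {mi!r}")
        if f"E:{ej}" not in idx:
            raise ValueError(f"unknown expression node {ej!r}")
        return idx[f"M:{mi}"], idx[f"E:{ej}"]

    # shared (subtype-independent) background structure
    S_shared = np.zeros((p, p))
    flip_pairs: list[tuple[int, int]] = []
    if flip_spec is not None:
        for mi, ej in flip_spec.edges:
            i, j = _pair(mi, ej)
            if mi == ej:
                raise ValueError("flip edges must connect distinct TFs")
            flip_pairs.append((i, j))
            planted.add((i, j))
    sil_pairs: dict[str, list[tuple[int, int]]] = {}
    for s, tfs in silencing_spec.items():
        pairs = []
        for t in sorted(tfs):
            i, j = _pair(t, t)
            pairs.append((i, j))
            planted.add((i, j))
        sil_pairs[s] = pairs
    if background_density > 0:
        m_nodes = np.arange(len(tf_ids))
        e_nodes = len(tf_ids) + np.arange(len(gene_ids))
        for i in m_nodes:
            for j in e_nodes:
                if (i, j) in planted or tf_ids[i] == gene_ids[j - len(tf_ids)]:
                    continue
                if rng.random() < background_density:
                    r = rng.uniform(*background_magnitude)
                    S_shared[i, j] = S_shared[j, i] = -r  # rho = +r

    omegas: dict[str, np.ndarray] = {}
    for s in subtypes:
        S = S_shared.copy()
        for i, j in sil_pairs.get(s, []):
            S[i, j] = S[j, i] = +silencing_magnitude  # rho = -magnitude
        if flip_spec is not None:
            sgn = 0.0
            if s == flip_spec.positive_subtype:
                sgn = -flip_spec.magnitude  # rho = +magnitude
            elif s == flip_spec.negative_subtype:
                sgn = +flip_spec.magnitude  # rho = -magnitude
            for i, j in flip_pairs:
                S[i, j] = S[j, i] = sgn
        omegas[s] = np.eye(p) + S

    # PD repair: one uniform off-diagonal scale across subtypes
    alpha = 1.0
    for s in subtypes:
        lam_min = float(np.linalg.eigvalsh(omegas[s])[0])
        if lam_min < _EIG_FLOOR:
            alpha = min(alpha, (1.0 - _EIG_FLOOR) / (1.0 - lam_min))
    if alpha < 1.0:
        if alpha * max(
            silencing_magnitude,
            flip_spec.magnitude if flip_spec is not None else 0.0,
        ) < _EIG_FLOOR:
            raise GenerationError(
                "positive-definiteness repair would erase planted edges; "
                "reduce background density or planted magnitudes"
            )
        for s in subtypes:
            omega = omegas[s]
            off = omega - np.diag(np.diag(omega))
            omegas[s] = np.diag(np.diag(omega)) + alpha * off

    truth = SyntheticTruth(
        silenced_tfs_by_subtype={s: set(tfs) for s, tfs in silencing_spec.items()},
        flip_cluster_edges=(
            {(f"M:{mi}", f"E:{ej}") for mi, ej in flip_spec.edges}
            if flip_spec is not None
            else set()
        ),
    )
    out: dict[str, pd.DataFrame] = {}
    for s in subtypes:
        omega = omegas[s]
        lam_min = float(np.linalg.eigvalsh(omega)[0])
        if lam_min <= 0:
            raise GenerationError("precision matrix not positive definite")
        d = np.sqrt(np.diag(omega))
        rho = -omega / np.outer(d, d)
        np.fill_diagonal(rho, 1.0)
        truth.true_partial_correlations[s] = pd.DataFrame(rho, index=nodes, columns=nodes)
        out[s] = pd.DataFrame(omega, index=nodes, columns=nodes)
    return out, truth


# --------------------------------------------------------------------------
# cohort simulation


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(
    precisions: dict[str, pd.DataFrame],
    annotation: tuple[pd.DataFrame, pd.DataFrame],
    n_samples_per_subtype: int,
    depth_range: tuple[float, float] = (30.0, 80.0),
    duplicate_fraction: float = 0.0,
    missing_rate: float = 0.01,
    purity_range: tuple[float, float] = (0.55, 0.95),
    seed: int = 0,
    include_cnv: bool = True,
    mu_m: float = -1.0,
    sigma_m: float = 1.2,
    mu_e: float = 3.0,
    sigma_e: float = 0.7,
    cnv_coupling: float = 0.5,
    window_bp: int = 200,
    return_latent: bool = False,
) -> dict[str, OmicsBundle] | tuple[dict[str, OmicsBundle], dict[str, pd.DataFrame]]:
    """Simulate one :class:`OmicsBundle` per subtype from latent Gaussians.

    Per subject a latent vector ``Z ~ N(0, Omega^{-1})`` is drawn over the
    M + E nodes of the subtype's precision matrix. Observed layers are linked
    to it marginally:

    * promoter probes: ``beta = invlogit(mu_m + sigma_m * Z_M + probe offset
      + noise)``; probes outside the promoter window carry independent
      baselines;
    * expression: ``counts ~ Poisson(depth_s * softplus(mu_e + sigma_e *
      Z_E))`` with a per-sample depth drawn from ``depth_range``;
    * CNV: a per-gene latent correlated with the expression latent
      (``cnv_coupling``) plus a segment-level Gaussian shared by genes within
      1 Mb on the same chromosome.

    ``duplicate_fraction`` of subjects get a second vial (same latent, fresh
    depth and noise, extra methylation missingness); methylation entries are
    masked at ``missing_rate``.

    With ``return_latent=True`` the per-subtype latent node x subject matrix
    is returned alongside the bundles (for recovery checks against the
    planted partial correlations).
    """
    if n_samples_per_subtype < 4:
        raise ValueError("n_samples_per_subtype must be >= 4")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if not 0.0 <= duplicate_fraction <= 1.0:
        raise ValueError("duplicate_fraction must lie in [0, 1]")

    genes, probes = annotation
    tf_ids, gene_ids = _node_names(genes)
    from .prep_meth import map_probes_to_promoters

    mapping = map_probes_to_promoters(probes, genes, window_bp=window_bp)
    promoter_probe_gene: dict[str, str] = {}
    for g, probe_set in mapping.items():
        for pr in probe_set:
            promoter_probe_gene[pr] = g

    out: dict[str, OmicsBundle] = {}
    latents: dict[str, pd.DataFrame] = {}
    for k_sub, (s, omega_df) in enumerate(sorted(precisions.items())):
        nodes = list(omega_df.index)
        expected = [f"M:{t}" for t in tf_ids] + [f"E:{g}" for g in gene_ids]
        if nodes != expected:
            raise ValueError("precision nodes do not match the annotation")
        omega = omega_df.to_numpy()
        sigma = np.linalg.inv(omega)
        # enforce exact symmetry before factorization
        sigma = (sigma + sigma.T) / 2.0
        chol = np.linalg.cholesky(sigma)

        (rng_z, rng_depth, rng_probe, rng_noise, rng_counts, rng_cnv,
         rng_dup, rng_miss, rng_purity) = spawn_rngs(int(seed) + 7919 * k_sub, 9)

        n = int(n_samples_per_subtype)
        z = rng_z.standard_normal((n, len(nodes))) @ chol.T  # subjects x nodes
        z_m = z[:, : len(tf_ids)]
        z_e = z[:, len(tf_ids):]

        subjects = [f"{s}-SUBJ{i:04d}" for i in range(n)]
        n_dup = int(round(duplicate_fraction * n))
        dup_subjects = set(
            rng_dup.choice(n, size=n_dup, replace=False).tolist()
        ) if n_dup else set()

        # fixed probe-level parameters
        probe_ids = list(probes.index)
        probe_offset = rng_probe.normal(0.0, 0.4, size=len(probe_ids))
        probe_baseline = rng_probe.normal(mu_m, 1.0, size=len(probe_ids))
        tf_pos = {t: i for i, t in enumerate(tf_ids)}

        def draw_beta(rng: np.random.Generator, cols: list[int]) -> np.ndarray:
            """Probe x subject beta for the given subject indices."""
            mat = np.empty((len(probe_ids), len(cols)))
            for r, pid in enumerate(probe_ids):
                g = promoter_probe_gene.get(pid)
                if g is not None and g in tf_pos:
                    logit = mu_m + sigma_m * z_m[cols, tf_pos[g]] + probe_offset[r]
                else:
                    logit = np.full(len(cols), probe_baseline[r])
                mat[r] = _invlogit(logit + rng.normal(0.0, 0.3, size=len(cols)))
            return mat

        def draw_counts(rng: np.random.Generator, depths: np.ndarray) -> np.ndarray:
            rate = _softplus(mu_e + sigma_e * z_e.T)  # genes x subjects
            return rng.poisson(rate * depths[None, :]).astype(np.int64)

        sample_ids: list[str] = []
        sample_subject: list[int] = []
        vial_no: list[int] = []
        for i in range(n):
            sample_ids.append(f"{subjects[i]}-V1")
            sample_subject.append(i)
            vial_no.append(1)
        for i in sorted(dup_subjects):
            sample_ids.append(f"{subjects[i]}-V2")
            sample_subject.append(i)
            vial_no.append(2)

        depths = rng_depth.uniform(*depth_range, size=len(sample_ids))
        counts_full = np.empty((len(gene_ids), len(sample_ids)), dtype=np.int64)
        rate = _softplus(mu_e + sigma_e * z_e.T)
        for c, subj in enumerate(sample_subject):
            counts_full[:, c] = rng_counts.poisson(rate[:, subj] * depths[c])

        beta_full = np.empty((len(probe_ids), len(sample_ids)))
        base = draw_beta(rng_noise, sample_subject)
        beta_full[:] = base
        # missingness: baseline everywhere, extra on second vials
        miss = rng_miss.random(beta_full.shape) < missing_rate
        for c, v in enumerate(vial_no):
            if v > 1:
                miss[:, c] |= rng_miss.random(len(probe_ids)) < 0.10
        beta_full[miss] = np.nan

        expr = pd.DataFrame(counts_full, index=gene_ids, columns=sample_ids)
        meth = pd.DataFrame(beta_full, index=probe_ids, columns=sample_ids)
        purity = pd.Series(
            rng_purity.uniform(*purity_range, size=len(sample_ids)),
            index=sample_ids,
            name="purity",
        )

        cnv = None
        if include_cnv:
            # segment blocks: same chromosome, TSS within 1 Mb of block start
            seg_of_gene = np.empty(len(gene_ids), dtype=int)
            seg_id = -1
            block_start: dict[str, int] = {}
            order = genes.sort_values(["chrom", "tss"]).index
            seg_map: dict[str, int] = {}
            for gid in order:
                chrom, tss = genes.at[gid, "chrom"], int(genes.at[gid, "tss"])
                if chrom not in block_start or tss - block_start[chrom] > 1_000_000:
                    seg_id += 1
                    block_start[chrom] = tss
                seg_map[gid] = seg_id
            for gi, gid in enumerate(gene_ids):
                seg_of_gene[gi] = seg_map[gid]
            n_seg = seg_id + 1
            seg_noise = rng_cnv.normal(0.0, 0.5, size=(n_seg, n))
            z_c = cnv_coupling * z_e + np.sqrt(1 - cnv_coupling**2) * (
                rng_cnv.standard_normal(z_e.shape)
            )
            cnv_mat = np.empty((len(gene_ids), len(sample_ids)))
            for c, subj in enumerate(sample_subject):
                cnv_mat[:, c] = (
                    z_c[subj, :]
                    + seg_noise[seg_of_gene, subj]
                    + rng_cnv.normal(0.0, 0.1, size=len(gene_ids))
                )
            cnv = pd.DataFrame(cnv_mat, index=gene_ids, columns=sample_ids)

        out[s] = OmicsBundle(
            expression_counts=expr,
            methylation_beta=meth,
            purity=purity,
            cnv=cnv,
            subtype=s,
        )
        latents[s] = pd.DataFrame(z.T, index=nodes, columns=subjects)
    if return_latent:
        return out, latents
    return out


# --------------------------------------------------------------------------
# bipartite network pairs


def generate_bipartite_pair(
    n_tf: int,
    n_genes: int,
    n_modules: int,
    planted_module: int,
    delta: float,
    noise_sd: float,
    seed: int = 0,
) -> tuple[BipartiteNetwork, BipartiteNetwork, ModulePartition, SyntheticTruth]:
    """Generate two weighted TF x gene networks differing by ``+delta`` on
    the in-module edges of ``planted_module``, plus the module partition.

    ``A = baseline + noise`` and ``B = A's baseline + delta * in-module mask
    + independent noise``; the partition assigns every TF and gene to exactly
    one of ``n_modules`` modules (all nonempty).
    """
    if n_modules < 1 or n_modules > min(n_tf, n_genes):
        raise ValueError("need 1 <= n_modules <= min(n_tf, n_genes)")
    if not 0 <= planted_module < n_modules:
        raise ValueError("planted_module must be a valid module id")
    if delta < 0:
        raise ValueError("delta must be nonnegative")

    rng_base, rng_part, rng_na, rng_nb = spawn_rngs(int(seed), 4)
    tf_ids = [f"TF{i:03d}" for i in range(n_tf)]
    gene_ids = [f"G{j:04d}" for j in range(n_genes)]
    baseline = rng_base.standard_normal((n_tf, n_genes))

    tf_mod = np.array([i % n_modules for i in range(n_tf)])
    gene_mod = np.array([j % n_modules for j in range(n_genes)])
    rng_part.shuffle(tf_mod)
    rng_part.shuffle(gene_mod)
    # round-robin assignment guarantees nonempty modules before shuffling
    partition = ModulePartition(
        assignments={
            **{t: int(m) for t, m in zip(tf_ids, tf_mod)},
            **{g: int(m) for g, m in zip(gene_ids, gene_mod)},
        },
        n_modules=n_modules,
    )

    mask = (tf_mod[:, None] == planted_module) & (gene_mod[None, :] == planted_module)
    a = baseline + (rng_na.standard_normal(baseline.shape) * noise_sd if noise_sd else 0.0)
    b = (
        baseline
        + delta * mask
        + (rng_nb.standard_normal(baseline.shape) * noise_sd if noise_sd else 0.0)
    )
    net_a = BipartiteNetwork(
        weights=pd.DataFrame(a, index=tf_ids, columns=gene_ids), condition="A"
    )
    net_b = BipartiteNetwork(
        weights=pd.DataFrame(b, index=tf_ids, columns=gene_ids), condition="B"
    )
    truth = SyntheticTruth(planted_module=(planted_module, float(delta)))
    return net_a, net_b, partition, truth


# --------------------------------------------------------------------------
# gene sets


def generate_gene_sets(
    universe: list[str],
    query: list[str],
    n_sets: int = 20,
    set_size: int = 50,
    enriched_overlap_frac: float = 0.6,
    seed: int = 0,
):
    """Generate a gene-set collection with exactly one set enriched in
    ``query``: the planted set draws ``enriched_overlap_frac`` of its members
    from the query and the rest uniformly; all other sets are uniform draws
    from the universe.

    Returns ``(GeneSetCollection, SyntheticTruth)``.
    """
    from .enrich import GeneSetCollection

    if not query or not set(query) <= set(universe):
        raise ValueError("query must be a nonempty subset of the universe")
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe size")
    rng = np.random.default_rng(int(seed))
    universe = list(universe)
    query = list(query)
    non_query = sorted(set(universe) - set(query))

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    k_enriched = min(int(round(enriched_overlap_frac * set_size)), len(query))
    enr_members = {str(g) for g in rng.choice(query, size=k_enriched, replace=False)}
    filler = {
        str(g)
        for g in rng.choice(non_query, size=set_size - k_enriched, replace=False)
    }
    enriched_id = "SET000"
    sets[enriched_id] = ("planted enriched set", frozenset(enr_members | filler))
    for i in range(1, n_sets):
        members = rng.choice(universe, size=set_size, replace=False)
        sets[f"SET{i:03d}"] = (f"background set {i}", frozenset(str(g) for g in members))

    truth = SyntheticTruth(enriched_set=enriched_id)
    return GeneSetCollection(sets=sets), truth
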