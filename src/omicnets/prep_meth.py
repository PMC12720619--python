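"""Methylation preprocessing: probe-to-promoter aggregation, duplicate
policies, missingness filtering with mean imputation, beta <-> M-value
conversion, and a rank-based nonparanormal transform.

The promoter of a gene is the ``window_bp`` region upstream of its TSS,
strand aware, with 0-based half-open coordinates: on the + strand a probe at
position ``pos`` belongs to the promoter iff ``tss - window_bp <= pos < tss``;
on the - strand iff ``tss < pos <= tss + window_bp``.

The enforced stage order is: aggregate -> duplicates -> filter/impute ->
convert -> nonparanormal. Converting with missing entries present raises an
error instructing to impute first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._util import subject_of

__all__ = [
    "MethylationMatrix",
    "MValueMatrix",
    "map_probes_to_promoters",
    "aggregate_promoter_beta",
    "resolve_duplicates_methylation",
    "filter_and_impute_missing",
    "convert_beta_m",
    "nonparanormal_transform",
]

log = logging.getLogger(__name__)


@dataclass
class MethylationMatrix:
    """Features x samples beta-value matrix in [0, 1]; NaN marks missing.

    ``kind`` is ``"probe"`` (CpG-level) or ``"gene_promoter"`` (aggregated).
    """

    values: pd.DataFrame
    kind: str = "probe"

    def __post_init__(self) -> None:
        if self.kind not in {"probe", "gene_promoter"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MValueMatrix:
    """Features x samples M-value (logit2 beta) matrix; entries are finite."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("M-value matrix must be finite (impute and clamp first)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def map_probes_to_promoters(
    probes: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 200,
    gene_subset: set[str] | None = None,
) -> dict[str, set[str]]:
    """Map CpG probes to the genes whose promoter window they fall in.

    ``probes``: index probe_id, columns chrom, pos (0-based).
    ``genes``: index gene_id, columns chrom, tss (0-based), strand.
    When ``gene_subset`` is given (e.g. TF genes only), other genes are
    skipped. Returns gene_id -> set of probe_ids, genes with no mapped probe
    omitted.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    bad = set(genes["strand"].unique()) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strand symbol(s): {sorted(bad)}")
    by_chrom = {c: sub for c, sub in probes.groupby("chrom")}
    mapping: dict[str, set[str]] = {}
    for gid, row in genes.iterrows():
        if gene_subset is not None and gid not in gene_subset:
            continue
        sub = by_chrom.get(row["chrom"])
        if sub is None:
            continue
        tss = int(row["tss"])
        pos = sub["pos"]
        if row["strand"] == "+":
            hit = (pos >= tss - window_bp) & (pos < tss)
        else:
            hit = (pos > tss) & (pos <= tss + window_bp)
        ids = set(sub.index[hit])
        if ids:
            mapping[gid] = ids
    return mapping


def aggregate_promoter_beta(
    mat: MethylationMatrix, mapping: dict[str, set[str]]
) -> tuple[MethylationMatrix, list[str]]:
    """Average promoter methylation per gene: for each gene and sample, the
    mean beta over the gene's mapped probes, ignoring missing probes. If all
    mapped probes are missing the gene's value is missing for that sample.
    Genes whose mapped probes are absent from the matrix are omitted and
    reported."""
    if mat.kind != "probe":
        raise ValueError("aggregate_promoter_beta expects probe-level input")
    if not mapping:
        raise ValueError("empty probe-to-gene mapping")
    rows = {}
    skipped: list[str] = []
    for gid in sorted(mapping):
        probe_ids = [p for p in mapping[gid] if p in mat.values.index]
        if not probe_ids:
            skipped.append(gid)
            continue
        rows[gid] = mat.values.loc[probe_ids].mean(axis=0, skipna=True)
    if skipped:
        log.info("omitted %d genes with no probes in the matrix", len(skipped))
    agg = pd.DataFrame(rows).T
    agg.index.name = "gene_id"
    return MethylationMatrix(values=agg, kind="gene_promoter"), skipped


def resolve_duplicates_methylation(
    mat: MethylationMatrix, policy: str = "least_missing", seed: int = 0
) -> MethylationMatrix:
    """Resolve subjects with multiple vials.

    ``least_missing`` keeps the vial with the fewest missing entries (ties:
    first in column order); ``random`` keeps a seeded uniform choice;
    ``exclude`` drops every vial of duplicated subjects."""
    if policy not in {"least_missing", "random", "exclude"}:
        raise ValueError(f"unknown duplicate policy {policy!r}")
    cols = list(mat.values.columns)
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for sid in cols:
        subj = subject_of(sid)
        if subj not in groups:
            groups[subj] = []
            order.append(subj)
        groups[subj].append(sid)
    rng = np.random.default_rng(int(seed))
    keep: list[str] = []
    for subj in order:
        vials = groups[subj]
        if len(vials) == 1:
            keep.append(vials[0])
        elif policy == "exclude":
            continue
        elif policy == "random":
            keep.append(vials[int(rng.integers(len(vials)))])
        else:
            n_missing = mat.values[vials].isna().sum(axis=0)
            keep.append(n_missing.idxmin())
    return replace(mat, values=mat.values[keep])


def filter_and_impute_missing(
    mat: MethylationMatrix, m_fraction: float = 0.20
) -> MethylationMatrix:
    """Remove features missing in more than ``m_fraction`` of samples; mean
    impute the survivors' remaining missing entries from their non-missing
    values. ``m_fraction=0`` removes any feature with at least one missing
    value (no imputation happens)."""
    if mat.kind != "gene_promoter":
        raise ValueError("filter_and_impute_missing expects aggregated promoter values")
    if not 0.0 <= m_fraction < 1.0:
        raise ValueError("m_fraction must lie in [0, 1)")
    frac = mat.values.isna().mean(axis=1)
    kept = mat.values.loc[frac <= m_fraction].copy()
    means = kept.mean(axis=1, skipna=True)
    imputed = kept.T.fillna(means).T
    return replace(mat, values=imputed)


def convert_beta_m(
    mat: MethylationMatrix | MValueMatrix,
    direction: str = "beta_to_m",
    epsilon: float = 1e-6,
) -> MValueMatrix | MethylationMatrix:
    """Convert between beta- and M-values: ``M = log2(beta / (1 - beta))``
    and ``beta = 2**M / (1 + 2**M)``.

    Beta values are clamped to ``[epsilon, 1 - epsilon]`` first, since the
    logit is infinite at 0 and 1."""
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    if direction == "beta_to_m":
        if not isinstance(mat, MethylationMatrix):
            raise TypeError("beta_to_m expects a MethylationMatrix")
        if mat.values.isna().any().any():
            raise ValueError(
                "beta matrix has missing entries; run filter_and_impute_missing first"
            )
        beta = mat.values.clip(lower=epsilon, upper=1 - epsilon)
        m = np.log2(beta / (1 - beta))
        return MValueMatrix(values=m)
    if direction == "m_to_beta":
        if not isinstance(mat, MValueMatrix):
            raise TypeError("m_to_beta expects an MValueMatrix")
        pow2 = np.exp2(mat.values)
        beta = pow2 / (1 + pow2)
        return MethylationMatrix(values=beta, kind="gene_promoter")
    raise ValueError(f"unknown direction {direction!r}")


def nonparanormal_transform(mat: MValueMatrix) -> MValueMatrix:
    """Rank-based Gaussianization per feature: average ranks ``r`` over the
    ``n`` samples are mapped through ``z = Phi^{-1}(r / (n + 1))`` and the
    result rescaled to unit sample standard deviation. Strictly rank
    preserving; constant features become zero vectors (with a warning)."""
    n = mat.values.shape[1]
    if n < 3:
        raise ValueError("nonparanormal transform needs at least 3 samples")
    out = np.empty(mat.values.shape)
    vals = mat.values.to_numpy(dtype=float)
    for i in range(vals.shape[0]):
        row = vals[i]
        if np.allclose(row, row[0]):
            log.warning(
                "constant feature %s: nonparanormal output set to zeros",
                mat.values.index[i],
            )
            out[i] = 0.0
            continue
        ranks = stats.rankdata(row, method="average")
        z = stats.norm.ppf(ranks / (n + 1))
        out[i] = z / np.std(z, ddof=1)
    return MValueMatrix(
        values=pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns)
    )
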