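"""Expression preprocessing: duplicate resolution, normalization (TPM or
CPM with TMM library-size scaling), low-expression and purity filtering, and
log transformation.

Matrices are genes x samples. Sample ids encode subject and vial as
``SUBJ<k>-V<j>``; duplicate resolution keeps, per subject, the vial with the
greatest sequencing depth (total count sum).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._util import subject_of

__all__ = [
    "ExpressionMatrix",
    "ExprFilterParams",
    "resolve_duplicates_expression",
    "normalize_expression",
    "filter_low_expression",
    "filter_purity",
    "log_transform",
    "tmm_factors",
]

log = logging.getLogger(__name__)

_UNITS = {"counts", "TPM", "CPM", "logTPM", "logCPM"}


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a units tag.

    ``gene_lengths`` (bp) is required only for TPM normalization.
    """

    values: pd.DataFrame
    units: str = "counts"
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.units not in _UNITS:
            raise ValueError(f"unknown units tag {self.units!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix must not contain missing entries")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ExprFilterParams:
    """Thresholds for the expression filters.

    ``n_min_counts`` / ``p_fraction``: a gene is dropped when fewer than
    ``n_min_counts`` counts are seen in at least ``p_fraction`` of samples.
    """

    n_min_counts: int = 10
    p_fraction: float = 0.9
    purity_min: float = 0.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fraction <= 1.0:
            raise ValueError("p_fraction must lie in [0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def _require_counts(mat: ExpressionMatrix, op: str) -> None:
    if mat.units != "counts":
        raise ValueError(f"{op} requires raw counts, got units={mat.units!r}")


def resolve_duplicates_expression(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Keep one sample per subject: the vial with the greatest sequencing
    depth (largest column sum). Ties keep the first vial in column order and
    are logged. Subject order of the retained columns is preserved."""
    _require_counts(mat, "resolve_duplicates_expression")
    depth = mat.values.sum(axis=0)
    keep: list[str] = []
    best: dict[str, str] = {}
    order: list[str] = []
    for sid in mat.values.columns:
        subj = subject_of(sid)
        if subj not in best:
            best[subj] = sid
            order.append(subj)
        else:
            if depth[sid] > depth[best[subj]]:
                best[subj] = sid
            elif depth[sid] == depth[best[subj]]:
                log.info(
                    "duplicate depth tie for subject %s: keeping %s", subj, best[subj]
                )
    keep = [best[subj] for subj in order]
    return replace(mat, values=mat.values[keep])


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, rescaled to geometric mean 1.

    The reference is the sample whose 75th percentile of library-size-scaled
    counts is closest to the mean 75th percentile. Per sample, M (log2 count
    ratio vs reference) and A (mean log2 abundance) are computed over genes
    nonzero in both; the top and bottom ``trim_m`` of M and ``trim_a`` of A
    are trimmed, and the factor is 2**(weighted mean of M) with
    inverse-binomial-variance weights.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size in TMM computation")
    frac = x / lib
    q75 = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.ones(x.shape[1])
    for s in range(x.shape[1]):
        if s == ref:
            continue
        ok = (x[:, s] > 0) & (x[:, ref] > 0)
        if ok.sum() < 2:
            continue
        fs, fr = frac[ok, s], frac[ok, ref]
        m = np.log2(fs / fr)
        a = 0.5 * np.log2(fs * fr)
        if np.allclose(m, m[0]):
            factors[s] = 2.0 ** m[0]
            continue
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            continue
        ns, nr = lib[s], lib[ref]
        cs, cr = x[ok, s], x[ok, ref]
        w = (ns - cs) / (ns * cs) + (nr - cr) / (nr * cr)
        w = 1.0 / np.clip(w, 1e-12, None)
        factors[s] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize_expression(
    mat: ExpressionMatrix,
    method: str = "TPM",
    params: ExprFilterParams | None = None,
) -> ExpressionMatrix:
    """Normalize raw counts to TPM or to CPM on TMM-scaled library sizes.

    TPM: ``(c_gs / L_g) / sum_j (c_js / L_j) * 1e6`` (columns sum to 1e6).
    CPM_TMM: ``c_gs / (libsize_s * f_s) * 1e6`` with TMM factors ``f``
    normalized to geometric mean 1.
    """
    _require_counts(mat, "normalize_expression")
    lib = mat.values.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"zero library size for samples {bad}")
    if method == "TPM":
        if mat.gene_lengths is None or mat.gene_lengths.isna().any():
            raise ValueError("TPM normalization requires gene lengths for all genes")
        if (mat.gene_lengths <= 0).any():
            bad = list(mat.gene_lengths.index[mat.gene_lengths <= 0])
            raise ValueError(f"nonpositive gene length for {bad}")
        rate = mat.values.div(mat.gene_lengths, axis=0)
        tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
        return replace(mat, values=tpm, units="TPM")
    if method == "CPM_TMM":
        f = tmm_factors(mat.values)
        cpm = mat.values.div(lib * f, axis=1) * 1e6
        return replace(mat, values=cpm, units="CPM")
    raise ValueError(f"unknown normalization method {method!r}")


def filter_low_expression(
    mat: ExpressionMatrix, params: ExprFilterParams
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes with low expression: a gene is removed iff the number of
    samples with ``count < n_min_counts`` is at least ``ceil(p_fraction * S)``.
    Returns the filtered matrix and the removed-gene list."""
    _require_counts(mat, "filter_low_expression")
    n_samples = mat.values.shape[1]
    threshold = math.ceil(params.p_fraction * n_samples)
    low = (mat.values < params.n_min_counts).sum(axis=1)
    removed = list(mat.values.index[low >= threshold])
    kept = mat.values.drop(index=removed)
    lengths = (
        mat.gene_lengths.drop(index=removed) if mat.gene_lengths is not None else None
    )
    return replace(mat, values=kept, gene_lengths=lengths), removed


def filter_purity(
    mat: ExpressionMatrix,
    purity: pd.Series,
    purity_min: float,
    drop_missing: bool = False,
) -> ExpressionMatrix:
    """Drop samples whose tumor purity falls below ``purity_min``.

    Samples with no purity annotation are retained with a warning by default
    (``drop_missing=True`` drops them instead)."""
    purity = purity.reindex(mat.values.columns)
    missing = list(purity.index[purity.isna()])
    if missing:
        log.warning("no purity annotation for %d samples: %s", len(missing), missing)
    if drop_missing:
        keep = purity >= purity_min
    else:
        keep = purity.isna() | (purity >= purity_min)
    lengths = mat.gene_lengths
    return replace(mat, values=mat.values.loc[:, keep[keep].index], gene_lengths=lengths)


def log_transform(mat: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """``value -> log2(value + pseudocount)``; the units tag gains a ``log``
    prefix. A pseudocount avoids undefined logs at zero."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if mat.units not in {"TPM", "CPM"}:
        raise ValueError(f"log_transform expects TPM or CPM, got {mat.units!r}")
    vals = np.log2(mat.values + pseudocount)
    return replace(mat, values=vals, units="log" + mat.units)
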