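"""Differential expression: single-cell signature extraction and bulk DEGs.

Single-cell mode follows the Seurat convention: depth-normalise each cell to a
fixed target sum, log1p, Wilcoxon rank-sum per gene (normal approximation with
tie correction), fold change on de-logged normalised means with a pseudocount,
Benjamini-Hochberg adjustment. Signature1/signature2 are the genes passing
|log2FC| > 0.25 and adjusted p < 0.05 (strict inequalities); bulk mode uses
|log2FC| > 1 at the same alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, EmptySignatureError, ParameterError

logger = logging.getLogger(__name__)

TARGET_SUM = 1e4
MIN_CELLS_PER_GROUP = 3


@dataclass
class DERecord:
    gene: str
    log2fc: float
    p: float
    p_adj: float
    mean_a: float
    mean_b: float


@dataclass
class SignaturePair:
    """Up- (signature1) and down-regulated (signature2) gene lists."""

    signature1: list[str]
    signature2: list[str]


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def normalize(adata: ad.AnnData, target_sum: float = TARGET_SUM) -> ad.AnnData:
    """Depth-normalise counts to ``target_sum`` per cell, then log1p.

    Returns a new AnnData; raises :class:`DegenerateInputError` listing any
    cells with zero total counts.
    """
    x = _dense(adata.X).astype(np.float64)
    totals = x.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = list(adata.obs_names[zero[:20]])
        raise DegenerateInputError(f"cells with zero total counts: {ids}")
    out = adata.copy()
    out.X = np.log1p(x / totals[:, None] * target_sum)
    out.uns["normalized"] = {"target_sum": target_sum, "log1p": True}
    return out


def _delog_means(norm_x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-gene mean of expm1(normalised values) over a cell mask."""
    return np.expm1(norm_x[mask]).mean(axis=0)


def rank_sum_de(
    values: np.ndarray,
    genes: list[str],
    group_labels: np.ndarray,
    case_label: str,
    pseudocount: float = 1.0,
    already_log: bool = True,
    method: str = "auto",
) -> list[DERecord]:
    """Per-gene two-sided Wilcoxon rank-sum DE of case (group a) vs rest.

    ``values`` is cells x genes; with ``already_log`` the fold change is
    computed on de-logged (expm1) values, otherwise on the values directly.
    Groups smaller than three cells trigger a warning and an exact-test
    fallback; ``method`` may force ``"exact"`` or ``"asymptotic"``.
    """
    values = np.asarray(values, dtype=np.float64)
    group_labels = np.asarray(group_labels)
    mask_a = group_labels == case_label
    mask_b = ~mask_a
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise DegenerateInputError("both groups must be non-empty")

    if method == "auto":
        if min(n_a, n_b) < MIN_CELLS_PER_GROUP:
            warnings.warn(
                f"group sizes {n_a}/{n_b} below {MIN_CELLS_PER_GROUP}; "
                "falling back to the exact rank-sum test",
                stacklevel=2,
            )
            method = "exact"
        else:
            method = "asymptotic"
    if method not in ("exact", "asymptotic"):
        raise ParameterError(f"unknown method {method!r}")

    a, b = values[mask_a], values[mask_b]
    constant = values.std(axis=0) == 0
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(
            a, b, axis=0, alternative="two-sided", method=method
        )
    p = np.asarray(res.pvalue, dtype=np.float64)
    p[constant] = 1.0
    p = np.clip(p, 0.0, 1.0)

    if already_log:
        mean_a = np.expm1(a).mean(axis=0)
        mean_b = np.expm1(b).mean(axis=0)
    else:
        mean_a = a.mean(axis=0)
        mean_b = b.mean(axis=0)
    # non-positive shifted means (possible for non-count input) yield NaN
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    log2fc[constant] = 0.0

    p_adj = bh_adjust(list(p))
    return [
        DERecord(
            gene=g,
            log2fc=float(log2fc[j]),
            p=float(p[j]),
            p_adj=float(p_adj[j]),
            mean_a=float(mean_a[j]),
            mean_b=float(mean_b[j]),
        )
        for j, g in enumerate(genes)
    ]


def sc_de(
    adata: ad.AnnData,
    condition_key: str = "condition",
    case_label: str = "MB",
    min_cells: int = MIN_CELLS_PER_GROUP,
) -> list[DERecord]:
    """Normalise and run case-vs-rest rank-sum DE on a count matrix.

    Genes expressed in fewer than ``min_cells`` cells in both groups are
    skipped (reported via logging), not tested.
    """
    norm = adata if adata.uns.get("normalized") else normalize(adata)
    x = _dense(norm.X)
    labels = np.asarray(norm.obs[condition_key])
    mask_a = labels == case_label
    expressed_a = (x[mask_a] > 0).sum(axis=0)
    expressed_b = (x[~mask_a] > 0).sum(axis=0)
    keep = (expressed_a >= min_cells) | (expressed_b >= min_cells)
    n_skip = int((~keep).sum())
    if n_skip:
        logger.info("skipping %d genes expressed in < %d cells per group", n_skip, min_cells)
    genes = [g for g, k in zip(norm.var_names, keep) if k]
    return rank_sum_de(x[:, keep], genes, labels, case_label)


def bh_adjust(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment; order-preserving monotone."""
    arr = np.asarray(p, dtype=np.float64)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ParameterError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def extract_signatures(
    records: list[DERecord],
    lfc_thresh: float = 0.25,
    alpha: float = 0.05,
) -> SignaturePair:
    """Threshold DE records into signature1 (up) / signature2 (down).

    Strict inequalities: log2FC must exceed the threshold and adjusted p must
    fall below alpha. Raises if either signature comes out empty, since the
    downstream consensus scoring is undefined without both directions.
    """
    sig1 = sorted(r.gene for r in records if r.log2fc > lfc_thresh and r.p_adj < alpha)
    sig2 = sorted(r.gene for r in records if r.log2fc < -lfc_thresh and r.p_adj < alpha)
    if not sig1 or not sig2:
        raise EmptySignatureError(
            f"empty signature (up={len(sig1)}, down={len(sig2)}) at "
            f"|log2FC|>{lfc_thresh}, adj p<{alpha}"
        )
    logger.info("signature1: %d genes, signature2: %d genes", len(sig1), len(sig2))
    return SignaturePair(signature1=sig1, signature2=sig2)


def bulk_de(
    expr: pd.DataFrame,
    labels: pd.Series,
    lfc_thresh: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> tuple[list[str], list[DERecord]]:
    """Bulk cohort DEGs: rank-sum test + |log2FC| > 1, adj. p < 0.05 filter.

    ``expr`` is samples x genes (linear scale); ``labels`` is binary with
    1 = case. Returns (selected genes sorted, all records).
    """
    y = np.asarray(labels).astype(int)
    records = rank_sum_de(
        expr.to_numpy(),
        list(expr.columns),
        y,
        case_label=1,
        pseudocount=pseudocount,
        already_log=False,
    )
    degs = sorted(
        r.gene for r in records if abs(r.log2fc) > lfc_thresh and r.p_adj < alpha
    )
    logger.info("bulk DE: %d/%d genes pass |log2FC|>%g, adj p<%g",
                len(degs), len(records), lfc_thresh, alpha)
    return degs, records
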