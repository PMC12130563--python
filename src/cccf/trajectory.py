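"""Deterministic pseudotime and correlation-based feature selection.

Pseudotime is the first principal axis of the normalised expression matrix,
oriented so the mean position of consensus-``high`` cells exceeds that of
``low`` cells, then min-max rescaled to [0, 1]. This gives a monotone,
identifiable low-risk -> high-risk axis without a learned dynamical model.
Genes are then screened by Pearson correlation with pseudotime (signed
r > 0.6, p < 0.05 by default) and intersected across the two single-cell
datasets and both bulk cohorts' DEG lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .consensus import LABEL_HIGH, LABEL_LOW, ConsensusResult
from .de import normalize
from .errors import DegenerateInputError, EmptyFeatureSetError, OrientationError

logger = logging.getLogger(__name__)


@dataclass
class GeneCorrelation:
    gene: str
    r: float  # NaN for constant genes (excluded from selection)
    p: float


def _dense_norm(adata: ad.AnnData) -> np.ndarray:
    norm = adata if adata.uns.get("normalized") else normalize(adata)
    x = norm.X
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=np.float64)


def pseudotime(adata: ad.AnnData, consensus: list[ConsensusResult]) -> pd.Series:
    """First principal axis oriented from low- to high-risk, scaled to [0,1]."""
    x = _dense_norm(adata)
    if x.shape[0] < 2:
        raise DegenerateInputError("pseudotime needs at least 2 cells")
    xc = x - x.mean(axis=0)
    # full SVD for a deterministic axis (no randomised solver)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    t = u[:, 0] * s[0]

    labels = {r.cell: r.label for r in consensus}
    order = list(adata.obs_names)
    high = [i for i, c in enumerate(order) if labels.get(c) == LABEL_HIGH]
    low = [i for i, c in enumerate(order) if labels.get(c) == LABEL_LOW]
    if not high or not low:
        raise OrientationError(
            f"orientation needs both labels (high={len(high)}, low={len(low)})"
        )
    if t[high].mean() < t[low].mean():
        t = -t
    t = (t - t.min()) / (t.max() - t.min())
    return pd.Series(t, index=order, name="pseudotime")


def correlate(adata: ad.AnnData, t: pd.Series) -> list[GeneCorrelation]:
    """Per-gene Pearson correlation with pseudotime, two-sided t-test p."""
    x = _dense_norm(adata)
    n = x.shape[0]
    if n < 3:
        raise DegenerateInputError("correlation needs at least 3 cells")
    tv = t.reindex(adata.obs_names).to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(tv)):
        raise DegenerateInputError("pseudotime contains non-finite values")

    xc = x - x.mean(axis=0)
    tc = tv - tv.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    st = np.sqrt((tc**2).sum())
    constant = (sx == 0) | (st == 0)
    denom = np.where(constant, 1.0, sx * st)
    r = (xc * tc[:, None]).sum(axis=0) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isnan(p), 0.0, p)  # |r| == 1

    out = []
    n_const = 0
    for j, g in enumerate(adata.var_names):
        if constant[j]:
            n_const += 1
            out.append(GeneCorrelation(gene=g, r=float("nan"), p=1.0))
        else:
            out.append(GeneCorrelation(gene=g, r=float(r[j]), p=float(p[j])))
    if n_const:
        logger.info("%d constant genes excluded from correlation selection", n_const)
    return out


def correlated_genes(
    corr: list[GeneCorrelation],
    r_thresh: float = 0.6,
    alpha: float = 0.05,
    absolute: bool = False,
) -> list[str]:
    """Genes passing the correlation screen (signed r by default)."""
    def passes(c: GeneCorrelation) -> bool:
        if np.isnan(c.r):
            return False
        stat = abs(c.r) if absolute else c.r
        return stat > r_thresh and c.p < alpha

    return sorted(c.gene for c in corr if passes(c))


def select_features(
    corr_human: list[GeneCorrelation],
    corr_mouse: list[GeneCorrelation],
    degs_cohort1: list[str],
    degs_cohort2: list[str],
    r_thresh: float = 0.6,
    alpha: float = 0.05,
    absolute: bool = False,
) -> list[str]:
    """Intersect pseudotime-correlated genes (both single-cell datasets)
    with both bulk cohorts' DEGs; alphabetical output order."""
    sets = [
        set(correlated_genes(corr_human, r_thresh, alpha, absolute)),
        set(correlated_genes(corr_mouse, r_thresh, alpha, absolute)),
        set(degs_cohort1),
        set(degs_cohort2),
    ]
    selected = sorted(set.intersection(*sets))
    if not selected:
        raise EmptyFeatureSetError(
            "feature intersection is empty (correlated human/mouse genes x "
            "cohort DEGs)"
        )
    logger.info(
        "select_features: %d genes from intersection of %s",
        len(selected), [len(s) for s in sets],
    )
    return selected
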