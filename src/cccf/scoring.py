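"""Per-cell gene-set scoring registry.

The consensus framework needs many independent per-cell scores of the same
signature. The registry provides eight core single-sample scoring statistics
spanning the main families used for this task (mean z-score, rank-recovery
AUC, within-cell rank-sum, centred mean rank, weighted running-sum
enrichment, singular-vector projection, expression-bin-matched control
differences, and a dropout-adjusted rank), plus documented parameter
variants to reach any requested registry size up to ``MAX_SCORERS``. Every
scorer is oriented so that higher signature expression gives a higher score;
the downstream consensus is agnostic to scorer identity.

Scores are computed on depth-normalised log1p expression. Rank scorers break
within-cell ties by average rank; the running-sum scorer orders tied genes
stably by gene index.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata

from .de import SignaturePair, normalize
from .errors import EmptySignatureError, ParameterError

logger = logging.getLogger(__name__)

MAX_SCORERS = 20


@dataclass(frozen=True)
class Scorer:
    name: str
    kind: str
    params: dict = field(default_factory=dict)
    direction_sensitive: bool = True

    def __hash__(self) -> int:  # params dict is small and static
        return hash((self.name, self.kind))


@dataclass
class ScoreTensor:
    """cells x scorers x 2 (axis 2: signature1, signature2) score array."""

    cells: list[str]
    scorers: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cells), len(self.scorers), 2):
            raise ParameterError(
                f"score tensor shape {self.values.shape} does not match "
                f"{len(self.cells)} cells x {len(self.scorers)} scorers x 2"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("score tensor contains non-finite values")


class _MatrixContext:
    """Per-matrix precomputations shared by all scorers."""

    def __init__(self, x: np.ndarray):
        self.x = x
        self.n_cells, self.n_genes = x.shape
        self._asc_ranks: np.ndarray | None = None
        self._gene_mean: np.ndarray | None = None
        self._gene_std: np.ndarray | None = None

    @property
    def asc_ranks(self) -> np.ndarray:
        """Within-cell ascending average ranks (1 = lowest expression)."""
        if self._asc_ranks is None:
            self._asc_ranks = rankdata(self.x, axis=1)
        return self._asc_ranks

    @property
    def gene_mean(self) -> np.ndarray:
        if self._gene_mean is None:
            self._gene_mean = self.x.mean(axis=0)
        return self._gene_mean

    @property
    def gene_std(self) -> np.ndarray:
        if self._gene_std is None:
            self._gene_std = self.x.std(axis=0)
        return self._gene_std


def _score_mean_z(ctx: _MatrixContext, sig: np.ndarray, winsor: float = 0.0) -> np.ndarray:
    x = ctx.x[:, sig]
    if winsor > 0:
        lo = np.quantile(x, winsor, axis=0)
        hi = np.quantile(x, 1 - winsor, axis=0)
        x = np.clip(x, lo, hi)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return ((x - mu) / sd).mean(axis=1)


def _score_rank_auc(ctx: _MatrixContext, sig: np.ndarray, top_frac: float) -> np.ndarray:
    """Area under the signature-recovery curve within the top fraction of the
    per-cell expression ranking, normalised so a cell whose signature genes
    occupy the top |S| ranks scores 1."""
    n, s = ctx.n_genes, sig.size
    t = max(int(np.ceil(top_frac * n)), 1)
    desc = n + 1 - ctx.asc_ranks[:, sig]  # 1 = highest expression
    contrib = np.clip(t - desc + 1.0, 0.0, None)
    raw = contrib.sum(axis=1)
    m = min(s, t)
    max_raw = m * t - m * (m - 1) / 2.0
    return raw / max_raw


def _score_rank_sum(ctx: _MatrixContext, sig: np.ndarray) -> np.ndarray:
    """Normalised Mann-Whitney U of signature genes vs the rest within each
    cell; 1 when the signature genes are the most highly expressed."""
    n, s = ctx.n_genes, sig.size
    if s == n:
        return np.full(ctx.n_cells, 0.5)
    r = ctx.asc_ranks[:, sig].sum(axis=1)
    u = r - s * (s + 1) / 2.0
    return u / (s * (n - s))


def _score_mean_rank(ctx: _MatrixContext, sig: np.ndarray, centered: bool = True) -> np.ndarray:
    n = ctx.n_genes
    mean_rank = ctx.asc_ranks[:, sig].mean(axis=1)
    if not centered:
        return mean_rank / n
    return (mean_rank - (n + 1) / 2.0) / ((n - 1) / 2.0)


def _score_running_sum(ctx: _MatrixContext, sig: np.ndarray, alpha: float) -> np.ndarray:
    """ssGSEA-style weighted running-sum enrichment, integrated over the
    ranking and scaled by the number of genes."""
    x = ctx.x
    n = ctx.n_genes
    order = np.argsort(-x, axis=1, kind="stable")
    in_sig = np.zeros(n, dtype=bool)
    in_sig[sig] = True
    hit = in_sig[order]
    if alpha == 0:
        w = hit.astype(np.float64)
    else:
        sorted_x = np.take_along_axis(x, order, axis=1)
        w = np.where(hit, np.abs(sorted_x) ** alpha, 0.0)
    w_tot = w.sum(axis=1, keepdims=True)
    w_tot[w_tot == 0] = 1.0
    hit_cdf = np.cumsum(w, axis=1) / w_tot
    miss_cdf = np.cumsum(~hit, axis=1) / (n - sig.size)
    return (hit_cdf - miss_cdf).sum(axis=1) / n


def _score_svd_proj(ctx: _MatrixContext, sig: np.ndarray, on_ranks: bool = False) -> np.ndarray:
    """Projection of each cell onto the first right singular vector of the
    standardised signature submatrix, oriented along mean expression."""
    base = ctx.asc_ranks if on_ranks else ctx.x
    x = base[:, sig].astype(np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    score = u[:, 0] * s[0]
    ref = z.mean(axis=1)
    if np.dot(score, ref) < 0:
        score = -score
    return score


def _score_binned_ctrl(
    ctx: _MatrixContext, sig: np.ndarray, n_bins: int, ctrl_per_gene: int, seed: int
) -> np.ndarray:
    """Signature mean minus the mean of expression-bin-matched control genes
    (control pools drawn deterministically per scorer)."""
    n = ctx.n_genes
    bins = np.minimum(
        (rankdata(ctx.gene_mean, method="ordinal") - 1) * n_bins // n, n_bins - 1
    )
    rng = np.random.default_rng(seed)
    ctrl: list[int] = []
    for g in sig:
        pool = np.flatnonzero(bins == bins[g])
        take = min(ctrl_per_gene, pool.size)
        ctrl.extend(rng.choice(pool, size=take, replace=False))
    ctrl_idx = np.unique(np.asarray(ctrl, dtype=int))
    return ctx.x[:, sig].mean(axis=1) - ctx.x[:, ctrl_idx].mean(axis=1)


def _score_dropout_rank(ctx: _MatrixContext, sig: np.ndarray) -> np.ndarray:
    """Mean rank of signature genes among each cell's *expressed* genes;
    unexpressed signature genes contribute rank zero."""
    x = ctx.x
    expressed = x > 0
    n_expr = expressed.sum(axis=1).astype(np.float64)
    n_expr[n_expr == 0] = 1.0
    # rank only over expressed genes: zero-out the rest and subtract the
    # shared count of zeros so expressed genes rank 1..n_expr
    ranks = rankdata(x, axis=1)
    n_zero = (~expressed).sum(axis=1, keepdims=True)
    adj = np.where(expressed, ranks - n_zero, 0.0)
    return adj[:, sig].sum(axis=1) / (sig.size * n_expr)


_KINDS = {
    "mean_z": _score_mean_z,
    "rank_auc": _score_rank_auc,
    "rank_sum": _score_rank_sum,
    "mean_rank": _score_mean_rank,
    "running_sum": _score_running_sum,
    "svd_proj": _score_svd_proj,
    "binned_ctrl": _score_binned_ctrl,
    "dropout_rank": _score_dropout_rank,
}


def _ctrl_seed(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little") % (2**31)


def _registry_catalogue() -> list[Scorer]:
    core = [
        Scorer("mean_z", "mean_z"),
        Scorer("rank_auc_top05", "rank_auc", {"top_frac": 0.05}),
        Scorer("rank_sum", "rank_sum"),
        Scorer("mean_rank_centered", "mean_rank", {"centered": True}),
        Scorer("running_sum_a025", "running_sum", {"alpha": 0.25}),
        Scorer("svd_proj", "svd_proj"),
        Scorer("binned_ctrl_b25", "binned_ctrl", {"n_bins": 25, "ctrl_per_gene": 10}),
        Scorer("dropout_rank", "dropout_rank"),
    ]
    variants = [
        Scorer("rank_auc_top10", "rank_auc", {"top_frac": 0.10}),
        Scorer("rank_auc_top25", "rank_auc", {"top_frac": 0.25}),
        Scorer("running_sum_a0", "running_sum", {"alpha": 0.0}),
        Scorer("running_sum_a1", "running_sum", {"alpha": 1.0}),
        Scorer("binned_ctrl_b10", "binned_ctrl", {"n_bins": 10, "ctrl_per_gene": 10}),
        Scorer("binned_ctrl_b50", "binned_ctrl", {"n_bins": 50, "ctrl_per_gene": 10}),
        Scorer("mean_z_w01", "mean_z", {"winsor": 0.01}),
        Scorer("mean_z_w05", "mean_z", {"winsor": 0.05}),
        Scorer("running_sum_a05", "running_sum", {"alpha": 0.5}),
        Scorer("rank_auc_top50", "rank_auc", {"top_frac": 0.50}),
        Scorer("svd_proj_ranks", "svd_proj", {"on_ranks": True}),
        Scorer("mean_rank_scaled", "mean_rank", {"centered": False}),
    ]
    return core + variants


def build_registry(k: int = 19) -> list[Scorer]:
    """Deterministic list of ``k`` uniquely-named scorers.

    The first 8 entries are the core statistics; further entries are
    documented parameter variants. Raises if ``k`` exceeds the catalogue.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    catalogue = _registry_catalogue()
    if k > len(catalogue):
        raise ParameterError(
            f"k={k} exceeds the {len(catalogue)} available scorers"
        )
    registry = catalogue[:k]
    logger.info("scorer registry (k=%d): %s", k, [s.name for s in registry])
    return registry


def _resolve_signature(
    var_names, genes: list[str], label: str
) -> np.ndarray:
    uniq = list(dict.fromkeys(genes))
    if len(uniq) < len(genes):
        warnings.warn(f"duplicate genes in {label} deduplicated", stacklevel=3)
    lookup = {g: i for i, g in enumerate(var_names)}
    present = [g for g in uniq if g in lookup]
    if len(present) < len(uniq):
        warnings.warn(
            f"{len(uniq) - len(present)} {label} genes absent from the matrix",
            stacklevel=3,
        )
    if not present:
        raise EmptySignatureError(f"no {label} genes present in the matrix")
    return np.asarray([lookup[g] for g in present], dtype=int)


def score(adata: ad.AnnData, genes: list[str], scorer: Scorer) -> np.ndarray:
    """One finite score per cell for a single signature and scorer."""
    tensor = _score_signatures(adata, {"signature": genes}, [scorer])
    return tensor["signature"][:, 0]


def _score_signatures(
    adata: ad.AnnData, signatures: dict[str, list[str]], registry: list[Scorer]
) -> dict[str, np.ndarray]:
    norm = adata if adata.uns.get("normalized") else normalize(adata)
    x = norm.X
    x = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=np.float64)
    ctx = _MatrixContext(x.astype(np.float64))
    out: dict[str, np.ndarray] = {}
    for label, genes in signatures.items():
        sig = _resolve_signature(norm.var_names, genes, label)
        cols = np.empty((ctx.n_cells, len(registry)))
        for j, sc in enumerate(registry):
            params = dict(sc.params)
            if sc.kind == "binned_ctrl":
                params["seed"] = _ctrl_seed(sc.name + label)
            try:
                cols[:, j] = _KINDS[sc.kind](ctx, sig, **params)
            except Exception as exc:  # surface the failing scorer by name
                raise type(exc)(f"scorer {sc.name!r} on {label}: {exc}") from exc
        out[label] = cols
    return out


def score_all(
    adata: ad.AnnData, sig: SignaturePair, registry: list[Scorer]
) -> ScoreTensor:
    """Score every cell with every scorer for both signatures.

    With k scorers each cell receives 2k continuous scores (k per signature).
    """
    if not sig.signature1 or not sig.signature2:
        raise EmptySignatureError("both signatures must be non-empty")
    res = _score_signatures(
        adata, {"signature1": sig.signature1, "signature2": sig.signature2}, registry
    )
    values = np.stack([res["signature1"], res["signature2"]], axis=2)
    return ScoreTensor(
        cells=list(adata.obs_names),
        scorers=[s.name for s in registry],
        values=values,
    )
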