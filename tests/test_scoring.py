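"""Scorer registry and per-cell gene-set scoring statistics."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from cccf import de, scoring
from cccf.de import SignaturePair
from cccf.errors import EmptySignatureError, ParameterError

CORE_KINDS = [
    "mean_z", "rank_auc", "rank_sum", "mean_rank", "running_sum",
    "svd_proj", "binned_ctrl", "dropout_rank",
]
RANK_SCORER_NAMES = ["rank_auc_top05", "rank_sum", "mean_rank_centered", "dropout_rank"]


def _norm_adata(x):
    x = np.asarray(x, dtype=float)
    a = ad.AnnData(
        X=x,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(x.shape[0])]),
        var=pd.DataFrame(index=[f"g{j}" for j in range(x.shape[1])]),
    )
    a.uns["normalized"] = {"target_sum": None, "log1p": False}
    return a


def _scorer(name):
    return next(s for s in scoring._registry_catalogue() if s.name == name)


# ---------------------------------------------------------------------------
# registry


def test_registry_k19_has_unique_names():
    reg = scoring.build_registry(19)
    assert len(reg) == 19
    assert len({s.name for s in reg}) == 19


def test_registry_small_k_prefix():
    assert [s.name for s in scoring.build_registry(1)] == ["mean_z"]
    core = scoring.build_registry(8)
    assert [s.kind for s in core] == CORE_KINDS


def test_registry_k_too_large_names_maximum():
    with pytest.raises(ParameterError, match=str(scoring.MAX_SCORERS)):
        scoring.build_registry(scoring.MAX_SCORERS + 1)


# ---------------------------------------------------------------------------
# individual scorers


def test_single_gene_mean_z_equals_gene_zscore(rng):
    x = rng.normal(5, 2, size=(40, 6))
    a = _norm_adata(x)
    s = scoring.score(a, ["g2"], _scorer("mean_z"))
    col = x[:, 2]
    assert np.allclose(s, (col - col.mean()) / col.std())


def test_rank_auc_is_one_when_signature_tops_the_cell(rng):
    x = rng.uniform(0, 1, size=(5, 100))
    sig_idx = [10, 20, 30]
    x[0, sig_idx] = [10.0, 11.0, 12.0]  # top |S| ranks in cell 0
    a = _norm_adata(x)
    s = scoring.score(a, [f"g{j}" for j in sig_idx], _scorer("rank_auc_top05"))
    assert s[0] == pytest.approx(1.0)
    assert np.all(s[1:] < 1.0)


def test_rank_sum_score_bounds_and_perfection(rng):
    x = rng.uniform(size=(4, 50))
    x[1, :5] += 10  # signature genes highest in cell 1
    a = _norm_adata(x)
    s = scoring.score(a, [f"g{j}" for j in range(5)], _scorer("rank_sum"))
    assert s[1] == pytest.approx(1.0)
    assert np.all((s >= 0) & (s <= 1))


def test_permutation_null_mean_of_rank_sum_score(rng):
    """Permuting gene values within a cell leaves rank-based scores at their
    analytic null mean (0.5 for the within-cell rank-sum statistic)."""
    base = rng.uniform(size=60)
    sig = [f"g{j}" for j in range(8)]
    scores = []
    for _ in range(400):
        a = _norm_adata(rng.permutation(base)[None, :].repeat(2, axis=0))
        scores.append(scoring.score(a, sig, _scorer("rank_sum"))[0])
    assert np.mean(scores) == pytest.approx(0.5, abs=0.02)


@pytest.mark.parametrize("name", RANK_SCORER_NAMES)
def test_rank_scorers_invariant_under_monotone_transform(name, rng):
    x = rng.gamma(2.0, 1.0, size=(30, 80))
    x[rng.uniform(size=x.shape) < 0.3] = 0.0  # keep zeros for dropout scorer
    sig = [f"g{j}" for j in range(7)]
    s1 = scoring.score(_norm_adata(x), sig, _scorer(name))
    s2 = scoring.score(_norm_adata(x**1.7), sig, _scorer(name))  # monotone, 0-preserving
    assert np.allclose(s1, s2)


def test_cell_order_permutation_equivariance(rng):
    x = rng.gamma(2.0, 2.0, size=(25, 60))
    sig = [f"g{j}" for j in range(6)]
    perm = rng.permutation(25)
    for name in ["mean_z", "rank_auc_top05", "running_sum_a025", "binned_ctrl_b25"]:
        s = scoring.score(_norm_adata(x), sig, _scorer(name))
        sp = scoring.score(_norm_adata(x[perm]), sig, _scorer(name))
        assert np.allclose(s[perm], sp), name


def test_every_core_scorer_separates_planted_high_risk(cccf_chain):
    """At effect 1, each core statistic scores planted high-risk cells higher
    on the planted up-signature than the remaining cells, on average."""
    norm = cccf_chain["norm"]
    truth = cccf_chain["truth"]
    hr = norm.obs["high_risk"].to_numpy()
    for scorer in scoring.build_registry(8):
        s = scoring.score(norm, truth.sig_up_genes, scorer)
        assert s[hr].mean() > s[~hr].mean(), scorer.name


# ---------------------------------------------------------------------------
# score_all


def test_score_all_shapes(rng):
    x = rng.uniform(size=(10, 40))
    a = _norm_adata(x)
    sig = SignaturePair(signature1=["g0", "g1"], signature2=["g5", "g6"])
    tensor = scoring.score_all(a, sig, scoring.build_registry(3))
    assert tensor.values.shape == (10, 3, 2)
    assert tensor.values.size == 60
    t19 = scoring.score_all(a, sig, scoring.build_registry(19))
    assert t19.values.shape[1] * t19.values.shape[2] == 38
    assert np.all(np.isfinite(t19.values))


def test_score_all_deduplicates_and_warns(rng):
    a = _norm_adata(rng.uniform(size=(6, 20)))
    sig = SignaturePair(signature1=["g0", "g0", "g1"], signature2=["g2"])
    with pytest.warns(UserWarning, match="duplicate"):
        tensor = scoring.score_all(a, sig, scoring.build_registry(2))
    dedup = scoring.score_all(
        a, SignaturePair(["g0", "g1"], ["g2"]), scoring.build_registry(2)
    )
    assert np.allclose(tensor.values, dedup.values)


def test_score_all_errors_when_signature_absent(rng):
    a = _norm_adata(rng.uniform(size=(6, 20)))
    with pytest.raises(EmptySignatureError, match="signature1"):
        scoring.score_all(
            a, SignaturePair(["missing1", "missing2"], ["g0"]), scoring.build_registry(2)
        )


def test_scores_computed_on_normalized_data(sc_small):
    """Raw counts are depth-normalised before scoring, so pre-normalising
    explicitly gives identical scores."""
    adata, truth = sc_small
    norm = de.normalize(adata)
    sig = SignaturePair(truth.sig_up_genes, truth.sig_down_genes)
    reg = scoring.build_registry(4)
    t_raw = scoring.score_all(adata, sig, reg)
    t_norm = scoring.score_all(norm, sig, reg)
    assert np.allclose(t_raw.values, t_norm.values)
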