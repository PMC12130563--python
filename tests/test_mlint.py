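"""Model grid enumeration, AUC, splitting, fitting and ranking."""

import numpy as np
import pandas as pd
import pytest

from cccf import mlint, synth
from _oracles import auc_oracle
from cccf.errors import DegenerateInputError


def _xy(n=40, p=6, seed=0, informative=0):
    rng = np.random.default_rng(seed)
    y = pd.Series(rng.integers(0, 2, size=n), index=[f"s{i}" for i in range(n)])
    x = rng.normal(size=(n, p))
    if informative:
        x[:, :informative] += 2.0 * y.to_numpy()[:, None]
    return pd.DataFrame(x, index=y.index, columns=[f"g{j}" for j in range(p)]), y


# ---------------------------------------------------------------------------
# split


def test_split_sizes_balanced():
    x, y = _xy(100)
    y[:] = [0, 1] * 50
    xtr, xte, ytr, yte = mlint.split(x, y, ratio=0.7, seed=1)
    assert (len(xtr), len(xte)) == (70, 30)
    assert set(xtr.index).isdisjoint(xte.index)


def test_split_stratifies_small_classes():
    x, y = _xy(10)
    y[:] = [0] * 5 + [1] * 5
    xtr, _, ytr, _ = mlint.split(x, y, ratio=0.7, seed=0)
    assert len(xtr) == 7
    assert ytr.value_counts().min() >= 3


def test_split_seed_determinism_and_errors():
    x, y = _xy(30)
    a = mlint.split(x, y, seed=4)
    b = mlint.split(x, y, seed=4)
    assert list(a[0].index) == list(b[0].index)
    y_one = y.copy()
    y_one[:] = 1
    with pytest.raises(DegenerateInputError):
        mlint.split(x, y_one)


# ---------------------------------------------------------------------------
# AUC vs pairwise oracle




def test_auc_fixed_examples():
    assert mlint.auc([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0]) == 1.0
    assert mlint.auc([0.2, 0.8], [1, 0]) == 0.0
    assert mlint.auc([0.5, 0.5], [1, 0]) == 0.5
    with pytest.raises(DegenerateInputError):
        mlint.auc([0.1, 0.2], [1, 1])


def test_auc_matches_pairwise_oracle_on_random_instances(rng):
    for _ in range(1000):
        n = rng.integers(4, 25)
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.integers(0, 5, size=n).astype(float)  # many ties
        assert mlint.auc(scores, labels) == pytest.approx(auc_oracle(scores, labels))


# ---------------------------------------------------------------------------
# grid enumeration and ranking


def test_enumerate_grid_is_deterministic_and_coherent():
    specs = mlint.enumerate_combinations()
    names = [s.name for s in specs]
    assert names == [s.name for s in mlint.enumerate_combinations()]
    assert len(set(names)) == len(names)
    expected = len(mlint.CLASSIFIERS) * len(mlint.SELECTORS) - len(mlint._INCOHERENT)
    assert len(specs) == expected
    assert "lasso+lasso-logistic" not in names


def test_enumerate_single_stage_only():
    specs = mlint.enumerate_combinations(allow_two_stage=False)
    assert len(specs) == len(mlint.CLASSIFIERS)
    assert all(s.selector == "none" for s in specs)


def _result(name_sel, name_clf, mean, n_genes):
    half = mean  # mean_auc = (test + valid)/2; use equal halves
    return mlint.ModelResult(
        spec=mlint.ModelSpec(name_sel, name_clf),
        genes_used=[f"g{j}" for j in range(n_genes)],
        coefficients=None,
        auc_train=0.9, auc_test=half, auc_valid=half,
    )


def test_rank_models_orders_by_mean_auc_then_parsimony():
    results = [
        _result("none", "logistic", 0.90, 5),
        _result("none", "lda", 0.95, 12),
        _result("lasso", "knn", 0.95, 7),
    ]
    ranked = mlint.rank_models(results)
    assert [r.spec.name for r in ranked] == [
        "lasso+knn", "none+lda", "none+logistic"
    ]
    assert mlint.rank_models([results[0]]) == [results[0]]


def test_gene_frequency_counts_models():
    results = [
        _result("none", "logistic", 0.9, 3),   # g0 g1 g2
        _result("none", "lda", 0.9, 1),        # g0
    ]
    freq = mlint.gene_frequency(results)
    assert freq["g0"] == 2
    assert freq["g2"] == 1
    assert "g9" not in freq


# ---------------------------------------------------------------------------
# fit_evaluate


def test_perfect_feature_gives_train_auc_one():
    x, y = _xy(40, p=1, seed=1)
    x["g0"] = y.to_numpy().astype(float)
    parts = (x, y)
    res = mlint.fit_evaluate(mlint.ModelSpec("none", "logistic"), parts, parts, parts)
    assert res.auc_train == 1.0
    assert res.genes_used == ["g0"]
    assert res.coefficients is not None


def test_empty_selection_is_flagged(monkeypatch):
    x, y = _xy(30)
    monkeypatch.setattr(mlint, "select_genes", lambda *a, **k: [])
    res = mlint.fit_evaluate(mlint.ModelSpec("lasso", "logistic"), (x, y), (x, y), (x, y))
    assert res.flagged
    assert res.genes_used == []
    assert res.mean_auc == 0.5


@pytest.mark.parametrize(
    "selector", ["lasso", "stepwise-forward", "stepwise-backward", "univariate-filter"]
)
def test_selectors_find_informative_genes(selector):
    x, y = _xy(60, p=12, seed=3, informative=3)
    genes = mlint.select_genes(selector, x, y, seed=0)
    assert set(genes) & {"g0", "g1", "g2"}
    assert set(genes) <= set(x.columns)


def test_no_information_leak_from_test_and_validation():
    """Replacing test/validation labels with noise leaves the fitted gene set
    and coefficients unchanged."""
    xtr, ytr = _xy(50, p=8, seed=2, informative=2)
    xte, yte = _xy(20, p=8, seed=3, informative=2)
    spec = mlint.ModelSpec("lasso", "logistic")
    r1 = mlint.fit_evaluate(spec, (xtr, ytr), (xte, yte), (xte, yte), seed=0)
    rng = np.random.default_rng(0)
    noise = pd.Series(rng.integers(0, 2, size=len(yte)), index=yte.index)
    while noise.nunique() < 2:
        noise = pd.Series(rng.integers(0, 2, size=len(yte)), index=yte.index)
    r2 = mlint.fit_evaluate(spec, (xtr, ytr), (xte, noise), (xte, noise), seed=0)
    assert r1.genes_used == r2.genes_used
    assert r1.coefficients == r2.coefficients
    assert r1.auc_train == r2.auc_train


def test_grid_reruns_identically():
    b1, b2, _ = synth.simulate_bulk(
        synth.BulkSimParams(n_samples_per_cohort=40, n_features=12, n_informative=3, seed=6)
    )
    xtr, xte, ytr, yte = mlint.split(b1.expr, b1.labels, seed=6)
    specs = [
        mlint.ModelSpec("none", "random-forest"),
        mlint.ModelSpec("univariate-filter", "knn"),
        mlint.ModelSpec("lasso", "logistic"),
    ]
    r1 = mlint.run_grid(specs, (xtr, ytr), (xte, yte), (b2.expr, b2.labels), seed=6)
    r2 = mlint.run_grid(specs, (xtr, ytr), (xte, yte), (b2.expr, b2.labels), seed=6)
    assert [(r.spec.name, r.mean_auc, tuple(r.genes_used)) for r in r1] == [
        (r.spec.name, r.mean_auc, tuple(r.genes_used)) for r in r2
    ]
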