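"""Multi-model machine-learning integration.

Enumerates feature-selector x classifier combinations, fits each on the
training partition only (cohort 1 split 7:3 into train/test; cohort 2 is the
external validation set), and ranks the candidates by the mean of the test
and validation AUCs. Per-gene model membership across the grid gives a
robustness measure of each candidate biomarker.

Selectors: none, L1-penalised logistic (lasso), elastic net, AIC-driven
stepwise logistic (forward / backward / both, on a univariate pre-screen so
the repeated maximum-likelihood fits stay well-posed at p ~ n), and a
univariate rank-sum filter. Classifiers: plain / ridge / lasso logistic
regression, LDA, Gaussian naive Bayes, kNN, random forest, linear SVM and
gradient boosting; hyperparameters are chosen by internal cross-validation
on the training partition only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .de import bh_adjust
from .errors import DegenerateInputError, ParameterError

logger = logging.getLogger(__name__)

SELECTORS = (
    "none",
    "lasso",
    "elastic-net",
    "stepwise-forward",
    "stepwise-backward",
    "stepwise-both",
    "univariate-filter",
)
CLASSIFIERS = (
    "logistic",
    "ridge-logistic",
    "lasso-logistic",
    "lda",
    "naive-bayes",
    "knn",
    "random-forest",
    "linear-svm",
    "gradient-boosting",
)
# Sparse selector feeding the same embedded-sparse classifier is redundant.
_INCOHERENT = {("lasso", "lasso-logistic"), ("elastic-net", "lasso-logistic")}

_LINEAR_CLASSIFIERS = {"logistic", "ridge-logistic", "lasso-logistic", "lda", "linear-svm"}

_MAX_STEPWISE_POOL = 15
_MAX_STEPWISE_STEPS = 12


@dataclass(frozen=True)
class ModelSpec:
    selector: str
    classifier: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.selector not in SELECTORS:
            raise ParameterError(f"unknown selector {self.selector!r}")
        if self.classifier not in CLASSIFIERS:
            raise ParameterError(f"unknown classifier {self.classifier!r}")

    @property
    def name(self) -> str:
        return f"{self.selector}+{self.classifier}"

    def __hash__(self) -> int:
        return hash((self.selector, self.classifier))


@dataclass
class ModelResult:
    spec: ModelSpec
    genes_used: list[str]
    coefficients: dict[str, float] | None
    auc_train: float
    auc_test: float
    auc_valid: float
    flagged: bool = False

    @property
    def mean_auc(self) -> float:
        return (self.auc_test + self.auc_valid) / 2.0


def split(
    x: pd.DataFrame,
    y: pd.Series,
    ratio: float = 0.7,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Seeded stratified train/test split at the given training ratio."""
    if not 0 < ratio < 1:
        raise ParameterError("ratio must be in (0, 1)")
    y = pd.Series(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DegenerateInputError("both classes must be present")
    if counts.min() < 2:
        raise DegenerateInputError("need >= 2 samples per class")
    xtr, xte, ytr, yte = train_test_split(
        x,
        y,
        train_size=ratio,
        random_state=seed,
        stratify=y if stratify else None,
        shuffle=True,
    )
    return xtr, xte, ytr, yte


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if np.unique(labels).size < 2:
        raise DegenerateInputError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def enumerate_combinations(allow_two_stage: bool = True) -> list[ModelSpec]:
    """All classifiers alone plus all coherent selector->classifier pairs."""
    specs = [ModelSpec("none", c) for c in CLASSIFIERS]
    if allow_two_stage:
        for s in SELECTORS:
            if s == "none":
                continue
            for c in CLASSIFIERS:
                if (s, c) in _INCOHERENT:
                    continue
                specs.append(ModelSpec(s, c))
    names = [sp.name for sp in specs]
    if len(set(names)) != len(names):
        raise ParameterError("duplicate spec names in the grid")
    logger.info("model grid: %d combinations", len(specs))
    return specs


# ---------------------------------------------------------------------------
# selectors


def _univariate_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(
            x[y == 1], x[y == 0], axis=0, alternative="two-sided", method="asymptotic"
        )
    p = np.asarray(res.pvalue, dtype=np.float64)
    return np.where(np.isfinite(p), p, 1.0)


def _sparse_logistic_genes(
    x: np.ndarray, y: np.ndarray, genes: list[str], seed: int, l1_ratio: float | None
) -> list[str]:
    cv = StratifiedKFold(3, shuffle=True, random_state=seed)
    if l1_ratio is None:
        model = LogisticRegressionCV(
            penalty="l1", solver="liblinear", Cs=7, cv=cv, max_iter=500,
            scoring="roc_auc", random_state=seed,
        )
    else:
        model = LogisticRegressionCV(
            penalty="elasticnet", solver="saga", l1_ratios=[l1_ratio], Cs=5,
            cv=cv, max_iter=3000, scoring="roc_auc", random_state=seed,
        )
    xs = StandardScaler().fit_transform(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(xs, y)
    keep = np.abs(model.coef_[0]) > 1e-8
    return [g for g, k in zip(genes, keep) if k]


def _logit_aic(x: np.ndarray, y: np.ndarray, cols: list[int]) -> float:
    if not cols:
        design = np.ones((len(y), 1))
    else:
        design = sm.add_constant(x[:, cols], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            llf = fit.llf
        except Exception:
            llf = 0.0  # separation: likelihood saturates
    if not np.isfinite(llf):
        llf = 0.0
    return 2 * design.shape[1] - 2 * llf


def _stepwise_genes(
    x: np.ndarray, y: np.ndarray, genes: list[str], mode: str
) -> list[str]:
    """AIC stepwise logistic selection on a univariate pre-screened pool."""
    n = len(y)
    pool_size = min(_MAX_STEPWISE_POOL, max(2, n // 3), len(genes))
    order = np.argsort(_univariate_p(x, y))[:pool_size]
    pool = [int(i) for i in order]

    def step_forward(current: list[int]) -> tuple[list[int], bool]:
        base = _logit_aic(x, y, current)
        best, best_aic = None, base
        for j in pool:
            if j in current:
                continue
            a = _logit_aic(x, y, current + [j])
            if a < best_aic - 1e-9:
                best, best_aic = j, a
        if best is None:
            return current, False
        return current + [best], True

    def step_backward(current: list[int]) -> tuple[list[int], bool]:
        base = _logit_aic(x, y, current)
        best, best_aic = None, base
        for j in current:
            a = _logit_aic(x, y, [c for c in current if c != j])
            if a < best_aic - 1e-9:
                best, best_aic = j, a
        if best is None:
            return current, False
        return [c for c in current if c != best], True

    if mode == "backward":
        current = list(pool)
        for _ in range(len(pool)):
            current, moved = step_backward(current)
            if not moved:
                break
    else:
        current: list[int] = []
        for _ in range(_MAX_STEPWISE_STEPS):
            current, moved = step_forward(current)
            if not moved:
                break
            if mode == "both":
                while True:
                    current, removed = step_backward(current)
                    if not removed:
                        break
    return [genes[j] for j in sorted(current)]


def select_genes(
    selector: str, x: pd.DataFrame, y: pd.Series, seed: int = 0
) -> list[str]:
    """Run one feature selector on the training partition only."""
    genes = list(x.columns)
    xv = x.to_numpy(dtype=np.float64)
    yv = np.asarray(y).astype(int)
    if selector == "none":
        return genes
    if selector == "lasso":
        return _sparse_logistic_genes(xv, yv, genes, seed, l1_ratio=None)
    if selector == "elastic-net":
        return _sparse_logistic_genes(xv, yv, genes, seed, l1_ratio=0.5)
    if selector.startswith("stepwise-"):
        return _stepwise_genes(xv, yv, genes, selector.split("-", 1)[1])
    if selector == "univariate-filter":
        p = _univariate_p(xv, yv)
        p_adj = np.asarray(bh_adjust(list(p)))
        keep = [g for g, pa in zip(genes, p_adj) if pa < 0.05]
        if not keep:
            top = np.argsort(p)[: min(5, len(genes))]
            keep = [genes[int(i)] for i in top]
        return sorted(keep)
    raise ParameterError(f"unknown selector {selector!r}")


# ---------------------------------------------------------------------------
# classifiers


def _make_classifier(name: str, seed: int):
    cv = StratifiedKFold(3, shuffle=True, random_state=seed)
    if name == "logistic":
        clf = LogisticRegression(penalty=None, max_iter=1000)
    elif name == "ridge-logistic":
        clf = LogisticRegressionCV(
            penalty="l2", Cs=7, cv=cv, max_iter=1000, scoring="roc_auc",
            random_state=seed,
        )
    elif name == "lasso-logistic":
        clf = LogisticRegressionCV(
            penalty="l1", solver="liblinear", Cs=7, cv=cv, scoring="roc_auc",
            random_state=seed,
        )
    elif name == "lda":
        clf = LinearDiscriminantAnalysis()
    elif name == "naive-bayes":
        clf = GaussianNB()
    elif name == "knn":
        clf = GridSearchCV(
            KNeighborsClassifier(), {"n_neighbors": [3, 5, 7]}, cv=cv,
            scoring="roc_auc",
        )
    elif name == "random-forest":
        clf = RandomForestClassifier(n_estimators=300, random_state=seed)
    elif name == "linear-svm":
        clf = GridSearchCV(
            SVC(kernel="linear"), {"C": [0.01, 0.1, 1.0]}, cv=cv,
            scoring="roc_auc",
        )
    elif name == "gradient-boosting":
        clf = GradientBoostingClassifier(
            n_estimators=100, max_depth=2, random_state=seed
        )
    else:
        raise ParameterError(f"unknown classifier {name!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _decision_scores(pipe: Pipeline, x: np.ndarray) -> np.ndarray:
    if hasattr(pipe, "predict_proba"):
        try:
            return pipe.predict_proba(x)[:, 1]
        except AttributeError:
            pass
    return pipe.decision_function(x)


def _linear_coefficients(pipe: Pipeline, genes: list[str]) -> dict[str, float] | None:
    clf = pipe.named_steps["clf"]
    if isinstance(clf, GridSearchCV):
        clf = clf.best_estimator_
    coef = getattr(clf, "coef_", None)
    if coef is None:
        return None
    return {g: float(c) for g, c in zip(genes, np.ravel(coef))}


def fit_evaluate(
    spec: ModelSpec,
    train: tuple[pd.DataFrame, pd.Series],
    test: tuple[pd.DataFrame, pd.Series],
    valid: tuple[pd.DataFrame, pd.Series],
    seed: int = 0,
) -> ModelResult:
    """Fit one selector+classifier combination and evaluate its AUCs.

    The selector and all hyperparameter tuning see the training partition
    only; test and validation labels enter solely through the final AUCs.
    """
    xtr, ytr = train
    genes = select_genes(spec.selector, xtr, ytr, seed=seed)
    if not genes:
        logger.warning("%s selected 0 genes; flagged with mean AUC 0.5", spec.name)
        return ModelResult(
            spec=spec, genes_used=[], coefficients=None,
            auc_train=0.5, auc_test=0.5, auc_valid=0.5, flagged=True,
        )
    pipe = _make_classifier(spec.classifier, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(xtr[genes].to_numpy(), np.asarray(ytr).astype(int))

    coefs = _linear_coefficients(pipe, genes)
    genes_used = genes
    if coefs is not None and spec.classifier == "lasso-logistic":
        genes_used = [g for g in genes if abs(coefs[g]) > 1e-8] or genes

    aucs = {}
    for part, (x, y) in (("train", train), ("test", test), ("valid", valid)):
        s = _decision_scores(pipe, x[genes].to_numpy())
        aucs[part] = auc(s, np.asarray(y).astype(int))
    return ModelResult(
        spec=spec,
        genes_used=genes_used,
        coefficients=coefs,
        auc_train=aucs["train"],
        auc_test=aucs["test"],
        auc_valid=aucs["valid"],
    )


def run_grid(
    specs: list[ModelSpec],
    train: tuple[pd.DataFrame, pd.Series],
    test: tuple[pd.DataFrame, pd.Series],
    valid: tuple[pd.DataFrame, pd.Series],
    seed: int = 0,
) -> list[ModelResult]:
    results = []
    for spec in specs:
        res = fit_evaluate(spec, train, test, valid, seed=seed)
        logger.info(
            "%-35s genes=%3d test=%.3f valid=%.3f mean=%.3f",
            spec.name, len(res.genes_used), res.auc_test, res.auc_valid, res.mean_auc,
        )
        results.append(res)
    return results


def rank_models(results: list[ModelResult]) -> list[ModelResult]:
    """Descending mean AUC; ties broken by fewer genes, then name."""
    if not results:
        raise ParameterError("rank_models needs at least one result")
    return sorted(
        results, key=lambda r: (-r.mean_auc, len(r.genes_used), r.spec.name)
    )


def gene_frequency(results: list[ModelResult]) -> dict[str, int]:
    """Per gene, the number of models whose final gene set contains it."""
    if not results:
        raise ParameterError("gene_frequency needs at least one result")
    counts: dict[str, int] = {}
    for res in results:
        for g in set(res.genes_used):
            counts[g] = counts.get(g, 0) + 1
    return counts


def results_frame(results: list[ModelResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [r.spec.name for r in results],
            "n_genes": [len(r.genes_used) for r in results],
            "auc_train": [r.auc_train for r in results],
            "auc_test": [r.auc_test for r in results],
            "auc_valid": [r.auc_valid for r in results],
            "mean_auc": [r.mean_auc for r in results],
            "flagged": [r.flagged for r in results],
        }
    )
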