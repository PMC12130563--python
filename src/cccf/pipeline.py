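"""End-to-end pipeline: simulation -> signatures -> consensus -> pseudotime
-> feature selection -> multi-model integration.

``run_all`` executes the whole chain in memory on synthetic data and returns
every intermediate artifact; the CLI and the reproduction script are thin
wrappers over it. The "mouse" single-cell dataset is a second simulated
replicate sharing the gene universe, standing in for the cross-species
validation arm.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import consensus as cons
from . import de, mlint, scoring, synth, trajectory
from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds, defaulting to the published cut-offs."""

    lfc_sc: float = 0.25
    lfc_bulk: float = 1.0
    alpha: float = 0.05
    r_thresh: float = 0.6
    k_scorers: int = 19
    split_ratio: float = 0.7
    seed: int = 0
    sc: dict = field(default_factory=dict)     # SCSimParams overrides
    bulk: dict = field(default_factory=dict)   # BulkSimParams overrides

    def __post_init__(self) -> None:
        for fld in ("lfc_sc", "lfc_bulk", "alpha", "r_thresh"):
            if getattr(self, fld) <= 0:
                raise ParameterError(f"{fld} must be positive")
        if not 0 < self.split_ratio < 1:
            raise ParameterError("split_ratio must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    def sc_params(self, seed_offset: int = 0) -> synth.SCSimParams:
        kw = dict(self.sc)
        kw.setdefault("seed", self.seed)
        kw["seed"] = kw["seed"] + seed_offset
        return synth.SCSimParams(**kw)

    def bulk_params(self, n_features: int | None = None) -> synth.BulkSimParams:
        kw = dict(self.bulk)
        kw.setdefault("seed", self.seed + 2000)
        if n_features is not None:
            kw["n_features"] = n_features
        return synth.BulkSimParams(**kw)


@dataclass
class RunResult:
    """Every artifact of one end-to-end run."""

    sc_human: Any
    sc_mouse: Any
    truth_human: synth.PlantedTruth
    truth_mouse: synth.PlantedTruth
    bulk1: synth.BulkCohort
    bulk2: synth.BulkCohort
    truth_bulk: synth.PlantedTruth
    signatures: de.SignaturePair
    tensors: dict[str, scoring.ScoreTensor]
    consensus: dict[str, list]
    proportions: dict[str, pd.DataFrame]
    pseudotimes: dict[str, pd.Series]
    correlations: dict[str, list]
    degs: dict[str, list[str]]
    selected_features: list[str]
    model_results: list[mlint.ModelResult]
    ranked: list[mlint.ModelResult]
    gene_freq: dict[str, int]


def simulate_inputs(config: RunConfig):
    """Generate the two single-cell replicates and the two bulk cohorts."""
    sc_human, truth_human = synth.simulate_sc(config.sc_params(0))
    sc_mouse, truth_mouse = synth.simulate_sc(config.sc_params(1000))
    genes = list(sc_human.var_names)
    bp = config.bulk_params(n_features=len(genes))
    informative = truth_human.monotone_pseudotime_genes[: bp.n_informative]
    bulk1, bulk2, truth_bulk = synth.simulate_bulk(
        bp, gene_names=genes, informative_genes=informative
    )
    return sc_human, truth_human, sc_mouse, truth_mouse, bulk1, bulk2, truth_bulk


def center_cohort(cohort: synth.BulkCohort) -> synth.BulkCohort:
    """Per-cohort centring: subtract each gene's cohort mean (the only batch
    handling in scope)."""
    expr = cohort.expr - cohort.expr.mean(axis=0)
    return synth.BulkCohort(name=cohort.name, expr=expr, labels=cohort.labels)


def run_all(config: RunConfig | None = None) -> RunResult:
    config = config or RunConfig()
    (sc_human, truth_human, sc_mouse, truth_mouse,
     bulk1, bulk2, truth_bulk) = simulate_inputs(config)

    norm_human = de.normalize(sc_human)
    norm_mouse = de.normalize(sc_mouse)

    records = de.sc_de(norm_human, case_label=synth.CASE_CONDITION)
    signatures = de.extract_signatures(records, config.lfc_sc, config.alpha)

    registry = scoring.build_registry(config.k_scorers)
    tensors, consensus_by, props, ptimes, corrs = {}, {}, {}, {}, {}
    for name, norm in (("human", norm_human), ("mouse", norm_mouse)):
        tensor = scoring.score_all(norm, signatures, registry)
        results = cons.classify(tensor)
        tensors[name] = tensor
        consensus_by[name] = results
        props[name] = cons.proportions(
            results, norm.obs["condition"].astype(str)
        )
        t = trajectory.pseudotime(norm, results)
        ptimes[name] = t
        corrs[name] = trajectory.correlate(norm, t)

    degs = {}
    for cohort in (bulk1, bulk2):
        degs[cohort.name], _ = de.bulk_de(
            cohort.expr, cohort.labels, config.lfc_bulk, config.alpha
        )

    selected = trajectory.select_features(
        corrs["human"], corrs["mouse"], degs["cohort1"], degs["cohort2"],
        r_thresh=config.r_thresh, alpha=config.alpha,
    )

    c1, c2 = center_cohort(bulk1), center_cohort(bulk2)
    xtr, xte, ytr, yte = mlint.split(
        c1.expr[selected], c1.labels, ratio=config.split_ratio, seed=config.seed
    )
    valid = (c2.expr[selected], c2.labels)
    specs = mlint.enumerate_combinations()
    results = mlint.run_grid(specs, (xtr, ytr), (xte, yte), valid, seed=config.seed)
    ranked = mlint.rank_models(results)
    freq = mlint.gene_frequency(results)

    return RunResult(
        sc_human=norm_human, sc_mouse=norm_mouse,
        truth_human=truth_human, truth_mouse=truth_mouse,
        bulk1=bulk1, bulk2=bulk2, truth_bulk=truth_bulk,
        signatures=signatures, tensors=tensors, consensus=consensus_by,
        proportions=props, pseudotimes=ptimes, correlations=corrs,
        degs=degs, selected_features=selected,
        model_results=results, ranked=ranked, gene_freq=freq,
    )
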