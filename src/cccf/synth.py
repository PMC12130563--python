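"""Synthetic single-cell and bulk data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two single-cell conditions (hypertensive controls, ``HBP``, and
microbleed cases, ``MB``) that share a neutrophil compartment but differ in a
planted up-/down-regulated signature carried only by a "high-risk" subset of
case cells; a continuous differentiation latent in [0, 1] per cell along which
a set of monotone genes increases; and two bulk cohorts with a constant batch
offset and a planted set of outcome-discriminative genes drawn from the
single-cell monotone set, so the trajectory/bulk intersection is non-empty by
construction.

Counts are negative binomial via a gamma-Poisson mixture with a shared
dispersion and per-cell lognormal library-size factors.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ParameterError

CONTROL_CONDITION = "HBP"
CASE_CONDITION = "MB"

# Latent threshold separating low-risk from high-risk case cells: high-risk
# cells occupy the top of the differentiation axis.
_LATENT_SPLIT = 0.6


@dataclass(frozen=True)
class SCSimParams:
    """Parameters of the single-cell simulator.

    ``effect_log2fc`` is the planted shift: in high-risk case cells the mean of
    each signature1 gene is multiplied by ``2**effect_log2fc`` and each
    signature2 gene divided by it. Monotone genes ramp linearly in the latent
    with an amplitude tied to the same effect size (1x at latent 0 up to
    ``8**effect_log2fc`` at latent 1), so an effect of 0 switches off every
    planted structure at once.
    """

    n_cells_per_condition: int = 1000
    n_genes: int = 500
    n_sig_up: int = 25
    n_sig_down: int = 25
    n_monotone: int = 15
    effect_log2fc: float = 1.0
    nb_dispersion: float = 0.05
    libsize_lognormal_sigma: float = 0.3
    frac_high_risk_in_case: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_condition < 1:
            raise ParameterError("n_cells_per_condition must be >= 1")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        for fld in ("n_sig_up", "n_sig_down", "n_monotone"):
            if getattr(self, fld) < 0:
                raise ParameterError(f"{fld} must be >= 0")
        if self.n_sig_up + self.n_sig_down + self.n_monotone > self.n_genes:
            raise ParameterError(
                "n_sig_up + n_sig_down + n_monotone exceeds n_genes; planted "
                "gene sets must be disjoint subsets of the gene universe"
            )
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be > 0")
        if self.libsize_lognormal_sigma < 0:
            raise ParameterError("libsize_lognormal_sigma must be >= 0")
        if not 0.0 <= self.frac_high_risk_in_case <= 1.0:
            raise ParameterError("frac_high_risk_in_case must be in [0, 1]")


@dataclass(frozen=True)
class BulkSimParams:
    """Parameters of the bulk cohort simulator (Gaussian features)."""

    n_samples_per_cohort: int = 65
    n_features: int = 64
    n_informative: int = 10
    informative_effect: float = 2.5
    batch_offset: float = 0.5
    noise_sd: float = 1.0
    case_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_cohort < 2:
            raise ParameterError("n_samples_per_cohort must be >= 2")
        if self.n_features < 1:
            raise ParameterError("n_features must be >= 1")
        if not 0 <= self.n_informative <= self.n_features:
            raise ParameterError("n_informative must be in [0, n_features]")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if not 0.0 < self.case_fraction < 1.0:
            raise ParameterError("case_fraction must be in (0, 1)")


@dataclass
class PlantedTruth:
    """Ground truth planted by the simulators; ids resolve against the data."""

    sig_up_genes: list[str] = field(default_factory=list)
    sig_down_genes: list[str] = field(default_factory=list)
    informative_genes: list[str] = field(default_factory=list)
    high_risk_cell_ids: list[str] = field(default_factory=list)
    monotone_pseudotime_genes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        return cls(**json.loads(text))


def gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def simulate_sc(params: SCSimParams) -> tuple[ad.AnnData, PlantedTruth]:
    """Simulate a two-condition neutrophil count matrix with planted truth.

    Returns an :class:`anndata.AnnData` (cells x genes, integer counts in
    ``.X``, obs columns ``condition``, ``cell_type``, ``sample``,
    ``high_risk``, ``latent``) and the :class:`PlantedTruth`.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    n_per = params.n_cells_per_condition
    n_cells = 2 * n_per
    genes = gene_ids(params.n_genes)

    up = slice(0, params.n_sig_up)
    down = slice(params.n_sig_up, params.n_sig_up + params.n_sig_down)
    mono = slice(
        params.n_sig_up + params.n_sig_down,
        params.n_sig_up + params.n_sig_down + params.n_monotone,
    )

    # Background genes get a lognormal baseline (median ~3 counts); planted
    # signature genes get moderately-expressed baselines, as real marker
    # genes do, and monotone genes sit a little higher so their ramp stays
    # detectable above counting noise. The heavy background mass keeps the
    # compositional dilution caused by the monotone ramp small.
    base_mean = rng.lognormal(mean=1.0, sigma=1.0, size=params.n_genes)
    n_sig = params.n_sig_up + params.n_sig_down
    base_mean[:n_sig] = rng.uniform(5.0, 15.0, size=n_sig)
    base_mean[n_sig:n_sig + params.n_monotone] = rng.uniform(
        10.0, 20.0, size=params.n_monotone
    )

    condition = np.array(
        [CONTROL_CONDITION] * n_per + [CASE_CONDITION] * n_per
    )
    is_case = condition == CASE_CONDITION

    # High-risk cells are the top of the differentiation latent, and exist
    # only in the case condition.
    n_high = int(round(params.frac_high_risk_in_case * n_per))
    high_risk = np.zeros(n_cells, dtype=bool)
    case_idx = np.flatnonzero(is_case)
    high_idx = rng.choice(case_idx, size=n_high, replace=False)
    high_risk[high_idx] = True

    latent = rng.uniform(0.0, _LATENT_SPLIT, size=n_cells)
    latent[high_risk] = rng.uniform(_LATENT_SPLIT, 1.0, size=n_high)

    lib = rng.lognormal(mean=0.0, sigma=params.libsize_lognormal_sigma, size=n_cells)

    mu = np.outer(lib, base_mean)
    fold = 2.0 ** params.effect_log2fc
    mu[np.ix_(high_risk, np.arange(params.n_genes)[up])] *= fold
    mu[np.ix_(high_risk, np.arange(params.n_genes)[down])] /= fold
    # Monotone ramp: linear in the latent, 1x at latent 0 to 8**effect at 1.
    amp = 8.0 ** params.effect_log2fc - 1.0
    ramp = 1.0 + amp * latent
    mu[:, mono] = mu[:, mono] * ramp[:, None]

    shape = 1.0 / params.nb_dispersion
    lam = rng.gamma(shape, mu * params.nb_dispersion)
    counts = rng.poisson(lam)

    cell_ids = [f"c{i:05d}" for i in range(n_cells)]
    # Three pseudo-samples per condition, round-robin.
    sample = np.array(
        [f"{c}_s{i % 3 + 1}" for i, c in enumerate(condition)]
    )
    obs = pd.DataFrame(
        {
            "condition": pd.Categorical(condition),
            "cell_type": pd.Categorical(["neutrophil"] * n_cells),
            "sample": sample,
            "high_risk": high_risk,
            "latent": latent,
        },
        index=cell_ids,
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.float64)),
        obs=obs,
        var=pd.DataFrame(index=genes),
    )

    truth = PlantedTruth(
        sig_up_genes=genes[up],
        sig_down_genes=genes[down],
        monotone_pseudotime_genes=genes[mono],
        high_risk_cell_ids=[cell_ids[i] for i in np.flatnonzero(high_risk)],
    )
    return adata, truth


@dataclass
class BulkCohort:
    """One bulk cohort: samples x genes expression plus binary labels."""

    name: str
    expr: pd.DataFrame
    labels: pd.Series  # 1 = case (ICH), 0 = control (HBP)


def simulate_bulk(
    params: BulkSimParams,
    gene_names: list[str] | None = None,
    informative_genes: list[str] | None = None,
) -> tuple[BulkCohort, BulkCohort, PlantedTruth]:
    """Simulate two bulk cohorts with a planted outcome signal.

    ``gene_names`` / ``informative_genes`` let the caller align the bulk
    feature space with the single-cell gene universe (informative genes are
    normally drawn from the single-cell monotone set). When omitted, fresh
    ids are generated and the first ``n_informative`` genes are informative.
    Cohort 2 receives a constant additive ``batch_offset`` on every feature.
    """
    params.validate()
    if gene_names is None:
        gene_names = gene_ids(params.n_features)
    if len(gene_names) != params.n_features:
        raise ParameterError(
            f"n_features={params.n_features} but {len(gene_names)} gene names given"
        )
    if informative_genes is None:
        informative_genes = gene_names[: params.n_informative]
    missing = set(informative_genes) - set(gene_names)
    if missing:
        raise ParameterError(f"informative genes absent from feature space: {sorted(missing)}")
    if len(informative_genes) != params.n_informative:
        raise ParameterError(
            f"n_informative={params.n_informative} but {len(informative_genes)} informative genes given"
        )

    rng = np.random.default_rng(params.seed)
    baseline = rng.uniform(0.2, 0.8, size=params.n_features)
    info_mask = np.isin(np.asarray(gene_names), np.asarray(informative_genes))

    cohorts = []
    for c, offset in (("cohort1", 0.0), ("cohort2", params.batch_offset)):
        n = params.n_samples_per_cohort
        n_case = int(round(params.case_fraction * n))
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=n_case, replace=False)] = 1
        mean = baseline[None, :] + offset
        mean = np.repeat(mean, n, axis=0)
        mean[np.ix_(y == 1, np.flatnonzero(info_mask))] += params.informative_effect
        x = mean + rng.normal(0.0, params.noise_sd, size=(n, params.n_features))
        idx = [f"{c}_sample{i:03d}" for i in range(n)]
        cohorts.append(
            BulkCohort(
                name=c,
                expr=pd.DataFrame(x, index=idx, columns=list(gene_names)),
                labels=pd.Series(y, index=idx, name="label"),
            )
        )

    truth = PlantedTruth(informative_genes=list(informative_genes))
    return cohorts[0], cohorts[1], truth
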