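"""Approximate Bayesian Computation over the coevolution and neutral models.

Two inference scenarios are supported.  Scenario 1 treats the cost of
infection ``s`` and the two population sizes as unknown (costs of
resistance/infectivity fixed at 0.05/0.1); scenario 2 treats the three
costs as unknown at fixed population sizes (N = 10,000, theta = 5).  For
each model, reference-table rows pair a prior draw with the average of the
17 summary statistics over ``r`` independent replicate histories --
coevolution rows run the full forward-backward pipeline, neutral rows run
unconditioned discrete Kingman genealogies per species.

Model choice follows rejection ABC on MAD-standardized statistics with a
1% retention fraction, evaluated by leave-one-out cross-validation
(confusion matrix, FNR/FPR).  Parameter estimation retains the 1,000
closest coevolution rows in unnormalized Euclidean distance, applies a
local-linear regression adjustment to the observed statistics, smooths
with a Gaussian kernel (width 0.01 on the prior-range-normalized parameter
scale) and reports posterior medians; estimation can use host statistics,
parasite statistics, or both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coalescent import drop_mutations, neutral_genealogy, simulate_genealogy
from .dynamics import GFGParams
from .forward import (
    DEFAULT_LOCUS_LENGTH,
    DEFAULT_MU_SITE,
    DEFAULT_SAMPLE_SIZE,
    PopulationConfig,
    SimulationSettings,
    simulate_frequency_path,
)
from .sumstats import (
    STAT_COLUMNS,
    SumStatVector,
    replicate_average,
    statistics_from_matrices,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioPrior",
    "ReferenceTable",
    "ModelChoiceResult",
    "ConfusionMatrix",
    "ParamPosterior",
    "draw_prior",
    "simulate_reference_entry",
    "build_reference_table",
    "model_choice",
    "cross_validate",
    "estimate_parameters",
]

HOST_COLUMNS = tuple(c for c in STAT_COLUMNS if c.startswith("host_"))
PARA_COLUMNS = tuple(c for c in STAT_COLUMNS if c.startswith("para_"))
_SUBSETS = {
    "joint": STAT_COLUMNS,
    "host_only": HOST_COLUMNS,
    "parasite_only": PARA_COLUMNS,
}

PARAM_COLUMNS = ("s", "c_H", "c_P", "N_H", "N_P")


@dataclass(frozen=True)
class ScenarioPrior:
    """Priors and fixed parameters of one inference scenario.

    Scenario 1: ``s ~ U(0.1, 0.9)``, ``N_H, N_P ~ logU(2000, 40000)``,
    ``c_H = 0.05``, ``c_P = 0.1``; the neutral model draws only the two
    population sizes.  Scenario 2: ``N_H = N_P = 10,000`` (theta = 5),
    ``s ~ U(0.1, 0.9)``, ``c_H, c_P ~ U(0.01, 0.35)``; the neutral model
    has no free parameters.  ``theta`` is always ``2 N L mu_site``.
    """

    scenario: int
    g_max_override: Optional[int] = None
    r: int = 30
    n: int = DEFAULT_SAMPLE_SIZE
    L: int = DEFAULT_LOCUS_LENGTH
    mu_site: float = DEFAULT_MU_SITE

    S_RANGE = (0.1, 0.9)
    COST_RANGE = (0.01, 0.35)
    N_RANGE = (2_000, 40_000)
    FIXED_N = 10_000
    SCEN1_C_H = 0.05
    SCEN1_C_P = 0.1

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        if self.r < 1:
            raise ValueError("r must be >= 1")

    def free_parameters(self, model: str) -> Tuple[str, ...]:
        if model == "coevolution":
            return ("s", "N_H", "N_P") if self.scenario == 1 else ("s", "c_H", "c_P")
        if model == "neutral":
            return ("N_H", "N_P") if self.scenario == 1 else ()
        raise ValueError(f"unknown model {model!r}")

    def support(self, name: str) -> Tuple[float, float]:
        if name == "s":
            return self.S_RANGE
        if name in ("c_H", "c_P"):
            return self.COST_RANGE
        if name in ("N_H", "N_P"):
            return self.N_RANGE
        raise KeyError(name)


def draw_prior(prior: ScenarioPrior, model: str, rng: np.random.Generator) -> Dict[str, float]:
    """One parameter draw for the given model under the scenario's priors.

    Log-uniform population sizes are drawn as ``exp(U(log lo, log hi))``
    and rounded to integers.  The returned dict always carries the full
    parameter set (fixed values filled in).
    """
    draw: Dict[str, float] = {}
    if prior.scenario == 1:
        draw["c_H"], draw["c_P"] = prior.SCEN1_C_H, prior.SCEN1_C_P
        lo, hi = prior.N_RANGE
        draw["N_H"] = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        draw["N_P"] = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        draw["s"] = float(rng.uniform(*prior.S_RANGE)) if model == "coevolution" else 0.0
    else:
        draw["N_H"] = draw["N_P"] = prior.FIXED_N
        if model == "coevolution":
            draw["s"] = float(rng.uniform(*prior.S_RANGE))
            draw["c_H"] = float(rng.uniform(*prior.COST_RANGE))
            draw["c_P"] = float(rng.uniform(*prior.COST_RANGE))
        else:
            draw["s"] = draw["c_H"] = draw["c_P"] = 0.0
    return draw


def _coevolution_replicate(
    params: GFGParams,
    config: PopulationConfig,
    settings: SimulationSettings,
    rng: np.random.Generator,
) -> SumStatVector:
    host_path, para_path = simulate_frequency_path(params, config, settings, rng)
    host_tree = simulate_genealogy(host_path, params, config.n_H, rng)
    para_tree = simulate_genealogy(para_path, params, config.n_P, rng)
    return statistics_from_matrices(
        drop_mutations(host_tree, config, rng),
        drop_mutations(para_tree, config, rng),
    )


def _neutral_replicate(config: PopulationConfig, rng: np.random.Generator) -> SumStatVector:
    host_tree = neutral_genealogy(config.N_H, config.n_H, rng, species="host")
    para_tree = neutral_genealogy(config.N_P, config.n_P, rng, species="parasite")
    return statistics_from_matrices(
        drop_mutations(host_tree, config, rng),
        drop_mutations(para_tree, config, rng),
    )


def simulate_reference_entry(
    draw: Dict[str, float],
    prior: ScenarioPrior,
    model: str,
    rng: np.random.Generator,
    r: Optional[int] = None,
) -> SumStatVector:
    """Average of the 17 statistics over ``r`` independent replicates.

    Coevolution: each replicate is one forward frequency path, two
    conditioned genealogies and two SNP matrices.  Neutral: each replicate
    is two unconditioned Kingman genealogies at the drawn/fixed population
    sizes.  Both models share the sample sizes, locus length and neutral
    mutation rate, and the same replicate-averaging, mirroring the
    pseudo-observed data.
    """
    r = prior.r if r is None else r
    config = PopulationConfig(
        N_H=int(draw["N_H"]), N_P=int(draw["N_P"]),
        n_H=prior.n, n_P=prior.n, L=prior.L, mu_site=prior.mu_site,
    )
    reps: List[SumStatVector] = []
    if model == "coevolution":
        params = GFGParams(s=draw["s"], c_H=draw["c_H"], c_P=draw["c_P"])
        settings = SimulationSettings(g_max=prior.g_max_override, r=1)
        for stream in rng.spawn(r):
            reps.append(_coevolution_replicate(params, config, settings, stream))
    elif model == "neutral":
        for stream in rng.spawn(r):
            reps.append(_neutral_replicate(config, stream))
    else:
        raise ValueError(f"unknown model {model!r}")
    return replicate_average(reps)


@dataclass
class ReferenceTable:
    """Model labels, parameter draws and averaged statistics as a DataFrame.

    Columns: ``model`` plus :data:`PARAM_COLUMNS` plus the 17 statistic
    columns.  All rows share the scenario and replicate count ``r``.
    """

    data: pd.DataFrame
    scenario: int
    r: int

    REQUIRED = ("model",) + PARAM_COLUMNS + STAT_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"reference table misses columns {missing}")
        if self.data[list(STAT_COLUMNS)].isna().any().any():
            raise ValueError("reference table contains missing statistics")

    def rows_for(self, model: str) -> pd.DataFrame:
        return self.data[self.data["model"] == model]

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out["r"] = self.r
        out["scenario"] = self.scenario
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        df = pd.read_csv(path, sep="\t")
        r = int(df.pop("r").iloc[0]) if "r" in df else 1
        scenario = int(df.pop("scenario").iloc[0]) if "scenario" in df else 1
        return cls(data=df, scenario=scenario, r=r)


def build_reference_table(
    prior: ScenarioPrior,
    n_per_model: int,
    rng: np.random.Generator,
    models: Sequence[str] = ("coevolution", "neutral"),
    progress: bool = False,
) -> ReferenceTable:
    """Simulate a reference table with ``n_per_model`` rows per model."""
    records = []
    for model in models:
        for i in range(n_per_model):
            draw = draw_prior(prior, model, rng)
            stats = simulate_reference_entry(draw, prior, model, rng)
            rec = {"model": model, **{k: draw.get(k, 0.0) for k in PARAM_COLUMNS}}
            rec.update(dict(zip(STAT_COLUMNS, stats.to_array())))
            records.append(rec)
            if progress and (i + 1) % 100 == 0:
                logger.info("%s: %d/%d rows", model, i + 1, n_per_model)
    return ReferenceTable(data=pd.DataFrame.from_records(records), scenario=prior.scenario, r=prior.r)


@dataclass(frozen=True)
class ModelChoiceResult:
    """Posterior model probabilities from rejection ABC."""

    posterior: Dict[str, float]
    retained_indices: np.ndarray
    tolerance: float

    @property
    def best_model(self) -> str:
        return max(self.posterior, key=self.posterior.get)


def _mad_normalize(stats: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Columnwise MAD standardization; zero-MAD columns are dropped."""
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    keep = mad > 0
    if not keep.all():
        dropped = [STAT_COLUMNS[j] for j in np.flatnonzero(~keep) if j < len(STAT_COLUMNS)]
        logger.warning("dropping zero-MAD statistic columns: %s", dropped)
    return stats[:, keep] / mad[keep], mad, keep


def model_choice(
    observed: SumStatVector,
    table: ReferenceTable,
    tolerance: float = 0.01,
) -> ModelChoiceResult:
    """Rejection-ABC model choice between coevolution and neutrality.

    All 17 statistics are standardized by their median absolute deviation
    computed over the pooled two-model table; the
    ``ceil(tolerance * rows)`` rows closest to the observation in Euclidean
    distance are retained, and each model's posterior probability is its
    share among the retained rows.
    """
    models = table.data["model"].to_numpy()
    if len(set(models)) < 2:
        raise ValueError("model choice requires both models in the table")
    stats = table.data[list(STAT_COLUMNS)].to_numpy(dtype=float)
    normed, mad, keep = _mad_normalize(stats)
    if not keep.any():
        raise ValueError("all statistic columns have zero MAD")
    obs = observed.to_array()[keep] / mad[keep]
    d2 = np.sum((normed - obs) ** 2, axis=1)
    n_keep = math.ceil(tolerance * len(d2))
    retained = np.argsort(d2, kind="stable")[:n_keep]
    labels, counts = np.unique(models[retained], return_counts=True)
    post = {m: 0.0 for m in np.unique(models)}
    for lab, cnt in zip(labels, counts):
        post[lab] = cnt / n_keep
    return ModelChoiceResult(posterior=post, retained_indices=retained, tolerance=tolerance)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Leave-one-out cross-validation tallies for ABC model choice.

    ``FNR`` is the percentage of truly coevolving validation rows
    classified neutral; ``FPR`` the percentage of truly neutral rows
    classified coevolving.
    """

    correct: Dict[str, int]
    incorrect: Dict[str, int]

    @property
    def fnr_percent(self) -> float:
        tot = self.correct["coevolution"] + self.incorrect["coevolution"]
        return 100.0 * self.incorrect["coevolution"] / tot if tot else float("nan")

    @property
    def fpr_percent(self) -> float:
        tot = self.correct["neutral"] + self.incorrect["neutral"]
        return 100.0 * self.incorrect["neutral"] / tot if tot else float("nan")

    def to_dict(self) -> dict:
        return {
            "correct": dict(self.correct),
            "incorrect": dict(self.incorrect),
            "fnr_percent": self.fnr_percent,
            "fpr_percent": self.fpr_percent,
        }


def cross_validate(
    table: ReferenceTable,
    rng: np.random.Generator,
    n_val: int = 500,
    tolerance: float = 0.01,
) -> ConfusionMatrix:
    """Leave-one-out cross-validation of the rejection model choice.

    For ``n_val`` randomly chosen rows per model: remove the row, run
    :func:`model_choice` against the remainder, classify by the larger
    posterior.  MAD standardization is computed once over the full table
    (removing a single row perturbs the medians negligibly).
    """
    models = table.data["model"].to_numpy()
    stats = table.data[list(STAT_COLUMNS)].to_numpy(dtype=float)
    normed, mad, keep = _mad_normalize(stats)
    correct = {"coevolution": 0, "neutral": 0}
    incorrect = {"coevolution": 0, "neutral": 0}
    n_rows = len(models)
    n_keep = math.ceil(tolerance * (n_rows - 1))
    for true_model in ("coevolution", "neutral"):
        pool = np.flatnonzero(models == true_model)
        if len(pool) < 1:
            raise ValueError(f"table has no rows for model {true_model!r}")
        chosen = rng.choice(pool, size=min(n_val, len(pool)), replace=False)
        for idx in chosen:
            d2 = np.sum((normed - normed[idx]) ** 2, axis=1)
            d2[idx] = np.inf  # leave the validation row out
            retained = np.argpartition(d2, n_keep)[:n_keep]
            n_coev = int(np.sum(models[retained] == "coevolution"))
            if n_coev * 2 == n_keep:  # posterior tie: fair coin
                predicted = "coevolution" if rng.random() < 0.5 else "neutral"
            else:
                predicted = "coevolution" if n_coev * 2 > n_keep else "neutral"
            if predicted == true_model:
                correct[true_model] += 1
            else:
                incorrect[true_model] += 1
    return ConfusionMatrix(correct=correct, incorrect=incorrect)


@dataclass(frozen=True)
class ParamPosterior:
    """Marginal posterior summary for one parameter.

    ``retained`` are the raw rejection-step values, ``adjusted`` the
    regression-adjusted values (clamped to the prior support),
    ``median`` the median of the Gaussian-kernel-smoothed marginal density,
    and ``stat_subset`` records which statistics were used.
    """

    name: str
    retained: np.ndarray
    adjusted: np.ndarray
    median: float
    stat_subset: str
    support: Tuple[float, float]


def _smoothed_median(values: np.ndarray, support: Tuple[float, float], width: float = 0.01) -> float:
    """Median of a Gaussian-KDE-smoothed sample on the normalized scale.

    The kernel width (the Dirac-peak width) is interpreted on the
    parameter scale normalized to its prior range, and the density is
    truncated to the support before the median is read off the CDF.
    """
    lo, hi = support
    span = hi - lo
    z = (values - lo) / span
    grid = np.linspace(0.0, 1.0, 2048)
    dens = np.exp(-0.5 * ((grid[None, :] - z[:, None]) / width) ** 2).sum(axis=0)
    cdf = np.cumsum(dens)
    if cdf[-1] == 0:
        return float(np.median(values))
    cdf /= cdf[-1]
    med = float(np.interp(0.5, cdf, grid))
    return lo + med * span


def estimate_parameters(
    observed: SumStatVector,
    table: ReferenceTable,
    rng: Optional[np.random.Generator] = None,
    n_retain: int = 1000,
    stat_subset: str = "joint",
    kernel_width: float = 0.01,
    supports: Optional[Dict[str, Tuple[float, float]]] = None,
) -> Dict[str, ParamPosterior]:
    """Rejection + local-linear regression-adjusted parameter estimation.

    Retains the ``n_retain`` coevolution rows closest to the observation in
    *unnormalized* Euclidean distance on the selected statistic columns
    (all 17 for ``joint``; 8 host or 8 parasite columns otherwise -- PMD is
    a cross-species statistic and enters only the joint set).  For each
    free parameter, a linear regression on the selected statistics shifts
    the retained values to the observed statistics; adjusted values are
    clamped to the prior support, smoothed with a Gaussian kernel of width
    ``kernel_width`` on the range-normalized scale, and summarized by the
    posterior median.

    Constant statistic columns are dropped from the regression with a
    warning; if all columns are dropped the estimate falls back to pure
    rejection.
    """
    if stat_subset not in _SUBSETS:
        raise ValueError(f"stat_subset must be one of {sorted(_SUBSETS)}")
    cols = list(_SUBSETS[stat_subset])
    coev = table.rows_for("coevolution")
    if len(coev) < n_retain:
        raise ValueError(f"need >= {n_retain} coevolution rows, have {len(coev)}")
    prior = ScenarioPrior(scenario=table.scenario, r=table.r)
    free = prior.free_parameters("coevolution")

    stats = coev[cols].to_numpy(dtype=float)
    obs_full = observed.to_array()
    obs = obs_full[[STAT_COLUMNS.index(c) for c in cols]]
    d2 = np.sum((stats - obs) ** 2, axis=1)
    order = np.argsort(d2, kind="stable")[:n_retain]
    X = stats[order]
    result: Dict[str, ParamPosterior] = {}

    # regression design: drop constant columns, add intercept
    spread = X.max(axis=0) - X.min(axis=0)
    keep = spread > 0
    if not keep.all():
        logger.warning(
            "estimate_parameters: dropping constant columns %s",
            [cols[j] for j in np.flatnonzero(~keep)],
        )
    for name in free:
        theta = coev[name].to_numpy(dtype=float)[order]
        if keep.any():
            design = np.column_stack([np.ones(n_retain), X[:, keep]])
            beta, *_ = np.linalg.lstsq(design, theta, rcond=None)
            adjusted = theta - (X[:, keep] - obs[keep]) @ beta[1:]
        else:
            logger.warning("all statistic columns constant; falling back to rejection")
            adjusted = theta.copy()
        support = (supports or {}).get(name) or prior.support(name)
        adjusted = np.clip(adjusted, *support)
        median = _smoothed_median(adjusted, support, kernel_width)
        result[name] = ParamPosterior(
            name=name,
            retained=theta,
            adjusted=adjusted,
            median=float(median),
            stat_subset=stat_subset,
            support=support,
        )
    return result
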