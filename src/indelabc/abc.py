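"""Rejection-ABC estimation of indel model parameters.

The scheme: simulate ``n_sims`` alignments with parameters drawn from
the prior, summarize each with the 27 gap-pattern statistics, measure a
weighted Euclidean distance to the observed statistics, keep the
fraction ``acceptance_fraction`` of simulations with the smallest
distances, and report the arithmetic mean of the accepted parameter
draws as the posterior point estimate.

Weights make statistics of different magnitudes contribute comparably:
w_j = 1 / sd_j^2 with sd_j the standard deviation of statistic j across
``n_weight_sims`` independent prior simulations. A statistic with zero
variance under the prior carries no information and gets weight 0.

The model surface follows the statsmodels convention: build a
:class:`RejectionABC` from data, call :meth:`~RejectionABC.fit`, and
read estimates and diagnostics off the returned :class:`AbcResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .msa import Msa
from .params import (
    SIM,
    RIM,
    IndelParams,
    PriorConfig,
    param_names,
    sample_prior,
)
from .simulator import simulate_gap_matrix
from .stats import N_STATS, STAT_NAMES, compute_summary_vector, summary_from_gap_matrix
from .trees import PhyloTree

logger = logging.getLogger(__name__)

POOLED = "pooled"


@dataclass(frozen=True)
class AbcConfig:
    """Tuning constants of the rejection sampler.

    Defaults are the full-scale settings (100,000 simulations, 0.1%
    acceptance, 10,000 weight-calibration simulations); the ``desk``
    profile trades accuracy for interactive runtimes.
    """

    n_sims: int = 100_000
    acceptance_fraction: float = 0.001
    n_weight_sims: int = 10_000
    n_train: int = 200  # correction-model training simulations

    def __post_init__(self) -> None:
        if not (0 < self.acceptance_fraction <= 1):
            raise ValueError("acceptance_fraction must be in (0, 1]")
        if self.n_accept < 1:
            raise ValueError("acceptance_fraction * n_sims must be >= 1")
        if self.n_weight_sims < 2:
            raise ValueError("n_weight_sims must be >= 2")

    @property
    def n_accept(self) -> int:
        return int(round(self.acceptance_fraction * self.n_sims))

    @classmethod
    def full_profile(cls) -> "AbcConfig":
        """The full-scale default settings."""
        return cls()

    @classmethod
    def desk_profile(cls) -> "AbcConfig":
        """Reduced-scale settings for interactive use and testing."""
        return cls(
            n_sims=10_000,
            acceptance_fraction=0.01,
            n_weight_sims=2_000,
            n_train=50,
        )


@dataclass(frozen=True)
class WeightVector:
    """Per-statistic weights w_j = 1/sd_j^2 with an exclusion mask.

    ``weights[j] == 0`` iff statistic j is excluded (masked by a
    correction model) or had zero variance across the calibration
    simulations.
    """

    weights: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        if self.weights.shape != (N_STATS,):
            raise ValueError("weight vector must have length 27")

    @property
    def retained(self) -> np.ndarray:
        return self.weights > 0


def _simulate_summary(tree, params, rng, max_indel_len) -> np.ndarray:
    gap = simulate_gap_matrix(tree, params, rng, max_indel_len=max_indel_len)
    return summary_from_gap_matrix(gap)


@dataclass
class ReferenceTable:
    """Prior draws with their simulated (optionally corrected) statistics.

    ``models`` records the generating model of each row, which matters
    only for pooled tables used in model selection.
    """

    model: str
    param_names: tuple[str, ...]
    params: np.ndarray  # (n, k)
    stats: np.ndarray  # (n, 27)
    models: Optional[np.ndarray] = None  # per-row model labels if pooled

    @property
    def n(self) -> int:
        return self.stats.shape[0]


def generate_reference_table(
    tree: PhyloTree,
    model: str,
    prior: PriorConfig,
    n: int,
    rng: np.random.Generator,
    correction=None,
) -> ReferenceTable:
    """Simulate ``n`` prior draws and their summary statistics.

    If a correction model is given, each simulated (true-alignment)
    statistic vector is replaced by its predicted post-alignment value,
    so distances are comparable with statistics of an alignment inferred
    by an alignment program.
    """
    names = param_names(model)
    params = np.empty((n, len(names)), dtype=np.float64)
    stats = np.empty((n, N_STATS), dtype=np.float64)
    for i in range(n):
        p = sample_prior(model, prior, rng)
        params[i] = p.as_vector()
        stats[i] = _simulate_summary(tree, p, rng, prior.max_indel_len)
    if correction is not None:
        stats = correction.predict_matrix(stats, params)
    return ReferenceTable(model=model, param_names=names, params=params, stats=stats)


def estimate_weights(
    tree: PhyloTree,
    prior: PriorConfig,
    model: str,
    config: AbcConfig,
    rng: np.random.Generator,
    correction=None,
) -> WeightVector:
    """Weight calibration: 1/sd^2 over ``n_weight_sims`` prior draws.

    ``model`` may be "SIM", "RIM" or "pooled" (a 50/50 mixture of the
    two, used for model selection so distances are comparable across the
    pooled table). With a correction model (or a per-model dict of them
    for "pooled"), SDs are computed on corrected statistics and masked
    statistics get weight 0.
    """
    B = config.n_weight_sims
    if model == POOLED:
        corr = correction or {}
        half = B // 2
        tab_sim = generate_reference_table(
            tree, SIM, prior, half, rng, corr.get(SIM)
        )
        tab_rim = generate_reference_table(
            tree, RIM, prior, B - half, rng, corr.get(RIM)
        )
        stats = np.vstack([tab_sim.stats, tab_rim.stats])
        masks = [
            c.retained_mask for c in (corr.get(SIM), corr.get(RIM)) if c is not None
        ]
        mask = np.logical_and.reduce(masks) if masks else np.ones(N_STATS, bool)
    else:
        tab = generate_reference_table(tree, model, prior, B, rng, correction)
        stats = tab.stats
        mask = (
            correction.retained_mask if correction is not None
            else np.ones(N_STATS, bool)
        )
    sds = stats.std(axis=0, ddof=1)
    weights = np.zeros(N_STATS)
    nonzero = sds > 0
    weights[nonzero] = 1.0 / sds[nonzero] ** 2
    for j in np.flatnonzero(~nonzero):
        logger.warning(
            "summary statistic %d (%s) is constant across the %d "
            "calibration simulations; weight set to 0", j + 1, STAT_NAMES[j], B
        )
    weights[~mask] = 0.0
    return WeightVector(weights=weights, sds=sds)


def weighted_distance(
    s_obs: np.ndarray, s_sim: np.ndarray, w: WeightVector | np.ndarray
) -> float:
    """sqrt( sum_j w_j (s_obs_j - s_sim_j)^2 )."""
    wv = w.weights if isinstance(w, WeightVector) else np.asarray(w, float)
    diff = np.asarray(s_obs, float) - np.asarray(s_sim, float)
    return float(np.sqrt(np.sum(wv * diff * diff)))


def _distance_matrix(s_obs: np.ndarray, stats: np.ndarray, weights: np.ndarray):
    diff = stats - s_obs[None, :]
    return np.sqrt((diff * diff) @ weights)


def _accept(distances: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest distances, ties broken by simulation
    order (stable sort)."""
    return np.argsort(distances, kind="stable")[:k]


def _observed_vector(observed) -> np.ndarray:
    if isinstance(observed, Msa):
        return compute_summary_vector(observed)
    arr = np.asarray(observed, dtype=float)
    if arr.shape != (N_STATS,):
        raise ValueError("observed summary vector must have length 27")
    return arr


class RejectionABC:
    """Rejection-ABC model for one indel model and one data set.

    Parameters
    ----------
    observed : Msa or length-27 summary vector
        The observed alignment (or its precomputed statistics).
    tree : PhyloTree
        Rooted tree with branch lengths in substitutions/site.
    model : "SIM" or "RIM"
    prior : PriorConfig, optional
        Defaults to the standard prior with the root-length range
        derived from the observed alignment (requires an Msa).
    config : AbcConfig, optional (default: full-scale profile)
    correction : CorrectionModel, optional
        Maps true-alignment statistics of each simulation to expected
        post-alignment values.

    Examples
    --------
    >>> model = RejectionABC(msa, tree, model="RIM",
    ...                      config=AbcConfig.desk_profile())
    >>> res = model.fit(seed=1)
    >>> res.params  # posterior means           # doctest: +SKIP
    """

    def __init__(
        self,
        observed,
        tree: PhyloTree,
        model: str = RIM,
        prior: Optional[PriorConfig] = None,
        config: Optional[AbcConfig] = None,
        correction=None,
    ):
        if model not in (SIM, RIM):
            raise ValueError(f"model must be SIM or RIM, got {model!r}")
        self.s_obs = _observed_vector(observed)
        self.tree = tree
        self.model = model
        if prior is None:
            if not isinstance(observed, Msa):
                raise ValueError(
                    "prior required when observed is a bare summary vector"
                )
            prior = PriorConfig.from_msa(observed)
        self.prior = prior
        self.config = config or AbcConfig()
        self.correction = correction

    @classmethod
    def from_files(cls, msa_path, tree_path, **kwargs) -> "RejectionABC":
        from .msa import read_msa
        from .trees import read_tree

        return cls(read_msa(msa_path), read_tree(tree_path), **kwargs)

    def fit(
        self,
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        weights: Optional[WeightVector] = None,
        pool: Optional[ReferenceTable] = None,
    ) -> "AbcResults":
        """Run the rejection sampler.

        ``weights`` and ``pool`` allow reuse of a precomputed weight
        vector or reference table (e.g. across replicate analyses on the
        same tree and prior); by default both are generated afresh.
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        if weights is None:
            weights = estimate_weights(
                self.tree, self.prior, self.model, self.config, rng,
                self.correction,
            )
        if pool is None:
            pool = generate_reference_table(
                self.tree, self.model, self.prior, self.config.n_sims, rng,
                self.correction,
            )
        distances = _distance_matrix(self.s_obs, pool.stats, weights.weights)
        k = int(round(self.config.acceptance_fraction * pool.n))
        idx = _accept(distances, max(k, 1))
        accepted = pd.DataFrame(pool.params[idx], columns=pool.param_names)
        accepted["distance"] = distances[idx]
        return AbcResults(
            model=self.model,
            accepted=accepted,
            distances=distances,
            weights=weights,
            config=self.config,
            prior=self.prior,
            s_obs=self.s_obs,
        )


@dataclass
class AbcResults:
    """Output of one rejection-ABC fit.

    ``params`` holds the posterior mean of every model parameter (the
    arithmetic mean over accepted draws); ``accepted`` the accepted
    draws themselves with their distances; ``distances`` the full
    distance distribution for diagnostics.
    """

    model: str
    accepted: pd.DataFrame
    distances: np.ndarray
    weights: WeightVector
    config: AbcConfig
    prior: PriorConfig
    s_obs: np.ndarray

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    @property
    def params(self) -> pd.Series:
        cols = [c for c in self.accepted.columns if c != "distance"]
        return self.accepted[cols].mean()

    @property
    def params_sd(self) -> pd.Series:
        cols = [c for c in self.accepted.columns if c != "distance"]
        return self.accepted[cols].std(ddof=1)

    def posterior_quantiles(self, q=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        cols = [c for c in self.accepted.columns if c != "distance"]
        return self.accepted[cols].quantile(list(q))

    def summary(self) -> str:
        lines = [
            f"Rejection-ABC results ({self.model})",
            f"  simulations: {len(self.distances)}   accepted: "
            f"{self.n_accepted}   max accepted distance: "
            f"{self.accepted['distance'].max():.4g}",
            "",
            f"  {'parameter':<12}{'post. mean':>12}{'post. sd':>12}",
        ]
        for name, mean in self.params.items():
            sd = self.params_sd[name]
            lines.append(f"  {name:<12}{mean:>12.5g}{sd:>12.4g}")
        used = int(self.weights.retained.sum())
        lines.append("")
        lines.append(f"  summary statistics used: {used}/27")
        return "\n".join(lines)

    def plot_posterior(self, param: str, ax=None, bins: int = 20):
        """Histogram of the accepted draws of one parameter."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.accepted[param], bins=bins, density=True, alpha=0.7)
        ax.axvline(self.params[param], color="k", ls="--", label="posterior mean")
        ax.set_xlabel(param)
        ax.set_ylabel("posterior density")
        ax.legend()
        return ax


def run_rejection(
    s_obs,
    tree: PhyloTree,
    model: str,
    prior: PriorConfig,
    config: AbcConfig,
    rng: np.random.Generator,
    correction=None,
    weights: Optional[WeightVector] = None,
    pool: Optional[ReferenceTable] = None,
) -> AbcResults:
    """Functional wrapper around :class:`RejectionABC`."""
    m = RejectionABC(
        s_obs, tree, model=model, prior=prior, config=config, correction=correction
    )
    return m.fit(rng=rng, weights=weights, pool=pool)


def feature_importance(
    s_obs,
    truth: IndelParams,
    tree: PhyloTree,
    model: str,
    prior: PriorConfig,
    config: AbcConfig,
    rng: np.random.Generator,
    weights: Optional[WeightVector] = None,
    pool: Optional[ReferenceTable] = None,
) -> pd.DataFrame:
    """Leave-one-statistic-out importance for each model parameter.

    For each statistic j, the acceptance step is rerun on the *same*
    simulation pool with w_j forced to 0; the importance of j for a
    parameter is the increase in absolute estimation error relative to
    the all-statistics run. Scores are noisy for a single data set and
    should be averaged over replicate data sets.
    """
    s_obs = _observed_vector(s_obs)
    if weights is None:
        weights = estimate_weights(tree, prior, model, config, rng)
    if pool is None:
        pool = generate_reference_table(tree, model, prior, config.n_sims, rng)
    k = max(int(round(config.acceptance_fraction * pool.n)), 1)
    truth_vec = truth.as_vector()

    def errors(w: np.ndarray) -> np.ndarray:
        d = _distance_matrix(s_obs, pool.stats, w)
        idx = _accept(d, k)
        est = pool.params[idx].mean(axis=0)
        return np.abs(est - truth_vec)

    base = errors(weights.weights)
    rows = np.zeros((N_STATS, len(truth_vec)))
    for j in range(N_STATS):
        if weights.weights[j] == 0:
            continue  # already absent: zero importance by definition
        w = weights.weights.copy()
        w[j] = 0.0
        rows[j] = errors(w) - base
    return pd.DataFrame(
        rows,
        index=[f"s{j + 1}" for j in range(N_STATS)],
        columns=list(pool.param_names),
    )
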