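"""ABC model choice between the simple and rich indel models.

A uniform prior over the two models is realized exactly by simulating
half the budget under each model. All simulations are pooled, ranked by
one shared weighted distance, and the closest fraction is retained; the
posterior probability of each model is its relative frequency among the
retained simulations.

The shared weight vector is calibrated on a 50/50 prior mixture of the
two models so that distances are comparable across the pooled table
(per-model weights would break the pooled ranking).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .abc import (
    POOLED,
    AbcConfig,
    ReferenceTable,
    WeightVector,
    _accept,
    _distance_matrix,
    _observed_vector,
    estimate_weights,
    generate_reference_table,
)
from .params import SIM, RIM, PriorConfig, param_names
from .trees import PhyloTree


@dataclass
class ModelPosterior:
    """Result of one ABC model-selection run.

    ``posterior`` maps model name to its retained frequency; counts sum
    to the acceptance quota and probabilities to 1.
    """

    counts: dict[str, int]
    posterior: dict[str, float]
    selected: str
    param_means: dict[str, pd.Series]
    n_pooled: int

    def summary(self) -> str:
        lines = [
            "ABC model selection (SIM vs RIM)",
            f"  pooled simulations: {self.n_pooled}   accepted: "
            f"{sum(self.counts.values())}",
        ]
        for m in (SIM, RIM):
            lines.append(
                f"  {m}: retained {self.counts[m]:>5d}   "
                f"P({m}|data) = {self.posterior[m]:.3f}"
            )
        lines.append(f"  selected model: {self.selected}")
        return "\n".join(lines)


def build_pooled_table(
    tree: PhyloTree,
    prior: PriorConfig,
    config: AbcConfig,
    rng: np.random.Generator,
    corrections: Optional[dict] = None,
) -> ReferenceTable:
    """Half the simulation budget under each model, pooled.

    Rows generated under SIM are embedded with their own 3 parameters
    (padded with NaN to the RIM width for storage); ``models`` labels
    each row's generating model.
    """
    corrections = corrections or {}
    half = config.n_sims // 2
    tab_sim = generate_reference_table(
        tree, SIM, prior, half, rng, corrections.get(SIM)
    )
    tab_rim = generate_reference_table(
        tree, RIM, prior, config.n_sims - half, rng, corrections.get(RIM)
    )
    k_sim, k_rim = tab_sim.params.shape[1], tab_rim.params.shape[1]
    width = max(k_sim, k_rim)
    params = np.full((config.n_sims, width), np.nan)
    params[:half, :k_sim] = tab_sim.params
    params[half:, :k_rim] = tab_rim.params
    models = np.array([SIM] * half + [RIM] * (config.n_sims - half))
    stats = np.vstack([tab_sim.stats, tab_rim.stats])
    return ReferenceTable(
        model=POOLED,
        param_names=param_names(RIM),
        params=params,
        stats=stats,
        models=models,
    )


def select_model(
    observed,
    tree: PhyloTree,
    prior: PriorConfig,
    config: AbcConfig,
    rng: np.random.Generator,
    corrections: Optional[dict] = None,
    weights: Optional[WeightVector] = None,
    pool: Optional[ReferenceTable] = None,
) -> ModelPosterior:
    """Choose between SIM and RIM for one observed alignment.

    ``corrections`` optionally maps model name to its CorrectionModel;
    each is applied to the simulations generated under that model.
    ``weights``/``pool`` allow reuse across replicate analyses.
    """
    s_obs = _observed_vector(observed)
    if weights is None:
        weights = estimate_weights(
            tree, prior, POOLED, config, rng, corrections
        )
    if pool is None:
        pool = build_pooled_table(tree, prior, config, rng, corrections)
    distances = _distance_matrix(s_obs, pool.stats, weights.weights)
    k = max(int(round(config.acceptance_fraction * pool.n)), 1)
    idx = _accept(distances, k)
    labels = pool.models[idx]
    counts = {m: int((labels == m).sum()) for m in (SIM, RIM)}
    posterior = {m: counts[m] / k for m in (SIM, RIM)}
    # posterior-mean parameters per model from that model's accepted rows
    param_means: dict[str, pd.Series] = {}
    for m in (SIM, RIM):
        rows = idx[labels == m]
        names = param_names(m)
        if rows.size:
            vals = pool.params[rows][:, : len(names)]
            param_means[m] = pd.Series(vals.mean(axis=0), index=names)
        else:
            param_means[m] = pd.Series(np.nan, index=names)
    selected = max((SIM, RIM), key=lambda m: counts[m])
    return ModelPosterior(
        counts=counts,
        posterior=posterior,
        selected=selected,
        param_means=param_means,
        n_pooled=pool.n,
    )


class ModelSelection:
    """Object-style wrapper mirroring :class:`~indelabc.abc.RejectionABC`."""

    def __init__(
        self,
        observed,
        tree: PhyloTree,
        prior: Optional[PriorConfig] = None,
        config: Optional[AbcConfig] = None,
        corrections: Optional[dict] = None,
    ):
        from .msa import Msa

        self.s_obs = _observed_vector(observed)
        self.tree = tree
        if prior is None:
            if not isinstance(observed, Msa):
                raise ValueError(
                    "prior required when observed is a bare summary vector"
                )
            prior = PriorConfig.from_msa(observed)
        self.prior = prior
        self.config = config or AbcConfig()
        self.corrections = corrections

    def fit(
        self,
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        weights: Optional[WeightVector] = None,
        pool: Optional[ReferenceTable] = None,
    ) -> ModelPosterior:
        if rng is None:
            rng = np.random.default_rng(seed)
        return select_model(
            self.s_obs,
            self.tree,
            self.prior,
            self.config,
            rng,
            corrections=self.corrections,
            weights=weights,
            pool=pool,
        )
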