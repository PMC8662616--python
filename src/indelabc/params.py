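"""Indel model parameters and their prior distributions.

Two nested models are supported:

* **SIM** (simple indel model, 3 parameters): root length RL, a single
  indel-to-substitution rate ratio R_ID shared by insertions and
  deletions (R_ID is the *sum* of the two equal rates), and a single
  Zipf length exponent A_ID.
* **RIM** (rich indel model, 5 parameters): root length RL, separate
  insertion and deletion rate ratios R_I and R_D, and separate length
  exponents A_I and A_D.

All rates are events per substitution per site, so branch lengths in
substitutions/site directly clock the indel process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .zipf import DEFAULT_MAX_INDEL_LEN

SIM = "SIM"
RIM = "RIM"
MODELS = (SIM, RIM)


@dataclass(frozen=True)
class IndelParams:
    """Parameter vector of one indel model.

    Exactly the fields of the declared model are set: (r_id, a_id) for
    SIM, (r_i, r_d, a_i, a_d) for RIM; root_length always.
    """

    model: str
    root_length: int
    r_id: Optional[float] = None
    a_id: Optional[float] = None
    r_i: Optional[float] = None
    r_d: Optional[float] = None
    a_i: Optional[float] = None
    a_d: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.root_length < 1:
            raise ValueError("root_length must be a positive integer")
        sim_fields = (self.r_id, self.a_id)
        rim_fields = (self.r_i, self.r_d, self.a_i, self.a_d)
        if self.model == SIM:
            if any(f is None for f in sim_fields) or any(
                f is not None for f in rim_fields
            ):
                raise ValueError("SIM requires exactly r_id and a_id")
        else:
            if any(f is None for f in rim_fields) or any(
                f is not None for f in sim_fields
            ):
                raise ValueError("RIM requires exactly r_i, r_d, a_i, a_d")
        for a in (self.a_id, self.a_i, self.a_d):
            if a is not None and a <= 1.0:
                raise ValueError(f"Zipf exponent must exceed 1, got {a}")
        for r in (self.r_id, self.r_i, self.r_d):
            if r is not None and r < 0:
                raise ValueError("rates must be non-negative")

    # --- canonical insertion/deletion view -----------------------------
    # Under SIM the insertion and deletion rates are equal and R_ID is
    # their sum, so each process runs at R_ID / 2.

    @property
    def insertion_rate(self) -> float:
        return self.r_id / 2.0 if self.model == SIM else self.r_i

    @property
    def deletion_rate(self) -> float:
        return self.r_id / 2.0 if self.model == SIM else self.r_d

    @property
    def insertion_a(self) -> float:
        return self.a_id if self.model == SIM else self.a_i

    @property
    def deletion_a(self) -> float:
        return self.a_id if self.model == SIM else self.a_d

    def param_names(self) -> tuple[str, ...]:
        if self.model == SIM:
            return ("r_id", "a_id", "root_length")
        return ("r_i", "r_d", "a_i", "a_d", "root_length")

    def as_vector(self) -> np.ndarray:
        """Free parameters as a flat vector (3 for SIM, 5 for RIM)."""
        return np.array([getattr(self, n) for n in self.param_names()], float)


def param_names(model: str) -> tuple[str, ...]:
    if model == SIM:
        return ("r_id", "a_id", "root_length")
    if model == RIM:
        return ("r_i", "r_d", "a_i", "a_d", "root_length")
    raise ValueError(f"unknown model {model!r}")


def params_from_vector(model: str, vec: np.ndarray) -> IndelParams:
    names = param_names(model)
    kw = dict(zip(names, vec))
    rl = int(round(kw.pop("root_length")))
    return IndelParams(model=model, root_length=rl, **kw)


@dataclass(frozen=True)
class PriorConfig:
    """Uniform priors over the indel model parameters.

    Rate priors: R_ID ~ U[0, 0.1] (SIM), R_I, R_D ~ U[0, 0.05] (RIM);
    length exponents ~ U[1.001, 2]; the root length is uniform on an
    integer interval derived from the input sequences (see
    :func:`indelabc.msa.rl_prior_range`).
    """

    rl_range: tuple[int, int]
    r_id_range: tuple[float, float] = (0.0, 0.1)
    r_i_range: tuple[float, float] = (0.0, 0.05)
    r_d_range: tuple[float, float] = (0.0, 0.05)
    a_range: tuple[float, float] = (1.001, 2.0)
    max_indel_len: int = DEFAULT_MAX_INDEL_LEN

    def __post_init__(self) -> None:
        lo, hi = self.rl_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid root-length range {self.rl_range}")
        for rng_ in (self.r_id_range, self.r_i_range, self.r_d_range, self.a_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"empty prior range {rng_}")

    @classmethod
    def from_msa(cls, msa, **overrides) -> "PriorConfig":
        from .msa import rl_prior_range

        return cls(rl_range=rl_prior_range(msa), **overrides)


def sample_prior(
    model: str, prior: PriorConfig, rng: np.random.Generator
) -> IndelParams:
    """Draw one parameter set from the prior of the given model."""
    rl = int(rng.integers(prior.rl_range[0], prior.rl_range[1] + 1))
    if model == SIM:
        return IndelParams(
            model=SIM,
            root_length=rl,
            r_id=rng.uniform(*prior.r_id_range),
            a_id=rng.uniform(*prior.a_range),
        )
    if model == RIM:
        return IndelParams(
            model=RIM,
            root_length=rl,
            r_i=rng.uniform(*prior.r_i_range),
            r_d=rng.uniform(*prior.r_d_range),
            a_i=rng.uniform(*prior.a_range),
            a_d=rng.uniform(*prior.a_range),
        )
    raise ValueError(f"unknown model {model!r}")


def prior_mean(model: str, prior: PriorConfig) -> dict[str, float]:
    """Analytic prior mean of every free parameter (uniform midpoints)."""
    rl_mean = (prior.rl_range[0] + prior.rl_range[1]) / 2.0
    a_mean = (prior.a_range[0] + prior.a_range[1]) / 2.0
    if model == SIM:
        return {
            "r_id": sum(prior.r_id_range) / 2.0,
            "a_id": a_mean,
            "root_length": rl_mean,
        }
    return {
        "r_i": sum(prior.r_i_range) / 2.0,
        "r_d": sum(prior.r_d_range) / 2.0,
        "a_i": a_mean,
        "a_d": a_mean,
        "root_length": rl_mean,
    }
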