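"""Truncated Zipf (power-law) indel length distribution.

Indel lengths follow P(k) = k^(-a) / sum_{j=1..max_len} j^(-a) on
k in {1, ..., max_len}. The truncation (default max_len = 50) reflects
the empirical deficit of very long indels relative to the power law
fitted to short ones. Sampling is exact inverse-CDF on the precomputed
table; no rejection step.
"""

from __future__ import annotations

import numpy as np

DEFAULT_MAX_INDEL_LEN = 50


def truncated_zipf_pmf(a: float, max_len: int = DEFAULT_MAX_INDEL_LEN) -> np.ndarray:
    """Probability of each length 1..max_len under the truncated Zipf law."""
    if a <= 1.0:
        raise ValueError(f"Zipf exponent must exceed 1, got {a}")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    k = np.arange(1, max_len + 1, dtype=np.float64)
    w = k ** (-a)
    return w / w.sum()


def truncated_zipf_mean(a: float, max_len: int = DEFAULT_MAX_INDEL_LEN) -> float:
    """Expected indel length under the truncated Zipf law.

    At a = 2 with max_len = 50 this is ~2.769; the value used to convert
    fitted exponents into reported mean insertion/deletion lengths.
    """
    pmf = truncated_zipf_pmf(a, max_len)
    return float(pmf @ np.arange(1, max_len + 1))


def zipf_cdf(a: float, max_len: int = DEFAULT_MAX_INDEL_LEN) -> np.ndarray:
    """Cumulative table for inverse-CDF sampling."""
    return np.cumsum(truncated_zipf_pmf(a, max_len))


def sample_indel_length(
    a: float,
    max_len: int = DEFAULT_MAX_INDEL_LEN,
    rng: np.random.Generator | None = None,
    size: int | None = None,
):
    """Draw indel length(s) by inverse-CDF on the truncated Zipf table."""
    if rng is None:
        rng = np.random.default_rng()
    cdf = zipf_cdf(a, max_len)
    if size is None:
        return int(np.searchsorted(cdf, rng.random(), side="right")) + 1
    return np.searchsorted(cdf, rng.random(size), side="right") + 1
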