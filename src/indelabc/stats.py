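"""The 27 gap-pattern summary statistics of an alignment.

A *gap block* is a maximal run of gap characters within one row. A
*unique gap block* is a distinct (start column, length) coordinate pair,
counted once however many rows carry it; a block coordinate "shared
between exactly m sequences" occurs in exactly m rows. Sharing classes
are m = 1, m = 2 and m = n-1 (n = number of rows); when these classes
coincide (n = 2 or n = 3) the coinciding statistics report the same
value. Length classes are 1, 2, 3 and >= 4.

Statistic index (1-based, the canonical order):

 1  total gap blocks                 15 columns with n-1 gaps
 2  unique gap blocks                16 len-1 blocks in exactly 1 row
 3  mean block length                17 len-1 blocks in exactly 2 rows
 4  mean unique-block length         18 len-1 blocks in exactly n-1 rows
 5  blocks of length 1               19 len-2 blocks in exactly 1 row
 6  blocks of length 2               20 len-2 blocks in exactly 2 rows
 7  blocks of length 3               21 len-2 blocks in exactly n-1 rows
 8  blocks of length >= 4            22 len-3 blocks in exactly 1 row
 9  alignment length                 23 len-3 blocks in exactly 2 rows
10  min ungapped sequence length     24 len-3 blocks in exactly n-1 rows
11  max ungapped sequence length     25 len>=4 blocks in exactly 1 row
12  columns with zero gaps           26 len>=4 blocks in exactly 2 rows
13  columns with one gap             27 len>=4 blocks in exactly n-1 rows
14  columns with two gaps

Means over an empty block set are defined as 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .msa import Msa

N_STATS = 27

STAT_NAMES: tuple[str, ...] = (
    "Total number of gap blocks in the alignment",
    "Total number of unique gap blocks in the alignment",
    "Average gap block length",
    "Average unique gap block length",
    "Number of gap blocks of length one",
    "Number of gap blocks of length two",
    "Number of gap blocks of length three",
    "Number of gap blocks of length four or more",
    "Alignment length",
    "Minimum length of sequence in the alignment",
    "Maximum length of sequence in the alignment",
    "Number of MSA columns with zero gap",
    "Number of MSA columns with one gap",
    "Number of MSA columns with two gaps",
    "Number of MSA columns with n-1 gaps",
    "Number of gaps of length one that appear only in one sequence",
    "Number of gaps of length one that are shared between exactly two sequences",
    "Number of gaps of length one that are shared between exactly n-1 sequences",
    "Number of gaps of length two that appear only in one sequence",
    "Number of gaps of length two that are shared between exactly two sequences",
    "Number of gaps of length two that are shared between exactly n-1 sequences",
    "Number of gaps of length three that appear only in one sequence",
    "Number of gaps of length three that are shared between exactly two sequences",
    "Number of gaps of length three that are shared between exactly n-1 sequences",
    "Number of gaps of length at least four that appear only in one sequence",
    "Number of gaps of length at least four that are shared between exactly two sequences",
    "Number of gaps of length at least four that are shared between exactly n-1 sequences",
)


@dataclass(frozen=True)
class GapBlock:
    """A maximal gap run in one alignment row (0-based start column)."""

    row: int
    start: int
    length: int


def _row_blocks(gap_row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(starts, lengths) of maximal gap runs in one boolean row."""
    padded = np.empty(gap_row.size + 2, dtype=np.int8)
    padded[0] = padded[-1] = 0
    padded[1:-1] = gap_row
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return starts, ends - starts


def find_gap_blocks(msa: Msa | np.ndarray) -> list[GapBlock]:
    """All maximal gap blocks, ordered by (row, start)."""
    gap = msa.gap_matrix() if isinstance(msa, Msa) else np.asarray(msa, bool)
    out: list[GapBlock] = []
    for r in range(gap.shape[0]):
        starts, lengths = _row_blocks(gap[r])
        out.extend(
            GapBlock(r, int(s), int(l)) for s, l in zip(starts, lengths)
        )
    return out


def summary_from_gap_matrix(gap: np.ndarray) -> np.ndarray:
    """The 27 statistics from a boolean gap matrix (True = gap)."""
    gap = np.asarray(gap, dtype=bool)
    n, ncols = gap.shape
    if n < 2:
        raise ValueError("summary statistics require at least 2 sequences")
    s = np.zeros(N_STATS, dtype=np.float64)

    all_lengths: list[np.ndarray] = []
    coord_counter: Counter = Counter()
    for r in range(n):
        starts, lengths = _row_blocks(gap[r])
        if starts.size:
            all_lengths.append(lengths)
            coord_counter.update(zip(starts.tolist(), lengths.tolist()))

    lengths_flat = (
        np.concatenate(all_lengths) if all_lengths else np.empty(0, dtype=np.int64)
    )
    total_blocks = lengths_flat.size
    s[0] = total_blocks
    s[1] = len(coord_counter)
    s[2] = lengths_flat.mean() if total_blocks else 0.0
    if coord_counter:
        s[3] = float(np.mean([ln for (_, ln) in coord_counter]))
    if total_blocks:
        clipped = np.minimum(lengths_flat, 4)
        bins = np.bincount(clipped, minlength=5)
        s[4:8] = bins[1:5]

    s[8] = ncols
    ungapped = ncols - gap.sum(axis=1)
    s[9] = ungapped.min()
    s[10] = ungapped.max()

    col_gaps = gap.sum(axis=0)
    cnt = np.bincount(col_gaps, minlength=n + 1)
    s[11] = cnt[0]
    s[12] = cnt[1]
    s[13] = cnt[2]
    s[14] = cnt[n - 1]

    # sharing classes of unique block coordinates; m = 2 and m = n-1 may
    # coincide (n = 3), in which case both statistics count the block
    for (_, ln), m in coord_counter.items():
        len_class = min(ln, 4) - 1  # 0..3
        base = 15 + 3 * len_class
        if m == 1:
            s[base] += 1
        if m == 2:
            s[base + 1] += 1
        if m == n - 1:
            s[base + 2] += 1
    return s


def compute_summary_vector(msa: Msa) -> np.ndarray:
    """The 27 summary statistics of an alignment, canonical order.

    Requires at least 2 rows. Returns a float vector of length 27;
    element i is statistic i+1 of the table in the module docstring.
    """
    return summary_from_gap_matrix(msa.gap_matrix())
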