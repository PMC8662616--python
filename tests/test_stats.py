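"""The 27 gap-pattern summary statistics, against hand counts and a
brute-force reimplementation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indelabc import (
    GapBlock,
    Msa,
    compute_summary_vector,
    find_gap_blocks,
    sample_prior,
    simulate_alignment,
)
from tests.conftest import balanced_tree8

# exhaustive hand enumeration on the toy fixture
MSA_T1_EXPECTED = {
    1: 4, 2: 3, 3: 1.5, 4: 4 / 3, 5: 2, 6: 2, 7: 0, 8: 0, 9: 10, 10: 7,
    11: 10, 12: 6, 13: 2, 14: 2, 15: 0, 16: 2, 17: 0, 18: 0, 19: 0, 20: 1,
    21: 0, 22: 0, 23: 0, 24: 0, 25: 0, 26: 0, 27: 0,
}


def brute_force_stats(msa: Msa) -> np.ndarray:
    """Independent O(n * ncols^2) re-derivation from the definitions."""
    n, c = msa.nrows, msa.ncols
    rows = msa.sequences
    blocks = []  # (row, start, length) by direct maximality scan
    for r in range(n):
        for start in range(c):
            if rows[r][start] != "-":
                continue
            if start > 0 and rows[r][start - 1] == "-":
                continue  # not maximal on the left
            end = start
            while end < c and rows[r][end] == "-":
                end += 1
            blocks.append((r, start, end - start))
    coords = {}
    for _, s, l in blocks:
        coords[(s, l)] = coords.get((s, l), 0) + 1
    out = np.zeros(27)
    lens = [l for (_, _, l) in blocks]
    out[0] = len(blocks)
    out[1] = len(coords)
    out[2] = sum(lens) / len(lens) if lens else 0.0
    out[3] = sum(l for (_, l) in coords) / len(coords) if coords else 0.0
    out[4] = sum(1 for l in lens if l == 1)
    out[5] = sum(1 for l in lens if l == 2)
    out[6] = sum(1 for l in lens if l == 3)
    out[7] = sum(1 for l in lens if l >= 4)
    out[8] = c
    ungapped = [sum(1 for ch in row if ch != "-") for row in rows]
    out[9] = min(ungapped)
    out[10] = max(ungapped)
    col_gaps = [sum(1 for r in range(n) if rows[r][j] == "-") for j in range(c)]
    out[11] = sum(1 for g in col_gaps if g == 0)
    out[12] = sum(1 for g in col_gaps if g == 1)
    out[13] = sum(1 for g in col_gaps if g == 2)
    out[14] = sum(1 for g in col_gaps if g == n - 1)
    for (s, l), m in coords.items():
        cls = min(l, 4) - 1
        if m == 1:
            out[15 + 3 * cls] += 1
        if m == 2:
            out[16 + 3 * cls] += 1
        if m == n - 1:
            out[17 + 3 * cls] += 1
    return out


class TestGapBlocks:
    def test_toy_fixture_blocks(self, msa_t1):
        assert find_gap_blocks(msa_t1) == [
            GapBlock(1, 3, 2),
            GapBlock(2, 3, 2),
            GapBlock(2, 8, 1),
            GapBlock(3, 1, 1),
        ]

    def test_gap_free_no_blocks(self):
        assert find_gap_blocks(Msa(["a", "b"], ["AAAA", "CCCC"])) == []

    def test_all_gap_row_single_block(self):
        blocks = find_gap_blocks(Msa(["a", "b"], ["----", "AAAA"]))
        assert blocks == [GapBlock(0, 0, 4)]


class TestSummaryVector:
    def test_toy_fixture_all_27(self, msa_t1):
        s = compute_summary_vector(msa_t1)
        for idx, expected in MSA_T1_EXPECTED.items():
            assert s[idx - 1] == pytest.approx(expected), f"statistic {idx}"

    def test_gap_free_alignment(self):
        msa = Msa([f"r{i}" for i in range(5)], ["A" * 100] * 5)
        s = compute_summary_vector(msa)
        assert s[0] == 0 and s[2] == 0 and s[3] == 0
        assert s[8] == s[9] == s[10] == 100
        assert s[11] == 100
        assert s[[1, 4, 5, 6, 7, 12, 13, 14]].sum() == 0
        assert s[15:].sum() == 0

    def test_duplicated_row_changes_total_not_unique(self, msa_t1):
        s0 = compute_summary_vector(msa_t1)
        dup = Msa(
            msa_t1.labels + ["r3b"], msa_t1.sequences + [msa_t1.sequences[2]]
        )
        s1 = compute_summary_vector(dup)
        assert s1[1] == s0[1]  # unique coordinates unchanged
        assert s1[0] == s0[0] + 2  # r3 carries two blocks

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            compute_summary_vector(Msa(["a"], ["AA-A"]))

    def test_length_class_counts_sum_to_total(self, msa_t1):
        s = compute_summary_vector(msa_t1)
        assert s[4] + s[5] + s[6] + s[7] == s[0]
        assert s[1] <= s[0]

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_row_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        gap = rng.random((5, 30)) < 0.2
        gap[:, rng.integers(0, 30)] = False  # ensure no all-gap column
        rows = ["".join("-" if g else "A" for g in r) for r in gap]
        msa = Msa([f"r{i}" for i in range(5)], rows)
        perm = rng.permutation(5)
        permuted = Msa(
            [f"r{i}" for i in range(5)], [rows[i] for i in perm]
        )
        assert np.allclose(
            compute_summary_vector(msa), compute_summary_vector(permuted)
        )

    def test_matches_brute_force_on_simulated_alignments(self):
        tree = balanced_tree8()
        rng = np.random.default_rng(77)
        from indelabc import PriorConfig

        prior = PriorConfig(rl_range=(20, 60))
        for _ in range(200):
            params = sample_prior("RIM", prior, rng)
            msa, _ = simulate_alignment(tree, params, rng)
            assert np.allclose(
                compute_summary_vector(msa), brute_force_stats(msa)
            )

    def test_three_rows_sharing_classes_coincide(self):
        # with n = 3 the m = 2 and m = n-1 classes are the same class and
        # both statistics report the same value
        msa = Msa(["a", "b", "c"], ["A-A", "A-A", "AAA"])
        s = compute_summary_vector(msa)
        assert s[16] == s[17] == 1
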