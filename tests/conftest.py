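import numpy as np
import pytest

from indelabc import Msa, PhyloTree, PriorConfig

# 4-row toy alignment used throughout; gap blocks by hand:
# r2 (3,2); r3 (3,2) and (8,1); r4 (1,1)
MSA_T1_ROWS = [
    ("r1", "AAAAAAAAAA"),
    ("r2", "AAA--AAAAA"),
    ("r3", "AAA--AAA-A"),
    ("r4", "A-AAAAAAAA"),
]


@pytest.fixture
def msa_t1() -> Msa:
    return Msa([r[0] for r in MSA_T1_ROWS], [r[1] for r in MSA_T1_ROWS])


def balanced_tree8(total_length: float = 3.0) -> PhyloTree:
    """Balanced 8-leaf tree with equal branch lengths summing to total."""
    bl = total_length / 14
    nw = (
        f"(((t1:{bl},t2:{bl}):{bl},(t3:{bl},t4:{bl}):{bl}):{bl},"
        f"((t5:{bl},t6:{bl}):{bl},(t7:{bl},t8:{bl}):{bl}):{bl});"
    )
    return PhyloTree.from_newick(nw)


@pytest.fixture
def tree8() -> PhyloTree:
    return balanced_tree8()


@pytest.fixture
def two_leaf_tree() -> PhyloTree:
    return PhyloTree.from_newick("(A:0.5,B:0.5);")


@pytest.fixture
def prior_small() -> PriorConfig:
    return PriorConfig(rl_range=(80, 110))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
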