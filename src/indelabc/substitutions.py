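"""Forward simulation of substitutions, superimposed on a true alignment.

The indel simulator emits gap structure only; when realistic residues
are needed (e.g. so an external aligner can be run on the sequences),
substitutions are simulated independently, column by column, along the
same tree, and the two alignments are superimposed: each non-gap cell of
the true alignment receives the character simulated for its column and
leaf, and the gap structure is untouched.

Two model families are provided: GTR(+I+G) for nucleotides and the WAG
empirical matrix for amino acids. Rate matrices are normalized so one
unit of branch length equals one expected substitution per site at
stationarity. Rate heterogeneity uses the usual discrete-gamma
approximation (category means) plus an invariant-site category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .msa import Msa
from .trees import PhyloTree

DNA_ALPHABET = "ACGT"
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

# WAG empirical amino-acid exchangeabilities (lower triangle, row-major:
# s[i][j] for i in 1..19, j < i, alphabet order ARNDCQEGHILKMFPSTWYV)
# and stationary frequencies, as distributed with standard phylogenetics
# software.
_WAG_LOWER = [
    0.551571,
    0.509848, 0.635346,
    0.738998, 0.147304, 5.429420,
    1.027040, 0.528191, 0.265256, 0.030295,
    0.908598, 3.035500, 1.543640, 0.616783, 0.098818,
    1.582850, 0.439157, 0.947198, 6.174160, 0.021352, 5.469470,
    1.416720, 0.584665, 1.125560, 0.865584, 0.306674, 0.330052, 0.567717,
    0.316954, 2.137150, 3.956290, 0.930676, 0.248972, 4.294110, 0.570025,
    0.249410,
    0.193335, 0.186979, 0.554236, 0.039437, 0.170135, 0.113917, 0.127395,
    0.030450, 0.138190,
    0.397915, 0.497671, 0.131528, 0.084805, 0.384287, 0.869489, 0.154263,
    0.061304, 0.499462, 3.170970,
    0.906265, 5.351420, 3.012010, 0.479855, 0.074034, 3.894900, 2.584430,
    0.373558, 0.890432, 0.323832, 0.257555,
    0.893496, 0.683162, 0.198221, 0.103754, 0.390482, 1.545260, 0.315124,
    0.174100, 0.404141, 4.257460, 4.854020, 0.934276,
    0.210494, 0.102711, 0.096162, 0.046730, 0.398020, 0.099921, 0.081134,
    0.049931, 0.679371, 1.059470, 2.115170, 0.088836, 1.190630,
    1.438550, 0.679489, 0.195081, 0.423984, 0.109404, 0.933372, 0.682355,
    0.243570, 0.696198, 0.099929, 0.415844, 0.556896, 0.171329, 0.161444,
    3.370790, 1.224190, 3.974230, 1.071760, 1.407660, 1.028870, 0.704939,
    1.341820, 0.740169, 0.319440, 0.344739, 0.967130, 0.493905, 0.545931,
    1.613280,
    2.121110, 0.554413, 2.030060, 0.374866, 0.512984, 0.857928, 0.822765,
    0.225833, 0.473307, 1.458160, 0.326622, 1.386980, 1.516120, 0.171903,
    0.795384, 4.378020,
    0.113133, 1.163920, 0.071917, 0.129767, 0.717070, 0.215737, 0.156557,
    0.336983, 0.262569, 0.212483, 0.665309, 0.137505, 0.515706, 1.529640,
    0.139405, 0.523742, 0.110864,
    0.240735, 0.381533, 1.086000, 0.325711, 0.543833, 0.227710, 0.196303,
    0.103604, 3.873440, 0.420170, 0.398618, 0.133264, 0.428437, 6.454280,
    0.216046, 0.786993, 0.291148, 2.485390,
    2.006010, 0.251849, 0.196246, 0.152335, 1.002140, 0.301281, 0.588731,
    0.187247, 0.118358, 7.821300, 1.800340, 0.305434, 2.058450, 0.649892,
    0.314887, 0.232739, 1.388230, 0.365369, 0.314730,
]

_WAG_FREQS = np.array([
    0.0866279, 0.0439720, 0.0390894, 0.0570451, 0.0193078, 0.0367281,
    0.0580589, 0.0832518, 0.0244313, 0.0484660, 0.0862090, 0.0620286,
    0.0195027, 0.0384319, 0.0457631, 0.0695179, 0.0610127, 0.0143859,
    0.0352742, 0.0708956,
])


def _exchangeability_matrix(lower: list[float], n: int) -> np.ndarray:
    S = np.zeros((n, n))
    it = iter(lower)
    for i in range(1, n):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    return S


def _rate_matrix(S: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Normalized reversible rate matrix Q from exchangeabilities S and
    stationary frequencies pi: q_ij = s_ij * pi_j, rows sum to 0, mean
    rate 1."""
    Q = S * freqs[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(freqs @ np.diag(Q))
    return Q / mu


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible substitution model with optional +I+G rates."""

    alphabet: str
    exchangeabilities: np.ndarray = field(repr=False)
    freqs: np.ndarray = field(repr=False)
    p_inv: float = 0.0
    gamma_shape: float | None = None
    n_gamma_cats: int = 4

    def site_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, probabilities) of the discrete site-rate categories.

        Gamma category means are rescaled so the average rate over all
        categories (including the invariant one) is exactly 1.
        """
        if self.gamma_shape is None:
            rates = np.array([1.0])
            probs = np.array([1.0])
        else:
            a = self.gamma_shape
            k = self.n_gamma_cats
            edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
            # mean rate within each equal-probability slice
            cdf_upper = gamma_dist.cdf(edges[1:], a + 1, scale=1.0 / a)
            cdf_lower = gamma_dist.cdf(edges[:-1], a + 1, scale=1.0 / a)
            rates = (cdf_upper - cdf_lower) * k
            probs = np.full(k, 1.0 / k)
        if self.p_inv > 0:
            rates = np.concatenate([[0.0], rates])
            probs = np.concatenate(
                [[self.p_inv], probs * (1.0 - self.p_inv)]
            )
        mean = rates @ probs
        if mean > 0:
            rates = rates / mean
        return rates, probs

    def rate_matrix(self) -> np.ndarray:
        return _rate_matrix(self.exchangeabilities, self.freqs)

    def _eigen(self):
        """Symmetrized eigendecomposition of Q (reversible models)."""
        pi = self.freqs
        sq = np.sqrt(pi)
        Q = self.rate_matrix()
        B = (Q * sq[:, None]) / sq[None, :]
        lam, U = np.linalg.eigh((B + B.T) / 2.0)
        left = U.T * sq[None, :]
        right = U / sq[:, None]
        return lam, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), rows = ancestral state."""
        lam, right, left = self._eigen()
        P = (right * np.exp(lam * t)) @ left
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


def GTRModel(
    freqs=None,
    rates=None,
    p_inv: float = 0.0,
    gamma_shape: float | None = None,
    n_gamma_cats: int = 4,
) -> SubstitutionModel:
    """General time-reversible nucleotide model (+I+G optional).

    ``rates`` are the 6 exchangeabilities in order AC, AG, AT, CG, CT,
    GT. Defaults (equal frequencies, equal rates, no rate variation)
    reduce to the Jukes-Cantor model.
    """
    freqs = np.full(4, 0.25) if freqs is None else np.asarray(freqs, float)
    rates = np.ones(6) if rates is None else np.asarray(rates, float)
    if freqs.shape != (4,) or not np.isclose(freqs.sum(), 1.0):
        raise ValueError("freqs must be 4 probabilities summing to 1")
    if rates.shape != (6,):
        raise ValueError("rates must be the 6 GTR exchangeabilities")
    S = np.zeros((4, 4))
    S[np.triu_indices(4, 1)] = rates
    S = S + S.T
    return SubstitutionModel(
        alphabet=DNA_ALPHABET,
        exchangeabilities=S,
        freqs=freqs,
        p_inv=p_inv,
        gamma_shape=gamma_shape,
        n_gamma_cats=n_gamma_cats,
    )


def WAGModel(
    p_inv: float = 0.0, gamma_shape: float | None = None, n_gamma_cats: int = 4
) -> SubstitutionModel:
    """WAG empirical amino-acid model with its published frequencies."""
    S = _exchangeability_matrix(_WAG_LOWER, 20)
    return SubstitutionModel(
        alphabet=AA_ALPHABET,
        exchangeabilities=S,
        freqs=_WAG_FREQS / _WAG_FREQS.sum(),
        p_inv=p_inv,
        gamma_shape=gamma_shape,
        n_gamma_cats=n_gamma_cats,
    )


def resolve_model(name_or_model) -> SubstitutionModel:
    """Accept a SubstitutionModel or one of the names 'GTR', 'WAG', 'JC'."""
    if isinstance(name_or_model, SubstitutionModel):
        return name_or_model
    name = str(name_or_model).upper()
    if name in ("GTR", "GTR+I+G", "JC"):
        return GTRModel()
    if name == "WAG":
        return WAGModel()
    raise ValueError(f"unknown substitution model {name_or_model!r}")


def simulate_site_characters(
    tree: PhyloTree,
    nsites: int,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``nsites`` independent sites along the tree.

    Returns an integer (n_leaves, nsites) matrix of alphabet indices.
    Sites draw a rate category first; ancestral states come from the
    stationary distribution and children are sampled from exp(Q t r).
    """
    flat = tree.flat
    nstates = len(model.alphabet)
    rates, probs = model.site_rates()
    cats = rng.choice(len(rates), size=nsites, p=probs)

    lam, right, left = model._eigen()

    def pmat(t: float) -> np.ndarray:
        P = (right * np.exp(lam * t)) @ left
        P = np.clip(P, 0.0, None)
        return np.cumsum(P / P.sum(axis=1, keepdims=True), axis=1)

    n_nodes = len(flat.parent)
    states = np.empty((n_nodes, nsites), dtype=np.int64)
    root_cdf = np.cumsum(model.freqs)
    states[0] = np.searchsorted(root_cdf, rng.random(nsites))
    for node in range(1, n_nodes):
        t = flat.blen[node]
        parent_states = states[flat.parent[node]]
        child = np.empty(nsites, dtype=np.int64)
        for ci, r in enumerate(rates):
            mask = cats == ci
            if not mask.any():
                continue
            if r == 0.0 or t == 0.0:
                child[mask] = parent_states[mask]
                continue
            cum = pmat(t * r)
            u = rng.random(int(mask.sum()))
            child[mask] = (
                cum[parent_states[mask]] < u[:, None]
            ).sum(axis=1)
        states[node] = child
    return states[flat.leaf_nodes]


def overlay_substitutions(
    msa: Msa,
    tree: PhyloTree,
    subst_model,
    rng: np.random.Generator,
) -> Msa:
    """Superimpose column-wise substitution evolution on a true alignment.

    Gap structure is preserved exactly; each non-gap cell is replaced by
    the character simulated for its (leaf, column) under the model. The
    MSA row order must match ``tree.leaf_labels``.
    """
    model = resolve_model(subst_model)
    if tuple(msa.labels) != tuple(tree.leaf_labels):
        order = {lab: i for i, lab in enumerate(msa.labels)}
        missing = set(tree.leaf_labels) - set(msa.labels)
        if missing:
            raise ValueError(f"MSA lacks tree leaves: {sorted(missing)}")
        perm = [order[lab] for lab in tree.leaf_labels]
    else:
        perm = list(range(msa.nrows))
    gap = msa.gap_matrix()[perm]
    chars = simulate_site_characters(tree, msa.ncols, model, rng)
    alpha = np.frombuffer(model.alphabet.encode("ascii"), dtype=np.uint8)
    cells = alpha[chars]
    cells[gap] = ord("-")
    rows = ["".join(map(chr, row)) for row in cells]
    return Msa(list(tree.leaf_labels), rows)
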