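"""Correcting alignment-program bias in the summary statistics.

ABC compares an *inferred* alignment (e.g. produced by MAFFT) with
*true* simulated alignments, and alignment programs distort gap
patterns — most notably "gap attraction", the tendency to merge nearby
independent gaps. The correction learns, per summary statistic, how the
aligner transforms true-alignment statistics: ``n_train`` prior draws
are simulated, substitutions are overlaid so the sequences carry real
signal, the true alignments are stripped of gaps and realigned, and a
linear L1-regularized (lasso) regression per statistic predicts the
post-alignment value from the 27 pre-alignment statistics plus the
model parameters (30 predictors for SIM, 32 for RIM). The
regularization strength is chosen by 3-fold cross-validation, and a
statistic is retained only when the Pearson correlation between its
out-of-fold predictions and the realigned values is at least 0.9 —
below that, the statistic carries more noise than signal and is
excluded from the ABC distance altogether.
"""

from __future__ import annotations

import json
import logging
import shlex
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold, cross_val_predict

from .msa import Msa, read_msa, write_fasta
from .params import IndelParams, PriorConfig, param_names, sample_prior
from .simulator import simulate_alignment
from .stats import N_STATS, compute_summary_vector
from .substitutions import overlay_substitutions, resolve_model
from .trees import PhyloTree

logger = logging.getLogger(__name__)

R_THRESHOLD = 0.9


# --------------------------------------------------------------------------
# Aligners


class IdentityAligner:
    """Returns the input alignment unchanged (testing/calibration).

    With this aligner the corrected pipeline must reproduce the
    uncorrected one, which anchors the correction machinery.
    """

    name = "identity"

    def realign(self, msa: Msa) -> Msa:
        return msa


class ExternalAligner:
    """Realign via an external command (default: ``mafft --auto``).

    The true alignment is degapped, written as FASTA, and the command is
    run with ``{input}`` substituted; the aligned FASTA is read from
    stdout. Rows are returned in the input order.
    """

    def __init__(self, command: str = "mafft --auto {input}"):
        self.command = command
        self.name = command

    def realign(self, msa: Msa) -> Msa:
        rows = msa.degapped()
        with tempfile.TemporaryDirectory(prefix="indelabc_aln_") as tmp:
            fasta = Path(tmp) / "unaligned.fasta"
            write_fasta(rows, fasta)
            cmd = [
                part.replace("{input}", str(fasta))
                for part in shlex.split(self.command)
            ]
            logger.debug("aligner command: %s", " ".join(cmd))
            proc = subprocess.run(
                cmd, capture_output=True, text=True, check=False
            )
            if proc.returncode != 0:
                raise RuntimeError(
                    f"aligner failed (exit {proc.returncode}): {proc.stderr[-500:]}"
                )
            out = Path(tmp) / "aligned.fasta"
            out.write_text(proc.stdout)
            aligned = read_msa(out)
        order = {lab: i for i, lab in enumerate(aligned.labels)}
        missing = [lab for lab in msa.labels if lab not in order]
        if missing:
            raise RuntimeError(f"aligner dropped sequences: {missing}")
        perm = [order[lab] for lab in msa.labels]
        return Msa(
            list(msa.labels),
            [aligned.sequences[i].upper() for i in perm],
        )


class GapMergingAligner:
    """Synthetic distortion model mimicking gap attraction (testing only).

    Within each row, whenever two gap blocks are separated by at most
    ``max_sep`` residues, the separating residues are moved past the
    second block so the two gaps fuse into one. Residue content and
    order are preserved; the total number of gap blocks drops. This is a
    controlled stand-in for the qualitative bias of real aligners, not a
    model of any particular program.
    """

    name = "gap-merging-distorter"

    def __init__(self, max_sep: int = 2):
        self.max_sep = max_sep

    def _merge_row(self, row: str) -> str:
        chars = list(row)
        changed = True
        while changed:
            changed = False
            s = "".join(chars)
            blocks = []
            i = 0
            while i < len(s):
                if s[i] == "-":
                    j = i
                    while j < len(s) and s[j] == "-":
                        j += 1
                    blocks.append((i, j))
                    i = j
                else:
                    i += 1
            for (a0, a1), (b0, b1) in zip(blocks, blocks[1:]):
                sep = b0 - a1
                if 0 < sep <= self.max_sep:
                    # slide the separating residues past the second block
                    middle = chars[a1:b0]
                    chars[a1:b1] = ["-"] * (b1 - b0) + middle
                    changed = True
                    break
        return "".join(chars)

    def realign(self, msa: Msa) -> Msa:
        return Msa(list(msa.labels), [self._merge_row(r) for r in msa.sequences])


# --------------------------------------------------------------------------
# Correction model


@dataclass
class CorrectionModel:
    """Per-statistic linear maps from true- to realigned-statistic space.

    One regression per summary statistic over d predictors (the 27
    pre-alignment statistics followed by the model parameters).
    ``retained_mask[j]`` is False when the validation correlation
    ``r[j]`` fell below 0.9; masked statistics are excluded from the ABC
    distance (their weight is zeroed downstream).
    """

    model: str
    coef: np.ndarray  # (27, d)
    intercept: np.ndarray  # (27,)
    r: np.ndarray  # (27,)
    retained_mask: np.ndarray  # (27,) bool
    predictor_names: tuple[str, ...]
    aligner: str = ""
    subst_model: str = ""

    def __post_init__(self) -> None:
        k = len(param_names(self.model))
        if self.coef.shape != (N_STATS, N_STATS + k):
            raise ValueError(
                f"coefficient matrix must be (27, {N_STATS + k}) for {self.model}"
            )

    def predict_matrix(self, stats: np.ndarray, params: np.ndarray) -> np.ndarray:
        """Corrected statistics for a batch of simulations.

        Retained statistics are replaced by their regression prediction;
        masked statistics pass through unchanged (they are zero-weighted
        downstream, so the value is irrelevant to the distance).
        """
        X = np.hstack([stats, params])
        pred = X @ self.coef.T + self.intercept[None, :]
        out = stats.copy()
        out[:, self.retained_mask] = pred[:, self.retained_mask]
        return out

    def apply(self, s_true: np.ndarray, params: IndelParams) -> np.ndarray:
        if params.model != self.model:
            raise ValueError(
                f"correction model trained for {self.model}, got parameters "
                f"of {params.model}"
            )
        return self.predict_matrix(
            np.asarray(s_true, float)[None, :], params.as_vector()[None, :]
        )[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "coef": self.coef.tolist(),
                "intercept": self.intercept.tolist(),
                "r": self.r.tolist(),
                "retained_mask": self.retained_mask.astype(int).tolist(),
                "predictor_names": list(self.predictor_names),
                "aligner": self.aligner,
                "subst_model": self.subst_model,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CorrectionModel":
        d = json.loads(text)
        return cls(
            model=d["model"],
            coef=np.asarray(d["coef"], float),
            intercept=np.asarray(d["intercept"], float),
            r=np.asarray(d["r"], float),
            retained_mask=np.asarray(d["retained_mask"], bool),
            predictor_names=tuple(d["predictor_names"]),
            aligner=d.get("aligner", ""),
            subst_model=d.get("subst_model", ""),
        )


def _fit_one_stat(X_std, y, cv):
    """LassoCV fit plus honest out-of-fold validation correlation."""
    if np.std(y) == 0.0:
        # constant response: trivially predictable by the intercept
        return np.zeros(X_std.shape[1]), float(y[0]), 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # eps extends the automatic alpha grid to near-zero penalties so
        # an exact linear relation (e.g. an undistorting aligner) can be
        # recovered without shrinkage
        lcv = LassoCV(cv=cv, max_iter=50_000, alphas=60, eps=1e-5)
        lcv.fit(X_std, y)
        oof = cross_val_predict(
            Lasso(alpha=lcv.alpha_, max_iter=50_000), X_std, y, cv=cv
        )
    if np.std(oof) == 0.0:
        r = 0.0
    else:
        r = float(np.corrcoef(oof, y)[0, 1])
    return lcv.coef_, float(lcv.intercept_), r


def learn_correction(
    tree: PhyloTree,
    prior: PriorConfig,
    model: str,
    aligner,
    rng: np.random.Generator,
    n_train: int = 200,
    subst_model="WAG",
) -> CorrectionModel:
    """Learn the aligner-distortion regressions for one indel model.

    For each of ``n_train`` prior draws: simulate the true alignment,
    overlay substitutions (so the aligner sees realistic residues),
    record the 27 pre-alignment statistics, realign, and record the
    post-alignment statistics. Per statistic a lasso regression (3-fold
    CV for the penalty) maps (pre-stats, parameters) to the
    post-alignment value. Predictors are standardized for the fit and
    the coefficients stored back on the original scale.

    An aligner failure on a training instance is retried once; a second
    failure aborts with the offending FASTA preserved for inspection.
    """
    if n_train < 6:
        raise ValueError("n_train must be at least 6 (3-fold CV needs >= 2/fold)")
    names = param_names(model)
    subst = resolve_model(subst_model)
    pre = np.empty((n_train, N_STATS))
    post = np.empty((n_train, N_STATS))
    pars = np.empty((n_train, len(names)))
    for i in range(n_train):
        p = sample_prior(model, prior, rng)
        pars[i] = p.as_vector()
        true_msa, _ = simulate_alignment(
            tree, p, rng, max_indel_len=prior.max_indel_len
        )
        pre[i] = compute_summary_vector(true_msa)
        with_subs = overlay_substitutions(true_msa, tree, subst, rng)
        try:
            realigned = aligner.realign(with_subs)
        except Exception as first_err:  # retry once, then preserve input
            logger.warning("aligner failed (%s); retrying once", first_err)
            try:
                realigned = aligner.realign(with_subs)
            except Exception:
                dump = Path(tempfile.gettempdir()) / f"indelabc_failed_{i}.fasta"
                write_fasta(with_subs.degapped(), dump)
                raise RuntimeError(
                    f"aligner failed twice on training instance {i}; "
                    f"unaligned input preserved at {dump}"
                )
        post[i] = compute_summary_vector(realigned)

    X = np.hstack([pre, pars])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X_std = (X - mu) / sd

    cv = KFold(n_splits=3, shuffle=False)
    coef = np.zeros((N_STATS, X.shape[1]))
    intercept = np.zeros(N_STATS)
    rvals = np.zeros(N_STATS)
    for j in range(N_STATS):
        c_std, b_std, r = _fit_one_stat(X_std, post[:, j], cv)
        coef[j] = c_std / sd
        intercept[j] = b_std - float((c_std * mu / sd).sum())
        rvals[j] = r
    mask = rvals >= R_THRESHOLD
    dropped = np.flatnonzero(~mask) + 1
    if dropped.size:
        logger.info(
            "correction (%s, aligner=%s): excluded statistics %s (r < %.2f)",
            model, getattr(aligner, "name", "?"), dropped.tolist(), R_THRESHOLD,
        )
    predictor_names = tuple(
        [f"s{j + 1}" for j in range(N_STATS)] + list(names)
    )
    return CorrectionModel(
        model=model,
        coef=coef,
        intercept=intercept,
        r=rvals,
        retained_mask=mask,
        predictor_names=predictor_names,
        aligner=getattr(aligner, "name", str(aligner)),
        subst_model=getattr(subst, "alphabet", "") and (
            "WAG" if len(subst.alphabet) == 20 else "GTR"
        ),
    )


def apply_correction(
    s_true: np.ndarray, params: IndelParams, cm: CorrectionModel
) -> np.ndarray:
    """Corrected summary vector for one simulation (see CorrectionModel)."""
    return cm.apply(s_true, params)
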