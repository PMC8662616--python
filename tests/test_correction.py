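"""Alignment-bias correction: learning, application, masking."""

import numpy as np
import pytest

from indelabc import (
    CorrectionModel,
    GapMergingAligner,
    IdentityAligner,
    IndelParams,
    Msa,
    PriorConfig,
    apply_correction,
    compute_summary_vector,
    learn_correction,
    sample_prior,
    simulate_alignment,
)
from indelabc.params import RIM, SIM, param_names
from indelabc.stats import N_STATS


def small_prior():
    return PriorConfig(rl_range=(80, 110))


class TestGapMergingAligner:
    def test_merges_nearby_blocks(self):
        msa = Msa(["a", "b"], ["AA--G--AA", "AAAAAAAAA"])
        out = GapMergingAligner(max_sep=2).realign(msa)
        # the single separating residue slides past the second block
        assert out.sequences[0].count("-") == 4
        assert "----" in out.sequences[0]
        assert out.sequences[0].replace("-", "") == "AAGAA"

    def test_distant_blocks_untouched(self):
        row = "A--AAAA--A"
        out = GapMergingAligner(max_sep=2).realign(Msa(["a", "b"], [row, "A" * 10]))
        assert out.sequences[0] == row

    def test_reduces_block_count_on_simulated_data(self, tree8, rng):
        prior = small_prior()
        drops = []
        for _ in range(10):
            p = sample_prior(RIM, prior, rng)
            msa, _ = simulate_alignment(tree8, p, rng)
            pre = compute_summary_vector(msa)
            post = compute_summary_vector(GapMergingAligner(2).realign(msa))
            drops.append(post[0] - pre[0])
        assert np.mean(drops) <= 0.0


class TestExternalAligner:
    def test_mafft_roundtrip_preserves_labels_and_residues(self, tree8, rng):
        from indelabc import ExternalAligner, overlay_substitutions

        p = sample_prior(RIM, small_prior(), rng)
        true_msa, _ = simulate_alignment(tree8, p, rng)
        with_subs = overlay_substitutions(true_msa, tree8, "WAG", rng)
        realigned = ExternalAligner().realign(with_subs)
        assert realigned.labels == with_subs.labels
        assert dict(realigned.degapped()) == dict(with_subs.degapped())


class TestLearnAndApply:
    def test_identity_aligner_near_perfect_regressions(self, tree8):
        cm = learn_correction(
            tree8, small_prior(), RIM, IdentityAligner(),
            np.random.default_rng(0), n_train=50,
        )
        assert (cm.r >= 0.95).all()
        assert cm.retained_mask.all()
        # predictions reproduce inputs on held-out simulations
        rng = np.random.default_rng(1)
        p = sample_prior(RIM, small_prior(), rng)
        msa, _ = simulate_alignment(tree8, p, rng)
        s = compute_summary_vector(msa)
        pred = apply_correction(s, p, cm)
        assert np.allclose(pred, s, rtol=0.1, atol=2.0)

    def test_constant_intercept_only_model(self):
        d = N_STATS + len(param_names(SIM))
        cm = CorrectionModel(
            model=SIM,
            coef=np.zeros((N_STATS, d)),
            intercept=np.full(N_STATS, 7.5),
            r=np.ones(N_STATS),
            retained_mask=np.ones(N_STATS, bool),
            predictor_names=tuple(f"x{i}" for i in range(d)),
        )
        p = IndelParams(model=SIM, root_length=50, r_id=0.01, a_id=1.5)
        out = apply_correction(np.arange(N_STATS, dtype=float), p, cm)
        assert np.allclose(out, 7.5)

    def test_model_mismatch_rejected(self):
        d = N_STATS + len(param_names(SIM))
        cm = CorrectionModel(
            model=SIM,
            coef=np.zeros((N_STATS, d)),
            intercept=np.zeros(N_STATS),
            r=np.ones(N_STATS),
            retained_mask=np.ones(N_STATS, bool),
            predictor_names=tuple(f"x{i}" for i in range(d)),
        )
        p = IndelParams(
            model=RIM, root_length=50, r_i=0.01, r_d=0.01, a_i=1.5, a_d=1.5
        )
        with pytest.raises(ValueError, match="trained for"):
            apply_correction(np.zeros(N_STATS), p, cm)

    def test_masked_statistics_pass_through_unchanged(self):
        d = N_STATS + len(param_names(SIM))
        mask = np.ones(N_STATS, bool)
        mask[0] = False
        cm = CorrectionModel(
            model=SIM,
            coef=np.zeros((N_STATS, d)),
            intercept=np.full(N_STATS, 99.0),
            r=np.ones(N_STATS),
            retained_mask=mask,
            predictor_names=tuple(f"x{i}" for i in range(d)),
        )
        p = IndelParams(model=SIM, root_length=50, r_id=0.01, a_id=1.5)
        out = apply_correction(np.arange(N_STATS, dtype=float), p, cm)
        assert out[0] == 0.0  # masked: original value kept
        assert np.allclose(out[1:], 99.0)

    def test_masked_statistic_gets_zero_weight(self, tree8):
        from indelabc import AbcConfig, estimate_weights

        cm = learn_correction(
            tree8, small_prior(), RIM, GapMergingAligner(2),
            np.random.default_rng(3), n_train=30,
        )
        assert not cm.retained_mask.all()  # the distorter breaks some stats
        cfg = AbcConfig(n_sims=100, acceptance_fraction=0.1, n_weight_sims=100)
        w = estimate_weights(
            tree8, small_prior(), RIM, cfg, np.random.default_rng(4), cm
        )
        assert (w.weights[~cm.retained_mask] == 0).all()

    def test_json_roundtrip(self, tree8):
        cm = learn_correction(
            tree8, small_prior(), SIM, IdentityAligner(),
            np.random.default_rng(5), n_train=20,
        )
        back = CorrectionModel.from_json(cm.to_json())
        assert back.model == cm.model
        assert np.allclose(back.coef, cm.coef)
        assert np.array_equal(back.retained_mask, cm.retained_mask)

    def test_n_train_too_small_rejected(self, tree8):
        with pytest.raises(ValueError, match="n_train"):
            learn_correction(
                tree8, small_prior(), SIM, IdentityAligner(),
                np.random.default_rng(0), n_train=3,
            )
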