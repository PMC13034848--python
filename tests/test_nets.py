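"""Sub-model construction contracts, prediction behaviour, mean fusion."""

import numpy as np
import pytest

from otpred import nn
from otpred.alphabet import GuideTargetPair, encode_pair
from otpred.nets import (
    SubModelConfig,
    build_submodel,
    encode_batch,
    ensemble_predict,
    load_checkpoint,
    predict,
    save_checkpoint,
)


def random_pairs(rng, n, conv):
    pairs = []
    for i in range(n):
        g = "".join(rng.choice(list("ACGT"), size=24))
        t = "".join(rng.choice(list("ACGT"), size=24))
        pairs.append(encode_pair(GuideTargetPair(f"g{i}", g, t, 0), conv))
    return pairs


class TestBuild:
    def test_embedding_initialized_bit_for_bit(self, mtp_prior):
        model = build_submodel(SubModelConfig(kind="M"), mtp_prior, seed=0)
        np.testing.assert_array_equal(model.embedding.W.value, mtp_prior.matrix)
        assert model.embedding.W.value.dtype == mtp_prior.matrix.dtype

    def test_kind_prior_mismatch_rejected(self, mtp_prior, drics_prior):
        with pytest.raises(ValueError):
            build_submodel(SubModelConfig(kind="D"), mtp_prior, seed=0)
        with pytest.raises(ValueError):
            build_submodel(SubModelConfig(kind="M"), drics_prior, seed=0)

    def test_unnormalized_drics_rejected(self, conv):
        from otpred.priors import build_drics_init
        from otpred.simdata import gen_prior_table

        raw = build_drics_init(gen_prior_table("DRICS", seed=0), conv)
        with pytest.raises(ValueError, match="normalized"):
            build_submodel(SubModelConfig(kind="D"), raw, seed=0)

    def test_same_seed_identical_parameters(self, mtp_prior):
        a = build_submodel(SubModelConfig(kind="M"), mtp_prior, seed=9)
        b = build_submodel(SubModelConfig(kind="M"), mtp_prior, seed=9)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_frozen_embedding_excluded_from_trainable_set(self, mtp_prior):
        model = build_submodel(
            SubModelConfig(kind="M", embedding_trainable=False), mtp_prior, seed=0
        )
        trainable = [p.name for p in model.params() if p.trainable]
        assert "embedding" not in trainable

    @pytest.mark.parametrize("kind,layers,hidden", [("M", 2, 25), ("D", 1, 20)])
    def test_default_recurrent_sizes(self, kind, layers, hidden):
        cfg = SubModelConfig(kind=kind)
        assert (cfg.recurrent_layers, cfg.recurrent_hidden) == (layers, hidden)


class TestAblations:
    def test_removed_blocks_shrink_parameter_set(self, mtp_prior):
        full = build_submodel(SubModelConfig(kind="M"), mtp_prior, seed=0)
        no_inc = build_submodel(SubModelConfig(kind="M", use_inception=False), mtp_prior, seed=0)
        no_lstm = build_submodel(SubModelConfig(kind="M", use_bilstm=False), mtp_prior, seed=0)

        def count(m):
            return sum(p.value.size for p in m.params())

        names_full = {p.name for p in full.params()}
        names_no_inc = {p.name for p in no_inc.params()}
        names_no_lstm = {p.name for p in no_lstm.params()}
        assert not any(n.startswith("inception") for n in names_no_inc)
        assert not any(n.startswith("bilstm") for n in names_no_lstm)
        assert count(no_inc) < count(full)
        assert any(n.startswith("bilstm") for n in names_no_inc)
        assert any(n.startswith("inception") for n in names_no_lstm)
        assert names_no_inc < names_full

    def test_gradient_flows_to_embedding_iff_trainable(self, mtp_prior, conv, rng):
        """One optimizer step on a toy batch moves the embedding exactly when
        it is trainable."""
        batch = encode_batch(random_pairs(rng, 8, conv), conv.L)
        y = np.array([1, 0, 1, 0, 1, 0, 0, 0])
        for trainable in (True, False):
            model = build_submodel(
                SubModelConfig(kind="M", embedding_trainable=trainable), mtp_prior, seed=5
            )
            before = model.embedding_matrix()
            opt = nn.Adam(model.params(), lr=1e-2)
            logits = model.forward_logits(batch)
            _, d = nn.bce_loss_and_grad(logits, y)
            opt.zero_grad()
            model.backward(d)
            opt.step()
            after = model.embedding_matrix()
            if trainable:
                assert not np.array_equal(before, after)
            else:
                np.testing.assert_array_equal(before, after)


class TestPredict:
    def test_outputs_in_open_unit_interval(self, mtp_prior, conv, rng):
        model = build_submodel(SubModelConfig(kind="M"), mtp_prior, seed=1)
        p = predict(model, random_pairs(rng, 16, conv))
        assert p.shape == (16,)
        assert (p > 0).all() and (p < 1).all()

    def test_duplicate_inputs_identical_outputs(self, mtp_prior, conv, rng):
        model = build_submodel(SubModelConfig(kind="M"), mtp_prior, seed=1)
        pair = random_pairs(rng, 1, conv)[0]
        p = predict(model, [pair, pair])
        assert p[0] == p[1]

    def test_batch_size_invariance(self, mtp_prior, conv, rng):
        model = build_submodel(SubModelConfig(kind="M"), mtp_prior, seed=1)
        pairs = random_pairs(rng, 33, conv)
        single = predict(model, [pairs[7]])
        batched = predict(model, pairs, batch_size=32)
        assert batched[7] == pytest.approx(single[0], abs=1e-6)

    def test_wrong_length_rejected(self, mtp_prior, rng):
        from otpred.alphabet import PositionConvention

        model = build_submodel(SubModelConfig(kind="M"), mtp_prior, seed=1)
        short_conv = PositionConvention(L=26, n_pad=3)
        with pytest.raises(ValueError):
            predict(model, random_pairs(rng, 2, short_conv))


class TestEnsemble:
    def test_elementwise_mean(self):
        np.testing.assert_allclose(
            ensemble_predict([0.2, 0.5], [0.4, 0.5]), [0.3, 0.5]
        )

    def test_symmetry_near_extremes(self):
        eps = 1e-9
        assert ensemble_predict([eps], [1 - eps])[0] == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([0.1], [0.1, 0.2])


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, mtp_prior, conv, rng):
        model = build_submodel(SubModelConfig(kind="M"), mtp_prior, seed=3)
        pairs = random_pairs(rng, 5, conv)
        before = predict(model, pairs)
        save_checkpoint(model, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        np.testing.assert_allclose(predict(loaded, pairs), before, atol=1e-7)
        np.testing.assert_allclose(loaded.prior.matrix, mtp_prior.matrix, atol=1e-12)
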