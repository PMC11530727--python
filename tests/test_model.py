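"""Forward-path contracts of the macro-micro model."""

import logging

import numpy as np
import pytest

from moodfuse.model import (EmotionModel, FusionParameters, MicroLayerBank,
                            ModelConfig, PredictionHeads, druw_fuse)
from moodfuse.nn import FeedForward, Tensor


@pytest.fixture()
def small_model():
    return EmotionModel(["A", "B"], speech_dim=10,
                        config=ModelConfig(embed_dim=16, hidden_dim=8), seed=0)


def batch(rng, n=4, speech_dim=10):
    return (rng.normal(size=(n, 60)), rng.normal(size=(n, 60)),
            rng.normal(size=(n, speech_dim)),
            np.array(["A", "B"] * (n // 2)))


class TestEncoders:
    def test_output_shapes(self, small_model, rng):
        zcm, pim, speech, _ = batch(rng)
        hz, hp, hs = small_model.encode_modalities(zcm, pim, speech)
        assert hz.shape == hp.shape == hs.shape == (4, 16)

    def test_zero_weights_give_zero_vectors(self, small_model, rng):
        zcm, pim, speech, _ = batch(rng)
        for name, p in small_model.enc_zcm.named_parameters():
            p.data = np.zeros_like(p.data)
        hz, _, _ = small_model.encode_modalities(zcm, pim, speech)
        assert np.allclose(hz.data, 0.0)

    def test_toy_encoder_matches_pencil_and_paper(self, rng):
        """1-unit encoder with hand-set weights reproduces the affine+ReLU
        composition computed by hand."""
        enc = FeedForward(2, 1, 1, np.random.default_rng(0), dropout=0.0)
        enc.fc1.weight.data = np.array([[2.0], [-1.0]])
        enc.fc1.bias.data = np.array([0.5])
        enc.fc2.weight.data = np.array([[3.0]])
        enc.fc2.bias.data = np.array([-1.0])
        x = np.array([[1.0, 1.0], [0.0, 1.0]])
        # hidden = relu([2 - 1 + 0.5, -1 + 0.5]) = [1.5, 0.0]; out = 3h - 1
        out = enc(Tensor(x)).data
        assert np.allclose(out, [[3.5], [-1.0]])

    def test_speech_width_mismatch(self, small_model, rng):
        zcm, pim, _, _ = batch(rng)
        with pytest.raises(ValueError):
            small_model.encode_modalities(zcm, pim, rng.normal(size=(4, 7)))


class TestPhysCombiner:
    def test_identity_block_projection_recovers_zcm_stream(self, small_model, rng):
        d = 16
        small_model.phys_proj.weight.data = np.vstack([np.eye(d), np.zeros((d, d))])
        small_model.phys_proj.bias.data = np.zeros(d)
        hz = Tensor(rng.normal(size=(3, d)))
        hp = Tensor(rng.normal(size=(3, d)))
        assert np.allclose(small_model.combine_physiological(hz, hp).data, hz.data)

    def test_zero_inputs_return_bias(self, small_model):
        d = 16
        out = small_model.combine_physiological(Tensor(np.zeros((2, d))),
                                                Tensor(np.zeros((2, d))))
        assert np.allclose(out.data, small_model.phys_proj.bias.data)

    def test_random_case_matches_matrix_oracle(self, small_model, rng):
        d = 16
        hz, hp = rng.normal(size=(3, d)), rng.normal(size=(3, d))
        want = (np.concatenate([hz, hp], axis=1) @ small_model.phys_proj.weight.data
                + small_model.phys_proj.bias.data)
        got = small_model.combine_physiological(Tensor(hz), Tensor(hp)).data
        assert np.allclose(got, want, atol=1e-12)


class TestDruwFusion:
    def test_symmetric_initialization(self, rng):
        params = FusionParameters(2, restraint_coefficient=0.3)  # tau = 1
        hp, hs = rng.normal(size=(3, 8)), rng.normal(size=(3, 8))
        fused, penalty = druw_fuse([Tensor(hp), Tensor(hs)], params)
        assert np.allclose(fused.data, (hp + hs) / 2.0)
        assert float(penalty.data) == pytest.approx(0.0, abs=1e-15)

    def test_weights_strictly_decreasing_in_s(self):
        params = FusionParameters(2)
        params.s.data = np.array([0.0, np.log(2.0)])
        w = params.weights().data
        assert w[0] == pytest.approx(0.5) and w[1] == pytest.approx(0.25)

    def test_penalty_gradient_matches_finite_differences(self, rng):
        """50 random draws of (s, lambda): d(penalty)/d(s_m) vs central
        differences, relative error < 1e-4."""
        h = 1e-5
        for _ in range(50):
            params = FusionParameters(2, restraint_coefficient=float(rng.uniform(0, 0.5)))
            params.s.data = rng.normal(0, 1, size=2)
            hp = Tensor(rng.normal(size=(2, 4)))
            hs = Tensor(rng.normal(size=(2, 4)))

            def penalty_value():
                return float(druw_fuse([hp, hs], params)[1].data)

            params.s.zero_grad()
            druw_fuse([hp, hs], params)[1].backward()
            grad = params.s.grad.copy()
            for m in range(2):
                base = params.s.data[m]
                params.s.data[m] = base + h
                hi = penalty_value()
                params.s.data[m] = base - h
                lo = penalty_value()
                params.s.data[m] = base
                fd = (hi - lo) / (2 * h)
                assert abs(grad[m] - fd) / max(abs(fd), 1e-8) < 1e-4

    def test_weight_positivity_bound(self, rng):
        params = FusionParameters(2)
        for _ in range(100):
            params.s.data = rng.normal(0, 3, size=2)
            w = params.weights().data
            assert (w > 0).all()
            assert (w < np.exp(np.abs(params.s.data))).all()

    def test_nonfinite_parameters_rejected(self, rng):
        params = FusionParameters(2)
        params.s.data = np.array([np.nan, 0.0])
        with pytest.raises(ValueError):
            druw_fuse([Tensor(rng.normal(size=(1, 4)))] * 2, params)


class TestMacroForward:
    def test_output_shape(self, small_model, rng):
        d = 16
        vecs = [Tensor(rng.normal(size=(5, d))) for _ in range(3)]
        assert small_model.macro_forward(*vecs).shape == (5, d)

    def test_modality_token_permutation_with_tied_embeddings(self, small_model, rng):
        """With tied token-type embeddings for the two modality tokens,
        swapping them leaves the mean-pooled macro embedding unchanged."""
        small_model.eval()
        small_model.token_type.data[2] = small_model.token_type.data[1]
        d = 16
        fused = Tensor(rng.normal(size=(2, d)))
        hp = Tensor(rng.normal(size=(2, d)))
        hs = Tensor(rng.normal(size=(2, d)))
        a = small_model.macro_forward(fused, hp, hs).data
        b = small_model.macro_forward(fused, hs, hp).data
        assert np.allclose(a, b, atol=1e-10)


class TestMicro:
    def make_bank(self, alpha, rng):
        return MicroLayerBank(["A", "B"], dim=6, rng=rng, alpha=alpha)

    def test_alpha_one_returns_macro(self, rng):
        bank = self.make_bank(1.0, rng)
        # give the micro layer a nonzero perturbation
        bank.layers["A"].fc2.weight.data += 0.7
        M = Tensor(rng.normal(size=(3, 6)))
        out = bank(M, np.array(["A"] * 3))
        assert np.allclose(out.data, M.data)

    def test_alpha_zero_returns_micro_layer_output(self, rng):
        bank = self.make_bank(0.0, rng)
        bank.layers["A"].fc2.weight.data += 0.3
        M = Tensor(rng.normal(size=(3, 6)))
        want = (M + bank.layers["A"](M)).data
        assert np.allclose(bank(M, np.array(["A"] * 3)).data, want)

    def test_identity_micro_layer_is_identity(self, rng):
        """alpha = 0.5 with an identity micro layer returns M exactly
        (0.5 M + 0.5 M); zero-init layers are identity at construction."""
        bank = self.make_bank(0.5, rng)
        M = Tensor(rng.normal(size=(4, 6)))
        assert np.allclose(bank(M, np.array(["A", "B", "A", "B"])).data, M.data)

    def test_unknown_participant_passthrough_with_warning(self, rng, caplog):
        bank = self.make_bank(0.3, rng)
        bank.layers["A"].fc2.weight.data += 1.0
        M = Tensor(rng.normal(size=(2, 6)))
        with caplog.at_level(logging.WARNING, logger="moodfuse.model"):
            out = bank(M, np.array(["ZZ", "ZZ"]))
        assert np.allclose(out.data, M.data)
        assert any("ZZ" in rec.getMessage() for rec in caplog.records)

    def test_batch_grouping_matches_per_row(self, rng):
        bank = self.make_bank(0.25, rng)
        for pid in "AB":
            bank.layers[pid].fc2.weight.data = rng.normal(size=(6, 6)) * 0.1
        M = Tensor(rng.normal(size=(5, 6)))
        pids = np.array(["B", "A", "A", "B", "A"])
        got = bank(M, pids).data
        for i in range(5):
            row = bank.forward_one(Tensor(M.data[i:i + 1]), pids[i]).data
            assert np.allclose(got[i], row[0], atol=1e-12)


class TestHeads:
    def test_zero_parameters_give_half(self, rng):
        heads = PredictionHeads(8, rng)
        heads.linear.weight.data[:] = 0.0
        heads.linear.bias.data[:] = 0.0
        out = heads(Tensor(rng.normal(size=(3, 8))))
        assert np.allclose(out.data, 0.5)

    def test_outputs_strictly_in_unit_interval(self, rng):
        heads = PredictionHeads(8, rng)
        out = heads(Tensor(rng.normal(scale=5, size=(10, 8)))).data
        assert (out > 0).all() and (out < 1).all()

    def test_toy_head_matches_manual_computation(self):
        heads = PredictionHeads(2, np.random.default_rng(0), n_tasks=2)
        heads.linear.weight.data = np.array([[1.0, -2.0], [0.5, 0.0]])
        heads.linear.bias.data = np.array([0.0, 1.0])
        x = np.array([[2.0, 4.0]])
        logits = x @ heads.linear.weight.data + heads.linear.bias.data
        want = 1.0 / (1.0 + np.exp(-logits))
        assert np.allclose(heads(Tensor(x)).data, want)


class TestEndToEnd:
    def test_forward_determinism_with_dropout_disabled(self, small_model, rng):
        small_model.eval()
        zcm, pim, speech, pids = batch(rng)
        a, pen_a = small_model(zcm, pim, speech, pids)
        b, pen_b = small_model(zcm, pim, speech, pids)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(pen_a.data, pen_b.data)

    def test_prediction_shape_and_range(self, small_model, rng):
        small_model.eval()
        zcm, pim, speech, pids = batch(rng)
        preds, _ = small_model(zcm, pim, speech, pids)
        assert preds.shape == (4, 9)
        assert (preds.data > 0).all() and (preds.data < 1).all()

    def test_gradient_flows_to_every_component(self, small_model, rng):
        """Fusion log-variances and the micro layers all receive nonzero
        gradients from a scalar loss (no silently detached parameters)."""
        small_model.eval()  # no dropout; keeps gradient paths deterministic
        zcm, pim, speech, pids = batch(rng)
        preds, penalty = small_model(zcm, pim, speech, pids)
        loss = (preds ** 2).mean() + penalty
        loss.backward()
        assert np.abs(small_model.fusion_params.s.grad).min() > 0
        for pid in ("A", "B"):
            grads = [p.grad for _, p in small_model.micro.layers[pid].named_parameters()]
            assert any(g is not None and np.abs(g).max() > 0 for g in grads)

    def test_three_way_fusion_flag(self, rng):
        model = EmotionModel(["A"], speech_dim=10,
                             config=ModelConfig(embed_dim=16, hidden_dim=8,
                                                three_way_fusion=True), seed=0)
        model.eval()
        zcm, pim, speech, _ = batch(rng)
        preds, penalty = model(zcm, pim, speech, np.array(["A"] * 4))
        assert preds.shape == (4, 9)
        assert model.fusion_params.n_modalities == 3
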