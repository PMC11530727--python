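"""Fusion, personalization, and multitask baseline variants."""

import numpy as np
import pytest

from moodfuse.baselines import (COMPARISON_GRID, AblationSpec, Adapter,
                                AttentionFusion, ConcatFusion, GatedFusion,
                                MaxFusion, PureWeightedFusion, SharedFFNN,
                                make_fusion)
from moodfuse.nn import Tensor

D = 8


@pytest.fixture()
def pair(rng):
    return Tensor(rng.normal(size=(3, D))), Tensor(rng.normal(size=(3, D)))


class TestConcatFusion:
    def test_identity_block_recovers_phys(self, pair, rng):
        fusion = ConcatFusion(D, rng)
        fusion.proj.weight.data = np.vstack([np.eye(D), np.zeros((D, D))])
        fusion.proj.bias.data = np.zeros(D)
        hp, hs = pair
        assert np.allclose(fusion(hp, hs).data, hp.data)

    def test_zero_inputs_give_bias(self, rng):
        fusion = ConcatFusion(D, rng)
        out = fusion(Tensor(np.zeros((2, D))), Tensor(np.zeros((2, D))))
        assert np.allclose(out.data, fusion.proj.bias.data)

    def test_matches_matrix_oracle(self, pair, rng):
        fusion = ConcatFusion(D, rng)
        hp, hs = pair
        want = (np.concatenate([hp.data, hs.data], axis=1)
                @ fusion.proj.weight.data + fusion.proj.bias.data)
        assert np.allclose(fusion(hp, hs).data, want, atol=1e-12)


class TestMaxFusion:
    def test_max_with_self(self, pair, rng):
        hp, _ = pair
        assert np.allclose(MaxFusion(D, rng)(hp, hp).data, hp.data)

    def test_very_negative_vector_yields_other(self, pair, rng):
        hp, _ = pair
        low = Tensor(np.full((3, D), -1e12))
        assert np.allclose(MaxFusion(D, rng)(hp, low).data, hp.data)

    def test_elementwise_loop_oracle(self, pair, rng):
        hp, hs = pair
        got = MaxFusion(D, rng)(hp, hs).data
        for i in range(3):
            for j in range(D):
                assert got[i, j] == max(hp.data[i, j], hs.data[i, j])


class TestGatedFusion:
    def test_zero_gate_parameters_average_inputs(self, pair, rng):
        fusion = GatedFusion(D, rng)
        fusion.gate.weight.data[:] = 0.0
        fusion.gate.bias.data[:] = 0.0
        hp, hs = pair
        assert np.allclose(fusion(hp, hs).data, (hp.data + hs.data) / 2.0)

    def test_saturated_gate_selects_phys(self, pair, rng):
        fusion = GatedFusion(D, rng)
        fusion.gate.weight.data[:] = 0.0
        fusion.gate.bias.data[:] = 50.0
        hp, hs = pair
        assert np.allclose(fusion(hp, hs).data, hp.data, atol=1e-12)

    def test_matches_formula_oracle(self, pair, rng):
        fusion = GatedFusion(D, rng)
        hp, hs = pair
        z = np.concatenate([hp.data, hs.data], axis=1) @ fusion.gate.weight.data \
            + fusion.gate.bias.data
        g = 1.0 / (1.0 + np.exp(-z))
        want = g * hp.data + (1 - g) * hs.data
        assert np.allclose(fusion(hp, hs).data, want, atol=1e-12)


class TestAttentionFusion:
    def test_identical_tokens_post_concat_equals_shared_transform(self, rng):
        """With identical modality tokens, attention mixes equal tokens, so
        the pooled output equals the value projection of that token."""
        fusion = AttentionFusion(D, rng, mode="post_concat")
        h = Tensor(rng.normal(size=(2, D)))
        got = fusion(h, h).data
        want = fusion.attn.wv(h).data
        assert np.allclose(got, want, atol=1e-10)

    def test_attention_rows_sum_to_one(self, pair, rng):
        fusion = AttentionFusion(D, rng, mode="post_concat")
        fusion(*pair)
        assert np.allclose(fusion.attn.last_attention.sum(axis=-1), 1.0, atol=1e-6)

    def test_two_token_hand_example(self, rng):
        """Single-head attention on a 2-token sequence matches
        softmax(QK^T/sqrt(d))V computed by hand."""
        fusion = AttentionFusion(2, np.random.default_rng(5), mode="post_concat")
        for lin in (fusion.attn.wq, fusion.attn.wk, fusion.attn.wv):
            lin.bias.data[:] = 0.0
        fusion.attn.wq.weight.data = np.eye(2)
        fusion.attn.wk.weight.data = np.eye(2)
        fusion.attn.wv.weight.data = np.array([[1.0, 0.0], [1.0, 1.0]])
        hp = Tensor(np.array([[1.0, 0.0]]))
        hs = Tensor(np.array([[0.0, 2.0]]))
        q = k = np.array([[1.0, 0.0], [0.0, 2.0]])
        scores = q @ k.T / np.sqrt(2.0)
        att = np.exp(scores - scores.max(axis=1, keepdims=True))
        att /= att.sum(axis=1, keepdims=True)
        v = q @ fusion.attn.wv.weight.data
        want = (att @ v).mean(axis=0)
        assert np.allclose(fusion(hp, hs).data[0], want, atol=1e-12)

    def test_solo_mode_is_learned_reweighting(self, pair, rng):
        fusion = AttentionFusion(D, rng, mode="solo")
        hp, hs = pair
        out = fusion(hp, hs)
        assert out.shape == (3, D)
        # single-token attention weight is exactly 1
        assert np.allclose(fusion.attn.last_attention, 1.0)

    def test_cross_modal_sums_value_projections(self, pair, rng):
        fusion = AttentionFusion(D, rng, mode="cross_modal")
        hp, hs = pair
        want = fusion.attn.wv(hs).data + fusion.attn_speech.wv(hp).data
        assert np.allclose(fusion(hp, hs).data, want, atol=1e-10)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            AttentionFusion(D, rng, mode="bogus")


class TestPureWeighted:
    def test_one_zero_weights_select_phys(self, pair, rng):
        hp, hs = pair
        fusion = PureWeightedFusion(D, rng, weights=(1.0, 0.0))
        assert np.allclose(fusion(hp, hs).data, hp.data)

    def test_half_half_is_average(self, pair, rng):
        hp, hs = pair
        fusion = PureWeightedFusion(D, rng, weights=(0.5, 0.5))
        assert np.allclose(fusion(hp, hs).data, (hp.data + hs.data) / 2)

    def test_random_weights_match_oracle(self, pair, rng):
        hp, hs = pair
        w = rng.uniform(size=2)
        fusion = PureWeightedFusion(D, rng, weights=tuple(w))
        assert np.allclose(fusion(hp, hs).data, w[0] * hp.data + w[1] * hs.data)

    def test_negative_weights_rejected(self, rng):
        with pytest.raises(ValueError):
            PureWeightedFusion(D, rng, weights=(0.5, -0.1))


class TestPersonalizationVariants:
    def test_adapter_is_identity_at_init(self, rng):
        adapter = Adapter(D, rng)
        x = Tensor(rng.normal(size=(4, D)))
        assert np.allclose(adapter(x).data, x.data)

    def test_adapter_bottleneck_matches_hand_computation(self):
        adapter = Adapter(4, np.random.default_rng(0), ratio=4)
        adapter.down.weight.data = np.array([[1.0], [0.0], [-1.0], [2.0]])
        adapter.down.bias.data = np.array([0.5])
        adapter.up.weight.data = np.array([[1.0, 2.0, 0.0, 0.0]])
        adapter.up.bias.data = np.array([0.0, 0.0, 0.0, 1.0])
        x = np.array([[1.0, 1.0, 1.0, 1.0]])
        hidden = max(0.0, 1.0 + 0.0 - 1.0 + 2.0 + 0.5)  # 2.5
        want = x + np.array([[hidden, 2 * hidden, 0.0, 1.0]])
        assert np.allclose(adapter(Tensor(x)).data, want)

    def test_shared_ffnn_has_no_per_user_parameters(self, rng):
        shared = SharedFFNN(D, rng)
        names = [n for n, _ in shared.named_parameters()]
        assert names and not any("." in n and n.split(".")[0].startswith("P") for n in names)


class TestGrid:
    def test_seventeen_comparison_rows_constructible(self):
        assert len(COMPARISON_GRID) == 17
        assert len(set((s.fusion, s.personalization, s.mtl)
                       for s in COMPARISON_GRID)) == 17
        assert AblationSpec("druw", "macromicro", "druw") in COMPARISON_GRID

    def test_invalid_spec_fields_rejected(self):
        with pytest.raises(ValueError):
            AblationSpec(fusion="bogus")
        with pytest.raises(ValueError):
            AblationSpec(personalization="bogus")
        with pytest.raises(ValueError):
            AblationSpec(mtl="bogus")
        with pytest.raises(ValueError):
            AblationSpec(modality_mask="bogus")

    @pytest.mark.parametrize("kind", ["basic_concat", "max", "gated", "attention",
                                      "solo_attention", "cross_modal", "pure_weighted"])
    def test_shape_closure_over_grid(self, kind, pair, rng):
        """Every fusion variant maps (B, d) pairs to a (B, d) vector."""
        fusion = make_fusion(kind, D, rng)
        assert fusion(*pair).shape == (3, D)


class TestRunAblation:
    @staticmethod
    def _data(seed):
        from moodfuse import preprocess
        from moodfuse.simulate import SimulatorConfig, simulate_dataset
        cfg = SimulatorConfig(n_participants=30, n_days=14, speech_dim=16,
                              seed=seed, subject_offset_sd=0.15)
        dataset, _ = simulate_dataset(cfg)
        ds, split, _, _ = preprocess(dataset)
        return ds, split

    def test_seeded_spec_is_deterministic(self, tmp_path):
        from moodfuse import TrainConfig, run_ablation
        from moodfuse.model import ModelConfig
        ds, split = self._data(3)
        spec = AblationSpec("druw", "macromicro", "druw")
        cfg = TrainConfig(epochs=2, seed=3)
        mc = ModelConfig(embed_dim=16, hidden_dim=16)
        a = run_ablation(spec, ds, split, cfg, mc, tmp_path / "grid.csv")
        b = run_ablation(spec, ds, split, cfg, mc, tmp_path / "grid.csv")
        assert (a.ccc == b.ccc).all()
        text = (tmp_path / "grid.csv").read_text()
        assert text.count("druw,macromicro,druw") == 2

    def test_proposed_row_spec(self):
        """The full proposed combination is one constructible grid cell."""
        spec = AblationSpec("druw", "macromicro", "druw")
        assert spec in COMPARISON_GRID

    def test_personalized_cell_beats_unpersonalized_cell(self):
        """With per-subject offsets, (basic fusion, macro-micro, equal MTL)
        outscores (basic fusion, no personalization, equal MTL) on test
        mean CCC averaged over 3 seeds."""
        from moodfuse import TrainConfig, run_ablation
        from moodfuse.model import ModelConfig
        gaps = []
        for seed in (1, 2, 3):
            ds, split = self._data(seed)
            cfg = TrainConfig(epochs=40, seed=seed)
            mc = ModelConfig(embed_dim=32, hidden_dim=32)
            plain = run_ablation(AblationSpec("basic_concat", "none", "equal"),
                                 ds, split, cfg, mc)
            pers = run_ablation(AblationSpec("basic_concat", "macromicro", "equal"),
                                ds, split, cfg, mc)
            gaps.append(pers.mean - plain.mean)
        assert np.mean(gaps) > 0, gaps
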