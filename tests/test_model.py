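"""Architecture contracts: projections, the four fusion operators,
attention pooling, the classifier head, trace capture and parameter
bookkeeping."""

import numpy as np
import pytest

from dynfuse import nn
from dynfuse.config import STRATEGIES, FusionConfig
from dynfuse.model import (Classifier, ConcatFusion, CrossAttentionFusion,
                           FusionModel, GatedFusion, ProjectionSpec,
                           SumFusion, TemporalAttentionPool,
                           count_stage_params, load_checkpoint,
                           save_checkpoint, project)
from dynfuse.synth import SessionRecord
from dynfuse.tensor import Tensor
from conftest import TINY_DIMS, tiny_fusion

D = 8


@pytest.fixture()
def pair(rng):
    return (Tensor(rng.normal(size=(5, D))), Tensor(rng.normal(size=(5, D))))


class TestProjections:
    @pytest.mark.parametrize("modality,in_dim", [
        ("visual_semantic", 768), ("pose", 3), ("audio", 88), ("text", 1024)])
    def test_output_width_is_shared_d(self, modality, in_dim, rng):
        spec = ProjectionSpec.default(modality, in_dim, d=256)
        proj = spec.build(rng)
        out = project(rng.normal(size=(7, in_dim)), proj)
        assert out.shape == (7, 256)

    def test_visual_streams_are_pre_normalized(self, rng):
        spec = ProjectionSpec.default("visual_semantic", 12, d=D)
        proj = spec.build(rng)
        assert isinstance(proj.layers[0], nn.LayerNorm)
        pose = ProjectionSpec.default("pose", 3, d=D).build(rng)
        assert isinstance(pose.layers[0], nn.LayerNorm)

    def test_zero_linear_projects_to_zero(self, rng):
        spec = ProjectionSpec.default("audio", 6, d=D, audio_hidden=4)
        proj = spec.build(rng)
        for name, p in proj.named_parameters().items():
            if "weight" in name or "bias" in name or "beta" in name:
                p.data[:] = 0.0
        out = project(rng.normal(size=(5, 6)), proj)
        np.testing.assert_allclose(out, 0.0)

    def test_eval_mode_is_deterministic(self, rng):
        spec = ProjectionSpec.default("text", 10, d=D, dropout=0.5)
        proj = spec.build(rng)
        x = rng.normal(size=(6, 10))
        a = project(x, proj)
        b = project(x, proj)
        np.testing.assert_array_equal(a, b)

    def test_width_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="width"):
            ProjectionSpec("audio", 6, D, [(5, None, "relu")]).build(rng)


class TestFusionOperators:
    def test_concat_constructed_identity(self, rng):
        stage = ConcatFusion(D, rng)
        stage.proj.weight.data[:] = np.hstack([np.eye(D), np.zeros((D, D))])
        stage.proj.bias.data[:] = 0.0
        ha = Tensor(rng.normal(size=(4, D)))
        out, _ = stage(ha, Tensor(rng.normal(size=(4, D))))
        np.testing.assert_allclose(out.data, ha.data)

    def test_concat_of_zeros_is_bias(self, rng):
        stage = ConcatFusion(D, rng)
        z = Tensor(np.zeros((3, D)))
        out, _ = stage(z, z)
        np.testing.assert_allclose(out.data, np.tile(stage.proj.bias.data, (3, 1)))

    def test_sum_identity_and_commutativity(self, pair):
        ha, hb = pair
        stage = SumFusion()
        out, trace = stage(ha, Tensor(np.zeros_like(hb.data)))
        np.testing.assert_array_equal(out.data, ha.data)
        assert trace is None
        ab, _ = stage(ha, hb)
        ba, _ = stage(hb, ha)
        np.testing.assert_array_equal(ab.data, ba.data)

    def test_gated_zero_weights_is_even_mixture(self, pair, rng):
        ha, hb = pair
        stage = GatedFusion(D, rng)
        stage.gate.weight.data[:] = 0.0
        stage.gate.bias.data[:] = 0.0
        out, info = stage(ha, hb)
        np.testing.assert_allclose(info["gate"], 0.5)
        np.testing.assert_allclose(out.data, (ha.data + hb.data) / 2)

    def test_gated_saturates_to_primary(self, pair, rng):
        ha, hb = pair
        stage = GatedFusion(D, rng)
        stage.gate.weight.data[:] = 0.0
        stage.gate.bias.data[:] = 20.0
        out, info = stage(ha, hb)
        np.testing.assert_allclose(out.data, ha.data, atol=1e-7)
        assert np.all(info["gate"] > 0) and np.all(info["gate"] < 1)

    def test_scalar_gate_shape(self, pair, rng):
        ha, hb = pair
        out, info = GatedFusion(D, rng, scalar=True)(ha, hb)
        assert info["gate"].shape == (5, 1)
        assert out.data.shape == (5, D)

    def test_attention_single_utterance_alpha_is_one(self, rng):
        stage = CrossAttentionFusion(D, rng)
        ha = Tensor(rng.normal(size=(4, D)))
        hb = Tensor(rng.normal(size=(1, D)))
        _, info = stage(ha, hb)
        np.testing.assert_array_equal(info["alpha"], np.ones((4, 1)))

    def test_attention_rows_normalized(self, pair, rng):
        ha, hb = pair
        _, info = CrossAttentionFusion(D, rng)(ha, hb)
        np.testing.assert_allclose(info["alpha"].sum(axis=1), 1.0, atol=1e-6)

    def test_attention_identical_keys_ignore_alpha(self, rng):
        stage = CrossAttentionFusion(D, rng)
        ha = Tensor(rng.normal(size=(3, D)))
        row = rng.normal(size=D)
        hb = Tensor(np.tile(row, (6, 1)))
        out1, _ = stage(ha, hb)
        out2, _ = stage(ha, Tensor(np.tile(row, (2, 1))))
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-12)

    def test_attention_empty_complement_raises(self, rng):
        stage = CrossAttentionFusion(D, rng)
        with pytest.raises(ValueError, match="utterances"):
            stage(Tensor(rng.normal(size=(3, D))),
                  Tensor(np.zeros((0, D))))

    @pytest.mark.parametrize("cls", [ConcatFusion, SumFusion, GatedFusion])
    def test_shape_mismatch_raises(self, cls, rng):
        stage = cls() if cls is SumFusion else cls(D, rng)
        with pytest.raises(ValueError):
            stage(Tensor(np.zeros((4, D))), Tensor(np.zeros((3, D))))


class TestPoolingAndHead:
    def test_zero_scorer_gives_uniform_mean(self, rng):
        pool = TemporalAttentionPool(D, rng)
        pool.w.weight.data[:] = 0.0
        h = Tensor(rng.normal(size=(6, D)))
        pooled, alpha = pool(h)
        np.testing.assert_allclose(alpha, 1 / 6)
        np.testing.assert_allclose(pooled.data.ravel(), h.data.mean(axis=0))

    def test_single_and_identical_rows(self, rng):
        pool = TemporalAttentionPool(D, rng)
        h1 = Tensor(rng.normal(size=(1, D)))
        pooled, alpha = pool(h1)
        np.testing.assert_array_equal(alpha, [1.0])
        np.testing.assert_array_equal(pooled.data, h1.data)
        row = rng.normal(size=D)
        pooled, _ = pool(Tensor(np.tile(row, (5, 1))))
        np.testing.assert_allclose(pooled.data.ravel(), row)

    def test_empty_sequence_raises(self, rng):
        with pytest.raises(ValueError):
            TemporalAttentionPool(D, rng)(Tensor(np.zeros((0, D))))

    def test_classifier_zero_params_is_half(self, rng):
        clf = Classifier(D, rng)
        clf.head.weight.data[:] = 0.0
        clf.head.bias.data[:] = 0.0
        out = clf(Tensor(np.ones((1, D))))
        assert out.data.item() == pytest.approx(0.5)

    def test_classifier_monotone_in_bias(self, rng):
        clf = Classifier(D, rng)
        h = Tensor(np.ones((1, D)))
        outs = []
        for b in (-20.0, -1.0, 0.0, 1.0, 20.0):
            clf.head.bias.data[:] = b
            outs.append(clf(h).data.item())
        assert outs == sorted(outs)
        assert outs[0] < 1e-6 and outs[-1] > 1 - 1e-6

    def test_classifier_rejects_nonfinite(self, rng):
        clf = Classifier(D, rng)
        with pytest.raises(ValueError):
            clf(Tensor(np.full((1, D), np.nan)))


class TestParameterLedger:
    @pytest.mark.parametrize("strategy,weights,total", [
        ("sum", 0, 0),
        ("concat", 2 * 256 * 256, 2 * 256 * 256 + 256),
        ("gated", 2 * 256 * 256, 2 * 256 * 256 + 256),
        ("attention", 4 * 256 * 256, 4 * 256 * 256 + 3 * 256),
    ])
    def test_counts_at_d256(self, strategy, weights, total):
        counts = count_stage_params(strategy, 256)
        assert counts["weights"] == weights
        assert counts["total"] == total

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_counts_match_built_modules(self, strategy, rng):
        builders = {"concat": lambda: ConcatFusion(D, rng),
                    "sum": SumFusion,
                    "gated": lambda: GatedFusion(D, rng),
                    "attention": lambda: CrossAttentionFusion(D, rng)}
        stage = builders[strategy]()
        actual = sum(p.data.size for p in stage.parameters())
        assert actual == count_stage_params(strategy, D)["total"]


def _record(rng, t=5, dims=TINY_DIMS, label=0, sid="S0"):
    return SessionRecord(subject_id=sid, label=label,
                         blocks={m: rng.normal(size=(t, d))
                                 for m, d in dims.items()})


class TestFullModel:
    def test_absent_modalities_are_ignored(self, rng):
        cfg = tiny_fusion(use_audio=False, use_text=False)
        model = FusionModel(cfg, TINY_DIMS, seed=1)
        rec = _record(rng)
        p1 = model.predict_proba([rec])[0]
        rec.blocks["audio"] = rng.normal(size=rec.blocks["audio"].shape) * 100
        rec.blocks["text"] = rng.normal(size=rec.blocks["text"].shape) * 100
        p2 = model.predict_proba([rec])[0]
        assert p1 == p2
        assert "audio" not in model.stages and "text" not in model.stages
        assert "audio" not in model.projections

    def test_all_64_strategy_triples_finite(self, rng):
        rec = _record(rng)
        probs = []
        for vis in STRATEGIES:
            for aud in STRATEGIES:
                for txt in STRATEGIES:
                    cfg = tiny_fusion(vis_fusion=vis, audio_fusion=aud,
                                      text_fusion=txt)
                    model = FusionModel(cfg, TINY_DIMS, seed=2)
                    probs.append(model.predict_proba([rec])[0])
        probs = np.array(probs)
        assert probs.shape == (64,)
        assert np.all(np.isfinite(probs))
        assert np.all((probs > 0) & (probs < 1))

    def test_repeat_forward_identical(self, rng):
        model = FusionModel(tiny_fusion(vis_fusion="attention"), TINY_DIMS,
                            seed=3)
        rec = _record(rng)
        assert model.predict_proba([rec])[0] == model.predict_proba([rec])[0]

    def test_utterance_permutation_invariance(self, rng):
        """Session probability is invariant to utterance reordering."""
        for strat in STRATEGIES:
            model = FusionModel(tiny_fusion(vis_fusion=strat,
                                            audio_fusion=strat,
                                            text_fusion=strat),
                                TINY_DIMS, seed=4)
            rec = _record(rng, t=6)
            perm = np.random.default_rng(7).permutation(6)
            shuffled = SessionRecord(
                subject_id="S0", label=0,
                blocks={m: b[perm] for m, b in rec.blocks.items()})
            p1 = model.predict_proba([rec])[0]
            p2 = model.predict_proba([shuffled])[0]
            assert p1 == pytest.approx(p2, abs=1e-10), strat

    def test_trace_bundle_contents(self, rng):
        model = FusionModel(tiny_fusion(vis_fusion="gated",
                                        audio_fusion="attention",
                                        text_fusion="gated"),
                            TINY_DIMS, seed=5)
        _, traces = model.predict_proba([_record(rng, t=4)], with_traces=True)
        tr = traces[0]
        assert set(tr.gate_vectors) == {"vis", "text"}
        assert set(tr.attention_maps) == {"audio"}
        for g in tr.gate_vectors.values():
            assert np.all((g > 0) & (g < 1))
        np.testing.assert_allclose(tr.attention_maps["audio"].sum(axis=1),
                                   1.0, atol=1e-6)
        assert tr.pooling_weights.sum() == pytest.approx(1.0, abs=1e-6)

    def test_missing_block_raises(self, rng):
        model = FusionModel(tiny_fusion(), TINY_DIMS, seed=6)
        rec = _record(rng)
        del rec.blocks["text"]
        with pytest.raises(KeyError, match="text"):
            model.forward_session(rec)

    def test_wrong_width_raises(self, rng):
        model = FusionModel(tiny_fusion(), TINY_DIMS, seed=6)
        rec = _record(rng)
        rec.blocks["audio"] = rng.normal(size=(5, 99))
        with pytest.raises(ValueError, match="width"):
            model.forward_session(rec)


def test_checkpoint_round_trip(tmp_path, rng):
    model = FusionModel(tiny_fusion(vis_fusion="gated"), TINY_DIMS, seed=8)
    model.predict_proba([_record(rng)])  # touch batchnorm buffers
    save_checkpoint(model, tmp_path / "ckpt", meta={"seed": 8})
    state, meta = load_checkpoint(tmp_path / "ckpt")
    assert meta["seed"] == 8
    model2 = FusionModel(tiny_fusion(vis_fusion="gated"), TINY_DIMS, seed=99)
    model2.load_state_dict(state)
    for k, v in model2.state_dict().items():
        np.testing.assert_array_equal(v, state[k], err_msg=k)
    rec = _record(rng)
    assert model.predict_proba([rec])[0] == model2.predict_proba([rec])[0]
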