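"""The fusion network: attention, splitting, scenarios, alignment, predict."""

import numpy as np
import pytest

from mumo import nn
from mumo.features import TokenSequence
from mumo.fusion import (FusionConfig, MuMoNet, PatientFeatures,
                         alignment_loss, cross_attention)
from mumo.nn import Tensor


def attention_oracle(Q, K, V, heads):
    """Straight-line multi-head scaled-dot-product attention (no mixing)."""
    nq, d = Q.shape
    hd = d // heads
    out = np.zeros((nq, d))
    for h in range(heads):
        sl = slice(h * hd, (h + 1) * hd)
        S = Q[:, sl] @ K[:, sl].T / np.sqrt(hd)
        A = np.exp(S - S.max(axis=1, keepdims=True))
        A /= A.sum(axis=1, keepdims=True)
        out[:, sl] = A @ V[:, sl]
    return out


def infonce_oracle(A, R, tau):
    """Straight-line symmetric InfoNCE over cosine similarities."""
    An = A / np.linalg.norm(A, axis=1, keepdims=True)
    Rn = R / np.linalg.norm(R, axis=1, keepdims=True)
    S = An @ Rn.T / tau
    B = len(A)
    total = 0.0
    for i in range(B):
        total += -np.log(np.exp(S[i, i]) / np.exp(S[i]).sum())
        total += -np.log(np.exp(S[i, i]) / np.exp(S[:, i]).sum())
    return total / (2 * B)


def small_config(**over):
    kw = dict(d=16, heads=4, d_word=8, omics_dim=20, att_hidden=8,
              mlp_hidden=8, path_token_width=6, rad_token_width=5,
              info_token_width=7, seed=0)
    kw.update(over)
    return FusionConfig(**kw)


def make_sample(rng, has_path=True, has_rad=True, cfg=None, label=1):
    cfg = cfg or small_config()
    def tokens(width, n=3):
        return TokenSequence(rng.uniform(size=(n, width)), np.ones(n),
                             tuple(f"f{i}" for i in range(n)))
    s = PatientFeatures(patient_id="P0", label=label,
                        info_tokens=tokens(cfg.info_token_width))
    if has_path:
        s.path_words = [rng.uniform(size=(4, 3, 16, 16)) for _ in range(2)]
        s.path_omics = rng.normal(size=20)
        s.path_tokens = tokens(cfg.path_token_width)
    if has_rad:
        s.rad_words = [rng.uniform(size=(4, 1, 16, 16))]
        s.rad_omics = rng.normal(size=20)
        s.rad_tokens = tokens(cfg.rad_token_width)
    return s


class TestCrossAttention:
    def test_single_token_returns_value(self, rng):
        Q = Tensor(rng.normal(size=(1, 16)))
        V = Tensor(rng.normal(size=(1, 16)))
        out = cross_attention(Q, Tensor(rng.normal(size=(1, 16))), V, heads=4)
        assert np.allclose(out.data, V.data, atol=1e-12)

    def test_equal_scores_average_values(self, rng):
        # zero query -> all scores equal -> uniform attention
        Q = Tensor(np.zeros((1, 8)))
        K = Tensor(rng.normal(size=(2, 8)))
        V = Tensor(rng.normal(size=(2, 8)))
        out = cross_attention(Q, K, V, heads=2)
        assert np.allclose(out.data, V.data.mean(axis=0), atol=1e-12)

    def test_matches_straight_line_oracle(self, rng):
        Q = rng.normal(size=(3, 16))
        K = rng.normal(size=(5, 16))
        V = rng.normal(size=(5, 16))
        got = cross_attention(Tensor(Q), Tensor(K), Tensor(V), heads=4)
        assert np.abs(got.data - attention_oracle(Q, K, V, 4)).max() < 1e-6

    def test_mismatched_kv_counts_raise(self, rng):
        with pytest.raises(ValueError, match="equal counts"):
            cross_attention(Tensor(rng.normal(size=(1, 8))),
                            Tensor(rng.normal(size=(2, 8))),
                            Tensor(rng.normal(size=(3, 8))), heads=2)


class TestAlignmentLoss:
    def test_single_identical_pair_is_zero(self, rng):
        v = rng.normal(size=8)
        loss = alignment_loss([(Tensor(v), Tensor(v.copy()))], temperature=0.1)
        assert loss.item() == pytest.approx(0.0, abs=1e-12)

    def test_two_pair_closed_form(self):
        e1 = np.zeros(8); e1[0] = 1.0
        e2 = np.zeros(8); e2[1] = 1.0
        pairs = [(Tensor(e1), Tensor(e1.copy())), (Tensor(e2), Tensor(e2.copy()))]
        loss = alignment_loss(pairs, temperature=1.0)
        assert loss.item() == pytest.approx(np.log(1 + np.exp(-1)), abs=1e-9)

    def test_matches_infonce_oracle(self, rng):
        A = rng.normal(size=(5, 8))
        R = rng.normal(size=(5, 8))
        pairs = [(Tensor(a), Tensor(r)) for a, r in zip(A, R)]
        got = alignment_loss(pairs, temperature=0.3)
        assert got.item() == pytest.approx(infonce_oracle(A, R, 0.3), abs=1e-6)

    def test_empty_batch_returns_zero(self):
        assert alignment_loss([], temperature=0.1).item() == 0.0

    def test_nonnegative_on_random_batches(self, rng):
        for _ in range(10):
            pairs = [(Tensor(rng.normal(size=6)), Tensor(rng.normal(size=6)))
                     for _ in range(4)]
            assert alignment_loss(pairs, 0.2).item() >= -1e-9


class TestSplitAndScenarios:
    def test_split_affine_at_zero_gives_bias(self):
        net = MuMoNet(small_config())
        s, a = net.split_features("path", Tensor(np.zeros(16)))
        assert np.allclose(s.data, net.params["path.split_s.b"].data)
        assert np.allclose(a.data, net.params["split_a.b"].data)

    def test_split_homogeneous_with_zero_bias(self, rng):
        net = MuMoNet(small_config())
        net.params["path.split_s.b"].data[:] = 0
        net.params["split_a.b"].data[:] = 0
        f = rng.normal(size=16)
        s1, a1 = net.split_features("path", Tensor(f))
        s2, a2 = net.split_features("path", Tensor(3.0 * f))
        assert np.allclose(3 * s1.data, s2.data)
        assert np.allclose(3 * a1.data, a2.data)

    def test_agnostic_map_is_shared_across_modalities(self, rng):
        net = MuMoNet(small_config())
        f = Tensor(rng.normal(size=16))
        _, a_path = net.split_features("path", f)
        _, a_rad = net.split_features("rad", f)
        assert np.allclose(a_path.data, a_rad.data)

    def test_all_scenarios_have_dim_3d(self, rng):
        net = MuMoNet(small_config())
        fp = Tensor(rng.normal(size=16))
        fr = Tensor(rng.normal(size=16))
        for args in [(fp, fr), (fp, None), (None, fr)]:
            fused, *_ = net.inter_modal_fuse(*args)
            assert fused.shape == (48,)

    def test_scenario_one_mean_of_equal_agnostics(self, rng):
        net = MuMoNet(small_config())
        f = Tensor(rng.normal(size=16))
        fused, eligible, pa, ra = net.inter_modal_fuse(f, f)
        assert eligible
        assert np.allclose(fused.data[16:32], pa.data)
        assert np.allclose(pa.data, ra.data)

    def test_scenario_two_embeds_rad_placeholder_bitwise(self, rng):
        net = MuMoNet(small_config())
        fused, eligible, *_ = net.inter_modal_fuse(Tensor(rng.normal(size=16)),
                                                   None)
        assert not eligible
        assert np.array_equal(fused.data[32:], net.params["placeholder.rad"].data)

    def test_scenario_three_embeds_path_placeholder_bitwise(self, rng):
        net = MuMoNet(small_config())
        fused, eligible, *_ = net.inter_modal_fuse(None,
                                                   Tensor(rng.normal(size=16)))
        assert not eligible
        assert np.array_equal(fused.data[:16],
                              net.params["placeholder.path"].data)

    def test_both_absent_raises(self):
        net = MuMoNet(small_config())
        with pytest.raises(ValueError, match="both modalities absent"):
            net.inter_modal_fuse(None, None)


class TestForward:
    @pytest.mark.parametrize("has_path,has_rad", [(True, True), (True, False),
                                                  (False, True)])
    def test_probabilities_for_every_availability_pattern(self, rng, has_path,
                                                          has_rad):
        net = MuMoNet(small_config())
        out = net.forward(make_sample(rng, has_path, has_rad))
        assert out.probs.shape == (2,)
        assert np.all(out.probs.data >= 0)
        assert out.probs.data.sum() == pytest.approx(1.0, abs=1e-7)
        assert out.fused.shape == (48,)
        assert out.eligible_for_alignment == (has_path and has_rad)

    def test_intra_fuse_residual_identity_at_zero_attention(self, rng):
        net = MuMoNet(small_config())
        for pre in ("path.intra", "path.report"):
            net.params[f"{pre}.Wo"].data[:] = 0
            net.params[f"{pre}.bo"].data[:] = 0
        f = rng.normal(size=16)
        toks = TokenSequence(rng.uniform(size=(3, 6)), np.ones(3), ("a", "b", "c"))
        out = net.intra_modal_fuse("path", Tensor(f), toks)
        assert np.allclose(out.data, f, atol=1e-12)

    def test_patient_fuse_residual_at_zero_value_maps(self, rng):
        net = MuMoNet(small_config())
        net.params["pinfo.Wv"].data[:] = 0
        net.params["pinfo.bv"].data[:] = 0
        net.params["pinfo.Wo"].data[:] = 0
        net.params["pinfo.bo"].data[:] = 0
        fi = rng.normal(size=48)
        toks = TokenSequence(np.zeros((2, 7)), np.zeros(2), ("x", "y"))
        out = net.patient_fuse(Tensor(fi), toks)
        expected = fi @ net.params["pinfo.Wproj"].data + net.params["pinfo.bproj"].data
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_predict_softmax_properties(self, rng):
        net = MuMoNet(small_config())
        probs = net.predict(Tensor(rng.normal(size=16)))
        assert probs.data.sum() == pytest.approx(1.0, abs=1e-7)
        net.params["mlp.W2"].data[:] = 0
        net.params["mlp.b2"].data[:] = 0
        probs = net.predict(Tensor(rng.normal(size=16)))
        assert np.allclose(probs.data, [0.5, 0.5])

    def test_forward_deterministic(self, rng):
        net = MuMoNet(small_config())
        s = make_sample(rng)
        a = net.forward(s).probs.data
        b = net.forward(s).probs.data
        assert np.array_equal(a, b)

    def test_placeholder_gradients_flow_iff_modality_absent(self, rng):
        net = MuMoNet(small_config())
        # scenario II: radiology absent -> rad placeholder receives gradient
        out = net.forward(make_sample(rng, has_path=True, has_rad=False))
        (out.probs[0].log() * -1).backward()
        g_rad = net.params["placeholder.rad"].grad
        g_path = net.params["placeholder.path"].grad
        assert g_rad is not None and np.abs(g_rad).sum() > 0
        assert g_path is None
        # scenario I: both present -> neither placeholder updated
        net2 = MuMoNet(small_config())
        out2 = net2.forward(make_sample(rng, True, True))
        (out2.probs[0].log() * -1).backward()
        assert net2.params["placeholder.rad"].grad is None
        assert net2.params["placeholder.path"].grad is None


class TestCombinersAndPersistence:
    @pytest.mark.parametrize("combiner,dim", [("concat", 32), ("sum", 16),
                                              ("multiply", 16)])
    def test_simple_combiner_dims(self, rng, combiner, dim):
        cfg = small_config(combiner=combiner)
        net = MuMoNet(cfg)
        out = net.forward(make_sample(rng, cfg=cfg))
        assert out.fused.shape == (dim,)
        assert not out.eligible_for_alignment

    @pytest.mark.parametrize("mods", [("path",), ("rad",)])
    def test_unimodal_models(self, rng, mods):
        cfg = small_config(modalities=mods)
        net = MuMoNet(cfg)
        out = net.forward(make_sample(rng, cfg=cfg))
        assert out.fused.shape == (16,)
        assert out.probs.data.sum() == pytest.approx(1.0, abs=1e-7)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        net = MuMoNet(small_config())
        s = make_sample(rng)
        before = net.forward(s).probs.data
        path = tmp_path / "model.npz"
        net.save(path)
        net2 = MuMoNet.load(path)
        assert net2.config == net.config
        assert np.array_equal(net2.forward(s).probs.data, before)
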