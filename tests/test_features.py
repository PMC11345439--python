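"""Deep/omics feature extraction and parameterless encoders."""

import numpy as np
import pytest

from mumo import features as ft
from mumo.nn import Tensor


# -- independent straight-line oracles --------------------------------------

def gated_attention_oracle(H, V, U, w):
    """Direct evaluation of softmax(w^T (tanh(HV) * sigmoid(HU))) pooling."""
    gate = np.tanh(H @ V) * (1.0 / (1.0 + np.exp(-(H @ U))))
    s = gate @ w
    a = np.exp(s - s.max())
    a = (a / a.sum()).ravel()
    return a @ H, a


def first_order_oracle(vals):
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    std = var ** 0.5
    if std > 0:
        skew = (sum((v - mean) ** 3 for v in vals) / n) / std ** 3
        kurt = (sum((v - mean) ** 4 for v in vals) / n) / std ** 4 - 3.0
    else:
        skew = kurt = 0.0
    return mean, std, skew, kurt, sum(v * v for v in vals)


def glcm_oracle(image, mask, levels=32):
    """Pair-counting oracle for masked GLCM statistics (4 directions,
    symmetric, distance 1), independent of any library."""
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.clip(((image - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    else:
        q = np.zeros(image.shape, dtype=int)
    h, w = image.shape
    out = []
    for dr, dc in [(0, 1), (-1, 1), (-1, 0), (-1, -1)]:
        P = np.zeros((levels, levels))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    P[q[r, c], q[r2, c2]] += 1
                    P[q[r2, c2], q[r, c]] += 1  # symmetric
        if P.sum() == 0:
            continue
        P /= P.sum()
        i = np.arange(levels, dtype=float)
        pi, pj = P.sum(1), P.sum(0)
        mi, mj = i @ pi, i @ pj
        vi, vj = ((i - mi) ** 2) @ pi, ((i - mj) ** 2) @ pj
        d2 = (i[:, None] - i[None, :]) ** 2
        contrast = (P * d2).sum()
        corr = ((P * np.outer(i - mi, i - mj)).sum() / np.sqrt(vi * vj)
                if vi > 0 and vj > 0 else 1.0)
        out.append((contrast, corr, (P ** 2).sum(), (P / (1 + d2)).sum()))
    return tuple(np.mean(out, axis=0))


class TestEmbedWords:
    def test_identical_words_identical_rows(self, rng):
        w = rng.uniform(size=(16, 16, 3))
        feats = ft.embed_words([w, w.copy()], seed=0)
        assert np.array_equal(feats[0], feats[1])

    def test_shape_contract(self, rng):
        words = [rng.uniform(size=(16, 16, 3)) for _ in range(5)]
        feats = ft.embed_words(words, seed=0)
        assert feats.shape == (5, 32)

    def test_seeded_determinism(self, rng):
        words = [rng.uniform(size=(16, 16, 3)) for _ in range(3)]
        a = ft.embed_words(words, seed=4)
        b = ft.embed_words(words, seed=4)
        assert np.array_equal(a, b)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ft.embed_words([])


class TestAggregateMil:
    def test_identical_words_give_uniform_importance(self):
        v = np.linspace(-1, 1, 8)
        bags = [np.tile(v, (3, 1)) for _ in range(4)]
        _, imp = ft.aggregate_mil(bags, seed=0)
        assert np.allclose(imp, 0.25, atol=1e-12)

    def test_importance_nonneg_sums_to_one(self, rng):
        bags = [rng.normal(size=(rng.integers(1, 5), 8)) for _ in range(5)]
        _, imp = ft.aggregate_mil(bags, seed=1)
        assert np.all(imp >= 0) and imp.sum() == pytest.approx(1.0)

    def test_bag_permutation_equivariance(self, rng):
        bags = [rng.normal(size=(3, 8)) for _ in range(4)]
        agg = ft.MILAggregator(d_word=8, seed=2)
        f1, i1 = agg.forward([Tensor(b) for b in bags])
        perm = [2, 0, 3, 1]
        f2, i2 = agg.forward([Tensor(bags[p]) for p in perm])
        assert np.allclose(f1.data, f2.data, atol=1e-12)
        assert np.allclose(i1.data[perm], i2.data, atol=1e-12)

    def test_word_order_invariance_within_bag(self, rng):
        bag = rng.normal(size=(6, 8))
        agg = ft.MILAggregator(d_word=8, seed=3)
        f1, _ = agg.forward([Tensor(bag)])
        f2, _ = agg.forward([Tensor(bag[::-1].copy())])
        assert np.allclose(f1.data, f2.data, atol=1e-12)

    def test_matches_brute_force_pooling_oracle(self, rng):
        bags = [rng.normal(size=(4, 8)) for _ in range(3)]
        agg = ft.MILAggregator(d_word=8, hidden=16, seed=5)
        got_f, got_imp = agg.forward([Tensor(b) for b in bags])
        wp = {k.split(".")[-1]: v.data for k, v in agg.word_pool.params.items()}
        bp = {k.split(".")[-1]: v.data for k, v in agg.bag_pool.params.items()}
        bag_feats = np.stack([gated_attention_oracle(b, wp["V"], wp["U"],
                                                     wp["w"])[0] for b in bags])
        exp_f, exp_imp = gated_attention_oracle(bag_feats, bp["V"], bp["U"],
                                                bp["w"])
        assert np.abs(got_f.data - exp_f).max() < 1e-6
        assert np.abs(got_imp.data - exp_imp).max() < 1e-6

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="inconsistent"):
            ft.aggregate_mil([rng.normal(size=(2, 8)),
                              rng.normal(size=(2, 6))], seed=0)


class TestOmicsFeatures:
    def test_constant_image_identities(self):
        img = np.full((12, 12), 3.5)
        mask = np.ones((12, 12), dtype=bool)
        om = ft.omics_features(img, mask)
        assert om["mean"] == pytest.approx(3.5)
        assert om["std"] == 0.0
        assert om["skewness"] == 0.0
        assert om["glcm_energy"] == pytest.approx(1.0)

    def test_square_mask_circularity_is_pi_over_four(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[4:36, 4:36] = True
        om = ft.omics_features(np.random.default_rng(0).uniform(size=(40, 40)),
                               mask)
        assert om["circularity"] == pytest.approx(np.pi / 4, abs=0.02)

    def test_first_order_matches_straight_line_oracle(self, rng):
        for _ in range(20):
            img = rng.uniform(size=(16, 16))
            mask = rng.uniform(size=(16, 16)) < 0.6
            if not mask.any():
                continue
            om = ft.omics_features(img, mask)
            mean, std, skew, kurt, energy = first_order_oracle(list(img[mask]))
            assert om["mean"] == pytest.approx(mean, abs=1e-6)
            assert om["std"] == pytest.approx(std, abs=1e-6)
            assert om["skewness"] == pytest.approx(skew, abs=1e-6)
            assert om["kurtosis"] == pytest.approx(kurt, abs=1e-6)
            assert om["energy"] == pytest.approx(energy, abs=1e-6)
            assert om["min"] == pytest.approx(img[mask].min())
            assert om["max"] == pytest.approx(img[mask].max())

    def test_glcm_matches_pair_counting_oracle(self, rng):
        for _ in range(5):
            img = rng.uniform(size=(12, 12))
            mask = rng.uniform(size=(12, 12)) < 0.7
            mask[5:8, 5:8] = True
            om = ft.omics_features(img, mask)
            contrast, corr, energy, homog = glcm_oracle(img, mask)
            assert om["glcm_contrast"] == pytest.approx(contrast, abs=1e-6)
            assert om["glcm_correlation"] == pytest.approx(corr, abs=1e-6)
            assert om["glcm_energy"] == pytest.approx(energy, abs=1e-6)
            assert om["glcm_homogeneity"] == pytest.approx(homog, abs=1e-6)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            ft.omics_features(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))


class TestEncoders:
    def test_report_encoding_deterministic_and_local(self):
        cb = ft.load_codebook("rad_report")
        base = dict(post_gastrectomy=False, n_met_lymph_nodes=5,
                    ln_locations=["celiac"], liver_met=False, lung_met=False,
                    peritoneal_met=False, ln_type_diversity=1)
        a = cb.encode(base)
        b = cb.encode(base)
        assert np.array_equal(a.tokens, b.tokens)
        flipped = cb.encode({**base, "peritoneal_met": True})
        diff_fields = np.where(
            np.any(a.tokens != flipped.tokens, axis=1))[0]
        assert list(a.field_names[i] for i in diff_fields) == ["peritoneal_met"]

    def test_count_min_max_scaling(self):
        cb = ft.load_codebook("rad_report")
        seq = cb.encode(dict(post_gastrectomy=False, n_met_lymph_nodes=5,
                             ln_locations=["celiac"], liver_met=False,
                             lung_met=False, peritoneal_met=False,
                             ln_type_diversity=1))
        i = seq.field_names.index("n_met_lymph_nodes")
        slot = cb.slots["n_met_lymph_nodes"][0]
        assert seq.tokens[i, slot] == pytest.approx(5 / 20)

    def test_age_min_max_scaling(self):
        cb = ft.load_codebook("patient_info")
        seq = cb.encode(dict(age=63))
        i = seq.field_names.index("age")
        assert seq.tokens[i, cb.slots["age"][0]] == pytest.approx(45 / 82)

    def test_na_gives_zero_token_presence_zero(self):
        cb = ft.load_codebook("patient_info")
        seq = cb.encode(dict(age=63, pdl1="NA"))
        i = seq.field_names.index("pdl1")
        assert seq.presence[i] == 0.0
        assert np.all(seq.tokens[i] == 0.0)

    def test_out_of_vocabulary_raises(self):
        cb = ft.load_codebook("patient_info")
        with pytest.raises(ValueError, match="vocabulary"):
            cb.encode(dict(sex="other"))

    def test_encoders_injective_by_sampling(self, rng):
        cb = ft.load_codebook("path_report")
        seen = {}
        for _ in range(50):
            rep = dict(tumor_proportion=float(np.round(rng.uniform(), 3)),
                       til_level=float(np.round(rng.uniform(), 3)),
                       her2_heterogeneity=sorted(
                           rng.choice(["0", "1+", "2+", "3+"],
                                      size=rng.integers(1, 4),
                                      replace=False).tolist()))
            seq = cb.encode(rep)
            sig = seq.tokens.tobytes()
            if sig in seen:
                assert seen[sig] == rep
            seen[sig] = rep
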