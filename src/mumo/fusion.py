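"""The multi-modal fusion network.

Per patient, each available modality (pathology, radiology) contributes an
image feature (MIL-aggregated deep feature combined with an omics vector and
projected to dimension ``d``) and a structured-report token sequence. The
network then applies:

* **intra-modal fusion** — the image feature forms a query/key/value triple;
  one cross-attention merges image-derived V with Q, a second attends from Q
  over report-derived keys/values; both outputs are added residually to the
  image feature, giving modal features ``F_path`` / ``F_rad``;
* **inter-modal fusion** — each modal feature is split into a modal-specific
  part (modality-specific affine map) and a modal-agnostic part (an affine
  map *shared* across modalities). With both modalities present the fused
  feature is ``[F_path_s | mean(F_path_a, F_rad_a) | F_rad_s]`` (dim 3d) and
  the patient is eligible for the contrastive alignment loss; with one
  modality absent a learnable placeholder vector fills the missing specific
  slot and the single agnostic feature stands in for the average;
* **contrastive alignment** — a symmetric InfoNCE over cosine similarities
  pulls the two agnostic features of the same patient together against
  in-batch negatives, encouraging one modality-invariant embedding space;
* **patient-information fusion** — a query derived from the fused feature
  attends over encoded patient-information tokens, with a residual
  projection of the fused feature;
* **prediction** — a two-layer MLP with softmax; the risk score is the
  probability of non-response (higher = worse expected outcome).

Simpler inter-modal combiners (element-wise product, sum, plain
concatenation) and unimodal variants are available for ablations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .nn import Tensor
from .features import (MILAggregator, SmallConvBackbone, TokenSequence)

__all__ = ["FusionConfig", "MuMoNet", "cross_attention", "alignment_loss",
           "ForwardOutput", "PatientFeatures"]

COMBINERS = ("full", "concat", "sum", "multiply")


@dataclass
class FusionConfig:
    """Architecture settings (desk-scale defaults; all configurable)."""

    d: int = 64
    heads: int = 4
    d_word: int = 32
    omics_dim: int = 20
    att_hidden: int = 32
    mlp_hidden: int = 32
    temperature: float = 0.1
    combiner: str = "full"
    modalities: tuple[str, ...] = ("path", "rad")
    use_reports: bool = True
    use_info: bool = True
    path_token_width: int = 0
    rad_token_width: int = 0
    info_token_width: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.d % self.heads != 0:
            raise ValueError("d must be divisible by heads")
        if self.combiner not in COMBINERS:
            raise ValueError(f"combiner must be one of {COMBINERS}")
        if not self.modalities or any(m not in ("path", "rad")
                                      for m in self.modalities):
            raise ValueError("modalities must be a non-empty subset of (path, rad)")

    @property
    def head_dim(self) -> int:
        return self.d // self.heads

    @property
    def fused_dim(self) -> int:
        if len(self.modalities) == 1:
            return self.d
        return {"full": 3 * self.d, "concat": 2 * self.d,
                "sum": self.d, "multiply": self.d}[self.combiner]


@dataclass
class PatientFeatures:
    """Precomputed per-patient inputs to the network (no learnable state).

    ``*_words`` are lists of (n_words, C, h, w) arrays — one per bag; omics
    vectors are standardised; token sequences come from the parameterless
    encoders (zero sequences for absent reports).
    """

    patient_id: str
    label: Optional[int]  # 1 = responder, 0 = non-responder, None = excluded
    info_tokens: TokenSequence
    path_words: Optional[list[np.ndarray]] = None
    path_omics: Optional[np.ndarray] = None
    path_tokens: Optional[TokenSequence] = None
    rad_words: Optional[list[np.ndarray]] = None
    rad_omics: Optional[np.ndarray] = None
    rad_tokens: Optional[TokenSequence] = None

    @property
    def has_path(self) -> bool:
        return self.path_words is not None

    @property
    def has_rad(self) -> bool:
        return self.rad_words is not None


@dataclass
class ForwardOutput:
    probs: Tensor                      # (2,) = (non-response risk, response)
    fused: Tensor                      # F_inter
    path_agnostic: Optional[Tensor]
    rad_agnostic: Optional[Tensor]
    eligible_for_alignment: bool
    bag_importance: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def risk_score(self) -> float:
        return float(self.probs.data[0])


def cross_attention(Q: Tensor, K: Tensor, V: Tensor, heads: int,
                    W_o: Tensor | None = None,
                    b_o: Tensor | None = None) -> Tensor:
    """Scaled-dot-product multi-head attention.

    ``Q``: (n_q, d); ``K``/``V``: (n_k, d). Per head,
    ``softmax(Q Kᵀ / sqrt(head_dim)) V``; heads are concatenated and, when an
    output map is given, linearly mixed. Returns (n_q, d).
    """
    if K.shape[0] != V.shape[0]:
        raise ValueError("cross_attention: K and V must have equal counts")
    n_q, d = Q.shape
    n_k = K.shape[0]
    if d % heads != 0:
        raise ValueError("feature dim must be divisible by heads")
    hd = d // heads
    Qh = Q.reshape(n_q, heads, hd).transpose(1, 0, 2)   # (h, n_q, hd)
    Kh = K.reshape(n_k, heads, hd).transpose(1, 0, 2)
    Vh = V.reshape(n_k, heads, hd).transpose(1, 0, 2)
    scores = (Qh @ Kh.transpose(0, 2, 1)) * (1.0 / np.sqrt(hd))
    attn = scores.softmax(axis=-1)                      # (h, n_q, n_k)
    out = (attn @ Vh).transpose(1, 0, 2).reshape(n_q, d)
    if W_o is not None:
        out = out @ W_o
        if b_o is not None:
            out = out + b_o
    return out


def alignment_loss(pairs: Sequence[tuple[Tensor, Tensor]],
                   temperature: float = 0.1) -> Tensor:
    """Symmetric InfoNCE over cosine similarities of modal-agnostic pairs.

    For patient i the positive is its own cross-modal pair; negatives are the
    other patients' opposite-modality features. Averaged over both directions
    and the batch. Empty input returns 0.
    """
    if len(pairs) == 0:
        return Tensor(0.0)
    eps = 1e-12

    def normalize(x: Tensor) -> Tensor:
        return x * ((x * x).sum() + eps) ** -0.5

    A = nn.stack([normalize(a) for a, _ in pairs], axis=0)   # (B, d)
    R = nn.stack([normalize(r) for _, r in pairs], axis=0)
    S = (A @ R.T) * (1.0 / temperature)                      # (B, B)
    B = len(pairs)
    idx = np.arange(B)
    loss_ar = (S.logsumexp(axis=1) - S[idx, idx]).mean()
    loss_ra = (S.T.logsumexp(axis=1) - S[idx, idx]).mean()
    return (loss_ar + loss_ra) * 0.5


class MuMoNet:
    """All learnable state plus the forward pass of the fusion model."""

    def __init__(self, config: FusionConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, dw = config.d, config.d_word
        self.params: dict[str, Tensor] = {}
        p = self.params

        self.backbones: dict[str, SmallConvBackbone] = {}
        self.aggregators: dict[str, MILAggregator] = {}
        seeds = rng.integers(0, 2 ** 31 - 1, size=8)
        for k, mod in enumerate(config.modalities):
            in_ch = 3 if mod == "path" else 1
            bb = SmallConvBackbone(d_word=dw, in_channels=in_ch,
                                   seed=int(seeds[k]), prefix=f"{mod}.backbone")
            agg = MILAggregator(d_word=dw, hidden=config.att_hidden,
                                seed=int(seeds[k + 2]), prefix=f"{mod}.mil")
            self.backbones[mod] = bb
            self.aggregators[mod] = agg
            p.update(bb.params)
            p.update(agg.params)
            # combine deep (+) omics -> d
            p[f"{mod}.comb.W"] = nn.glorot(rng, dw + config.omics_dim, d)
            p[f"{mod}.comb.b"] = nn.zeros(d)
            # intra-modal attention: image-derived Q, K, V
            for name in ("q", "k", "v"):
                p[f"{mod}.intra.W{name}"] = nn.glorot(rng, d, d)
                p[f"{mod}.intra.b{name}"] = nn.zeros(d)
            p[f"{mod}.intra.Wo"] = nn.glorot(rng, d, d)
            p[f"{mod}.intra.bo"] = nn.zeros(d)
            # report-derived K', V' (token width + presence flag)
            tw = (config.path_token_width if mod == "path"
                  else config.rad_token_width) + 1
            for name in ("k", "v"):
                p[f"{mod}.report.W{name}"] = nn.glorot(rng, tw, d)
                p[f"{mod}.report.b{name}"] = nn.zeros(d)
            p[f"{mod}.report.Wo"] = nn.glorot(rng, d, d)
            p[f"{mod}.report.bo"] = nn.zeros(d)
            # modal-specific split map
            p[f"{mod}.split_s.W"] = nn.glorot(rng, d, d)
            p[f"{mod}.split_s.b"] = nn.zeros(d)
            # placeholder for this modality when absent
            p[f"placeholder.{mod}"] = Tensor(rng.normal(0, 0.1, size=d),
                                             requires_grad=True)
        # shared modal-agnostic map
        p["split_a.W"] = nn.glorot(rng, d, d)
        p["split_a.b"] = nn.zeros(d)
        # patient-information fusion
        fd = config.fused_dim
        iw = config.info_token_width + 1
        p["pinfo.Wq"] = nn.glorot(rng, fd, d)
        p["pinfo.bq"] = nn.zeros(d)
        p["pinfo.Wk"] = nn.glorot(rng, iw, d)
        p["pinfo.bk"] = nn.zeros(d)
        p["pinfo.Wv"] = nn.glorot(rng, iw, d)
        p["pinfo.bv"] = nn.zeros(d)
        p["pinfo.Wo"] = nn.glorot(rng, d, d)
        p["pinfo.bo"] = nn.zeros(d)
        p["pinfo.Wproj"] = nn.glorot(rng, fd, d)
        p["pinfo.bproj"] = nn.zeros(d)
        # predictor MLP
        p["mlp.W1"] = nn.glorot(rng, d, config.mlp_hidden)
        p["mlp.b1"] = nn.zeros(config.mlp_hidden)
        p["mlp.W2"] = nn.glorot(rng, config.mlp_hidden, 2)
        p["mlp.b2"] = nn.zeros(2)

    # -- building blocks --------------------------------------------------
    @staticmethod
    def _tokens_tensor(tokens: TokenSequence) -> Tensor:
        """Tokens with the presence flag appended as the last column."""
        return Tensor(np.concatenate(
            [tokens.tokens, tokens.presence[:, None]], axis=1))

    def image_feature(self, mod: str, words: list[np.ndarray],
                      omics: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """Backbone + MIL aggregation + deep/omics combination -> dim d."""
        counts = [w.shape[0] for w in words]
        flat = Tensor(np.concatenate(words, axis=0))
        emb = self.backbones[mod].forward(flat)
        bags, start = [], 0
        for c in counts:
            bags.append(emb[start:start + c])
            start += c
        deep, importance = self.aggregators[mod].forward(bags)
        combined = nn.concat([deep, Tensor(np.asarray(omics))], axis=0)
        feat = combined @ self.params[f"{mod}.comb.W"] + self.params[f"{mod}.comb.b"]
        return feat, importance.data

    def intra_modal_fuse(self, mod: str, image_feature: Tensor,
                         report_tokens: TokenSequence) -> Tensor:
        """F_mod = f + CrossAttn(Q,K,V) + CrossAttn(Q,K',V')."""
        p, h = self.params, self.config.heads
        f = image_feature.reshape(1, self.config.d)
        Q = f @ p[f"{mod}.intra.Wq"] + p[f"{mod}.intra.bq"]
        K = f @ p[f"{mod}.intra.Wk"] + p[f"{mod}.intra.bk"]
        V = f @ p[f"{mod}.intra.Wv"] + p[f"{mod}.intra.bv"]
        att_img = cross_attention(Q, K, V, h, p[f"{mod}.intra.Wo"],
                                  p[f"{mod}.intra.bo"])
        toks = self._tokens_tensor(report_tokens)
        Kp = toks @ p[f"{mod}.report.Wk"] + p[f"{mod}.report.bk"]
        Vp = toks @ p[f"{mod}.report.Wv"] + p[f"{mod}.report.bv"]
        att_rep = cross_attention(Q, Kp, Vp, h, p[f"{mod}.report.Wo"],
                                  p[f"{mod}.report.bo"])
        return (f + att_img + att_rep).reshape(self.config.d)

    def split_features(self, mod: str, f: Tensor) -> tuple[Tensor, Tensor]:
        """(modal-specific, modal-agnostic); the agnostic map is shared."""
        p = self.params
        specific = f @ p[f"{mod}.split_s.W"] + p[f"{mod}.split_s.b"]
        agnostic = f @ p["split_a.W"] + p["split_a.b"]
        return specific, agnostic

    def inter_modal_fuse(self, f_path: Optional[Tensor],
                         f_rad: Optional[Tensor]
                         ) -> tuple[Tensor, bool, Optional[Tensor], Optional[Tensor]]:
        """Scenario-dependent fusion.

        Returns ``(F_inter, eligible_for_alignment, path_agnostic,
        rad_agnostic)``. Scenario I (both present) averages the agnostic
        features; scenarios II/III substitute the learnable placeholder for
        the missing modality's specific slot.
        """
        if f_path is None and f_rad is None:
            raise ValueError("inter_modal_fuse: both modalities absent")
        p, comb = self.params, self.config.combiner
        if len(self.config.modalities) == 1:
            mod = self.config.modalities[0]
            f = f_path if mod == "path" else f_rad
            return f, False, None, None
        if comb != "full":
            fp = f_path if f_path is not None else p["placeholder.path"]
            fr = f_rad if f_rad is not None else p["placeholder.rad"]
            fused = {"concat": lambda: nn.concat([fp, fr], axis=0),
                     "sum": lambda: fp + fr,
                     "multiply": lambda: fp * fr}[comb]()
            return fused, False, None, None
        if f_path is not None and f_rad is not None:  # scenario I
            ps, pa = self.split_features("path", f_path)
            rs, ra = self.split_features("rad", f_rad)
            avg = (pa + ra) * 0.5
            return nn.concat([ps, avg, rs], axis=0), True, pa, ra
        if f_rad is None:                             # scenario II
            ps, pa = self.split_features("path", f_path)
            fused = nn.concat([ps, pa, p["placeholder.rad"]], axis=0)
            return fused, False, None, None
        rs, ra = self.split_features("rad", f_rad)    # scenario III
        fused = nn.concat([p["placeholder.path"], ra, rs], axis=0)
        return fused, False, None, None

    def patient_fuse(self, f_inter: Tensor,
                     info_tokens: TokenSequence) -> Tensor:
        """Cross-attend from the fused feature over patient-info tokens."""
        p, h = self.params, self.config.heads
        fi = f_inter.reshape(1, self.config.fused_dim)
        Q = fi @ p["pinfo.Wq"] + p["pinfo.bq"]
        toks = self._tokens_tensor(info_tokens)
        K = toks @ p["pinfo.Wk"] + p["pinfo.bk"]
        V = toks @ p["pinfo.Wv"] + p["pinfo.bv"]
        att = cross_attention(Q, K, V, h, p["pinfo.Wo"], p["pinfo.bo"])
        proj = fi @ p["pinfo.Wproj"] + p["pinfo.bproj"]
        return (att + proj).reshape(self.config.d)

    def predict(self, patient_feature: Tensor) -> Tensor:
        """Two-layer MLP with softmax -> (non-response risk, response)."""
        p = self.params
        hcode = (patient_feature.reshape(1, self.config.d) @ p["mlp.W1"]
                 + p["mlp.b1"]).relu()
        logits = hcode @ p["mlp.W2"] + p["mlp.b2"]
        return logits.softmax(axis=-1).reshape(2)

    # -- end-to-end -------------------------------------------------------
    def forward(self, sample: PatientFeatures) -> ForwardOutput:
        cfg = self.config
        feats: dict[str, Tensor] = {}
        importance: dict[str, np.ndarray] = {}
        zero_tokens = {
            "path": TokenSequence(np.zeros((1, cfg.path_token_width)),
                                  np.zeros(1), ("none",)),
            "rad": TokenSequence(np.zeros((1, cfg.rad_token_width)),
                                 np.zeros(1), ("none",)),
        }
        for mod in cfg.modalities:
            words = sample.path_words if mod == "path" else sample.rad_words
            omics = sample.path_omics if mod == "path" else sample.rad_omics
            tokens = sample.path_tokens if mod == "path" else sample.rad_tokens
            if words is None:
                continue
            if tokens is None or not cfg.use_reports:
                tokens = zero_tokens[mod]
            img_feat, imp = self.image_feature(mod, words, omics)
            feats[mod] = self.intra_modal_fuse(mod, img_feat, tokens)
            importance[mod] = imp
        if not feats:
            raise ValueError(
                f"patient {sample.patient_id}: no modality available to the model")
        fused, eligible, pa, ra = self.inter_modal_fuse(
            feats.get("path"), feats.get("rad"))
        info_tokens = sample.info_tokens
        if not cfg.use_info:
            info_tokens = TokenSequence(
                np.zeros((1, cfg.info_token_width)), np.zeros(1), ("none",))
        patient = self.patient_fuse(fused, info_tokens)
        probs = self.predict(patient)
        return ForwardOutput(probs=probs, fused=fused, path_agnostic=pa,
                             rad_agnostic=ra, eligible_for_alignment=eligible,
                             bag_importance=importance)

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in state:
                raise ValueError(f"checkpoint missing parameter {k!r}")
            if state[k].shape != v.data.shape:
                raise ValueError(f"parameter {k!r} shape mismatch")
            v.data = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path: str | Path) -> None:
        """Versioned checkpoint: all parameters plus the producing config."""
        with open(Path(path), "wb") as fh:
            np.savez(fh, __config__=np.frombuffer(
                json.dumps({"schema": 1, **asdict(self.config)}).encode(),
                dtype=np.uint8), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "MuMoNet":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(bytes(data["__config__"].tobytes()).decode())
            meta.pop("schema", None)
            meta["modalities"] = tuple(meta["modalities"])
            net = cls(FusionConfig(**meta))
            net.load_state_dict({k: data[k] for k in data.files
                                 if k != "__config__"})
        return net
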