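"""Feature extraction: deep word features, MIL aggregation, omics features
and parameterless report/patient-information encoders.

Images enter as bags of words (see :mod:`mumo.preprocess`); a small
convolutional backbone embeds each word, and a two-level gated-attention
pooling aggregates word -> bag -> patient, yielding a patient-level deep
feature plus per-bag importance weights. In parallel, a fixed 20-feature
omics vector (first-order statistics, shape, GLCM texture) is computed from
each masked image region. Structured reports and patient information are
encoded by *parameterless* codebook encoders: every field owns a fixed slot,
categorical values are one-hot, sets multi-hot, continuous values min-max
scaled, and missing fields become zero tokens with presence flag 0.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats as sps
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage.feature import graycomatrix

from . import nn
from .nn import Tensor

__all__ = [
    "SmallConvBackbone",
    "embed_words",
    "GatedAttentionPooling",
    "MILAggregator",
    "aggregate_mil",
    "OMICS_FEATURE_NAMES",
    "OmicsVector",
    "omics_features",
    "Codebook",
    "load_codebook",
    "TokenSequence",
    "encode_report",
    "encode_patient_info",
]


# ---------------------------------------------------------------------------
# deep features

class SmallConvBackbone:
    """A 4-block strided convolutional feature extractor.

    Each block is a 3x3 stride-2 convolution (padding 1) followed by ReLU;
    a 16x16 word collapses to 1x1 spatially, giving a ``d_word`` vector.
    Lightweight pretrained backbones can be swapped in through the same
    ``forward(Tensor) -> Tensor`` contract.
    """

    def __init__(self, d_word: int = 32, in_channels: int = 3,
                 channels: tuple[int, ...] = (8, 16, 32), seed: int = 0,
                 prefix: str = "backbone"):
        rng = np.random.default_rng(seed)
        self.d_word = d_word
        self.prefix = prefix
        chain = (in_channels, *channels, d_word)
        self.params: dict[str, Tensor] = {}
        for i, (cin, cout) in enumerate(zip(chain[:-1], chain[1:])):
            self.params[f"{prefix}.w{i}"] = nn.glorot(rng, cout, cin, 3, 3)
            self.params[f"{prefix}.b{i}"] = nn.zeros(cout)
        self.n_blocks = len(chain) - 1

    def forward(self, x: Tensor) -> Tensor:
        """(N, C, H, W) word images -> (N, d_word) embeddings."""
        for i in range(self.n_blocks):
            x = nn.conv2d(x, self.params[f"{self.prefix}.w{i}"],
                          self.params[f"{self.prefix}.b{i}"],
                          stride=2, padding=1)
            x = x.relu()
        n = x.shape[0]
        return x.mean(axis=(2, 3)).reshape(n, self.d_word)


def embed_words(words: Sequence[np.ndarray], backbone=None,
                seed: int = 0) -> np.ndarray:
    """Embed word images into a (n_words, d_word) feature matrix.

    ``words`` are (H, W) or (H, W, C) float arrays in [0, 1]. With no
    backbone supplied, a seeded :class:`SmallConvBackbone` is created, so the
    embedding is deterministic in (inputs, seed).
    """
    if len(words) == 0:
        raise ValueError("embed_words: empty word list")
    arr = np.stack([np.atleast_3d(np.asarray(w, dtype=np.float64)) for w in words])
    if len({w.shape for w in map(np.asarray, words)}) > 1:
        raise ValueError("embed_words: words must share a single shape")
    x = arr.transpose(0, 3, 1, 2)  # NHWC -> NCHW
    if backbone is None:
        backbone = SmallConvBackbone(in_channels=x.shape[1], seed=seed)
    return backbone.forward(Tensor(x)).data


class GatedAttentionPooling:
    """Gated-attention MIL pooling: softmax(w^T (tanh(Vh) * sigmoid(Uh)))."""

    def __init__(self, dim: int, hidden: int = 32, seed: int = 0,
                 prefix: str = "att"):
        rng = np.random.default_rng(seed)
        self.params = {
            f"{prefix}.V": nn.glorot(rng, dim, hidden),
            f"{prefix}.U": nn.glorot(rng, dim, hidden),
            f"{prefix}.w": nn.glorot(rng, hidden, 1),
        }
        self.prefix = prefix

    def forward(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """(n, dim) instances -> ((dim,) pooled, (n,) attention weights)."""
        p = self.prefix
        gate = (h @ self.params[f"{p}.V"]).tanh() * \
               (h @ self.params[f"{p}.U"]).sigmoid()
        scores = (gate @ self.params[f"{p}.w"]).reshape(h.shape[0])
        a = scores.softmax(axis=0)
        pooled = a @ h
        return pooled, a


class MILAggregator:
    """Bottom-up word -> bag -> patient aggregation with gated attention."""

    def __init__(self, d_word: int = 32, hidden: int = 32, seed: int = 0,
                 prefix: str = "mil"):
        self.word_pool = GatedAttentionPooling(d_word, hidden, seed=seed,
                                               prefix=f"{prefix}.word")
        self.bag_pool = GatedAttentionPooling(d_word, hidden, seed=seed + 1,
                                              prefix=f"{prefix}.bag")
        self.params = {**self.word_pool.params, **self.bag_pool.params}

    def forward(self, bags: Sequence[Tensor]) -> tuple[Tensor, Tensor]:
        """List of (n_words_b, d_word) tensors -> ((d_word,) patient feature,
        (n_bags,) bag importance summing to 1)."""
        if len(bags) == 0:
            raise ValueError("aggregate_mil: need at least one bag")
        dims = {b.shape[1] for b in bags}
        if len(dims) > 1:
            raise ValueError(f"aggregate_mil: inconsistent word dims {dims}")
        bag_feats = [self.word_pool.forward(b)[0] for b in bags]
        stacked = nn.stack(bag_feats, axis=0)
        patient, importance = self.bag_pool.forward(stacked)
        return patient, importance


def aggregate_mil(word_features_per_bag: Sequence[np.ndarray],
                  aggregator: MILAggregator | None = None,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: aggregate per-bag word features to patient level.

    Returns ``(patient_feature, bag_importance)``; importance weights are
    non-negative and sum to 1, and the result is invariant to bag order and
    to word order within each bag.
    """
    bags = [Tensor(np.asarray(b, dtype=np.float64)) for b in word_features_per_bag]
    if aggregator is None:
        d = bags[0].shape[1] if bags else 0
        aggregator = MILAggregator(d_word=d, seed=seed)
    patient, importance = aggregator.forward(bags)
    return patient.data, importance.data


# ---------------------------------------------------------------------------
# omics features

OMICS_FEATURE_NAMES = (
    "mean", "std", "skewness", "kurtosis", "median", "p10", "p90",
    "energy", "entropy", "min", "max",
    "area", "perimeter", "circularity", "axis_ratio", "solidity",
    "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity",
)

_GLCM_LEVELS = 32
_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass(frozen=True)
class OmicsVector:
    """Named 20-dimensional omics feature vector (fixed name order)."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(OMICS_FEATURE_NAMES),):
            raise ValueError("OmicsVector must have exactly "
                             f"{len(OMICS_FEATURE_NAMES)} entries")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(OMICS_FEATURE_NAMES, map(float, self.values)))

    def __getitem__(self, name: str) -> float:
        return float(self.values[OMICS_FEATURE_NAMES.index(name)])


def _crack_perimeter(mask: np.ndarray) -> float:
    """Perimeter as the count of exposed pixel edges (crack length), so a
    filled s x s square has perimeter exactly 4s."""
    m = mask.astype(bool)
    pad = np.pad(m, 1)
    edges = 0
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        edges += np.count_nonzero(m & ~np.roll(pad, shift, axis=ax)[1:-1, 1:-1])
    return float(edges)


def _glcm_stats(image: np.ndarray, mask: np.ndarray) -> tuple[float, float, float, float]:
    """Masked grey-level co-occurrence statistics, 32 levels, distance 1,
    averaged over 4 directions (symmetric counts)."""
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.clip(((image - lo) / (hi - lo) * _GLCM_LEVELS).astype(np.int64),
                    0, _GLCM_LEVELS - 1)
    else:
        q = np.zeros_like(image, dtype=np.int64)
    # outside-mask pixels get a sentinel level that is dropped from the matrix
    q = np.where(mask, q, _GLCM_LEVELS).astype(np.uint8)
    glcm = graycomatrix(q, distances=[1], angles=list(_GLCM_ANGLES),
                        levels=_GLCM_LEVELS + 1, symmetric=True)
    contrast = correlation = energy = homogeneity = 0.0
    n_dir = 0
    i_idx = np.arange(_GLCM_LEVELS, dtype=np.float64)
    for a in range(len(_GLCM_ANGLES)):
        counts = glcm[:_GLCM_LEVELS, :_GLCM_LEVELS, 0, a].astype(np.float64)
        total = counts.sum()
        if total == 0:
            continue
        p = counts / total
        pi_ = p.sum(axis=1)
        pj_ = p.sum(axis=0)
        mu_i = (i_idx * pi_).sum()
        mu_j = (i_idx * pj_).sum()
        var_i = ((i_idx - mu_i) ** 2 * pi_).sum()
        var_j = ((i_idx - mu_j) ** 2 * pj_).sum()
        diff2 = (i_idx[:, None] - i_idx[None, :]) ** 2
        contrast += (p * diff2).sum()
        if var_i > 0 and var_j > 0:
            correlation += ((p * np.outer(i_idx - mu_i, i_idx - mu_j)).sum()
                            / np.sqrt(var_i * var_j))
        else:
            correlation += 1.0
        energy += (p ** 2).sum()
        homogeneity += (p / (1.0 + diff2)).sum()
        n_dir += 1
    if n_dir == 0:
        return 0.0, 1.0, 1.0, 1.0
    return (contrast / n_dir, correlation / n_dir, energy / n_dir,
            homogeneity / n_dir)


def omics_features(image: np.ndarray, mask: np.ndarray) -> OmicsVector:
    """Radiomics-style features of a masked image region.

    First-order statistics are computed on the masked pixels (entropy over a
    32-bin histogram, log base 2; skewness and kurtosis are 0 by convention
    for constant regions). Shape features use the crack-length perimeter and
    whole-mask region properties. Texture is a masked 32-level GLCM at
    distance 1 averaged over 4 directions; ``glcm_energy`` is the joint
    energy (sum of squared probabilities).
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape:
        raise ValueError("omics_features: image and mask shapes differ")
    if not mask.any():
        raise ValueError("omics_features: empty mask")
    vals = image[mask]

    mean = vals.mean()
    std = vals.std()
    skew = float(sps.skew(vals)) if std > 0 else 0.0
    kurt = float(sps.kurtosis(vals)) if std > 0 else 0.0
    median = float(np.median(vals))
    p10 = float(np.percentile(vals, 10))
    p90 = float(np.percentile(vals, 90))
    energy_fo = float((vals ** 2).sum())
    hist, _ = np.histogram(vals, bins=_GLCM_LEVELS,
                           range=(vals.min(), vals.max() if vals.max() > vals.min()
                                  else vals.min() + 1.0))
    p = hist / hist.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())

    area = float(mask.sum())
    perimeter = _crack_perimeter(mask)
    circularity = 4.0 * np.pi * area / perimeter ** 2 if perimeter > 0 else 0.0
    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    major, minor = props.axis_major_length, props.axis_minor_length
    axis_ratio = float(minor / major) if major > 0 else 1.0
    hull = skmorph.convex_hull_image(mask)
    solidity = area / float(hull.sum())

    contrast, correlation, glcm_energy, homogeneity = _glcm_stats(image, mask)

    return OmicsVector(np.array([
        mean, std, skew, kurt, median, p10, p90, energy_fo, entropy,
        float(vals.min()), float(vals.max()),
        area, perimeter, circularity, axis_ratio, solidity,
        contrast, correlation, glcm_energy, homogeneity,
    ]))


# ---------------------------------------------------------------------------
# parameterless encoders

@dataclass(frozen=True)
class TokenSequence:
    """One token per codebook field: (n_fields, width) values plus a
    presence flag per token (0 for missing/NA fields)."""

    tokens: np.ndarray
    presence: np.ndarray
    field_names: tuple[str, ...]

    @property
    def width(self) -> int:
        return self.tokens.shape[1]


class Codebook:
    """Versioned field layout for a parameterless encoder.

    Each field owns a contiguous slot: one-hot for categoricals, multi-hot
    for sets, a single min-max-scaled cell for continuous values and a 0/1
    cell for booleans. The layout (and hence the encoding) has no learned
    parameters.
    """

    def __init__(self, spec: Mapping):
        self.name = spec["name"]
        self.version = spec.get("version", 1)
        self.fields = list(spec["fields"])
        self.slots: dict[str, tuple[int, int]] = {}
        offset = 0
        for f in self.fields:
            w = {"categorical": lambda f: len(f["vocab"]),
                 "set": lambda f: len(f["vocab"]),
                 "continuous": lambda f: 1,
                 "binary": lambda f: 1}[f["kind"]](f)
            self.slots[f["name"]] = (offset, offset + w)
            offset += w
        self.width = offset

    def encode(self, values: Mapping) -> TokenSequence:
        n = len(self.fields)
        tokens = np.zeros((n, self.width))
        presence = np.ones(n)
        for i, f in enumerate(self.fields):
            name, kind = f["name"], f["kind"]
            lo_slot, hi_slot = self.slots[name]
            v = values.get(name, None)
            if v is None or (f.get("na") is not None and v == f["na"]):
                presence[i] = 0.0
                continue
            if kind == "categorical":
                if v not in f["vocab"]:
                    raise ValueError(
                        f"codebook {self.name}: value {v!r} not in vocabulary "
                        f"of field {name!r}")
                tokens[i, lo_slot + f["vocab"].index(v)] = 1.0
            elif kind == "set":
                for item in v:
                    if item not in f["vocab"]:
                        raise ValueError(
                            f"codebook {self.name}: value {item!r} not in "
                            f"vocabulary of field {name!r}")
                    tokens[i, lo_slot + f["vocab"].index(item)] = 1.0
            elif kind == "continuous":
                lo, hi = f["range"]
                if not lo <= v <= hi:
                    raise ValueError(
                        f"codebook {self.name}: value {v!r} outside range "
                        f"[{lo}, {hi}] of field {name!r}")
                tokens[i, lo_slot] = (v - lo) / (hi - lo)
            elif kind == "binary":
                tokens[i, lo_slot] = 1.0 if v else 0.0
        return TokenSequence(tokens=tokens, presence=presence,
                             field_names=tuple(f["name"] for f in self.fields))

    def zero_sequence(self) -> TokenSequence:
        """All-missing token sequence (used when a report is absent)."""
        n = len(self.fields)
        return TokenSequence(tokens=np.zeros((n, self.width)),
                             presence=np.zeros(n),
                             field_names=tuple(f["name"] for f in self.fields))


def load_codebook(name: str) -> Codebook:
    """Load a packaged codebook: ``patient_info``, ``rad_report`` or
    ``path_report`` (or a path to a YAML file)."""
    if name.endswith(".yaml") or name.endswith(".yml"):
        with open(name) as fh:
            return Codebook(yaml.safe_load(fh))
    ref = importlib.resources.files("mumo") / "codebooks" / f"{name}.yaml"
    return Codebook(yaml.safe_load(ref.read_text()))


def _dataclass_values(obj) -> dict:
    from dataclasses import asdict, is_dataclass
    return asdict(obj) if is_dataclass(obj) else dict(obj)


def encode_report(report, codebook: Codebook) -> TokenSequence:
    """Encode a structured radiology or pathology report (parameterless)."""
    return codebook.encode(_dataclass_values(report))


def encode_patient_info(info, codebook: Codebook) -> TokenSequence:
    """Encode baseline patient information (parameterless)."""
    return codebook.encode(_dataclass_values(info))
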