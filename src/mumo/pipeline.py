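"""From manifest records to network-ready patient features.

The pipeline is fitted on the training split only: it estimates the Reinhard
colour-transfer target statistics from training pathology tiles, per-organ
dynamic intensity windows from training lesion voxels, and the
standardisation (mean/std) of omics features. ``transform`` then maps any
record to a :class:`~mumo.fusion.PatientFeatures`: colour-normalised
pathology words per bag, windowed radiology lesion words (one bag per
lesion), standardised omics vectors, encoded report and patient-information
tokens, and the responder label (None for censor-excluded patients).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from . import data_model as dm
from . import preprocess as pp
from .features import (Codebook, load_codebook, omics_features,
                       encode_report, encode_patient_info)
from .fusion import PatientFeatures

__all__ = ["PipelineConfig", "FeaturePipeline"]

_LABEL_CODE = {"responder": 1, "non_responder": 0, "excluded": None}


@dataclass
class PipelineConfig:
    bag_size: int = 32
    word_size: int = 16
    window_percentiles: tuple[float, float] = (0.5, 99.5)
    max_stat_images: int = 64  # tiles sampled for the Reinhard target


class FeaturePipeline:
    """Stateful featurizer; fit on the training split, then transform."""

    def __init__(self, root: str | Path, config: PipelineConfig | None = None):
        self.root = Path(root)
        self.config = config or PipelineConfig()
        self.codebooks: dict[str, Codebook] = {
            "info": load_codebook("patient_info"),
            "rad": load_codebook("rad_report"),
            "path": load_codebook("path_report"),
        }
        self.target_stats: pp.ChannelStats | None = None
        self.windows: dict[str, pp.Window] = {}
        self.omics_mean: dict[str, np.ndarray] = {}
        self.omics_std: dict[str, np.ndarray] = {}

    # -- I/O helpers ------------------------------------------------------
    def _load_rgb(self, rel: str) -> np.ndarray:
        return np.asarray(Image.open(self.root / rel).convert("RGB"),
                          dtype=np.float64) / 255.0

    def _load_gray(self, rel: str) -> np.ndarray:
        return np.asarray(Image.open(self.root / rel).convert("L"),
                          dtype=np.float64) / 255.0

    # -- fitting ----------------------------------------------------------
    def fit(self, train_records: list[dm.PatientRecord]) -> "FeaturePipeline":
        means, stds = [], []
        lesion_vox: dict[str, list[np.ndarray]] = {}
        raw_omics: dict[str, list[np.ndarray]] = {"path": [], "rad": []}
        n_stat = 0
        for rec in train_records:
            if rec.has_pathology and n_stat < self.config.max_stat_images:
                st = pp.compute_channel_stats(self._load_rgb(rec.pathology_assets[0]))
                means.append(st.mean)
                stds.append(st.std)
                n_stat += 1
            if rec.has_radiology:
                for img_rel, mask_rel, organ in rec.radiology_assets:
                    img = self._load_gray(img_rel)
                    mask = self._load_gray(mask_rel) > 0.5
                    if mask.any():
                        lesion_vox.setdefault(organ, []).append(img[mask])
        if means:
            self.target_stats = pp.ChannelStats(
                tuple(np.mean(means, axis=0)), tuple(np.mean(stds, axis=0)))
        lo, hi = self.config.window_percentiles
        all_vox = []
        for organ, chunks in sorted(lesion_vox.items()):
            vox = np.concatenate(chunks)
            all_vox.append(vox)
            self.windows[organ] = pp.dynamic_window(vox, lo, hi)
        if all_vox:
            self.windows["__global__"] = pp.dynamic_window(
                np.concatenate(all_vox), lo, hi)
        # omics standardisation on raw training features
        for rec in train_records:
            for mod, om in self._raw_omics(rec).items():
                raw_omics[mod].append(om)
        for mod in ("path", "rad"):
            if raw_omics[mod]:
                arr = np.stack(raw_omics[mod])
                self.omics_mean[mod] = arr.mean(axis=0)
                std = arr.std(axis=0)
                self.omics_std[mod] = np.where(std < 1e-9, 1.0, std)
        return self

    # -- transformation ---------------------------------------------------
    def _pathology_words(self, rec: dm.PatientRecord) -> list[np.ndarray]:
        cfg = self.config
        bags: list[np.ndarray] = []
        for rel in rec.pathology_assets:
            img = self._load_rgb(rel)
            if self.target_stats is not None:
                img = pp.reinhard_normalize(img, self.target_stats)
            img = pp.white_balance(img)
            h, w = img.shape[:2]
            grid = pp.tile_roi((0, 0, w, h), cfg.bag_size, cfg.word_size)
            for bag_words in grid.words:
                words = [img[y0:y1, x0:x1].transpose(2, 0, 1)
                         for (x0, y0, x1, y1) in bag_words]
                bags.append(np.stack(words))
        return bags

    def _radiology_words(self, rec: dm.PatientRecord) -> list[np.ndarray]:
        cfg = self.config
        bags: list[np.ndarray] = []
        for img_rel, mask_rel, organ in rec.radiology_assets:
            img = self._load_gray(img_rel)
            w = self.windows.get(organ, self.windows.get("__global__"))
            if w is not None:
                img = pp.apply_window(img, w)
            hh, ww = img.shape
            grid = pp.tile_roi((0, 0, ww, hh), cfg.word_size, cfg.word_size)
            words = [img[y0:y1, x0:x1][None, :, :]
                     for bag in grid.words for (x0, y0, x1, y1) in bag]
            bags.append(np.stack(words))  # one bag per lesion
        return bags

    def _raw_omics(self, rec: dm.PatientRecord) -> dict[str, np.ndarray]:
        out = {}
        if rec.has_pathology:
            vecs = []
            for rel in rec.pathology_assets:
                img = self._load_rgb(rel).mean(axis=2)
                cfg = self.config
                h, w = img.shape
                grid = pp.tile_roi((0, 0, w, h), cfg.bag_size, cfg.word_size)
                for (x0, y0, x1, y1) in grid.bags:
                    bag_img = img[y0:y1, x0:x1]
                    vecs.append(omics_features(
                        bag_img, np.ones_like(bag_img, dtype=bool)).values)
            out["path"] = np.mean(vecs, axis=0)
        if rec.has_radiology:
            vecs = []
            for img_rel, mask_rel, organ in rec.radiology_assets:
                img = self._load_gray(img_rel)
                mask = self._load_gray(mask_rel) > 0.5
                if not mask.any():
                    mask = np.ones_like(img, dtype=bool)
                vecs.append(omics_features(img, mask).values)
            out["rad"] = np.mean(vecs, axis=0)
        return out

    def transform(self, rec: dm.PatientRecord) -> PatientFeatures:
        raw = self._raw_omics(rec)
        feats = PatientFeatures(
            patient_id=rec.patient_id,
            label=_LABEL_CODE[dm.label_responder(rec.outcome, rec.cohort)],
            info_tokens=encode_patient_info(rec.info, self.codebooks["info"]),
        )
        if rec.has_pathology:
            feats.path_words = self._pathology_words(rec)
            feats.path_omics = self._standardize("path", raw["path"])
            feats.path_tokens = encode_report(rec.path_report,
                                              self.codebooks["path"])
        if rec.has_radiology:
            feats.rad_words = self._radiology_words(rec)
            feats.rad_omics = self._standardize("rad", raw["rad"])
            feats.rad_tokens = encode_report(rec.rad_report,
                                             self.codebooks["rad"])
        return feats

    def _standardize(self, mod: str, vec: np.ndarray) -> np.ndarray:
        if mod not in self.omics_mean:
            return vec
        return (vec - self.omics_mean[mod]) / self.omics_std[mod]

    def transform_all(self, records: list[dm.PatientRecord]
                      ) -> list[PatientFeatures]:
        return [self.transform(r) for r in records]

    def token_widths(self) -> dict[str, int]:
        return {"path": self.codebooks["path"].width,
                "rad": self.codebooks["rad"].width,
                "info": self.codebooks["info"].width}
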