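"""High-level modelling interface.

:class:`MuMoModel` is built from a cohort (records + asset root, or a
manifest path); :meth:`MuMoModel.fit` splits the cohort, fits the feature
pipeline on the training split, trains the fusion network, averages the
top-k checkpoints and evaluates on the validation split, returning a
:class:`MuMoResults` with estimates, uncertainties, diagnostics and a
``summary()`` table.

>>> model = MuMoModel.from_manifest("cohort/manifest.jsonl")
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import data_model as dm
from .evaluation import (EvalReport, evaluate_scores, run_ablation,
                         stratify_and_survival)
from .fusion import FusionConfig, MuMoNet, PatientFeatures
from .pipeline import FeaturePipeline, PipelineConfig
from .training import (Checkpoint, TrainConfig, average_top_k, risk_scores,
                       train_model)

__all__ = ["MuMoModel", "MuMoResults"]


class MuMoModel:
    """Treatment-response model over a multi-modal cohort."""

    def __init__(self, records: Sequence[dm.PatientRecord], root: str | Path,
                 fusion_config: FusionConfig | None = None,
                 pipeline_config: PipelineConfig | None = None):
        if not records:
            raise ValueError("empty cohort")
        self.records = list(records)
        self.root = Path(root)
        self.fusion_config = fusion_config or FusionConfig()
        self.pipeline_config = pipeline_config or PipelineConfig()

    @classmethod
    def from_manifest(cls, manifest: str | Path, **kwargs) -> "MuMoModel":
        manifest = Path(manifest)
        return cls(dm.read_manifest(manifest), manifest.parent, **kwargs)

    def fit(self, train_config: TrainConfig | None = None,
            val_fraction: float = 56 / 271,
            split_seed: int | None = None,
            bootstrap_B: int = 2000) -> "MuMoResults":
        tc = train_config or TrainConfig()
        split_seed = tc.seed if split_seed is None else split_seed
        train_recs, val_recs = dm.split_cohort(self.records, val_fraction,
                                               split_seed)
        pipe = FeaturePipeline(self.root, self.pipeline_config).fit(train_recs)
        widths = pipe.token_widths()
        fcfg = replace(self.fusion_config,
                       path_token_width=widths["path"],
                       rad_token_width=widths["rad"],
                       info_token_width=widths["info"],
                       seed=tc.seed)
        train_feats = pipe.transform_all(train_recs)
        val_feats = pipe.transform_all(val_recs)
        net, ckpts, history = train_model(
            [s for s in train_feats if s.label is not None],
            val_feats, fcfg, tc)
        final = MuMoNet(fcfg)
        final.load_state_dict(average_top_k(ckpts, tc.top_k))

        scores_all = risk_scores(final, val_feats)
        labeled = np.array([s.label is not None for s in val_feats])
        y_nonresp = np.array([1 - s.label for s in val_feats if s.label is not None])
        report = evaluate_scores(scores_all[labeled], y_nonresp, B=bootstrap_B,
                                 seed=tc.seed)
        # survival uses every validation patient, censored-excluded included
        times = np.array([r.outcome.pfs_months for r in val_recs])
        events = np.array([r.outcome.pfs_event for r in val_recs])
        try:
            survival = stratify_and_survival(scores_all,
                                             report.youden_threshold,
                                             times, events)
        except ValueError:
            survival = None
        report = replace(report, survival=survival)
        return MuMoResults(model=self, net=final, pipeline=pipe,
                           checkpoints=ckpts, history=history,
                           eval_report=report, val_records=val_recs,
                           val_scores=scores_all, train_records=train_recs,
                           train_features=train_feats,
                           val_features=val_feats,
                           fusion_config=fcfg, train_config=tc)


@dataclass
class MuMoResults:
    """Fitted model, per-epoch diagnostics and validation-split evaluation."""

    model: MuMoModel
    net: MuMoNet
    pipeline: FeaturePipeline
    checkpoints: list[Checkpoint]
    history: list[dict]
    eval_report: EvalReport
    val_records: list[dm.PatientRecord]
    val_scores: np.ndarray
    train_records: list[dm.PatientRecord]
    train_features: list[PatientFeatures]
    val_features: list[PatientFeatures]
    fusion_config: FusionConfig
    train_config: TrainConfig

    @property
    def auc(self) -> float:
        return self.eval_report.auc

    def predict(self, records: Sequence[dm.PatientRecord]) -> np.ndarray:
        """Non-response risk scores for new records (same asset root)."""
        feats = self.pipeline.transform_all(list(records))
        return risk_scores(self.net, feats)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def ablation(self, variants=None, B: int = 200) -> pd.DataFrame:
        """Re-train ablation variants on this split (identical seeds)."""
        kwargs = {} if variants is None else {"variants": variants}
        return run_ablation(self.train_features, self.val_features,
                            self.fusion_config, self.train_config, B=B,
                            **kwargs)

    def summary(self) -> str:
        rows = [("n train / n val",
                 f"{len(self.train_records)} / {len(self.val_records)}"),
                ("epochs", str(self.train_config.epochs)),
                ("checkpoints averaged",
                 str(min(self.train_config.top_k, len(self.checkpoints))))]
        rows += self.eval_report.summary_rows()
        width = max(len(k) for k, _ in rows) + 2
        lines = ["Multi-modal treatment-response model",
                 "=" * 44]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        self.net.save(path)
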