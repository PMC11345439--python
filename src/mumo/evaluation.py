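"""Discrimination, risk stratification, survival statistics and ablations.

The model's risk score (probability of non-response) is evaluated with the
Mann–Whitney AUC (ties count one half) and a patient-level percentile
bootstrap CI. The Youden index (max over observed cutpoints of
TPR − FPR, rule "high-risk iff score >= t") dichotomises the cohort into
high-/low-risk groups, compared by Kaplan–Meier curves and the log-rank
(Mantel–Cox) test; the number needed to treat (NNT) is the reciprocal of
the response-rate difference between the low- and high-risk groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import rankdata

__all__ = ["auc", "bootstrap_ci", "youden_threshold", "stratify_and_survival",
           "nnt", "EvalReport", "SurvivalComparison", "evaluate_scores",
           "run_ablation"]


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: probability that a random positive outscores a
    random negative, ties counted one half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_ci(scores, labels, B: int = 2000, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC over patient-level resamples.

    Single-class replicates are redrawn (up to 10 attempts each, then
    skipped). Reproducible by seed.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 samples for a bootstrap CI")
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(B):
        for _attempt in range(10):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) == 2:
                stats.append(auc(scores[idx], labels[idx]))
                break
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def youden_threshold(scores, labels) -> float:
    """Cutpoint among observed scores maximising Youden's J = TPR − FPR,
    under the rule "positive (high-risk) iff score >= t"; ties resolve to the
    smallest such cutpoint."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_t, best_j = None, -np.inf
    for t in np.sort(np.unique(scores)):
        pred = scores >= t
        tpr = (pred & (labels == 1)).sum() / n_pos
        fpr = (pred & (labels == 0)).sum() / n_neg
        j = tpr - fpr
        if j > best_j + 1e-15:
            best_j, best_t = j, t
    return float(best_t)


@dataclass
class SurvivalComparison:
    """Kaplan–Meier summaries of two risk groups plus the log-rank test."""

    km_curves: dict[str, pd.DataFrame]
    median_survival: dict[str, float]
    logrank_chi2: float
    logrank_p: float


def stratify_and_survival(scores, threshold: float, times, events
                          ) -> SurvivalComparison:
    """Split by ``score >= threshold`` into high/low risk; estimate KM
    survival per group (median = first time S(t) <= 0.5, NaN if never) and
    the Mantel–Cox log-rank chi-square (1 df) with its two-sided p-value."""
    scores = np.asarray(scores, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(bool)
    high = scores >= threshold
    if high.all() or (~high).all():
        raise ValueError(
            "one risk group is empty; review the stratification threshold")
    curves, medians = {}, {}
    for name, m in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m], label=name)
        curves[name] = kmf.survival_function_
        medians[name] = float(kmf.median_survival_time_)
    res = logrank_test(times[high], times[~high], events[high], events[~high])
    return SurvivalComparison(km_curves=curves, median_survival=medians,
                              logrank_chi2=float(res.test_statistic),
                              logrank_p=float(res.p_value))


def nnt(groups, responder_flags) -> float:
    """Number needed to treat: 1 / (response rate low-risk − high-risk).

    ``groups`` holds "high"/"low" per patient. Equal rates are undefined and
    raise; a negative value indicates the grouping is anti-predictive (the
    reciprocal keeps its sign).
    """
    groups = np.asarray(groups)
    flags = np.asarray(responder_flags).astype(int)
    rates = {}
    for g in ("high", "low"):
        m = groups == g
        if not m.any():
            raise ValueError(f"no patients in the {g}-risk group")
        rates[g] = flags[m].mean()
    diff = rates["low"] - rates["high"]
    if diff == 0:
        raise ValueError("response rates are equal; NNT undefined")
    return float(1.0 / diff)


@dataclass
class EvalReport:
    """Full evaluation of risk scores on one split."""

    auc: float
    auc_ci: tuple[float, float]
    youden_threshold: float
    groups: list[str]
    survival: Optional[SurvivalComparison]
    nnt: Optional[float]
    nnt_ci: Optional[tuple[float, float]]
    n: int

    def summary_rows(self) -> list[tuple[str, str]]:
        rows = [("n evaluated", str(self.n)),
                ("AUC (non-response)", f"{self.auc:.3f}"),
                ("AUC 95% CI", f"({self.auc_ci[0]:.3f}, {self.auc_ci[1]:.3f})"),
                ("Youden threshold", f"{self.youden_threshold:.3f}")]
        if self.survival is not None:
            rows += [("log-rank chi2", f"{self.survival.logrank_chi2:.3f}"),
                     ("log-rank p", f"{self.survival.logrank_p:.4f}"),
                     ("median PFS high-risk", f"{self.survival.median_survival['high']:.1f}"),
                     ("median PFS low-risk", f"{self.survival.median_survival['low']:.1f}")]
        if self.nnt is not None:
            rows.append(("NNT", f"{self.nnt:.2f}"))
            if self.nnt_ci is not None:
                rows.append(("NNT 95% CI",
                             f"({self.nnt_ci[0]:.2f}, {self.nnt_ci[1]:.2f})"))
        return rows


def evaluate_scores(scores, labels, times=None, events=None,
                    threshold: float | None = None, B: int = 2000,
                    seed: int = 0) -> EvalReport:
    """Evaluate non-response risk scores against non-responder labels.

    ``labels`` are 1 for non-responders (the positive/"high-risk" class).
    ``threshold`` may be frozen from another split; by default the Youden
    threshold is learned on this data. Survival statistics are computed when
    times/events are given (these may include censor-excluded patients).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    a = auc(scores, labels)
    ci = bootstrap_ci(scores, labels, B=B, seed=seed)
    t = youden_threshold(scores, labels) if threshold is None else threshold
    groups = ["high" if s >= t else "low" for s in scores]
    surv = None
    if times is not None and events is not None:
        surv = stratify_and_survival(scores, t, times, events)
    responder = 1 - labels
    try:
        nnt_val = nnt(groups, responder)
    except ValueError:
        nnt_val = None
    nnt_ci = None
    if nnt_val is not None:
        rng = np.random.default_rng(seed + 1)
        garr = np.asarray(groups)
        vals = []
        for _ in range(B):
            idx = rng.integers(0, len(scores), size=len(scores))
            g, r = garr[idx], responder[idx]
            if (g == "high").any() and (g == "low").any():
                d = r[g == "low"].mean() - r[g == "high"].mean()
                if d != 0:
                    vals.append(1.0 / d)
        if vals:
            nnt_ci = tuple(np.percentile(vals, [2.5, 97.5]))
    return EvalReport(auc=a, auc_ci=ci, youden_threshold=float(t),
                      groups=groups, survival=surv, nnt=nnt_val,
                      nnt_ci=nnt_ci, n=len(scores))


# ---------------------------------------------------------------------------
# ablations

ABLATION_VARIANTS = ("pathology_only", "radiology_only", "fusion_multiply",
                     "fusion_sum", "fusion_concat", "fusion_full",
                     "no_reports", "no_info")


def run_ablation(train, val, base_fusion_config, train_config,
                 variants: Sequence[str] = ABLATION_VARIANTS,
                 B: int = 200) -> pd.DataFrame:
    """Train and evaluate model variants on identical splits and seeds.

    Unimodal and combiner variants mirror the design comparisons: radiology
    only, pathology only, simple combiners (element-wise product, sum,
    concatenation) and the full fusion (split + alignment), plus report and
    patient-information knockouts. Requires the complete-modality subset for
    the modality comparison; a variant whose data requirement is unmet is
    skipped with a log row. Returns a DataFrame with AUC and CI per variant.
    """
    from dataclasses import replace
    from .training import train_model, average_top_k, risk_scores
    from .fusion import MuMoNet

    rows = []
    for variant in variants:
        cfg = replace(base_fusion_config)
        if variant == "pathology_only":
            cfg.modalities = ("path",)
        elif variant == "radiology_only":
            cfg.modalities = ("rad",)
        elif variant.startswith("fusion_"):
            cfg.combiner = variant.split("_", 1)[1]
        elif variant == "no_reports":
            cfg.use_reports = False
        elif variant == "no_info":
            cfg.use_info = False
        else:
            raise ValueError(f"unknown ablation variant {variant!r}")

        def usable(s, cfg=cfg):
            present = {"path": s.has_path, "rad": s.has_rad}
            return all(present[m] for m in cfg.modalities)

        tr = [s for s in train if usable(s) and s.label is not None]
        va = [s for s in val if usable(s) and s.label is not None]
        if not tr or not va or len({s.label for s in tr}) < 2 \
                or len({s.label for s in va}) < 2:
            rows.append({"variant": variant, "auc": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "n_val": len(va),
                         "note": "skipped: insufficient data"})
            continue
        net, ckpts, _ = train_model(tr, va, cfg, train_config)
        final = MuMoNet(cfg)
        final.load_state_dict(average_top_k(ckpts, train_config.top_k))
        scores = risk_scores(final, va)
        y = np.array([1 - s.label for s in va])
        a = auc(scores, y)
        lo, hi = bootstrap_ci(scores, y, B=B, seed=train_config.seed)
        rows.append({"variant": variant, "auc": a, "ci_low": lo,
                     "ci_high": hi, "n_val": len(va), "note": ""})
    return pd.DataFrame(rows)
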