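"""Multi-label discrimination metrics with bootstrap uncertainty.

AUROC is computed as the tie-corrected rank statistic (Mann–Whitney):
AUC = (R_pos − n_pos(n_pos+1)/2) / (n_pos·n_neg) with midranks, which equals
pairwise comparison with half credit for ties.  Macro-AUROC is the
unweighted mean over classes that have at least one positive and one
negative (degenerate classes are excluded and flagged); micro-AUROC pools
the flattened label/probability pairs.  Bootstrap confidence intervals
resample images (rows) with replacement — 2000 replicates, percentile
2.5/97.5 bounds and the replicate standard error.  Operating-point metrics
use per-class thresholds fitted on a validation split by F1 maximisation
over observed score midpoints and applied unchanged to the test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .labels import CLASS_NAMES, N_CLASSES

__all__ = [
    "PredictionSet", "AUROCReport", "ClassThresholds",
    "rank_auroc", "macro_auroc", "auroc", "bootstrap_ci",
    "fit_thresholds", "apply_thresholds",
]


@dataclass
class PredictionSet:
    probs: np.ndarray     # (N, C) in [0, 1]
    labels: np.ndarray    # (N, C) binary
    split_tag: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.probs.shape != self.labels.shape:
            raise ValueError("probs/labels shape mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        self.labels = self.labels.astype(np.int8)

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]


@dataclass
class AUROCReport:
    per_class: np.ndarray          # NaN for degenerate classes
    macro: float
    micro: float
    degenerate: list[int] = field(default_factory=list)
    ci_low: dict = field(default_factory=dict)
    ci_high: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    n_boot: int = 0
    seed: int = 0

    def frame(self, class_names=CLASS_NAMES) -> pd.DataFrame:
        rows = []
        for c, name in enumerate(class_names[:len(self.per_class)]):
            rows.append({"class": name, "auroc": self.per_class[c],
                         "ci_low": self.ci_low.get(c, np.nan),
                         "ci_high": self.ci_high.get(c, np.nan)})
        rows.append({"class": "Macro-average", "auroc": self.macro,
                     "ci_low": self.ci_low.get("macro", np.nan),
                     "ci_high": self.ci_high.get("macro", np.nan)})
        rows.append({"class": "Micro-average", "auroc": self.micro,
                     "ci_low": self.ci_low.get("micro", np.nan),
                     "ci_high": self.ci_high.get("micro", np.nan)})
        return pd.DataFrame(rows)


def rank_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected rank AUROC (equivalent to pair counting with ½ ties)."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _report(probs: np.ndarray, labels: np.ndarray) -> AUROCReport:
    n_classes = probs.shape[1]
    per_class = np.full(n_classes, np.nan)
    degenerate = []
    for c in range(n_classes):
        v = rank_auroc(probs[:, c], labels[:, c])
        if np.isnan(v):
            degenerate.append(c)
        else:
            per_class[c] = v
    if len(degenerate) == n_classes:
        raise ValueError("all classes degenerate: no AUROC defined")
    macro = float(np.nanmean(per_class))
    micro = rank_auroc(probs.ravel(), labels.ravel())
    return AUROCReport(per_class, macro, micro, degenerate)


def auroc(preds: PredictionSet) -> AUROCReport:
    """Point estimates: per-class, macro (degenerates excluded), micro."""
    return _report(preds.probs, preds.labels)


def macro_auroc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Macro-AUROC over non-degenerate classes (training monitor)."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    labels = np.atleast_2d(np.asarray(labels))
    vals = [rank_auroc(probs[:, c], labels[:, c])
            for c in range(probs.shape[1])]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def bootstrap_ci(preds: PredictionSet, n_boot: int = 2000,
                 level: float = 0.95, seed: int = 42,
                 max_redraws: int = 100) -> AUROCReport:
    """Image-level bootstrap CIs for per-class, macro and micro AUROC.

    Resamples rows with replacement; replicates in which a class becomes
    degenerate are redrawn (up to ``max_redraws`` attempts, then that
    replicate is skipped and counted).  Reports percentile bounds at
    (1−level)/2 and 1−(1−level)/2 plus the replicate standard error.
    """
    report = auroc(preds)
    rng = np.random.default_rng(seed)
    n = preds.probs.shape[0]
    keys = [c for c in range(preds.n_classes)
            if c not in report.degenerate] + ["macro", "micro"]
    draws: dict = {k: [] for k in keys}
    skipped = 0
    for _ in range(n_boot):
        for _attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            labels = preds.labels[idx]
            ok = all(0 < labels[:, c].sum() < n
                     for c in range(preds.n_classes)
                     if c not in report.degenerate)
            if ok:
                break
        else:
            skipped += 1
            continue
        rep = _report(preds.probs[idx][:, [c for c in range(preds.n_classes)
                                           if c not in report.degenerate]],
                      labels[:, [c for c in range(preds.n_classes)
                                 if c not in report.degenerate]])
        kept = [c for c in range(preds.n_classes)
                if c not in report.degenerate]
        for j, c in enumerate(kept):
            draws[c].append(rep.per_class[j])
        draws["macro"].append(rep.macro)
        draws["micro"].append(rep.micro)
    if skipped:
        warnings.warn(f"{skipped} bootstrap replicates skipped after "
                      f"{max_redraws} degenerate redraws")
    alpha = (1.0 - level) / 2.0
    for k, vals in draws.items():
        if not vals:
            continue
        vals = np.asarray(vals)
        report.ci_low[k] = float(np.quantile(vals, alpha))
        report.ci_high[k] = float(np.quantile(vals, 1.0 - alpha))
        report.se[k] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    report.n_boot = n_boot
    report.seed = seed
    return report


# ---------------------------------------------------------------------------
# Thresholded operating metrics

@dataclass
class ClassThresholds:
    t: np.ndarray
    criterion: str = "f1_max"


def fit_thresholds(val_preds: PredictionSet) -> ClassThresholds:
    """Per-class thresholds maximising F1 on the validation split.

    The grid is the midpoints between consecutive distinct observed scores
    (plus the extremes), so every achievable confusion table is visited.
    Degenerate classes get t = 0.5.
    """
    n_classes = val_preds.n_classes
    t = np.full(n_classes, 0.5)
    for c in range(n_classes):
        y = val_preds.labels[:, c]
        s = val_preds.probs[:, c]
        if y.sum() == 0 or y.sum() == len(y):
            continue
        uniq = np.unique(s)
        grid = np.concatenate([[uniq[0] / 2.0],
                               (uniq[:-1] + uniq[1:]) / 2.0,
                               [(uniq[-1] + 1.0) / 2.0]])
        best_f1, best_t = -1.0, 0.5
        for cand in grid:
            pred = s >= cand
            tp = int((pred & (y == 1)).sum())
            fp = int((pred & (y == 0)).sum())
            fn = int((~pred & (y == 1)).sum())
            denom = 2 * tp + fp + fn
            f1 = 2 * tp / denom if denom else 0.0
            if f1 > best_f1:
                best_f1, best_t = f1, float(cand)
        t[c] = best_t
    return ClassThresholds(t)


def apply_thresholds(preds: PredictionSet,
                     thresholds: ClassThresholds) -> pd.DataFrame:
    """Per-class precision/recall/F1 at fixed thresholds, plus macro/micro.

    Precision with no positive predictions is reported as 0 and flagged.
    Macro rows average per-class values; the micro row pools all label
    instances into one confusion table.
    """
    rows = []
    tp_all = fp_all = fn_all = 0
    for c in range(preds.n_classes):
        y = preds.labels[:, c]
        pred = preds.probs[:, c] >= thresholds.t[c]
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        tp_all, fp_all, fn_all = tp_all + tp, fp_all + fp, fn_all + fn
        undefined = (tp + fp) == 0
        precision = 0.0 if undefined else tp / (tp + fp)
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        name = CLASS_NAMES[c] if preds.n_classes == N_CLASSES else f"class_{c}"
        rows.append({"class": name, "threshold": thresholds.t[c],
                     "precision": precision, "recall": recall, "f1": f1,
                     "precision_undefined": undefined})
    macro = {"class": "Macro-average", "threshold": np.nan,
             "precision": float(np.mean([r["precision"] for r in rows])),
             "recall": float(np.mean([r["recall"] for r in rows])),
             "f1": float(np.mean([r["f1"] for r in rows])),
             "precision_undefined": False}
    micro_p = tp_all / (tp_all + fp_all) if tp_all + fp_all else 0.0
    micro_r = tp_all / (tp_all + fn_all) if tp_all + fn_all else 0.0
    micro_f = (2 * micro_p * micro_r / (micro_p + micro_r)
               if micro_p + micro_r else 0.0)
    micro = {"class": "Micro-average", "threshold": np.nan,
             "precision": micro_p, "recall": micro_r, "f1": micro_f,
             "precision_undefined": False}
    return pd.DataFrame(rows + [macro, micro])
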