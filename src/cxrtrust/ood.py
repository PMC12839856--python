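"""Post hoc out-of-distribution detection for a multi-label classifier.

Four complementary per-image scores are computed from a fixed trained
checkpoint, with no retraining:

* confidence  s_conf = max_c σ(z_c)              (low for OOD)
* entropy     s_ent  = mean Bernoulli entropy of σ(z_c), natural log
* energy      s_energy = −T·log Σ_c exp(z_c/T),  T = 1
* Mahalanobis s_maha = sqrt(Σ_i (f_i−μ_i)²/(σ_i²+ε)) in the fused feature
  space, with diagonal covariance fitted on an in-distribution calibration
  set.

Thresholds are empirical quantiles of the ID calibration scores (5th
percentile for confidence, 95th for the rest, linear interpolation), so each
detector flags ≈5% of ID images by construction.  The combined decision is
an OR over the four flags.  The benchmark reports per-detector AUROC (rank
statistic), AUPRC (OOD positive), FPR95 (ID flag rate at the largest
threshold keeping OOD TPR ≥ 0.95) and the OR operating point's confusion
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .evalmetrics import rank_auroc

__all__ = [
    "ScoreVector", "FeatureStats", "Thresholds", "OODDecision",
    "BenchmarkReport", "score_image", "score_batch", "fit_feature_stats",
    "calibrate_thresholds", "decide", "benchmark", "operating_metrics",
    "export_scores", "read_scores",
]

SCORE_FIELDS = ("s_conf", "s_ent", "s_energy", "s_maha")
FLAG_FIELDS = ("flag_conf", "flag_ent", "flag_energy", "flag_maha")


@dataclass
class ScoreVector:
    s_conf: float
    s_ent: float
    s_energy: float
    s_maha: float
    image_id: str = ""


@dataclass
class FeatureStats:
    """Per-dimension mean and (population) variance of ID fused features."""

    mu: np.ndarray
    var: np.ndarray
    epsilon: float = 1e-3

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.var = np.asarray(self.var, dtype=np.float64)
        if self.mu.shape != self.var.shape or self.mu.ndim != 1:
            raise ValueError("mu/var must be matching 1-D vectors")
        if (self.var < 0).any() or self.epsilon <= 0:
            raise ValueError("variances must be >= 0 and epsilon > 0")

    @property
    def dim(self) -> int:
        return self.mu.size


@dataclass
class Thresholds:
    tau_conf: float
    tau_ent: float
    tau_energy: float
    tau_maha: float
    calib_n: int = 0
    seed: int = 0
    quantile_method: str = "linear"

    def to_json(self, path: str | Path) -> None:
        import json
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Thresholds":
        import json
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class OODDecision:
    flag_conf: bool
    flag_ent: bool
    flag_energy: bool
    flag_maha: bool

    @property
    def combined(self) -> bool:
        return (self.flag_conf or self.flag_ent or self.flag_energy
                or self.flag_maha)


@dataclass
class BenchmarkReport:
    per_detector: pd.DataFrame   # detector, auroc, auprc, fpr95
    tn: int
    fp: int
    fn: int
    tp: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    id_fpr: float


# ---------------------------------------------------------------------------

def score_image(logits: np.ndarray, fused_feature: np.ndarray | None = None,
                stats: FeatureStats | None = None, temperature: float = 1.0,
                image_id: str = "") -> ScoreVector:
    """All four scores for one image from its logits and fused feature."""
    z = np.asarray(logits, dtype=np.float64).ravel()
    p = 1.0 / (1.0 + np.exp(-z))
    s_conf = float(p.max())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -p * np.log(p) - (1.0 - p) * np.log(1.0 - p)
    s_ent = float(np.nan_to_num(ent, nan=0.0).mean())
    zmax = z.max() / temperature
    s_energy = float(-temperature * (
        zmax + np.log(np.exp(z / temperature - zmax).sum())))
    if fused_feature is None or stats is None:
        s_maha = float("nan")
    else:
        f = np.asarray(fused_feature, dtype=np.float64).ravel()
        if f.size != stats.dim:
            raise ValueError(f"feature dim {f.size} != stats dim {stats.dim}")
        s_maha = float(np.sqrt(
            ((f - stats.mu) ** 2 / (stats.var + stats.epsilon)).sum()))
    return ScoreVector(s_conf, s_ent, s_energy, s_maha, image_id)


def score_batch(logits: np.ndarray, features: np.ndarray | None = None,
                stats: FeatureStats | None = None,
                temperature: float = 1.0,
                image_ids: list[str] | None = None) -> list[ScoreVector]:
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    n = logits.shape[0]
    ids = image_ids or [f"img{i}" for i in range(n)]
    out = []
    for i in range(n):
        f = None if features is None else features[i]
        out.append(score_image(logits[i], f, stats, temperature, ids[i]))
    return out


def fit_feature_stats(calib_features: np.ndarray,
                      epsilon: float = 1e-3) -> FeatureStats:
    """Empirical mean and population (1/n) variance per dimension."""
    x = np.asarray(calib_features, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an (n >= 2) x D calibration matrix")
    return FeatureStats(x.mean(axis=0), x.var(axis=0, ddof=0), epsilon)


def calibrate_thresholds(id_scores: list[ScoreVector],
                         seed: int = 0) -> Thresholds:
    """Quantile thresholds on ID scores: 5th pct for confidence, 95th for
    entropy/energy/Mahalanobis (linear-interpolation empirical quantile)."""
    if len(id_scores) < 20:
        raise ValueError("need at least 20 ID scores for calibration")
    conf = np.array([s.s_conf for s in id_scores])
    ent = np.array([s.s_ent for s in id_scores])
    energy = np.array([s.s_energy for s in id_scores])
    maha = np.array([s.s_maha for s in id_scores])
    return Thresholds(
        tau_conf=float(np.quantile(conf, 0.05)),
        tau_ent=float(np.quantile(ent, 0.95)),
        tau_energy=float(np.quantile(energy, 0.95)),
        tau_maha=float(np.quantile(maha, 0.95)),
        calib_n=len(id_scores), seed=seed,
    )


def decide(scores: ScoreVector, tau: Thresholds) -> OODDecision:
    """Per-detector flags and the OR-combined decision."""
    return OODDecision(
        flag_conf=scores.s_conf < tau.tau_conf,
        flag_ent=scores.s_ent > tau.tau_ent,
        flag_energy=scores.s_energy > tau.tau_energy,
        flag_maha=scores.s_maha > tau.tau_maha,
    )


def operating_metrics(tn: int, fp: int, fn: int, tp: int) -> dict[str, float]:
    """Confusion-derived metrics with OOD as the positive class."""
    total = tn + fp + fn + tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {
        "accuracy": (tn + tp) / total if total else 0.0,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "id_fpr": fp / (tn + fp) if tn + fp else 0.0,
    }


def _fpr95(id_vals: np.ndarray, ood_vals: np.ndarray) -> float:
    """ID flag rate at the largest threshold keeping OOD TPR >= 0.95.

    Detector convention: score >= threshold flags OOD.
    """
    candidates = np.sort(ood_vals)[::-1]
    n = len(ood_vals)
    # TPR(t) = mean(ood >= t) is monotone in t along sorted candidates
    k = int(np.ceil(0.95 * n)) - 1
    t = candidates[k]
    return float((id_vals >= t).mean())


def benchmark(id_scores: list[ScoreVector], ood_scores: list[ScoreVector],
              tau: Thresholds) -> BenchmarkReport:
    """Per-detector discrimination metrics plus the OR operating point.

    Scores are oriented so that larger means more OOD (confidence is
    negated before ranking).  AUPRC treats OOD as the positive class.
    """
    from sklearn.metrics import average_precision_score

    if not id_scores or not ood_scores:
        raise ValueError("both cohorts must be non-empty")
    rows = []
    labels = np.concatenate([np.zeros(len(id_scores)),
                             np.ones(len(ood_scores))])
    for field, sign in (("s_conf", -1.0), ("s_ent", 1.0),
                        ("s_energy", 1.0), ("s_maha", 1.0)):
        id_vals = sign * np.array([getattr(s, field) for s in id_scores])
        ood_vals = sign * np.array([getattr(s, field) for s in ood_scores])
        pooled = np.concatenate([id_vals, ood_vals])
        rows.append({
            "detector": field,
            "auroc": rank_auroc(pooled, labels),
            "auprc": float(average_precision_score(labels, pooled)),
            "fpr95": _fpr95(id_vals, ood_vals),
        })
    tn = sum(not decide(s, tau).combined for s in id_scores)
    fp = len(id_scores) - tn
    tp = sum(decide(s, tau).combined for s in ood_scores)
    fn = len(ood_scores) - tp
    m = operating_metrics(tn, fp, fn, tp)
    return BenchmarkReport(pd.DataFrame(rows), tn, fp, fn, tp,
                           m["accuracy"], m["precision"], m["recall"],
                           m["f1"], m["id_fpr"])


# ---------------------------------------------------------------------------

def export_scores(records: list[tuple[ScoreVector, str, OODDecision]],
                  path: str | Path) -> pd.DataFrame:
    """Write per-image scores, flags and cohort tags to CSV."""
    rows = []
    for scores, cohort, decision in records:
        rows.append({
            "image_id": scores.image_id,
            "cohort": cohort,
            **{f: getattr(scores, f) for f in SCORE_FIELDS},
            **{f: bool(getattr(decision, f)) for f in FLAG_FIELDS},
            "combined": bool(decision.combined),
        })
    df = pd.DataFrame(rows, columns=["image_id", "cohort", *SCORE_FIELDS,
                                     *FLAG_FIELDS, "combined"])
    df.to_csv(path, index=False)
    return df


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
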