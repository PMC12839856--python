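"""Image-level multi-label targets from box-level radiograph annotations.

The annotation dialect is one row per radiologist bounding box (image id,
class name, optional pixel-space box).  This module aggregates those rows to
per-image binary target vectors over the 15 canonical classes, and provides
the imbalance machinery around them: prevalence summaries, positive-class
weights for the weighted BCE loss, multi-label stratified splitting, and
batch-level mixup.

The class order is frozen; index 14 is "No finding", the normal-case label.
An image whose only label is "No finding" has exactly that one positive
entry, and "No finding" never co-occurs with an abnormality in a valid
target vector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLASS_NAMES: tuple[str, ...] = (
    "Aortic enlargement",
    "Atelectasis",
    "Calcification",
    "Cardiomegaly",
    "Consolidation",
    "ILD",
    "Infiltration",
    "Lung opacity",
    "Nodule/Mass",
    "Other lesion",
    "Pleural effusion",
    "Pleural thickening",
    "Pneumothorax",
    "Pulmonary fibrosis",
    "No finding",
)
N_CLASSES = len(CLASS_NAMES)
NO_FINDING_INDEX = 14

# accepted spellings (lower-cased) -> canonical name
_ALIASES = {name.lower(): name for name in CLASS_NAMES}
_ALIASES["interstitial lung disease"] = "ILD"
_ALIASES["lung opacity"] = "Lung opacity"

SPLIT_NAMES = ("train", "val", "test")


def canonical_class_name(name: str) -> str:
    """Resolve a class-name spelling to the canonical form or raise."""
    key = str(name).strip().lower()
    if key not in _ALIASES:
        raise ValueError(f"unknown class name: {name!r}")
    return _ALIASES[key]


@dataclass(frozen=True)
class BoxAnnotation:
    """One radiologist bounding box (or a box-less "No finding" row)."""

    image_id: str
    class_name: str
    box: tuple[float, float, float, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "class_name",
                           canonical_class_name(self.class_name))
        if self.box is not None:
            x0, y0, x1, y1 = self.box
            if not (x0 < x1 and y0 < y1):
                raise ValueError(
                    f"degenerate box {self.box} on image {self.image_id!r}")


@dataclass
class LabelMatrix:
    """N×15 binary target matrix with a fixed class order."""

    image_ids: list[str]
    y: np.ndarray  # (N, 15) uint8
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.uint8)
        if self.y.shape != (len(self.image_ids), N_CLASSES):
            raise ValueError("label matrix shape mismatch")
        if len(set(self.image_ids)) != len(self.image_ids):
            raise ValueError("duplicate image ids in label matrix")

    def __len__(self):
        return len(self.image_ids)

    def row(self, image_id: str) -> np.ndarray:
        return self.y[self.image_ids.index(image_id)]

    def subset(self, image_ids: list[str]) -> "LabelMatrix":
        index = {iid: i for i, iid in enumerate(self.image_ids)}
        rows = [index[i] for i in image_ids]
        return LabelMatrix(list(image_ids), self.y[rows], self.class_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(self.class_names))
        df.insert(0, "image_id", self.image_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelMatrix":
        df = pd.read_csv(path)
        return cls(df["image_id"].astype(str).tolist(),
                   df[list(CLASS_NAMES)].to_numpy(dtype=np.uint8))


@dataclass
class ClassWeights:
    """Positive-class weights w_c = min(N_c^- / N_c^+, clip_max)."""

    w: np.ndarray
    clip_max: float = 20.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "class_names": list(CLASS_NAMES),
            "weights": [float(v) for v in self.w],
            "clip_max": self.clip_max,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassWeights":
        obj = json.loads(Path(path).read_text())
        return cls(np.asarray(obj["weights"], dtype=float),
                   float(obj["clip_max"]))


@dataclass
class SplitAssignment:
    """Disjoint, exhaustive image-id -> {train, val, test} mapping."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, split: str) -> list[str]:
        return [i for i, s in self.assignment.items() if s == split]

    def to_csv(self, directory: str | Path, prefix: str = "split") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in SPLIT_NAMES:
            pd.DataFrame({"image_id": self.ids(name)}).to_csv(
                directory / f"{prefix}_{name}.csv", index=False)


@dataclass
class MixupBatch:
    x_mixed: np.ndarray
    y_mixed: np.ndarray
    lam: float
    perm: np.ndarray
    alpha: float
    apply_prob: float


@dataclass
class PrevalenceRow:
    class_name: str
    n_pos_train: int
    n_pos_val: int
    n_pos_test: int
    n_pos_total: int
    freq_pct: float


# ---------------------------------------------------------------------------

def aggregate_boxes_to_labels(
    annotations: list[BoxAnnotation],
    conflict_policy: str = "drop_no_finding",
) -> LabelMatrix:
    """Aggregate box rows to one binary target vector per image.

    ``y_c = 1`` iff any box of class ``c`` exists for the image (set
    semantics: duplicate boxes are idempotent).  An image carrying both a
    "No finding" row and an abnormality box is contradictory; under the
    default policy the abnormalities win and "No finding" is zeroed with a
    warning (``conflict_policy="error"`` raises instead).
    """
    by_image: dict[str, set[str]] = {}
    order: list[str] = []
    for i, ann in enumerate(annotations):
        if not isinstance(ann, BoxAnnotation):
            raise TypeError(f"row {i}: expected BoxAnnotation, got {type(ann)}")
        if ann.image_id not in by_image:
            by_image[ann.image_id] = set()
            order.append(ann.image_id)
        by_image[ann.image_id].add(ann.class_name)

    rows = np.zeros((len(order), N_CLASSES), dtype=np.uint8)
    for r, image_id in enumerate(order):
        classes = by_image[image_id]
        abnormal = classes - {"No finding"}
        if "No finding" in classes and abnormal:
            if conflict_policy == "error":
                raise ValueError(
                    f"image {image_id!r} mixes 'No finding' with "
                    f"abnormality boxes {sorted(abnormal)}")
            warnings.warn(
                f"image {image_id!r}: 'No finding' co-occurs with "
                "abnormality boxes; keeping the abnormalities")
            classes = abnormal
        for name in classes:
            rows[r, CLASS_NAMES.index(name)] = 1
    return LabelMatrix(order, rows)


def read_annotations(path: str | Path) -> list[BoxAnnotation]:
    """Read a box-level annotation CSV (train.csv dialect).

    Expected columns: image_id, class_name, and optionally x_min, y_min,
    x_max, y_max (NaN allowed for box-less "No finding" rows).
    """
    df = pd.read_csv(path)
    anns: list[BoxAnnotation] = []
    has_box = {"x_min", "y_min", "x_max", "y_max"}.issubset(df.columns)
    for _, rec in df.iterrows():
        box = None
        if has_box and np.isfinite([rec.x_min, rec.y_min,
                                    rec.x_max, rec.y_max]).all():
            box = (float(rec.x_min), float(rec.y_min),
                   float(rec.x_max), float(rec.y_max))
        anns.append(BoxAnnotation(str(rec.image_id), str(rec.class_name), box))
    return anns


def compute_class_weights(labels: LabelMatrix,
                          clip_max: float = 20.0) -> ClassWeights:
    """w_c = min(N_c^- / N_c^+, clip_max) from the training label matrix.

    A class with no positives gets ``clip_max`` (with a warning) so the loss
    stays finite on degenerate training subsets.
    """
    n = len(labels)
    n_pos = labels.y.sum(axis=0).astype(float)
    w = np.empty(N_CLASSES)
    for c in range(N_CLASSES):
        if n_pos[c] == 0:
            warnings.warn(f"class {CLASS_NAMES[c]!r} has no positives; "
                          f"weight set to clip_max={clip_max}")
            w[c] = clip_max
        else:
            w[c] = min((n - n_pos[c]) / n_pos[c], clip_max)
    return ClassWeights(w, clip_max)


def class_weights_from_counts(n_pos: np.ndarray, n_total: int,
                              clip_max: float = 20.0) -> ClassWeights:
    """Same rule as :func:`compute_class_weights` but from printed counts."""
    n_pos = np.asarray(n_pos, dtype=float)
    raw = (n_total - n_pos) / np.where(n_pos > 0, n_pos, np.nan)
    w = np.where(np.isnan(raw), clip_max, np.minimum(raw, clip_max))
    return ClassWeights(w, clip_max)


def stratified_split(labels: LabelMatrix,
                     fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                     seed: int = 42) -> SplitAssignment:
    """Greedy iterative stratification over label sets.

    Repeatedly takes the label with the fewest unassigned positive examples
    and deals those examples to the split whose remaining per-label demand is
    largest (ties broken by remaining overall capacity, then by the seeded
    rng).  Preserves marginal label prevalence across splits to within a few
    examples per class; deterministic for a fixed seed.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n = len(labels)
    if n < len(SPLIT_NAMES):
        raise ValueError("fewer images than splits")

    rng = np.random.default_rng(seed)
    y = labels.y.astype(bool)
    remaining = np.ones(n, dtype=bool)
    # desired examples per split, overall and per label
    cap = np.array([f * n for f in fractions])
    label_cap = np.array([[f * y[:, c].sum() for c in range(N_CLASSES)]
                          for f in fractions])
    assign = np.full(n, -1, dtype=int)

    while remaining.any():
        counts = y[remaining].sum(axis=0)
        active = np.where(counts > 0)[0]
        if len(active) == 0:
            # label-free leftovers: deal by remaining capacity
            for i in np.where(remaining)[0]:
                s = _pick_split(cap, rng)
                assign[i] = s
                cap[s] -= 1
                remaining[i] = False
            break
        c = active[np.argmin(counts[active])]
        idx = np.where(remaining & y[:, c])[0]
        rng.shuffle(idx)
        for i in idx:
            demand = label_cap[:, c]
            best = np.where(demand == demand.max())[0]
            if len(best) > 1:
                sub = np.where(cap[best] == cap[best].max())[0]
                best = best[sub]
            s = int(rng.choice(best)) if len(best) > 1 else int(best[0])
            assign[i] = s
            cap[s] -= 1
            label_cap[s, y[i]] -= 1
            remaining[i] = False

    mapping = {labels.image_ids[i]: SPLIT_NAMES[assign[i]] for i in range(n)}
    return SplitAssignment(mapping, fractions, seed)


def _pick_split(cap: np.ndarray, rng) -> int:
    best = np.where(cap == cap.max())[0]
    return int(rng.choice(best)) if len(best) > 1 else int(best[0])


def prevalence_table(labels: LabelMatrix,
                     split: SplitAssignment | None = None
                     ) -> list[PrevalenceRow]:
    """Per-class positive counts (optionally per split) and total frequency.

    ``freq_pct`` is 100·n_pos_total/N rounded to two decimals, matching the
    convention of cohort summary tables.
    """
    n = len(labels)
    per_split = {s: np.zeros(N_CLASSES, dtype=int) for s in SPLIT_NAMES}
    if split is not None:
        for i, iid in enumerate(labels.image_ids):
            per_split[split.assignment[iid]] += labels.y[i]
    totals = labels.y.sum(axis=0).astype(int)
    rows = []
    for c, name in enumerate(CLASS_NAMES):
        rows.append(PrevalenceRow(
            class_name=name,
            n_pos_train=int(per_split["train"][c]),
            n_pos_val=int(per_split["val"][c]),
            n_pos_test=int(per_split["test"][c]),
            n_pos_total=int(totals[c]),
            freq_pct=round(100.0 * totals[c] / n, 2) if n else 0.0,
        ))
    return rows


def prevalence_frame(rows: list[PrevalenceRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def mixup_batch(x: np.ndarray, y: np.ndarray, alpha: float = 0.2,
                apply_prob: float = 0.3,
                rng: np.random.Generator | None = None) -> MixupBatch:
    """Batch-level mixup: x' = λx + (1−λ)x_π, y' = λy + (1−λ)y_π.

    One λ ~ Beta(alpha, alpha) per batch, applied with probability
    ``apply_prob``; otherwise the batch passes through with λ = 1.  Targets
    become convex combinations in [0,1]^15, which the weighted BCE loss
    accepts as soft labels.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 2:
        warnings.warn("mixup needs batch size >= 2; returning identity")
        return MixupBatch(x, y, 1.0, np.arange(n), alpha, apply_prob)
    if rng.random() >= apply_prob:
        return MixupBatch(x, y, 1.0, np.arange(n), alpha, apply_prob)
    lam = float(rng.beta(alpha, alpha))
    perm = rng.permutation(n)
    x_mixed = lam * x + (1.0 - lam) * x[perm]
    y_mixed = lam * y + (1.0 - lam) * y[perm]
    return MixupBatch(x_mixed, y_mixed, lam, perm, alpha, apply_prob)
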