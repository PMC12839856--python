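"""Gradient-based class activation maps and localisation metrics.

Given an activation tensor A (K×H'×W', taken either before or after the
attention block) and the gradient G = ∂z_c/∂A of a class logit with respect
to it, this module computes:

* Grad-CAM: channel weights w_k = mean_ij G_kij, map = ReLU(Σ_k w_k A_k);
* Grad-CAM++: the pixel-wise α-weighted variant (α from the second- and
  third-power gradient terms, weights from α ⊙ ReLU(G));
* min–max normalisation and bilinear upsampling to image resolution;
* the top-p binarisation (threshold at the k-th largest value,
  k = ceil(p·H·W), ties included) and its localisation metrics: IoU against
  a rasterised box union, hit (any overlap), anatomy overlap ratio
  |M_top-p ∩ M_anat| / |M_top-p|, and the inside-mask energy ratio
  Σ CAM·M / Σ CAM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage import transform

from .anatomy import RegionSet
from .scaffold import ForwardOutputs, HybridScaffold

__all__ = [
    "ActivationGradPair", "CamHeatmap", "TopPMask", "LocalisationMetrics",
    "grad_cam", "grad_cam_pp", "normalise_upsample", "top_p_mask",
    "mask_iou", "anatomy_overlap", "inside_energy_ratio", "boxes_to_mask",
    "cam_for_class", "localisation_summary",
]


@dataclass
class ActivationGradPair:
    """Activations and the matching class-logit gradients, one image."""

    activations: np.ndarray   # (K, H', W')
    gradients: np.ndarray     # (K, H', W') = ∂z_c/∂A
    class_index: int
    source: str = "post_mxa"  # or "pre_mxa"

    def __post_init__(self):
        self.activations = np.asarray(self.activations, dtype=np.float64)
        self.gradients = np.asarray(self.gradients, dtype=np.float64)
        if self.activations.shape != self.gradients.shape:
            raise ValueError("activation/gradient shape mismatch")
        if self.source not in ("pre_mxa", "post_mxa"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class CamHeatmap:
    """Normalised class-specific saliency map in [0, 1]."""

    values: np.ndarray
    class_index: int
    source: str
    variant: str = "gradcam"
    degenerate: bool = False   # constant raw map collapsed to all-zero


@dataclass
class TopPMask:
    pixels: np.ndarray   # boolean (H, W)
    p: float
    tau_p: float


@dataclass
class LocalisationMetrics:
    iou: float
    hit: bool
    r_inside: float
    inside_energy: float


# ---------------------------------------------------------------------------

def grad_cam(pair: ActivationGradPair) -> np.ndarray:
    """Raw Grad-CAM map: ReLU of the gradient-weighted channel sum."""
    w = pair.gradients.mean(axis=(1, 2))                  # (K,)
    raw = np.tensordot(w, pair.activations, axes=(0, 0))  # (H', W')
    return np.maximum(raw, 0.0)


def grad_cam_pp(pair: ActivationGradPair) -> np.ndarray:
    """Raw Grad-CAM++ map with pixel-wise α weighting of positive gradients.

    α_kij = G²_kij / (2 G²_kij + Σ_ab A_kab G³_kab), taken as 0 where the
    denominator vanishes; channel weights w_k = Σ_ij α_kij · ReLU(G_kij).
    """
    g = pair.gradients
    a = pair.activations
    g2 = g * g
    g3 = g2 * g
    denom = 2.0 * g2 + (a * g3).sum(axis=(1, 2), keepdims=True)
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1.0,
                                                          denom), 0.0)
    w = (alpha * np.maximum(g, 0.0)).sum(axis=(1, 2))
    raw = np.tensordot(w, a, axes=(0, 0))
    return np.maximum(raw, 0.0)


def normalise_upsample(raw_map: np.ndarray, out_size: int,
                       class_index: int = -1, source: str = "post_mxa",
                       variant: str = "gradcam") -> CamHeatmap:
    """Min–max normalise to [0, 1] and bilinearly upsample.

    A constant raw map has no min–max normalisation; it collapses to an
    all-zero heatmap flagged ``degenerate``.
    """
    raw_map = np.asarray(raw_map, dtype=np.float64)
    span = np.ptp(raw_map)
    degenerate = span == 0
    norm = (np.zeros_like(raw_map) if degenerate
            else (raw_map - raw_map.min()) / span)
    if norm.shape != (out_size, out_size):
        norm = transform.resize(norm, (out_size, out_size), order=1,
                                preserve_range=True, anti_aliasing=False)
        norm = np.clip(norm, 0.0, 1.0)
        if not degenerate and np.ptp(norm) > 0:
            # interpolation pulls the peak slightly below 1; restore the
            # [0, 1] span so downstream quantiles see a normalised map
            norm = (norm - norm.min()) / np.ptp(norm)
    return CamHeatmap(norm, class_index, source, variant, degenerate)


def top_p_mask(heatmap: CamHeatmap | np.ndarray, p: float = 0.20) -> TopPMask:
    """Binarise at the k-th largest value, k = ceil(p·H·W), ties included."""
    values = heatmap.values if isinstance(heatmap, CamHeatmap) else \
        np.asarray(heatmap, dtype=np.float64)
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if not values.any():
        warnings.warn("all-zero heatmap: empty top-p mask")
        return TopPMask(np.zeros(values.shape, dtype=bool), p, 0.0)
    k = math.ceil(p * values.size)
    flat = values.ravel()
    tau = float(np.partition(flat, values.size - k)[values.size - k])
    return TopPMask(values >= tau, p, tau)


def mask_iou(mask: TopPMask | np.ndarray, reference: np.ndarray) -> float:
    """|∩|/|∪| between a top-p mask and a reference mask; 0 if both empty."""
    m = mask.pixels if isinstance(mask, TopPMask) else np.asarray(mask, bool)
    r = np.asarray(reference, dtype=bool)
    union = (m | r).sum()
    if union == 0:
        return 0.0
    return float((m & r).sum() / union)


def anatomy_overlap(mask: TopPMask | np.ndarray,
                    anatomy: np.ndarray) -> float:
    """Fraction of top-p pixels inside the anatomy mask; 0 on empty mask."""
    m = mask.pixels if isinstance(mask, TopPMask) else np.asarray(mask, bool)
    n = m.sum()
    if n == 0:
        warnings.warn("empty top-p mask: anatomy overlap set to 0")
        return 0.0
    return float((m & np.asarray(anatomy, bool)).sum() / n)


def inside_energy_ratio(heatmap: CamHeatmap | np.ndarray,
                        region: np.ndarray) -> float:
    """Fraction of total heatmap activation lying inside the region."""
    values = heatmap.values if isinstance(heatmap, CamHeatmap) else \
        np.asarray(heatmap, dtype=np.float64)
    total = values.sum()
    if total == 0:
        warnings.warn("zero-energy heatmap: inside-energy ratio set to 0")
        return 0.0
    return float((values * np.asarray(region, dtype=float)).sum() / total)


def boxes_to_mask(boxes: list[tuple[float, float, float, float]],
                  shape: tuple[int, int]) -> np.ndarray:
    """Rasterise boxes as filled rectangles and union them."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for x0, y0, x1, y1 in boxes:
        r0 = max(0, int(math.floor(y0)))
        r1 = min(h, int(math.ceil(y1)))
        c0 = max(0, int(math.floor(x0)))
        c1 = min(w, int(math.ceil(x1)))
        if r1 > r0 and c1 > c0:
            mask[r0:r1, c0:c1] = True
    return mask


# ---------------------------------------------------------------------------
# Model hookup

def cam_for_class(model: HybridScaffold, image: np.ndarray, class_index: int,
                  source: str = "post_mxa",
                  variant: str = "gradcam") -> CamHeatmap:
    """Run one forward/backward pass and return the class heatmap.

    ``source`` selects the pre- or post-attention feature map; both come from
    the same forward pass, so pre/post comparisons isolate the attention
    refinement.
    """
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    out: ForwardOutputs = model.forward(x)
    seed = np.zeros_like(out.logits.data)
    seed[0, class_index] = 1.0
    out.logits.backward(seed)
    feat = out.f_cnn if source == "pre_mxa" else out.a_cnn
    pair = ActivationGradPair(feat.data[0], feat.grad[0], class_index, source)
    raw = grad_cam(pair) if variant == "gradcam" else grad_cam_pp(pair)
    return normalise_upsample(raw, model.config.input_size, class_index,
                              source, variant)


def localisation_summary(cases: list[dict], p: float = 0.20):
    """Per-class localisation table over a case suite.

    Each case is a dict with keys ``heatmap`` (CamHeatmap or array),
    ``class_name``, ``boxes`` (list of (x0,y0,x1,y1)), and ``lungs_heart``
    (mask).  Returns a DataFrame with Mean IoU and Hit Rate (%) per class
    plus a macro-average row; classes without cases are simply absent.
    """
    import pandas as pd

    per_class: dict[str, list[LocalisationMetrics]] = {}
    for case in cases:
        hm = case["heatmap"]
        values = hm.values if isinstance(hm, CamHeatmap) else np.asarray(hm)
        mask = top_p_mask(values, p)
        ref = boxes_to_mask(case["boxes"], values.shape)
        iou = mask_iou(mask, ref)
        hit = bool((mask.pixels & ref).any())
        r_in = anatomy_overlap(mask, case["lungs_heart"])
        energy = inside_energy_ratio(values, case["lungs_heart"])
        per_class.setdefault(case["class_name"], []).append(
            LocalisationMetrics(iou, hit, r_in, energy))

    rows = []
    for name in sorted(per_class):
        ms = per_class[name]
        rows.append({
            "class": name,
            "n": len(ms),
            "mean_iou": float(np.mean([m.iou for m in ms])),
            "hit_rate_pct": 100.0 * float(np.mean([m.hit for m in ms])),
            "mean_r_inside": float(np.mean([m.r_inside for m in ms])),
            "mean_inside_energy": float(np.mean([m.inside_energy
                                                 for m in ms])),
        })
    macro = {
        "class": "Macro-average",
        "n": int(sum(r["n"] for r in rows)),
        "mean_iou": float(np.mean([r["mean_iou"] for r in rows])),
        "hit_rate_pct": float(np.mean([r["hit_rate_pct"] for r in rows])),
        "mean_r_inside": float(np.mean([r["mean_r_inside"] for r in rows])),
        "mean_inside_energy": float(np.mean([r["mean_inside_energy"]
                                             for r in rows])),
    }
    return pd.DataFrame(rows + [macro])


def evidence_regions_for(regions: RegionSet) -> dict[str, np.ndarray]:
    """Convenience view of the region masks keyed by evidence-component name."""
    return {
        "inside": regions.lungs_heart,
        "inside_heart": regions.heart,
        "apical": regions.apical,
        "basal": regions.basal,
        "near_pleura": regions.pleural_band,
        "near_heart": regions.near_heart,
    }
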