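"""Anatomical masks and derived regions for post hoc saliency analysis.

Lung and heart segmentations arrive as run-length-encoded binary masks
(one RLE string per structure per image, CheXmask style).  From the three
base structures this module derives the regions that the saliency and
reasoning layers score against:

* ``lungs`` / ``lungs_heart`` — pixelwise unions;
* ``apical`` / ``basal`` — upper and lower halves of the lung mask's own
  vertical extent (split at the midpoint of its occupied rows, not the image
  midline);
* ``pleural_band`` — the peripheral lung rim, lungs minus their morphological
  erosion by a disk;
* ``near_heart`` — a dilation annulus around the heart (dilated heart minus
  heart).

It also provides the image preprocessing contract used ahead of the
classifier: photometric inversion, Gaussian denoising, CLAHE contrast
enhancement, and bilinear resize to the working resolution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import exposure, filters, morphology, transform

__all__ = [
    "GreyImage", "RLEMask", "RegionSet",
    "decode_rle", "encode_rle", "rle_from_string", "rle_to_string",
    "derive_regions", "preprocess_image", "resize_mask", "read_chexmask_csv",
]


@dataclass
class GreyImage:
    """Greyscale raster in [0, 255] with a photometric convention.

    ``photometric='inverted'`` marks MONOCHROME1-style data where high pixel
    values are displayed dark; such images are intensity-inverted before any
    enhancement.
    """

    pixels: np.ndarray
    photometric: str = "standard"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("GreyImage must be a non-empty 2-D array")
        if self.photometric not in ("standard", "inverted"):
            raise ValueError(f"unknown photometric {self.photometric!r}")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class RLEMask:
    """Run-length encoding of a binary mask.

    ``runs`` are (start, length) pairs over the flattened mask; the dialect
    (flattening order and start indexing) is explicit because public mask
    releases disagree on it.  Default: column-major, 1-based (Kaggle style).
    """

    runs: tuple[tuple[int, int], ...]
    shape: tuple[int, int]
    order: str = "column_major"       # or "row_major"
    indexing: str = "one_based"       # or "zero_based"

    def __post_init__(self):
        if self.order not in ("row_major", "column_major"):
            raise ValueError(f"unknown order {self.order!r}")
        if self.indexing not in ("zero_based", "one_based"):
            raise ValueError(f"unknown indexing {self.indexing!r}")


@dataclass
class RegionSet:
    """All derived anatomical regions at a common shape.

    Invariants (checked on construction): lungs = left ∪ right;
    lungs_heart = lungs ∪ heart; apical and basal partition lungs;
    pleural_band ⊆ lungs; near_heart is disjoint from heart.
    """

    left_lung: np.ndarray
    right_lung: np.ndarray
    heart: np.ndarray
    lungs: np.ndarray
    lungs_heart: np.ndarray
    apical: np.ndarray
    basal: np.ndarray
    pleural_band: np.ndarray
    near_heart: np.ndarray

    def __post_init__(self):
        shape = self.left_lung.shape
        for f in fields(self):
            m = getattr(self, f.name)
            m = np.asarray(m, dtype=bool)
            if m.shape != shape:
                raise ValueError(f"region {f.name} shape mismatch")
            setattr(self, f.name, m)
        if not np.array_equal(self.lungs, self.left_lung | self.right_lung):
            raise ValueError("lungs must equal left ∪ right")
        if not np.array_equal(self.lungs_heart, self.lungs | self.heart):
            raise ValueError("lungs_heart must equal lungs ∪ heart")
        if (self.apical & self.basal).any():
            raise ValueError("apical and basal must be disjoint")
        if not np.array_equal(self.apical | self.basal, self.lungs):
            raise ValueError("apical ∪ basal must equal lungs")
        if (self.pleural_band & ~self.lungs).any():
            raise ValueError("pleural_band must lie inside lungs")
        if (self.near_heart & self.heart).any():
            raise ValueError("near_heart must be disjoint from heart")

    @property
    def shape(self):
        return self.left_lung.shape

    def resize(self, out_size: int) -> "RegionSet":
        """Nearest-neighbour resize of the three base structures, then
        re-derivation is NOT performed; each region is resized directly and
        re-validated (unions/partitions survive nearest-neighbour resampling
        of consistent masks)."""
        kwargs = {f.name: resize_mask(getattr(self, f.name), out_size)
                  for f in fields(self)}
        return RegionSet(**kwargs)

    def save(self, path: str | Path) -> None:
        """Persist as a compressed array container plus a JSON sidecar."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            **{f.name: getattr(self, f.name) for f in fields(self)})
        path.with_suffix(".json").write_text(json.dumps({
            "regions": [f.name for f in fields(self)],
            "shape": list(self.shape),
        }, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RegionSet":
        arrays = np.load(Path(path).with_suffix(".npz"))
        return cls(**{k: arrays[k] for k in arrays.files})


# ---------------------------------------------------------------------------
# RLE codec

def decode_rle(mask: RLEMask) -> np.ndarray:
    """Decode an RLE mask to a boolean (H, W) array.

    Inverse of :func:`encode_rle` for the same dialect.  Out-of-bounds runs
    are rejected with the offending run index.
    """
    h, w = mask.shape
    flat = np.zeros(h * w, dtype=bool)
    offset = 1 if mask.indexing == "one_based" else 0
    for i, (start, length) in enumerate(mask.runs):
        s = start - offset
        if s < 0 or length < 0 or s + length > h * w:
            raise ValueError(f"run {i} ({start}, {length}) out of bounds "
                             f"for shape {mask.shape}")
        flat[s:s + length] = True
    np_order = "C" if mask.order == "row_major" else "F"
    return flat.reshape((h, w), order=np_order)


def encode_rle(mask: np.ndarray, order: str = "column_major",
               indexing: str = "one_based") -> RLEMask:
    """Run-length encode a boolean mask in the requested dialect."""
    mask = np.asarray(mask, dtype=bool)
    np_order = "C" if order == "row_major" else "F"
    flat = mask.reshape(-1, order=np_order)
    padded = np.concatenate([[False], flat, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[::2], edges[1::2]
    offset = 1 if indexing == "one_based" else 0
    runs = tuple((int(s) + offset, int(e - s)) for s, e in zip(starts, ends))
    return RLEMask(runs, mask.shape, order, indexing)


def rle_to_string(mask: RLEMask) -> str:
    return " ".join(f"{s} {l}" for s, l in mask.runs)


def rle_from_string(text: str, shape: tuple[int, int],
                    order: str = "column_major",
                    indexing: str = "one_based") -> RLEMask:
    tokens = [int(t) for t in str(text).split()]
    if len(tokens) % 2:
        raise ValueError("RLE string must contain start/length pairs")
    runs = tuple((tokens[i], tokens[i + 1]) for i in range(0, len(tokens), 2))
    return RLEMask(runs, shape, order, indexing)


def read_chexmask_csv(path: str | Path, order: str = "column_major",
                      indexing: str = "one_based") -> dict[str, dict]:
    """Read a CheXmask-style CSV of per-image lung/heart RLE masks.

    Columns: image_id, rle_left_lung, rle_right_lung, rle_heart, height,
    width.  Returns image_id -> {'left_lung','right_lung','heart'} boolean
    arrays.
    """
    df = pd.read_csv(path)
    out = {}
    for _, rec in df.iterrows():
        shape = (int(rec.height), int(rec.width))
        out[str(rec.image_id)] = {
            name: decode_rle(rle_from_string(rec[f"rle_{name}"], shape,
                                             order, indexing))
            for name in ("left_lung", "right_lung", "heart")
        }
    return out


# ---------------------------------------------------------------------------
# Region derivation

def derive_regions(left_lung: np.ndarray, right_lung: np.ndarray,
                   heart: np.ndarray, pleural_erosion_radius: int = 8,
                   heart_dilation_radius: int = 8) -> RegionSet:
    """Derive the full region set from the three base structures.

    The apical/basal split is taken at r_mid = floor((r_min+r_max+1)/2) over
    the lung mask's occupied rows; the pleural band is the lung rim left by a
    disk erosion; near_heart is a disk-dilation annulus around the heart.
    Default radii are 8 px at the 384² working resolution and should be
    scaled with the image size.
    """
    left_lung = np.asarray(left_lung, dtype=bool)
    right_lung = np.asarray(right_lung, dtype=bool)
    heart = np.asarray(heart, dtype=bool)
    if not (left_lung.shape == right_lung.shape == heart.shape):
        raise ValueError("masks must share shape")

    lungs = left_lung | right_lung
    lungs_heart = lungs | heart

    occupied = np.flatnonzero(lungs.any(axis=1))
    apical = np.zeros_like(lungs)
    basal = np.zeros_like(lungs)
    pleural = np.zeros_like(lungs)
    if occupied.size == 0:
        warnings.warn("empty lung mask: apical/basal/pleural are empty")
    else:
        r_mid = (int(occupied[0]) + int(occupied[-1]) + 1) // 2
        row_idx = np.arange(lungs.shape[0])[:, None]
        apical = lungs & (row_idx < r_mid)
        basal = lungs & ~apical
        if pleural_erosion_radius > 0:
            eroded = morphology.erosion(
                lungs, morphology.disk(pleural_erosion_radius))
            pleural = lungs & ~eroded

    near_heart = np.zeros_like(heart)
    if heart_dilation_radius > 0 and heart.any():
        dilated = morphology.dilation(
            heart, morphology.disk(heart_dilation_radius))
        near_heart = dilated & ~heart

    return RegionSet(left_lung, right_lung, heart, lungs, lungs_heart,
                     apical, basal, pleural, near_heart)


# ---------------------------------------------------------------------------
# Preprocessing contract

def preprocess_image(raw: GreyImage, blur_sigma: float = 1.0,
                     clahe_clip: float = 0.01, clahe_tiles: int = 8,
                     out_size: int = 384) -> GreyImage:
    """Standard enhancement pipeline: invert → blur → CLAHE → resize.

    The output is ``out_size``² with intensities range-normalised to
    [0, 255] and standard photometric.  A flat input field stays flat (CLAHE
    is skipped on zero-dynamic-range images).  Non-finite pixels are
    rejected.
    """
    px = raw.pixels
    if not np.isfinite(px).all():
        raise ValueError("non-finite pixels in input image")
    x = px / 255.0
    if raw.photometric == "inverted":
        x = x.max() + x.min() - x  # reflect inside the observed range
    if blur_sigma > 0:
        x = filters.gaussian(x, sigma=blur_sigma, preserve_range=True)
    if np.ptp(x) > 0:
        x01 = (x - x.min()) / np.ptp(x)
        kernel = max(1, min(x.shape) // clahe_tiles)
        x = exposure.equalize_adapthist(x01, kernel_size=kernel,
                                        clip_limit=clahe_clip)
    x = transform.resize(x, (out_size, out_size), order=1,
                         preserve_range=True, anti_aliasing=False)
    if np.ptp(x) > 0:
        x = (x - x.min()) / np.ptp(x)
    out = np.clip(x * 255.0, 0.0, 255.0)
    return GreyImage(out, photometric="standard")


def resize_mask(mask: np.ndarray, out_size: int) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask, re-binarised at 0.5."""
    mask = np.asarray(mask, dtype=float)
    if mask.shape == (out_size, out_size):
        return mask >= 0.5
    resized = transform.resize(mask, (out_size, out_size), order=0,
                               preserve_range=True, anti_aliasing=False)
    return resized >= 0.5


def mask_at_feature_resolution(mask: np.ndarray,
                               feature_shape: tuple[int, int]) -> np.ndarray:
    """Average-pool a pixel mask onto a coarse feature grid, in [0, 1]."""
    zoom = (feature_shape[0] / mask.shape[0], feature_shape[1] / mask.shape[1])
    return np.clip(ndimage.zoom(np.asarray(mask, dtype=float), zoom, order=1),
                   0.0, 1.0)
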