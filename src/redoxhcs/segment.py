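"""Cell segmentation for ratiometric roGFP fields.

Two strategies are provided, mirroring the two acquisition configurations
of the assay:

* **intensity mode** — Otsu threshold on the (background-corrected) ex405
  roGFP channel followed by connected-component labelling. Fails to separate
  touching cells in crowded epithelial monolayers.
* **nuclear-ring mode** — nuclei are segmented on the nuclear-marker
  channel (threshold, hole filling, distance-transform watershed to split
  touching nuclei) and a perinuclear ring ROI is built around each nucleus
  by Euclidean dilation of the (optionally eroded) nuclear mask. The ring
  is the readout plane for the mitochondrial signal.

All morphology uses the Euclidean metric: erosion keeps pixels whose
distance to the background exceeds the erosion radius, and ring dilation
admits pixels whose exact Euclidean distance to the nucleus pixel set is at
most the ring width. Pixels reachable from several nuclei are assigned to
the nearest one (ties to the lower label), so results are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential, watershed

from .errors import ValidationError

LABEL_KINDS = ("nucleus", "cell", "ring")


@dataclass
class LabelMap:
    """Integer per-pixel object assignment; 0 is background."""

    labels: np.ndarray
    kind: str = "cell"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label map must be integer-valued")
        if self.labels.min(initial=0) < 0:
            raise ValidationError("label map has negative labels")
        if self.kind not in LABEL_KINDS:
            raise ValidationError(f"label kind must be one of {LABEL_KINDS}")

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(len(self.ids))


@dataclass
class SegmentationParams:
    """Tunable segmentation knobs (all lengths in pixels)."""

    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: float | None = None
    min_object_area_px: int = 50
    ring_dilation_width_px: int = 6
    nucleus_erosion_px: int = 0
    split_min_peak_distance_px: int = 7

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValidationError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValidationError("fixed threshold_method requires fixed_threshold")
        if self.min_object_area_px < 1:
            raise ValidationError("min_object_area_px must be >= 1")
        if self.ring_dilation_width_px < 0 or self.nucleus_erosion_px < 0:
            raise ValidationError("morphological widths must be >= 0")


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 8-connected foreground components smaller than ``min_area``."""
    labels = cc_label(mask, connectivity=2)
    if labels.max() == 0:
        return mask
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def subtract_background(
    image: np.ndarray, reference: np.ndarray | None = None
) -> np.ndarray:
    """Background-correct an intensity image, clamped at zero.

    With a reference image: ``max(image - reference, 0)``. Without one, a
    robust scalar background — the median of the pixels below the Otsu
    threshold — is subtracted instead.
    """
    image = np.asarray(image, dtype=float)
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != image.shape:
            raise ValidationError(
                f"background reference shape {reference.shape} differs from "
                f"image shape {image.shape}"
            )
        return np.maximum(image - reference, 0.0)
    flat = image.ravel()
    if np.ptp(flat) == 0:
        return np.zeros_like(image)
    thr = threshold_otsu(flat)
    below = flat[flat < thr]
    level = float(np.median(below)) if below.size else float(np.median(flat))
    return np.maximum(image - level, 0.0)


def _threshold(image: np.ndarray, params: SegmentationParams) -> np.ndarray | None:
    """Foreground mask, or None for a blank (constant) image."""
    if params.threshold_method == "fixed":
        return image > params.fixed_threshold
    if np.ptp(image) == 0:
        return None
    return image > threshold_otsu(image)


def segment_intensity(
    ex405_image: np.ndarray, params: SegmentationParams | None = None
) -> LabelMap:
    """Intensity-threshold segmentation of whole cells on the roGFP channel.

    Threshold (Otsu by default), drop objects below ``min_object_area_px``,
    8-connected component labelling. A blank image yields an empty map.
    """
    params = params or SegmentationParams()
    image = np.asarray(ex405_image, dtype=float)
    mask = _threshold(image, params)
    if mask is None or not mask.any():
        return LabelMap(np.zeros(image.shape, dtype=np.int32), kind="cell")
    mask = _drop_small(mask, params.min_object_area_px)
    labels = cc_label(mask, connectivity=2).astype(np.int32)
    return LabelMap(labels, kind="cell")


def segment_nuclei(
    nuclear_image: np.ndarray, params: SegmentationParams | None = None
) -> LabelMap:
    """Nuclear-marker segmentation with watershed splitting of touching nuclei.

    Threshold, fill holes, then split the foreground by a watershed on the
    negated Euclidean distance transform, seeded at local distance maxima at
    least ``split_min_peak_distance_px`` apart.
    """
    params = params or SegmentationParams()
    image = np.asarray(nuclear_image, dtype=float)
    mask = _threshold(image, params)
    if mask is None or not mask.any():
        return LabelMap(np.zeros(image.shape, dtype=np.int32), kind="nucleus")
    mask = ndimage.binary_fill_holes(mask)
    mask = _drop_small(mask, params.min_object_area_px)
    if not mask.any():
        return LabelMap(np.zeros(image.shape, dtype=np.int32), kind="nucleus")
    dist = ndimage.distance_transform_edt(mask)
    blobs = cc_label(mask, connectivity=2)
    coords = peak_local_max(
        dist,
        min_distance=params.split_min_peak_distance_px,
        labels=blobs,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # degenerate: fall back to connected components
        labels = blobs.astype(np.int32)
    else:
        labels = watershed(-dist, markers, mask=mask).astype(np.int32)
    areas = np.bincount(labels.ravel())
    small = areas < params.min_object_area_px
    small[0] = False
    labels[small[labels]] = 0
    labels, _, _ = relabel_sequential(labels)
    return LabelMap(labels.astype(np.int32), kind="nucleus")


def ring_rois(nuclei: LabelMap, params: SegmentationParams | None = None) -> LabelMap:
    """Perinuclear ring ROIs by Euclidean dilation of each nucleus.

    For nucleus k: erode by ``nucleus_erosion_px`` (Euclidean), admit every
    pixel whose distance to the eroded seed is at most
    ``ring_dilation_width_px``, then remove all nucleus pixels. A pixel
    reachable from several seeds belongs to the seed at the smaller
    Euclidean distance; ties go to the lower label. Ring labels equal their
    nucleus labels.
    """
    params = params or SegmentationParams()
    if nuclei.kind != "nucleus":
        raise ValidationError("ring_rois expects a nucleus label map")
    labels = nuclei.labels
    w = params.ring_dilation_width_px
    out = np.zeros(labels.shape, dtype=np.int32)
    if w == 0:
        warnings.warn("ring_dilation_width_px = 0: all rings are empty",
                      stacklevel=2)
        return LabelMap(out, kind="ring")
    e = params.nucleus_erosion_px
    best_dist = np.full(labels.shape, np.inf)
    best_lab = np.zeros(labels.shape, dtype=np.int32)
    pad = w + e + 1
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        rs = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, labels.shape[0]))
        cs = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, labels.shape[1]))
        m = labels[rs, cs] == lab
        if e > 0:
            seed = ndimage.distance_transform_edt(m) > e
        else:
            seed = m
        if not seed.any():
            continue
        d = ndimage.distance_transform_edt(~seed)
        bd = best_dist[rs, cs]
        bl = best_lab[rs, cs]
        upd = (d <= w) & (d < bd)  # strict <: earlier (lower) label keeps ties
        bd[upd] = d[upd]
        bl[upd] = lab
    ring = (best_dist <= w) & (labels == 0)
    out[ring] = best_lab[ring]
    return LabelMap(out, kind="ring")


@dataclass
class MatchResult:
    precision: float
    recall: float
    f1: float
    pairs: pd.DataFrame  # columns pred_label, truth_label, iou


def match_to_ground_truth(
    pred: LabelMap | np.ndarray,
    truth: LabelMap | np.ndarray,
    iou_threshold: float = 0.5,
) -> MatchResult:
    """One-to-one object matching by greedy descending IoU above threshold.

    Precision/recall follow the usual detection convention; both are 1 when
    prediction and truth are empty and 0 when only one side is empty.
    """
    p = (pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)).ravel()
    t = (truth.labels if isinstance(truth, LabelMap) else np.asarray(truth)).ravel()
    if p.shape != t.shape:
        raise ValidationError("prediction and truth label maps differ in shape")
    areas_p = np.bincount(p)
    areas_t = np.bincount(t)
    n_pred = int((areas_p[1:] > 0).sum())
    n_truth = int((areas_t[1:] > 0).sum())

    both = (p > 0) & (t > 0)
    pairs = []
    if both.any():
        key = p[both].astype(np.int64) * (int(t.max()) + 1) + t[both]
        uniq, counts = np.unique(key, return_counts=True)
        pl = uniq // (int(t.max()) + 1)
        tl = uniq % (int(t.max()) + 1)
        inter = counts
        union = areas_p[pl] + areas_t[tl] - inter
        iou = inter / union
        order = np.lexsort((tl, pl, -iou))
        used_p: set[int] = set()
        used_t: set[int] = set()
        for idx in order:
            if iou[idx] < iou_threshold:
                break
            a, b = int(pl[idx]), int(tl[idx])
            if a in used_p or b in used_t:
                continue
            used_p.add(a)
            used_t.add(b)
            pairs.append((a, b, float(iou[idx])))

    tp = len(pairs)
    precision = tp / n_pred if n_pred else (1.0 if n_truth == 0 else 0.0)
    recall = tp / n_truth if n_truth else (1.0 if n_pred == 0 else 0.0)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MatchResult(
        precision=precision,
        recall=recall,
        f1=f1,
        pairs=pd.DataFrame(pairs, columns=["pred_label", "truth_label", "iou"]),
    )
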