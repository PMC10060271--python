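"""Brightfield organoid segmentation (classical path) and mask utilities.

The classical chain is a deterministic baseline: background flattening by
large-scale Gaussian subtraction, a darkness + edge response, Otsu
thresholding with an absolute contrast floor, morphological closing and
hole filling (so the bright lumen of cystic organoids is counted as part
of the object), connected components, a minimum-area filter, and optional
distance-transform watershed splitting of touching objects. Splitting is
off by default: organoids that fused during culture are deliberately kept
as one object, matching how counts behave under fusion.

A parallel path builds ground-truth masks from fluorescence channels
(nuclear blue, optionally death green) for training the semantic
segmentation network in :mod:`orgscreen.fcn`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation as sk_seg

from .config import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "background_sigma": 25.0,  # px; scale of illumination flattening
    "edge_weight": 0.5,  # weight of gradient magnitude in the response
    "min_contrast": 0.05,  # absolute response floor under the Otsu cut
    "min_object_area_px": 50,  # excludes debris specks and noise
    "closing_radius": 3,
    "split_touching": False,
    "split_min_distance": 15,  # px between watershed markers
}


@dataclass
class LabeledMask:
    """Per-frame labeled segmentation: 0 background, k>0 object k.

    ``boundary_labels`` flags objects touching the image edge (retained,
    not removed). ``provenance`` records which path produced the mask.
    """

    labels: np.ndarray
    frame: int = 0
    provenance: str = "classical"  # classical | fcn | truth
    boundary_labels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValidationError(f"labels: expected 2-D raster, got {self.labels.ndim}-D")
        self.labels = np.ascontiguousarray(self.labels)

    @property
    def n_objects(self) -> int:
        return int(len(self.label_ids))

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def areas_px(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel())
        return {int(k): int(counts[k]) for k in self.label_ids}

    def areas_um2(self, um_per_px: float) -> dict[int, float]:
        return {k: v * um_per_px**2 for k, v in self.areas_px().items()}

    def total_area_um2(self, um_per_px: float) -> float:
        return float(np.count_nonzero(self.labels)) * um_per_px**2

    def foreground(self) -> np.ndarray:
        return self.labels > 0


def _postprocess(
    fg: np.ndarray, params: dict, provenance: str, frame: int
) -> LabeledMask:
    """Shared tail of both segmentation paths: morphology, CC, filters."""
    radius = int(params["closing_radius"])
    min_area = int(params["min_object_area_px"])
    if radius > 0:
        fg = morphology.closing(fg, morphology.disk(radius))
    fg = ndi.binary_fill_holes(fg)
    # remove_small_objects drops components <= max_size; keep >= min_area
    fg = morphology.remove_small_objects(fg, max_size=min_area - 1)

    if params.get("split_touching"):
        dist = ndi.distance_transform_edt(fg)
        peaks = morphology.h_maxima(dist, 2)
        markers, _ = ndi.label(peaks)
        # suppress markers closer than split_min_distance: keep the deeper one
        labels = sk_seg.watershed(-dist, markers, mask=fg)
        labels = _suppress_close_markers(labels, dist, params["split_min_distance"])
        labels = morphology.remove_small_objects(labels, max_size=min_area - 1)
    else:
        labels, _ = ndi.label(fg)

    labels, _, _ = sk_seg.relabel_sequential(labels)
    labels = labels.astype(np.int32)

    edge = np.zeros_like(labels, dtype=bool)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    boundary = frozenset(int(k) for k in np.unique(labels[edge]) if k > 0)
    return LabeledMask(labels=labels, frame=frame, provenance=provenance,
                       boundary_labels=boundary)


def _suppress_close_markers(labels: np.ndarray, dist: np.ndarray, min_distance: float):
    """Re-merge watershed fragments whose maxima are closer than min_distance."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) < 2:
        return labels
    centers = ndi.maximum_position(dist, labels, ids)
    out = labels.copy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d < min_distance:
                out[out == ids[j]] = ids[i]
    return out


def segment_classical(
    bf: np.ndarray, params: dict | None = None, frame: int = 0
) -> LabeledMask:
    """Segment organoids from a single brightfield raster.

    Organoids are darker than the flattened background; air bubbles
    (bright rings) fall below the darkness response and debris below the
    minimum-area filter, so common artifacts do not enter the mask.
    """
    bf = np.asarray(bf, dtype=float)
    if bf.ndim != 2:
        raise ValidationError(f"bf: expected 2-D intensity raster, got {bf.ndim}-D")
    p = {**DEFAULT_PARAMS, **(params or {})}

    background = ndi.gaussian_filter(bf, p["background_sigma"])
    flat = bf - background
    darkness = np.clip(-flat, 0.0, None)
    edges = filters.sobel(ndi.gaussian_filter(bf, 1.0))
    response = darkness + p["edge_weight"] * edges

    thr = max(filters.threshold_otsu(response), p["min_contrast"])
    return _postprocess(response > thr, p, "classical", frame)


def fluorescence_ground_truth(
    blue: np.ndarray | None,
    green: np.ndarray | None = None,
    params: dict | None = None,
    frame: int = 0,
) -> LabeledMask:
    """Build a ground-truth organoid mask from fluorescence channels.

    The blue nuclear channel is auto-thresholded per frame; green-positive
    regions (dead nuclei remain part of the organoid) are unioned in; the
    rim-only signal of cystic organoids is closed and hole-filled into a
    solid object.
    """
    if blue is None:
        raise ValidationError("blue: nuclear channel required for ground truth")
    blue = np.asarray(blue, dtype=float)
    if blue.ndim != 2:
        raise ValidationError(f"blue: expected 2-D raster, got {blue.ndim}-D")
    p = {**DEFAULT_PARAMS, **(params or {})}

    if np.ptp(blue) < 1e-12:
        logger.warning("fluorescence_ground_truth: all-constant blue channel, empty mask")
        return LabeledMask(labels=np.zeros(blue.shape, np.int32), frame=frame,
                           provenance="truth")
    fg = blue > filters.threshold_otsu(blue)
    if green is not None:
        green = np.asarray(green, dtype=float)
        if green.shape != blue.shape:
            raise ValidationError("green: shape must match blue channel")
        if np.ptp(green) > 1e-12:
            fg |= green > max(filters.threshold_otsu(green), 0.3)
    # closing radius large enough to bridge the cystic rim before hole fill
    p = {**p, "closing_radius": max(p["closing_radius"], 4), "split_touching": False}
    return _postprocess(fg, p, "truth", frame)


def mask_overlap(
    a: LabeledMask | np.ndarray, b: LabeledMask | np.ndarray, um_per_px: float = 1.0
) -> dict:
    """Pairwise overlap summary between two masks.

    Reports |A|, |B| and |A∩B| in µm², the fraction |A∩B|/|A|, and the
    per-object fraction of each A-object covered by B.
    """
    fa = a.foreground() if isinstance(a, LabeledMask) else np.asarray(a) > 0
    fb = b.foreground() if isinstance(b, LabeledMask) else np.asarray(b) > 0
    if fa.shape != fb.shape:
        raise ValidationError(f"mask dimensions differ: {fa.shape} vs {fb.shape}")
    scale = um_per_px**2
    inter = fa & fb
    out = {
        "area_a_um2": float(fa.sum()) * scale,
        "area_b_um2": float(fb.sum()) * scale,
        "intersection_um2": float(inter.sum()) * scale,
        "fraction_a_in_b": float(inter.sum()) / fa.sum() if fa.sum() else float("nan"),
        "per_object_fraction": {},
    }
    if isinstance(a, LabeledMask):
        for k, area in a.areas_px().items():
            out["per_object_fraction"][k] = float(((a.labels == k) & fb).sum()) / area
    return out


def iou(a: LabeledMask | np.ndarray, b: LabeledMask | np.ndarray) -> float:
    """Foreground intersection-over-union between two masks."""
    fa = a.foreground() if isinstance(a, LabeledMask) else np.asarray(a) > 0
    fb = b.foreground() if isinstance(b, LabeledMask) else np.asarray(b) > 0
    if fa.shape != fb.shape:
        raise ValidationError(f"mask dimensions differ: {fa.shape} vs {fb.shape}")
    union = (fa | fb).sum()
    return float((fa & fb).sum() / union) if union else 1.0
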