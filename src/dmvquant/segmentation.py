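"""Classical detection of dark tubular vessels on MinIP slices.

The reference detector is a multi-scale Sato tubularity filter on the
intensity-inverted slice, followed by hysteresis thresholding and a
minimum-area filter, optionally refined back to the dark pixels so vessel
walls are delineated at image (not filter) resolution.  Any trained
semantic-segmentation model can replace it through the
:class:`SegmenterContract` callable surface (a MinIP slice in, a mask of
the same shape out); the quantification downstream is agnostic to where
the mask came from.

Also here: the pixelwise evaluation metrics (accuracy, Dice) and the
ratio/k-fold dataset split utility used when training such a model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from skimage.filters import apply_hysteresis_threshold, sato
from skimage.measure import label as cc_label
from scipy.ndimage import binary_dilation
from skimage.morphology import disk, remove_small_objects

from .morphometry import VesselInstance
from .reconstruction import MinipSlice

__all__ = [
    "VesselnessMap",
    "VesselMask",
    "SegEvalResult",
    "SegmenterContract",
    "ClassicalSegmenter",
    "DEFAULT_SCALES_MM",
    "vesselness_response",
    "segment_mask",
    "refine_mask",
    "label_vessels",
    "evaluate_segmentation",
    "split_dataset",
]

#: default tubularity radii (mm), spanning the 0.49-0.93 mm DMV width range
DEFAULT_SCALES_MM = (0.25, 0.4, 0.55, 0.7, 0.85, 1.0)


@dataclass
class VesselnessMap:
    response: np.ndarray  # 2D, >= 0
    scales_mm: tuple

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        if self.response.ndim != 2:
            raise ValueError("response must be 2D")


@dataclass
class VesselMask:
    mask: np.ndarray  # 2D bool
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self):
        return self.mask.shape


@dataclass
class SegEvalResult:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def pixel_accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.fn + self.tn)

    @property
    def dice(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 1.0


@runtime_checkable
class SegmenterContract(Protocol):
    """Anything mapping a MinIP slice to a same-shaped vessel mask.

    Trained models plug in here; the shipped classical detector is one
    implementation of the contract.
    """

    def __call__(self, s: MinipSlice) -> VesselMask: ...


def vesselness_response(s: MinipSlice | np.ndarray,
                        scales_mm: tuple = DEFAULT_SCALES_MM,
                        spacing_mm: float | None = None) -> VesselnessMap:
    """Multi-scale tubularity response for dark ridges.

    The slice is intensity-inverted (veins become bright ridges) and a
    Sato filter is run at Gaussian scales matched to the supplied vessel
    radii; the per-pixel maximum over scales is returned.  Deterministic,
    non-negative, zero on structure-free images.
    """
    if isinstance(s, MinipSlice):
        image = np.asarray(s.image, dtype=float)
        if spacing_mm is None:
            spacing_mm = float(s.spacing_mm[0])
    else:
        image = np.asarray(s, dtype=float)
        if spacing_mm is None:
            raise ValueError("spacing_mm is required for a bare array")
    if len(scales_mm) == 0:
        raise ValueError("scales_mm must not be empty")
    if any(x <= 0 for x in scales_mm):
        raise ValueError("scales must be positive")
    inverted = image.max() - image
    # sigma ~ radius / sqrt(2) peaks the second-derivative response at
    # the vessel half-width
    sigmas = [r / spacing_mm / np.sqrt(2.0) for r in scales_mm]
    resp = sato(inverted, sigmas=sigmas, black_ridges=False, mode="reflect")
    resp = np.maximum(resp, 0.0)
    return VesselnessMap(response=resp, scales_mm=tuple(scales_mm))


def segment_mask(response: VesselnessMap, low_threshold: float = 0.05,
                 high_threshold: float = 0.15, min_area_px: int = 5,
                 relative: bool = True) -> VesselMask:
    """Hysteresis thresholding of a tubularity response.

    Weak-response pixels survive only when connected to a strong seed;
    components below ``min_area_px`` are removed.  With ``relative`` the
    thresholds are fractions of the response maximum, making them
    contrast-invariant.
    """
    if low_threshold > high_threshold:
        raise ValueError("low_threshold must be <= high_threshold")
    if min_area_px < 0:
        raise ValueError("min_area_px must be >= 0")
    resp = response.response
    lo, hi = float(low_threshold), float(high_threshold)
    if relative:
        peak = resp.max()
        lo, hi = lo * peak, hi * peak
    if resp.max() <= 0:
        mask = np.zeros_like(resp, dtype=bool)
    elif lo == hi:
        mask = resp >= lo
    else:
        mask = apply_hysteresis_threshold(resp, lo, hi)
    if min_area_px > 0:
        mask = remove_small_objects(mask, max_size=min_area_px - 1,
                                    connectivity=2)
    return VesselMask(mask=mask, provenance={
        "detector": "sato-hysteresis", "low": low_threshold,
        "high": high_threshold, "min_area_px": min_area_px,
        "relative": relative, "scales_mm": response.scales_mm})


def refine_mask(image: np.ndarray, mask: VesselMask, dilate_px: int = 2,
                min_area_px: int = 5) -> VesselMask:
    """Snap a detected mask back to the dark pixels of the image.

    The tubularity response spreads past the vessel wall by roughly a
    filter scale, which would bias width estimates.  The refinement
    thresholds the image at the midpoint between the detected-vessel
    lower-quartile intensity and the background median and keeps every
    dark connected component
    touching a (slightly dilated) detection seed — an intensity-level
    hysteresis that both trims the halo and heals detections that
    fragmented along one vessel.  Components below ``min_area_px`` are
    dropped.
    """
    image = np.asarray(image, dtype=float)
    m = mask.mask
    if not m.any():
        return VesselMask(mask=m.copy(), provenance=dict(mask.provenance))
    seeds = binary_dilation(m, structure=disk(dilate_px))
    # lower quartile: the detected mask drags in partial-volume halo
    # pixels, which would inflate a plain mean
    vessel_level = np.percentile(image[m], 25)
    background = np.median(image[~seeds]) if (~seeds).any() else image.max()
    threshold = 0.5 * (vessel_level + background)
    dark = image < threshold
    dark_labels = cc_label(dark, connectivity=2)
    keep = np.unique(dark_labels[seeds & dark])
    keep = keep[keep > 0]
    refined = np.isin(dark_labels, keep)
    if min_area_px > 0:
        refined = remove_small_objects(refined, max_size=min_area_px - 1,
                                       connectivity=2)
    prov = dict(mask.provenance)
    prov.update({"refined": True, "refine_threshold": float(threshold)})
    return VesselMask(mask=refined, provenance=prov)


@dataclass
class ClassicalSegmenter:
    """The reference detector as a :class:`SegmenterContract`.

    ``roi_border_px`` masks out a border margin (a crude stand-in for a
    corona-radiata ROI when none is supplied); ``roi`` may carry an
    explicit boolean ROI instead.
    """

    scales_mm: tuple = DEFAULT_SCALES_MM
    low_threshold: float = 0.05
    high_threshold: float = 0.15
    min_area_px: int = 5
    refine: bool = True
    roi: np.ndarray | None = None
    roi_border_px: int = 0

    def __call__(self, s: MinipSlice) -> VesselMask:
        vmap = vesselness_response(s, self.scales_mm)
        if self.roi is not None or self.roi_border_px > 0:
            roi = np.ones_like(vmap.response, dtype=bool) if self.roi is None \
                else np.asarray(self.roi, dtype=bool)
            if self.roi_border_px > 0:
                b = self.roi_border_px
                border = np.zeros_like(roi)
                border[b:-b, b:-b] = True
                roi = roi & border
            vmap = VesselnessMap(np.where(roi, vmap.response, 0.0),
                                 vmap.scales_mm)
        mask = segment_mask(vmap, self.low_threshold, self.high_threshold,
                            self.min_area_px)
        if self.refine:
            mask = refine_mask(np.asarray(s.image, dtype=float), mask,
                               min_area_px=self.min_area_px)
        return mask


def label_vessels(mask: VesselMask | np.ndarray) -> list:
    """Split a binary mask into vessel instances by 8-connectivity.

    Thin vessels drawn at arbitrary angles fragment under 4-connectivity,
    so diagonal touching counts as connected.  Instances are ordered by
    first raster-scan appearance (top-left first); an empty mask yields
    an empty list.
    """
    m = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask, bool)
    labels = cc_label(m, connectivity=2)
    out = []
    for lab in range(1, labels.max() + 1):
        pix = np.column_stack(np.nonzero(labels == lab))
        out.append(VesselInstance(id=lab, pixels=pix))
    return out


def evaluate_segmentation(predicted: VesselMask | np.ndarray,
                          truth: VesselMask | np.ndarray) -> SegEvalResult:
    """Exact pixel confusion counts with accuracy and Dice."""
    p = predicted.mask if isinstance(predicted, VesselMask) \
        else np.asarray(predicted, bool)
    t = truth.mask if isinstance(truth, VesselMask) else np.asarray(truth, bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return SegEvalResult(tp=tp, fp=fp, fn=fn, tn=tn)


def _apportion(n_items: int, ratio: tuple) -> list:
    """Largest-remainder apportionment of n_items by the ratio parts."""
    total = sum(ratio)
    quotas = [n_items * r / total for r in ratio]
    sizes = [int(np.floor(q)) for q in quotas]
    remainder = n_items - sum(sizes)
    order = np.argsort([-(q - s) for q, s in zip(quotas, sizes)],
                       kind="stable")
    for i in range(remainder):
        sizes[order[i]] += 1
    return sizes


def split_dataset(n_items: int, ratio: tuple, seed: int,
                  k_folds: int | None = None):
    """Random disjoint index splits by ratio (e.g. 5:2:2).

    Returns a tuple of index arrays covering ``range(n_items)``; sizes by
    largest-remainder apportionment (900 at 5:2:2 gives 500/200/200).
    With ``k_folds`` set, returns a list of ``k_folds`` such partitions,
    each reshuffled with a distinct seed derived from ``seed``.
    """
    if any(r <= 0 for r in ratio):
        raise ValueError("ratio parts must be positive")
    if n_items < len(ratio):
        raise ValueError(f"cannot split {n_items} items into "
                         f"{len(ratio)} non-empty parts")
    if any(s == 0 for s in _apportion(n_items, ratio)):
        raise ValueError(f"ratio {ratio} leaves an empty part at "
                         f"n_items={n_items}")
    if k_folds is not None:
        if k_folds < 1:
            raise ValueError("k_folds must be >= 1")
        seeds = np.random.SeedSequence(seed).spawn(k_folds)
        return [_one_split(n_items, ratio, s) for s in seeds]
    return _one_split(n_items, ratio, np.random.SeedSequence(seed))


def _one_split(n_items, ratio, seed_seq):
    rng = np.random.default_rng(seed_seq)
    perm = rng.permutation(n_items)
    sizes = _apportion(n_items, ratio)
    parts, start = [], 0
    for s in sizes:
        parts.append(np.sort(perm[start:start + s]))
        start += s
    return tuple(parts)
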