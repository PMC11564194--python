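"""Slab MinIP reconstruction, display windowing, and analysis-slice selection.

A minimum intensity projection (MinIP) over a thick slab accentuates dark
veins on SWI: each output pixel is the minimum over every acquired slice
whose center falls inside the slab.  Two slab presets are common for this
kind of study: thick overlapping slabs (20 mm every 1 mm) used to build
analysis stacks, and the scanner's clinical 12 mm reconstruction; both are
plain parameter choices here, nothing is hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Volume",
    "MinipSlice",
    "GeometryError",
    "slab_minip",
    "apply_window",
    "window_slice",
    "select_analysis_slices",
    "DATASET_SLAB_MM",
    "CLINICAL_SLAB_MM",
    "DEFAULT_WINDOW",
]

#: slab (thickness_mm, spacing_mm) used to build overlapping analysis stacks
DATASET_SLAB_MM = (20.0, 1.0)
#: scanner-side clinical MinIP reconstruction thickness, mm
CLINICAL_SLAB_MM = 12.0
#: display (window_width, window_level) under which DMVs are read
DEFAULT_WINDOW = (240.0, 200.0)


class GeometryError(ValueError):
    """Slab geometry incompatible with the volume extent."""


@dataclass
class Volume:
    """3D intensity volume in (z, y, x) order with per-axis spacing in mm.

    The z spacing is the slice-center distance, i.e. slice thickness plus
    inter-slice gap (e.g. 1.5 mm + 0.3 mm = 1.8 mm).
    """

    data: np.ndarray
    spacing_mm: tuple  # (dz, dy, dx)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D (z, y, x)")
        if self.data.shape[0] < 2:
            raise ValueError("Volume needs at least 2 slices")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive values")

    @property
    def z_extent_mm(self) -> float:
        """Distance between first and last slice centers."""
        return (self.data.shape[0] - 1) * self.spacing_mm[0]

    def slice_positions_mm(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.spacing_mm[0]


@dataclass
class MinipSlice:
    """One reconstructed MinIP slice with its slab provenance."""

    image: np.ndarray
    spacing_mm: tuple  # in-plane (dy, dx)
    slab_center_mm: float
    slab_thickness_mm: float
    window_applied: bool = False
    midline_column: int | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("MinipSlice image must be 2D")
        if self.slab_thickness_mm <= 0:
            raise ValueError("slab_thickness_mm must be positive")

    @property
    def midline(self) -> int:
        if self.midline_column is not None:
            return int(self.midline_column)
        return int(self.image.shape[1] // 2)


def slab_members(positions_mm: np.ndarray, center_mm: float,
                 thickness_mm: float, tol: float = 1e-9) -> np.ndarray:
    """Indices of slices whose center lies in the slab.

    Membership is the half-open test ``-t/2 <= z - c < t/2``: the slice
    sitting exactly on the inferior slab face is included, the superior
    one is not, so abutting slabs never double-count a boundary slice.
    """
    rel = positions_mm - center_mm
    return np.nonzero((rel >= -thickness_mm / 2 - tol)
                      & (rel < thickness_mm / 2 - tol))[0]


def slab_centers(z_extent_mm: float, thickness_mm: float,
                 spacing_mm: float, tol: float = 1e-9) -> np.ndarray:
    """Slab center positions, every ``spacing_mm``, each slab fully inside
    ``[0, z_extent_mm]``."""
    if thickness_mm > z_extent_mm + tol:
        raise GeometryError(
            f"slab thickness {thickness_mm} mm exceeds the volume z extent "
            f"{z_extent_mm} mm; no full slab fits")
    first = thickness_mm / 2.0
    last = z_extent_mm - thickness_mm / 2.0
    n = int(np.floor((last - first) / spacing_mm + tol)) + 1
    return first + spacing_mm * np.arange(n)


def slab_minip(volume: Volume, slab_thickness_mm: float,
               slab_spacing_mm: float) -> list[MinipSlice]:
    """Reconstruct an ordered stack of slab MinIP slices.

    Slab centers are placed every ``slab_spacing_mm`` along z such that
    each slab lies fully inside the volume; each output pixel is the
    minimum over the slab's member slices.  Raises :class:`GeometryError`
    when the slab is thicker than the volume (never a silent single-slab
    fallback).
    """
    if slab_thickness_mm <= 0 or slab_spacing_mm <= 0:
        raise ValueError("slab thickness and spacing must be positive")
    if slab_thickness_mm < volume.spacing_mm[0]:
        raise ValueError(
            f"slab thickness {slab_thickness_mm} mm is below the slice "
            f"spacing {volume.spacing_mm[0]} mm")
    positions = volume.slice_positions_mm()
    centers = slab_centers(volume.z_extent_mm, slab_thickness_mm,
                           slab_spacing_mm)
    out = []
    for c in centers:
        members = slab_members(positions, c, slab_thickness_mm)
        img = volume.data[members].min(axis=0)
        out.append(MinipSlice(image=img,
                              spacing_mm=tuple(volume.spacing_mm[1:]),
                              slab_center_mm=float(c),
                              slab_thickness_mm=float(slab_thickness_mm)))
    return out


def apply_window(image: np.ndarray, window_width: float = DEFAULT_WINDOW[0],
                 window_level: float = DEFAULT_WINDOW[1]) -> np.ndarray:
    """Linear window/level display mapping to 8 bit.

    Maps ``[level - width/2, level + width/2]`` onto ``[0, 255]``, clips
    outside, and rounds half away from zero (so the window level itself,
    127.5 before rounding, maps to 128).
    """
    if window_width <= 0:
        raise ValueError("window_width must be positive")
    image = np.asarray(image, dtype=float)
    bad = np.count_nonzero(~np.isfinite(image))
    if bad:
        raise ValueError(f"image contains {bad} non-finite pixels")
    lo = window_level - window_width / 2.0
    scaled = np.clip((image - lo) / window_width * 255.0, 0.0, 255.0)
    return np.floor(scaled + 0.5).astype(np.uint8)


def window_slice(s: MinipSlice, window_width: float = DEFAULT_WINDOW[0],
                 window_level: float = DEFAULT_WINDOW[1]) -> MinipSlice:
    """Windowed copy of a slice; refuses to window twice."""
    if s.window_applied:
        raise ValueError("slice is already windowed; re-windowing an 8-bit "
                         "display image would distort intensities")
    return replace(s, image=apply_window(s.image, window_width, window_level),
                   window_applied=True)


def select_analysis_slices(stack: list, reference_index: int,
                           superior: str = "increasing") -> list:
    """Pick the six analysis slices around a reference slice.

    The reference is the slice showing the corpus callosum body
    horizontally (user-supplied); the selection takes the three slices
    superior and two inferior to it, six in total, returned in inferior ->
    superior order.  ``superior`` declares which index direction is
    superior ("increasing" or "decreasing") since stacking order varies
    between exports.
    """
    if superior not in ("increasing", "decreasing"):
        raise ValueError("superior must be 'increasing' or 'decreasing'")
    n = len(stack)
    if not (0 <= reference_index < n):
        raise IndexError(f"reference_index {reference_index} outside "
                         f"stack of length {n}")
    up, down = 3, 2
    if superior == "increasing":
        lo, hi = reference_index - down, reference_index + up
    else:
        lo, hi = reference_index - up, reference_index + down
    if lo < 0 or hi >= n:
        raise IndexError(
            f"need indices {lo}..{hi} but stack supplies 0..{n - 1}; "
            "the reference slice is too close to the stack boundary")
    return [stack[i] for i in range(lo, hi + 1)]
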