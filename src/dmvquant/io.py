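"""Reading and writing volumes, MinIP slices, masks and ground truth.

Volumes come in as NIfTI (nibabel) or a DICOM series directory (pydicom,
slice spacing taken from the image positions).  MinIP slices and masks
round-trip as 16-bit / 8-bit PNG with a JSON sidecar carrying spacing and
slab provenance; phantom ground truth serializes to JSON plus a 16-bit
label PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pydicom

from .phantom import GroundTruth, VesselTruth
from .reconstruction import MinipSlice, Volume

__all__ = [
    "load_nifti_volume",
    "load_dicom_series",
    "save_minip_slice",
    "load_minip_slice",
    "save_mask",
    "load_mask",
    "save_label_mask",
    "load_label_mask",
    "save_ground_truth",
    "load_ground_truth",
]


def load_nifti_volume(path) -> Volume:
    """Load a NIfTI file as a (z, y, x) volume with mm spacing."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    return Volume(data=np.transpose(data, (2, 1, 0)),
                  spacing_mm=(float(zooms[2]), float(zooms[1]),
                              float(zooms[0])),
                  meta={"source": str(path), "format": "nifti"})


def load_dicom_series(directory) -> Volume:
    """Load a single-series DICOM directory, sorted along the slice axis.

    The z spacing is the median distance between consecutive image
    positions (falling back to SliceThickness + SpacingBetweenSlices when
    positions are missing), so it already includes any inter-slice gap.
    """
    paths = sorted(Path(directory).glob("*"))
    datasets = []
    for p in paths:
        if p.is_dir():
            continue
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue
    if len(datasets) < 2:
        raise ValueError(f"no DICOM series found in {directory}")

    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    zs = np.array([z_of(ds) for ds in datasets])
    dz = float(np.median(np.diff(zs)))
    if dz <= 0:
        first = datasets[0]
        dz = float(getattr(first, "SliceThickness", 1.0)) + \
            float(getattr(first, "SpacingBetweenSlices", 0.0))
    dy, dx = (float(v) for v in datasets[0].PixelSpacing)
    data = np.stack([ds.pixel_array.astype(float) for ds in datasets])
    return Volume(data=data, spacing_mm=(abs(dz), dy, dx),
                  meta={"source": str(directory), "format": "dicom"})


def save_minip_slice(s: MinipSlice, path) -> None:
    """Write a slice as 16-bit PNG (windowed slices as 8-bit) plus a
    ``.json`` sidecar with spacing and slab provenance."""
    path = Path(path)
    if s.window_applied:
        img = np.asarray(s.image, dtype=np.uint8)
    else:
        img = np.clip(np.rint(s.image), 0, 65535).astype(np.uint16)
    iio.imwrite(path, img)
    sidecar = {
        "spacing_mm": list(s.spacing_mm),
        "slab_center_mm": s.slab_center_mm,
        "slab_thickness_mm": s.slab_thickness_mm,
        "window_applied": bool(s.window_applied),
        "midline_column": s.midline_column,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_minip_slice(path) -> MinipSlice:
    path = Path(path)
    image = iio.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return MinipSlice(image=np.asarray(image),
                      spacing_mm=tuple(meta["spacing_mm"]),
                      slab_center_mm=meta["slab_center_mm"],
                      slab_thickness_mm=meta["slab_thickness_mm"],
                      window_applied=meta["window_applied"],
                      midline_column=meta["midline_column"])


def save_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def save_label_mask(labels: np.ndarray, path) -> None:
    labels = np.asarray(labels)
    if labels.max() > 65535:
        raise ValueError("more than 65535 labels do not fit a 16-bit PNG")
    iio.imwrite(Path(path), labels.astype(np.uint16))


def load_label_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.int32)


def save_ground_truth(truth: GroundTruth, json_path,
                      label_path=None) -> None:
    """Serialize phantom truth: centerlines/widths/tortuosities as JSON,
    the instance label mask as 16-bit PNG (2D only) next to it."""
    json_path = Path(json_path)
    payload = {"records": [
        {"id": r.id, "width_mm": r.width_mm, "tortuosity": r.tortuosity,
         "hemisphere": r.hemisphere,
         "centerline": np.asarray(r.centerline).tolist()}
        for r in truth.records]}
    json_path.write_text(json.dumps(payload))
    if label_path is not None:
        save_label_mask(truth.label_mask, label_path)


def load_ground_truth(json_path, label_path=None) -> GroundTruth:
    payload = json.loads(Path(json_path).read_text())
    records = [VesselTruth(id=r["id"],
                           centerline=np.asarray(r["centerline"], float),
                           width_mm=r["width_mm"],
                           tortuosity=r["tortuosity"],
                           hemisphere=r["hemisphere"])
               for r in payload["records"]]
    labels = load_label_mask(label_path) if label_path is not None \
        else np.zeros((0, 0), dtype=np.int32)
    return GroundTruth(records=records, label_mask=labels)
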