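"""End-to-end convenience: MinIP slice -> mask -> slice/subject summary."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .morphometry import SliceSummary, SubjectSummary, quantify_slice, \
    subject_summary
from .reconstruction import MinipSlice
from .segmentation import ClassicalSegmenter, VesselMask, label_vessels

__all__ = ["analyze_slice", "analyze_subject"]


def analyze_slice(s: MinipSlice, segmenter=None, min_length_px: float = 2.0,
                  convention: str = "radiological"
                  ) -> tuple[VesselMask, SliceSummary]:
    """Segment one slice and quantify its vessels.

    ``segmenter`` is any :class:`~dmvquant.segmentation.SegmenterContract`
    implementation; defaults to the classical tubularity detector.  The
    distance transform of the full slice mask is shared across instances
    so touching vessels measure consistently.
    """
    if segmenter is None:
        segmenter = ClassicalSegmenter()
    mask = segmenter(s)
    instances = label_vessels(mask)
    edt = ndimage.distance_transform_edt(mask.mask) if instances else None
    spacing = float(s.spacing_mm[0]) if np.ndim(s.spacing_mm) else float(s.spacing_mm)
    summary = quantify_slice(instances, spacing, s.midline,
                             min_length_px=min_length_px,
                             convention=convention, edt=edt)
    return mask, summary


def analyze_subject(slices: list, subject_id: str = "", segmenter=None,
                    min_length_px: float = 2.0,
                    weighting: str = "vessel") -> SubjectSummary:
    """Run :func:`analyze_slice` over a subject's analysis slices and
    aggregate (vessel-weighted by default)."""
    summaries = [analyze_slice(s, segmenter=segmenter,
                               min_length_px=min_length_px)[1]
                 for s in slices]
    return subject_summary(summaries, subject_id=subject_id,
                           weighting=weighting)
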