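"""Synthetic SWI-like phantoms and synthetic subject cohorts.

Deep medullary veins (DMVs) appear on SWI minimum-intensity-projection
slices as thin dark tubular structures on a brighter white-matter
background.  This module draws such vessels from smooth random curves with
known width and arc-to-chord tortuosity, so segmentation and morphometry
can be validated against exact ground truth, and samples subject cohorts
with group-structured DMV parameters so the statistics layer can be
exercised at realistic effect sizes.

Everything here is a pure function of ``(spec, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "PhantomSpec",
    "VesselTruth",
    "GroundTruth",
    "CohortSpec",
    "PhantomCapacityError",
    "generate_vessel_phantom",
    "generate_cohort",
    "COHORT_COLUMNS",
]


class PhantomCapacityError(RuntimeError):
    """Raised when the requested vessels cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic vessel image.

    Widths and tortuosities default to the population values observed for
    neonatal DMVs (width 0.73 +/- 0.07 mm clipped to the 0.49-0.93 mm
    range; tortuosity around 1.1).  ``tortuosity_level`` scales the
    perpendicular control-point offsets of the random spline and thereby
    the arc/chord ratio; 0 gives straight vessels.
    """

    image_shape: tuple = (256, 256)
    spacing_mm: float = 0.703  # 180 mm FOV / 256 matrix
    n_vessels: int = 12
    width_mean_mm: float = 0.73
    width_sd_mm: float = 0.07
    width_clip_mm: tuple = (0.49, 0.93)
    tortuosity_level: float = 0.5
    background_intensity: float = 200.0
    vessel_intensity: float = 60.0
    noise_sd: float = 10.0
    midline_column: int | None = None
    # ancillary geometry (not part of the core morphometric truth)
    length_range_mm: tuple = (6.0, 14.0)
    min_separation_mm: float = 1.0
    background_field_sd: float = 5.0
    max_retries: int = 200

    def __post_init__(self):
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        if not (self.width_clip_mm[0] < self.width_clip_mm[1]):
            raise ValueError("width_clip_mm must satisfy low < high")
        if not (self.vessel_intensity < self.background_intensity):
            raise ValueError("vessel_intensity must be darker than background")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.width_sd_mm < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.tortuosity_level < 0:
            raise ValueError("tortuosity_level must be >= 0")
        if len(self.image_shape) not in (2, 3):
            raise ValueError("image_shape must be 2D or 3D")

    @property
    def midline(self) -> int:
        if self.midline_column is not None:
            return int(self.midline_column)
        return int(self.image_shape[-1] // 2)


@dataclass
class VesselTruth:
    """Ground truth for one generated vessel."""

    id: int
    centerline: np.ndarray  # (n, ndim) float pixel coordinates
    width_mm: float
    tortuosity: float
    hemisphere: str  # subject side under radiological display


@dataclass
class GroundTruth:
    records: list
    label_mask: np.ndarray  # int, 0 = background, 1..n = vessel ids

    @property
    def mask(self) -> np.ndarray:
        return self.label_mask > 0

    def record(self, vessel_id: int) -> VesselTruth:
        return next(r for r in self.records if r.id == vessel_id)


# Inverse calibration of the rasterization radius against the medial
# width convention mean(2*EDT - 1) along the centerline: for each target
# width (px) the radius whose rasterized tube, averaged over the
# generator's own curve/orientation distribution, measures exactly that
# width.  Needed because pixel-center inclusion plus integer-quantized
# distance transforms bias the naive r = w/2 low by 0.5-1 px depending
# on orientation; the relation is monotone, so linear interpolation
# between calibrated knots inverts it.
_WIDTH_CAL_W_PX = np.array([
    1.50, 1.75, 2.00, 2.25, 2.50, 2.75, 3.00, 3.25, 3.50, 3.75,
    4.00, 4.25, 4.50, 4.75, 5.00, 5.25, 5.50, 5.75, 6.00])
_WIDTH_CAL_R_PX = np.array([
    1.184, 1.297, 1.387, 1.459, 1.528, 1.620, 1.753, 2.103, 2.237, 2.326,
    2.405, 2.491, 2.595, 2.744, 2.945, 3.112, 3.222, 3.333, 3.454])


def _radius_for_width(width_px: float) -> float:
    """Rasterization radius (px) whose drawn tube reads ``width_px``
    under the medial ``2*EDT - 1`` width convention (calibrated knots,
    linear inter-/extrapolation; floored so thin tubes stay
    8-connected)."""
    w = float(width_px)
    lo, hi = _WIDTH_CAL_W_PX[0], _WIDTH_CAL_W_PX[-1]
    if w <= lo:
        slope = (_WIDTH_CAL_R_PX[1] - _WIDTH_CAL_R_PX[0]) / \
            (_WIDTH_CAL_W_PX[1] - _WIDTH_CAL_W_PX[0])
        r = _WIDTH_CAL_R_PX[0] + slope * (w - lo)
    elif w >= hi:
        slope = (_WIDTH_CAL_R_PX[-1] - _WIDTH_CAL_R_PX[-2]) / \
            (_WIDTH_CAL_W_PX[-1] - _WIDTH_CAL_W_PX[-2])
        r = _WIDTH_CAL_R_PX[-1] + slope * (w - hi)
    else:
        r = float(np.interp(w, _WIDTH_CAL_W_PX, _WIDTH_CAL_R_PX))
    return max(r, 0.75)


def _polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _bezier(p0, c1, c2, p1, n):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * c1
            + 3 * (1 - t) * t ** 2 * c2 + t ** 3 * p1)


def _sample_curve(rng, spec: PhantomSpec) -> tuple[np.ndarray, float]:
    """Random cubic Bezier polyline in pixel coordinates, with its true
    arc/chord tortuosity."""
    ndim = len(spec.image_shape)
    shape = np.asarray(spec.image_shape, dtype=float)
    length_px = rng.uniform(*spec.length_range_mm) / spec.spacing_mm
    length_px = min(length_px, 0.8 * float(shape.min()))

    # orientation: roughly along the row axis (veins run radially toward
    # the ventricles; a dominant direction also packs better)
    theta = rng.uniform(-np.pi / 6, np.pi / 6)
    direction = np.zeros(ndim)
    direction[-2] = math.cos(theta)
    direction[-1] = math.sin(theta)
    if ndim == 3:
        tilt = rng.uniform(-0.25, 0.25)
        direction[0] = tilt
        direction /= np.linalg.norm(direction)

    margin = 3.0 + length_px * 0.25
    lo = np.full(ndim, margin)
    hi = shape - 1 - margin
    if np.any(hi <= lo):
        raise PhantomCapacityError(
            f"image shape {spec.image_shape} too small for vessels of "
            f"length {spec.length_range_mm} mm at {spec.spacing_mm} mm/px")
    for _ in range(64):
        p0 = rng.uniform(lo, hi)
        p1 = p0 + direction * length_px
        if np.all(p1 >= 1.0) and np.all(p1 <= shape - 2):
            break
    else:
        raise PhantomCapacityError("could not place a vessel chord inside the image")

    # perpendicular unit vector (in-plane)
    normal = np.zeros(ndim)
    normal[-2], normal[-1] = -direction[-1], direction[-2]
    amp = spec.tortuosity_level * length_px
    h1 = rng.uniform(-amp, amp)
    h2 = rng.uniform(-amp, amp)
    c1 = p0 + direction * length_px / 3.0 + normal * h1
    c2 = p0 + direction * 2.0 * length_px / 3.0 + normal * h2
    n_samples = max(64, int(4 * length_px))
    curve = _bezier(p0, c1, c2, p1, n_samples)
    arc = _polyline_length(curve)
    chord = float(np.linalg.norm(p1 - p0))
    return curve, arc / chord


def _rasterize_curve(curve: np.ndarray, radius_px: float, shape: tuple,
                     halo_px: float):
    """Pixels within ``radius_px`` of the densely resampled curve.

    Returns (vessel_index_tuple, halo_index_tuple); the halo is the same
    test at ``radius_px + halo_px`` and is used for overlap rejection.
    """
    # resample to ~0.1 px steps so point-set distance ~ curve distance
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_dense = max(int(s[-1] / 0.1), 2)
    s_new = np.linspace(0.0, s[-1], n_dense)
    dense = np.column_stack([np.interp(s_new, s, curve[:, d])
                             for d in range(curve.shape[1])])
    tree = cKDTree(dense)
    r_out = radius_px + halo_px
    lo = np.maximum(np.floor(dense.min(axis=0) - r_out - 1), 0).astype(int)
    hi = np.minimum(np.ceil(dense.max(axis=0) + r_out + 1),
                    np.asarray(shape) - 1).astype(int)
    grids = np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)],
                        indexing="ij")
    pts = np.column_stack([g.ravel() for g in grids]).astype(float)
    dist, _ = tree.query(pts, workers=1)
    inside = dist <= radius_px
    halo = dist <= r_out
    idx_in = tuple(pts[inside, d].astype(int) for d in range(pts.shape[1]))
    idx_halo = tuple(pts[halo, d].astype(int) for d in range(pts.shape[1]))
    return idx_in, idx_halo


def _hemisphere(centerline: np.ndarray, midline: int) -> str:
    col = float(centerline[:, -1].mean())
    if col < midline:
        return "right"  # image-left = subject-right (radiological display)
    if col > midline:
        return "left"
    return "midline"


def generate_vessel_phantom(spec: PhantomSpec, seed: int):
    """Generate one synthetic slice (or volume) and its ground truth.

    Returns ``(image, truth)`` where ``image`` is a float array of
    ``spec.image_shape`` and ``truth`` records every vessel's centerline,
    width (mm) and arc/chord tortuosity, plus an instance label mask.
    Vessels never overlap (surfaces are kept ``min_separation_mm`` apart),
    so instance counts have unambiguous truth.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in spec.image_shape)
    label_mask = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    sep_px = spec.min_separation_mm / spec.spacing_mm
    records: list[VesselTruth] = []

    for vid in range(1, spec.n_vessels + 1):
        placed = False
        for _ in range(spec.max_retries):
            curve, tort = _sample_curve(rng, spec)
            width = float(rng.normal(spec.width_mean_mm, spec.width_sd_mm)) \
                if spec.width_sd_mm > 0 else spec.width_mean_mm
            width = float(np.clip(width, *spec.width_clip_mm))
            radius = _radius_for_width(width / spec.spacing_mm)
            idx_in, idx_halo = _rasterize_curve(curve, radius, shape, sep_px)
            if len(idx_in[0]) == 0:
                continue
            if occupied[idx_halo].any():
                continue
            label_mask[idx_in] = vid
            occupied[idx_halo] = True
            records.append(VesselTruth(
                id=vid, centerline=curve, width_mm=width,
                tortuosity=tort, hemisphere=_hemisphere(curve, spec.midline)))
            placed = True
            break
        if not placed:
            raise PhantomCapacityError(
                f"could not place vessel {vid}/{spec.n_vessels} after "
                f"{spec.max_retries} attempts; reduce n_vessels or "
                f"min_separation_mm, or enlarge the image")

    image = np.full(shape, spec.background_intensity, dtype=float)
    if spec.background_field_sd > 0:
        field = rng.standard_normal(shape)
        field = ndimage.gaussian_filter(field, sigma=min(shape) / 8.0)
        sd = field.std()
        if sd > 0:
            image += field / sd * spec.background_field_sd
    image[label_mask > 0] = spec.vessel_intensity
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=shape)
    return image, GroundTruth(records=records, label_mask=label_mask)


# ---------------------------------------------------------------------------
# cohort simulation

COHORT_COLUMNS = {
    "subject_id": "unique subject identifier",
    "sex": "male | female",
    "term": "term | preterm (gestational age >= 37 weeks or not)",
    "delivery": "vaginal | cesarean",
    "risk_group": "high | low (hypoxic-ischemic risk factors present or not)",
    "nich": "yes | no, any neonatal intracranial haemorrhage",
    "pvh_ivh": "yes | no, periventricular-intraventricular haemorrhage",
    "icech": "yes | no, intracranial extracerebral haemorrhage",
    "dmv_count": "mean number of DMVs per bilateral slice",
    "dmv_width_mm": "mean DMV width, mm",
    "dmv_curvature": "mean DMV arc/chord tortuosity (dimensionless)",
    "tsv_right_mm": "max diameter of right thalamostriate vein, mm (NaN = not seen)",
    "tsv_left_mm": "max diameter of left thalamostriate vein, mm (NaN = not seen)",
    "acv_right_mm": "max diameter of right anterior caudate vein, mm (NaN = not seen)",
    "acv_left_mm": "max diameter of left anterior caudate vein, mm (NaN = not seen)",
}

# cohort composition of the neonatal study population this generator
# emulates: 317 subjects, 64.98% term, 78.55% high risk, 52.7% male
_DEFAULT_FRACTIONS = {
    "sex_male": 167 / 317,
    "term": 206 / 317,
    "vaginal": 0.55,
    "high_risk": 249 / 317,
    "nich": 0.35,
    "pvh_ivh": 0.10,
    "icech": 0.25,
}

# group-specific DMV outcome distributions, keyed by the stratifying
# factor (term status): term neonates show more, wider, slightly more
# tortuous DMVs than preterm
_DEFAULT_OUTCOMES = {
    "term": {"dmv_count": (13.23, 5.52), "dmv_width_mm": (0.74, 0.07),
             "dmv_curvature": (1.10, 0.06)},
    "preterm": {"dmv_count": (11.04, 4.43), "dmv_width_mm": (0.70, 0.07),
                "dmv_curvature": (1.09, 0.07)},
}

_DEFAULT_DRAINAGE = {
    "tsv_right_mm": (1.59, 0.35),
    "tsv_left_mm": (1.63, 0.38),
    "acv_right_mm": (1.23, 0.19),
    "acv_left_mm": (1.23, 0.21),
}

# latent correlations tying drainage-vein calibre to the DMV bed it
# drains: (with count, with width)
_DEFAULT_DRAINAGE_CORR = {
    "tsv_right_mm": (0.25, 0.21),
    "tsv_left_mm": (0.28, 0.26),
    "acv_right_mm": (0.21, 0.11),
    "acv_left_mm": (0.23, 0.10),
}

_DEFAULT_DETECTION = {
    "tsv_right_mm": 310 / 317,
    "tsv_left_mm": 311 / 317,
    "acv_right_mm": 307 / 317,
    "acv_left_mm": 307 / 317,
}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a synthetic subject cohort.

    ``outcome_params`` maps each level of ``stratify_by`` to
    ``{outcome: (mean, sd)}``; all other covariates are sampled
    independently of the outcomes, so comparisons across them are null.
    ``drainage_corr`` gives, per drainage vein, the latent normal
    correlation with DMV count and width.  With ``quota`` set, factor
    level counts are exact (largest-remainder rounding of the fractions)
    instead of binomial.
    """

    n_subjects: int = 317
    fractions: dict = field(default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    stratify_by: str = "term"
    outcome_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_OUTCOMES.items()})
    drainage_params: dict = field(default_factory=lambda: dict(_DEFAULT_DRAINAGE))
    drainage_corr: dict = field(default_factory=lambda: dict(_DEFAULT_DRAINAGE_CORR))
    detection_rates: dict = field(default_factory=lambda: dict(_DEFAULT_DETECTION))
    count_clip: tuple = (1, 31)
    quota: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name, frac in {**self.fractions, **self.detection_rates}.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction {name}={frac} outside [0, 1]")
        for level, params in self.outcome_params.items():
            for outcome, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(
                        f"sd for {outcome} in level {level} must be >= 0")
        for _, (_, sd) in self.drainage_params.items():
            if sd < 0:
                raise ValueError("drainage sds must be >= 0")


def _sample_binary(rng, n, frac, quota):
    if quota:
        k = int(round(frac * n))
        flags = np.zeros(n, dtype=bool)
        flags[:k] = True
        rng.shuffle(flags)
        return flags
    return rng.random(n) < frac


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Sample a subject table with the structure of a neonatal SWI cohort.

    Deterministic in ``(spec, seed)``; ``seed`` defaults to ``spec.seed``.
    Undetected drainage veins are NaN, never zero.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    male = _sample_binary(rng, n, spec.fractions["sex_male"], spec.quota)
    term = _sample_binary(rng, n, spec.fractions["term"], spec.quota)
    vaginal = _sample_binary(rng, n, spec.fractions["vaginal"], spec.quota)
    high = _sample_binary(rng, n, spec.fractions["high_risk"], spec.quota)
    nich = _sample_binary(rng, n, spec.fractions["nich"], spec.quota)
    pvh = _sample_binary(rng, n, spec.fractions["pvh_ivh"], spec.quota)
    icech = _sample_binary(rng, n, spec.fractions["icech"], spec.quota)

    strata = {"term": np.where(term, "term", "preterm"),
              "sex": np.where(male, "male", "female"),
              "delivery": np.where(vaginal, "vaginal", "cesarean"),
              "risk_group": np.where(high, "high", "low"),
              "nich": np.where(nich, "yes", "no"),
              "pvh_ivh": np.where(pvh, "yes", "no"),
              "icech": np.where(icech, "yes", "no")}
    if spec.stratify_by not in strata:
        raise ValueError(f"unknown stratify_by factor {spec.stratify_by!r}")
    level = strata[spec.stratify_by]

    outcomes = sorted({o for params in spec.outcome_params.values()
                       for o in params})
    z = {o: rng.standard_normal(n) for o in outcomes}
    data = {}
    for o in outcomes:
        vals = np.empty(n)
        for lev, params in spec.outcome_params.items():
            if o not in params:
                raise ValueError(f"outcome {o} missing for level {lev}")
            mu, sd = params[o]
            sel = level == lev
            vals[sel] = mu + sd * z[o][sel]
        data[o] = vals
    if "dmv_count" in data:
        data["dmv_count"] = np.clip(np.rint(data["dmv_count"]),
                                    *spec.count_clip).astype(int)
    if "dmv_curvature" in data:
        data["dmv_curvature"] = np.maximum(data["dmv_curvature"], 1.0)

    zc = z.get("dmv_count", rng.standard_normal(n))
    zw = z.get("dmv_width_mm", rng.standard_normal(n))
    for vein, (mu, sd) in spec.drainage_params.items():
        r_c, r_w = spec.drainage_corr.get(vein, (0.0, 0.0))
        resid = max(1.0 - r_c ** 2 - r_w ** 2, 0.0) ** 0.5
        zv = r_c * zc + r_w * zw + resid * rng.standard_normal(n)
        vals = mu + sd * zv
        detected = rng.random(n) < spec.detection_rates.get(vein, 1.0)
        vals[~detected] = np.nan
        data[vein] = vals

    table = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(1, n + 1)],
        "sex": strata["sex"],
        "term": strata["term"],
        "delivery": strata["delivery"],
        "risk_group": strata["risk_group"],
        "nich": strata["nich"],
        "pvh_ivh": strata["pvh_ivh"],
        "icech": strata["icech"],
        **{k: data[k] for k in sorted(data)},
    })
    return table
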