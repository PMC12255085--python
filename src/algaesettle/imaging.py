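"""Hemocytometer micrograph segmentation and cell counting.

Lugol-fixed microalgal cells appear as dark round/ellipsoidal objects on the
bright ruled background of the counting chamber.  The pipeline is classical:
grayscale -> Gaussian blur -> global threshold -> hole fill / speck removal ->
Euclidean distance transform -> marker detection -> marker-controlled
watershed, which splits touching cells along the valleys of the distance map.
Counts convert to cells/mL through the chamber volume and dilution factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color, feature, filters, measure, morphology, segmentation

from .rsm import ValidationResult, linreg_validation

__all__ = [
    "SegmentParams",
    "SegmentedObject",
    "SegmentationResult",
    "segment_cells",
    "count_cells",
    "validate_counts",
]


@dataclass
class SegmentParams:
    """Tunable knobs of the watershed counting pipeline.

    ``min_marker_separation=None`` auto-estimates half the median equivalent
    diameter of a first-pass connected-component labeling, small enough to
    seed both halves of a moderately fused cell pair; area gates default to
    ``expected_diameter_px`` +/- 60% when that is given, else a permissive
    [20, inf) range.  ``min_contrast`` (normalized 0-1 units) rejects Otsu
    splits of essentially flat fields, e.g. a cell-free chamber where the
    faint rulings would otherwise threshold as objects.
    """

    blur_sigma: float = 1.5
    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: float | None = None
    min_marker_separation: float | None = None
    min_area: float | None = None
    max_area: float | None = None
    expected_diameter_px: float | None = None
    polarity: str = "dark_on_light"
    min_contrast: float = 0.15

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold requested but fixed_threshold is None")
        if self.polarity not in ("dark_on_light", "light_on_dark"):
            raise ValueError("polarity must be 'dark_on_light' or 'light_on_dark'")

    def area_gates(self) -> tuple[float, float]:
        if self.min_area is not None or self.max_area is not None:
            lo = self.min_area if self.min_area is not None else 0.0
            hi = self.max_area if self.max_area is not None else np.inf
        elif self.expected_diameter_px is not None:
            d = self.expected_diameter_px
            lo = np.pi * (0.4 * d / 2) ** 2
            hi = np.pi * (1.6 * d / 2) ** 2
        else:
            lo, hi = 20.0, np.inf
        if not lo < hi:
            raise ValueError(f"min_area ({lo}) must be < max_area ({hi})")
        return float(lo), float(hi)


@dataclass
class SegmentedObject:
    id: int
    centroid: tuple[float, float]  # (row, col)
    area_px2: float
    equivalent_diameter_px: float
    eccentricity: float


@dataclass
class SegmentationResult:
    labels: np.ndarray
    objects: list[SegmentedObject] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.objects)


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if img.ndim == 3:
        img = color.rgb2gray(img)
    elif img.ndim != 2:
        raise ValueError(f"expected a 2-D or RGB image, got shape {img.shape}")
    img = img.astype(float)
    if img.max() > 1.0:
        img = img / (65535.0 if img.max() > 255 else 255.0)
    return img


def segment_cells(image: np.ndarray, params: SegmentParams | None = None) -> SegmentationResult:
    """Detect and label individual cells; touching cells are split by watershed.

    Objects outside the area gates or touching the image border are discarded
    and labels relabeled contiguously from 1.  An image that thresholds to
    all-background yields an empty result, not an error.
    """
    params = params or SegmentParams()
    gray = _to_gray(image)
    if params.blur_sigma > 0:
        gray = filters.gaussian(gray, sigma=params.blur_sigma, preserve_range=True)
    if params.threshold_method == "otsu":
        if np.ptp(gray) == 0:
            return SegmentationResult(np.zeros(gray.shape, dtype=np.int32))
        t = filters.threshold_otsu(gray)
    else:
        t = params.fixed_threshold
        if np.asarray(image).max() > 1.0 and t > 1.0:
            t = t / (65535.0 if np.asarray(image).max() > 255 else 255.0)
    fg = gray < t if params.polarity == "dark_on_light" else gray > t
    if not fg.any():
        return SegmentationResult(np.zeros(gray.shape, dtype=np.int32))
    if params.threshold_method == "otsu" and fg.any() and (~fg).any():
        contrast = abs(float(gray[~fg].mean()) - float(gray[fg].mean()))
        if contrast < params.min_contrast:
            return SegmentationResult(np.zeros(gray.shape, dtype=np.int32))

    fg = ndi.binary_fill_holes(fg)
    min_area, max_area = params.area_gates()
    speck = max(1, int(min_area / 4))
    fg = morphology.remove_small_objects(fg, max_size=speck - 1) if speck > 1 else fg
    if not fg.any():
        return SegmentationResult(np.zeros(gray.shape, dtype=np.int32))

    sep = params.min_marker_separation
    if sep is None:
        if params.expected_diameter_px is not None:
            med = params.expected_diameter_px
        else:
            first_pass = measure.label(fg)
            diams = [
                r.equivalent_diameter_area
                for r in measure.regionprops(first_pass)
                if min_area <= r.area <= max_area
            ]
            med = np.median(diams) if diams else np.sqrt(4 * min_area / np.pi)
        sep = 0.5 * float(med)
    sep = max(1, int(round(sep)))

    dist = ndi.distance_transform_edt(fg)
    peaks = feature.peak_local_max(
        dist, min_distance=sep, labels=fg, exclude_border=False
    )
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndi.label(fg)
    labels = segmentation.watershed(-dist, markers, mask=fg)

    # drop border-touching and out-of-gate objects, then relabel 1..n
    keep = np.zeros(labels.max() + 1, dtype=bool)
    h, w = labels.shape
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    for r in measure.regionprops(labels):
        keep[r.label] = min_area <= r.area <= max_area and r.label not in border
    labels = np.where(keep[labels], labels, 0)
    labels, _, _ = segmentation.relabel_sequential(labels)
    labels = labels.astype(np.int32)

    objects = [
        SegmentedObject(
            id=r.label,
            centroid=tuple(map(float, r.centroid)),
            area_px2=float(r.area),
            equivalent_diameter_px=float(r.equivalent_diameter_area),
            eccentricity=float(r.eccentricity),
        )
        for r in measure.regionprops(labels)
    ]
    return SegmentationResult(labels=labels, objects=objects)


def count_cells(
    seg: SegmentationResult | int, chamber_volume_nl: float, dilution: float = 1.0
) -> float:
    """Convert a field count to cells per millilitre.

    1 nL = 1e-6 mL, so ``cells/mL = count / (volume_nl * 1e-6) * dilution``.
    """
    if chamber_volume_nl <= 0:
        raise ValueError("chamber volume must be > 0")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    count = seg.count if isinstance(seg, SegmentationResult) else int(seg)
    return count / (chamber_volume_nl * 1e-6) * dilution


@dataclass
class CountValidation:
    result: ValidationResult
    residuals: np.ndarray
    normal_quantiles: np.ndarray  # theoretical quantiles paired with sorted residuals
    sorted_residuals: np.ndarray


def validate_counts(pairs) -> CountValidation:
    """Manual-vs-automated count agreement: regression + plot-ready series."""
    res = linreg_validation(pairs)
    r = res.residuals
    order = np.argsort(r)
    n = len(r)
    from scipy import stats as _s

    q = _s.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    return CountValidation(
        result=res, residuals=r, normal_quantiles=q, sorted_residuals=r[order]
    )
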