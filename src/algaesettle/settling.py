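"""Non-invasive settling-curve quantification from time-lapse photographs.

A settling culture column photographed against constant illumination loses
green-channel intensity in a fixed region of interest (ROI) as cells leave
suspension.  Sedimentation efficiency at time t is the relative intensity
drop, SE_GCI = 100*(I0 - I_t)/I0, the photographic analogue of the classical
optical-density definition SE_OD = 100*(A0 - A_t)/A0 measured at 440 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rsm import ValidationResult, linreg_validation

__all__ = [
    "ROI",
    "IntensitySeries",
    "EfficiencySeries",
    "ODPair",
    "extract_green_series",
    "se_gci",
    "se_od",
    "settling_time",
    "crossval_gci_od",
]


@dataclass(frozen=True)
class ROI:
    """Rectangular pixel region; origin top-left, half-open intervals."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width)

    def check_within(self, shape: tuple[int, int]) -> None:
        h, w = shape[:2]
        if self.y0 + self.height > h or self.x0 + self.width > w:
            raise ValueError(f"ROI {self} exceeds frame bounds {(h, w)}")


@dataclass
class IntensitySeries:
    times: np.ndarray  # hours, strictly increasing
    values: np.ndarray  # mean green intensity per frame
    mode: str = "raw_green"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def initial(self) -> float:
        return float(self.values[0])


@dataclass
class EfficiencySeries:
    times: np.ndarray
    efficiency: np.ndarray  # percent
    final_efficiency: float
    settling_time_h: float | None = None
    has_negative: bool = False


@dataclass(frozen=True)
class ODPair:
    """Absorbance at 440 nm before/after settling, with dilution factors."""

    a0: float
    at: float
    dilution_0: float = 1.0
    dilution_t: float = 1.0

    def __post_init__(self) -> None:
        if self.dilution_0 < 1 or self.dilution_t < 1:
            raise ValueError("dilution factors must be >= 1")


def extract_green_series(frames, roi: ROI, mode: str = "raw_green") -> IntensitySeries:
    """Mean ROI green intensity per frame.

    ``frames`` is a sequence of ``(time_h, image)``.  ``mode='chromaticity'``
    uses G/(R+G+B), which is invariant to global brightness scaling and thus
    robust to illumination drift; ``raw_green`` is the plain green channel.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame list")
    if mode not in ("raw_green", "chromaticity"):
        raise ValueError("mode must be 'raw_green' or 'chromaticity'")
    times = np.array([t for t, _ in frames], float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    shape0 = np.asarray(frames[0][1]).shape
    values = []
    for t, img in frames:
        img = np.asarray(img)
        if img.shape != shape0:
            raise ValueError("all frames must share the same dimensions")
        roi.check_within(img.shape)
        ys, xs = roi.slices()
        patch = img[ys, xs].astype(float)
        if img.ndim == 2:
            warnings.warn(
                "grayscale frames: using the single channel as green intensity",
                stacklevel=2,
            )
            values.append(patch.mean())
        elif mode == "raw_green":
            values.append(patch[..., 1].mean())
        else:
            total = patch[..., :3].sum(axis=-1)
            chrom = np.divide(
                patch[..., 1], total, out=np.zeros_like(total), where=total > 0
            )
            values.append(chrom.mean())
    return IntensitySeries(times=times, values=np.array(values), mode=mode)


def se_gci(series: IntensitySeries) -> EfficiencySeries:
    """Efficiency curve 100*(I0 - I_t)/I0 from a column intensity series.

    Negative efficiencies (intensity increase over the start frame) are kept
    and flagged rather than clipped — they usually indicate illumination drift.
    """
    i0 = series.initial
    if i0 <= 0:
        raise ZeroDivisionError("initial intensity I0 must be > 0")
    eff = 100.0 * (i0 - series.values) / i0
    neg = bool(np.any(eff < -1e-12))
    if neg:
        warnings.warn("efficiency series contains negative values", stacklevel=2)
    return EfficiencySeries(
        times=series.times.copy(),
        efficiency=eff,
        final_efficiency=float(eff[-1]),
        has_negative=neg,
    )


def se_od(pair: ODPair) -> float:
    """Optical-density settling efficiency on dilution-corrected absorbances."""
    a0 = pair.a0 * pair.dilution_0
    at = pair.at * pair.dilution_t
    if a0 <= 0:
        raise ValueError("initial absorbance (dilution-corrected) must be > 0")
    return 100.0 * (a0 - at) / a0


def settling_time(
    series: EfficiencySeries, plateau_frac: float = 0.95, smooth_window: int = 3
) -> float | None:
    """Time to reach ``plateau_frac`` of the plateau efficiency.

    The efficiency curve is smoothed with a centred moving average; the plateau
    is the mean of the last ``smooth_window`` smoothed points, and the returned
    time linearly interpolates the first upward crossing of
    ``plateau_frac * plateau``.  Returns None (with a warning) when the curve
    never crosses — e.g. a culture that does not settle.
    """
    t = np.asarray(series.times, float)
    e = np.asarray(series.efficiency, float)
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if not 0 < plateau_frac <= 1:
        raise ValueError("plateau_frac must be in (0, 1]")
    w = max(1, int(smooth_window))
    kernel = np.ones(w) / w
    # centred moving average with edge shrinkage
    pad = w // 2
    padded = np.pad(e, pad, mode="edge")
    smooth = np.convolve(padded, kernel, mode="valid")[: len(e)]
    plateau = float(np.mean(smooth[-w:]))
    if plateau <= 0:
        warnings.warn("no settling detected (non-positive plateau)", stacklevel=2)
        return None
    target = plateau_frac * plateau
    above = smooth >= target
    if not above.any():
        warnings.warn("efficiency never reaches the plateau threshold", stacklevel=2)
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    e0, e1 = smooth[i - 1], smooth[i]
    if e1 == e0:
        return float(t[i])
    frac = (target - e0) / (e1 - e0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def crossval_gci_od(pairs) -> ValidationResult:
    """Agreement between photographic and optical-density efficiencies."""
    return linreg_validation(pairs)
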