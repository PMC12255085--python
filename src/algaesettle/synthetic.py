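"""Seeded synthetic-data generators with exported ground truth.

Every input class the analysis modules consume can be simulated here:
hemocytometer micrographs (dark ellipsoidal cells on a bright ruled
background), settling time-lapse frames (exponentially decaying green column
intensity over a static backdrop), designed-experiment response tables
(quadratic surface + block offsets + Gaussian noise), and piecewise
exponential growth series with lognormal count noise.  Identical parameters
and seed give bit-identical output, and each generator returns the ground
truth needed for recovery testing.

Settling is modelled as a single-exponential decay toward a plateau,
I(t) = I_inf + (I0 - I_inf) exp(-k t) — a deliberately simple stand-in for
monotone settling curves, not a hindered-settling model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import draw as _draw

from .rsm import DesignTable, Factor
from .settling import ROI

__all__ = [
    "GroundTruth",
    "gen_hemocytometer",
    "gen_settling_frames",
    "gen_response_surface",
    "gen_growth",
]


@dataclass
class GroundTruth:
    kind: str
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            return v

        return {"kind": self.kind, **{k: conv(v) for k, v in self.params.items()}}


class PackingError(RuntimeError):
    """Could not place the requested number of cells within the attempt budget."""


def gen_hemocytometer(
    n_cells: int = 50,
    radius_px: tuple[float, float] = (6.0, 10.0),
    ellipticity: tuple[float, float] = (1.0, 1.3),
    overlap_fraction: float = 0.0,
    noise_sd: float = 3.0,
    size: tuple[int, int] = (512, 512),
    grid_spacing: int = 64,
    seed: int = 0,
    max_attempts: int = 100_000,
) -> tuple[np.ndarray, GroundTruth]:
    """Render an 8-bit hemocytometer field with known cell positions.

    ``overlap_fraction`` caps how deeply two cells may interpenetrate: centre
    distance must exceed ``(1 - overlap_fraction) * (r_i + r_j)``.  At 0 cells
    are fully disjoint (with a safety margin so watershed recovery is exact).
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    h, w = size
    img = np.full((h, w), 220.0)
    for r in range(0, h, grid_spacing):  # faint chamber rulings
        img[r, :] = 200.0
    for c in range(0, w, grid_spacing):
        img[:, c] = 200.0

    centers: list[tuple[float, float]] = []
    axes: list[tuple[float, float]] = []
    angles: list[float] = []
    margin_pad = 2.0 if overlap_fraction == 0 else 0.0
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise PackingError(
                f"placed only {len(centers)}/{n_cells} cells in {max_attempts} attempts"
            )
        a = rng.uniform(*radius_px)  # major semi-axis
        ell = rng.uniform(*ellipticity)
        b = a / ell
        margin = a + 3
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        ok = True
        for (py, px), (pa, _pb) in zip(centers, axes):
            dist = np.hypot(cy - py, cx - px)
            if dist < (1 - overlap_fraction) * (a + pa) + margin_pad:
                ok = False
                break
        if not ok:
            continue
        theta = rng.uniform(0, np.pi)
        rr, cc = _draw.ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        img[rr, cc] = 60.0
        centers.append((cy, cx))
        axes.append((a, b))
        angles.append(theta)

    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    truth = GroundTruth(
        kind="hemocytometer",
        params={
            "count": len(centers),
            "centers": np.array(centers).reshape(-1, 2),
            "semi_axes": np.array(axes).reshape(-1, 2),
            "angles": np.array(angles),
            "seed": seed,
        },
    )
    return img, truth


def gen_settling_frames(
    i0: float = 180.0,
    i_inf: float = 20.0,
    k_per_h: float = 0.1,
    times=None,
    noise_sd: float = 2.0,
    frame_size: tuple[int, int] = (160, 100),
    roi: ROI | None = None,
    seed: int = 0,
) -> tuple[list[tuple[float, np.ndarray]], GroundTruth]:
    """Render RGB time-lapse frames of a settling column.

    The ROI's green channel follows I(t) = i_inf + (i0 - i_inf) exp(-k t) plus
    pixel noise; everything outside the ROI is a static textured background.
    Ground truth carries the closed-form efficiency curve
    100*(i0 - I(t))/i0.
    """
    if times is None:
        times = np.arange(0.0, 72.1, 2.0)
    times = np.asarray(times, float)
    if not (i0 > i_inf >= 0):
        raise ValueError("need i0 > i_inf >= 0")
    if k_per_h <= 0:
        raise ValueError("decay rate k must be > 0")
    h, w = frame_size
    if roi is None:
        roi = ROI(x0=w // 4, y0=h // 4, width=w // 2, height=h // 2)
    roi.check_within((h, w))
    rng = np.random.default_rng(seed)
    background = rng.uniform(90, 110, size=(h, w, 3))

    levels = i_inf + (i0 - i_inf) * np.exp(-k_per_h * times)
    if np.any(levels > 255):
        warnings.warn("intensity exceeds 8-bit range; clipping", stacklevel=2)
    frames = []
    ys, xs = roi.slices()
    for t, lvl in zip(times, levels):
        frame = background.copy()
        # red/blue through the column stay fixed; only the green level tracks
        # the suspended biomass, so chromaticity falls as cells settle
        frame[ys, xs, 0] = 60.0
        frame[ys, xs, 1] = lvl
        frame[ys, xs, 2] = 70.0
        if noise_sd > 0:
            frame = frame + rng.normal(0, noise_sd, size=frame.shape)
        frames.append((float(t), np.clip(frame, 0, 255).astype(np.uint8)))

    eff = 100.0 * (i0 - levels) / i0
    truth = GroundTruth(
        kind="settling_frames",
        params={
            "i0": i0,
            "i_inf": i_inf,
            "k_per_h": k_per_h,
            "times_h": times,
            "true_intensity": levels,
            "true_efficiency_pct": eff,
            "final_efficiency_pct": float(eff[-1]),
            "roi": {"x0": roi.x0, "y0": roi.y0, "width": roi.width, "height": roi.height},
            "seed": seed,
        },
    )
    return frames, truth


def evaluate_surface(coefficients: dict[str, float], factors, point) -> float:
    """Evaluate a term-keyed quadratic surface at an actual-units point."""
    names = [f.name if isinstance(f, Factor) else str(f) for f in factors]
    pt = np.asarray(point, float)
    val = coefficients["b0"]
    for nm, v in zip(names, pt):
        val += coefficients.get(nm, 0.0) * v
        val += coefficients.get(f"{nm}^2", 0.0) * v**2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            val += coefficients.get(f"{names[i]}*{names[j]}", 0.0) * pt[i] * pt[j]
    return float(val)


def gen_response_surface(
    design: DesignTable,
    coefficients: dict[str, float],
    response_name: str = "response",
    block_offsets: dict[int, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DesignTable, GroundTruth]:
    """Fill a design's response column from a known quadratic surface.

    response = surface(actual point) + block offset + N(0, noise_sd).
    """
    rng = np.random.default_rng(seed)
    pts = design.actual()
    y = np.array([evaluate_surface(coefficients, design.factors, p) for p in pts])
    if block_offsets:
        y = y + np.array([block_offsets.get(int(b), 0.0) for b in design.blocks()])
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, size=len(y))
    data = design.data.copy()
    data[response_name] = y
    truth = GroundTruth(
        kind="response_surface",
        params={
            "coefficients": dict(coefficients),
            "block_offsets": dict(block_offsets or {}),
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
    return DesignTable(design.factors, data), truth


def gen_growth(
    n0: float,
    mu_by_interval,
    times,
    noise_cv: float = 0.0,
    seed: int = 0,
):
    """Piecewise-exponential cell counts with lognormal multiplicative noise.

    ``mu_by_interval[i]`` applies between ``times[i]`` and ``times[i+1]``.
    ``noise_cv`` is the coefficient of variation of the multiplicative noise.
    """
    from .growth import GrowthSeries

    times = np.asarray(times, float)
    mus = np.asarray(mu_by_interval, float)
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if len(mus) != len(times) - 1:
        raise ValueError("need one growth rate per consecutive time interval")
    clean = [n0]
    for mu, dt in zip(mus, np.diff(times)):
        clean.append(clean[-1] * np.exp(mu * dt))
    clean = np.array(clean)
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1 + noise_cv**2))
        noisy = clean * np.exp(rng.normal(-sigma**2 / 2, sigma, size=len(clean)))
    else:
        noisy = clean.copy()
    series = GrowthSeries(times=times, cells_per_ml=noisy)
    truth = GroundTruth(
        kind="growth",
        params={
            "n0": n0,
            "mu_by_interval": mus,
            "times_d": times,
            "clean_counts": clean,
            "noise_cv": noise_cv,
            "seed": seed,
        },
    )
    return series, truth
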