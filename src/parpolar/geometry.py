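"""Embryo contour geometry: curvature profiles and attachment-rate fields.

The zygote's 1D cortex is parameterised by arc length around a closed convex
contour.  Two shapes are provided: the free embryo (ellipse, ~50 x 30 um) and
the embryo squeezed into an equilateral triangular micro-chamber (rounded
triangle, side ~40 um).  Curvature enters the dynamics only through the
posterior attachment rate, which is enhanced in proportion to the excess
curvature over the flattest ("central") part of the cortex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter1d


@dataclass(frozen=True)
class CurvatureProfile:
    """Signed curvature sampled uniformly in arc length on a closed contour.

    ``positions`` are the arc-length coordinates of the grid points (first
    point at 0, uniform spacing, the contour closes after the last point);
    ``baseline`` is the reference curvature of the central cortex against
    which excess curvature is measured; ``peaks`` are the arc positions of
    the high-curvature features (ellipse poles or triangle corners).
    """

    positions: np.ndarray
    curvature: np.ndarray
    baseline: float
    peaks: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        curv = np.asarray(self.curvature, dtype=float)
        if pos.ndim != 1 or pos.shape != curv.shape:
            raise ValueError("positions and curvature must be matching 1D arrays")
        if pos.size >= 2 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "curvature", curv)

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def circumference(self) -> float:
        return float(self.positions.size * self.spacing)

    @property
    def total_turning(self) -> float:
        """Integral of curvature around the contour (2*pi for a convex loop)."""
        return float(np.sum(self.curvature) * self.spacing)


def ellipse_curvature(semi_major: float, semi_minor: float, n: int) -> CurvatureProfile:
    """Arc-length-parameterised curvature of an ellipse.

    Position 0 is one pole (anterior by convention); the opposite pole sits
    at half the perimeter.  Curvature maxima ``a/b^2`` occur at the poles,
    minima ``b/a^2`` at the lateral midpoints; the lateral minimum is the
    baseline.
    """
    if not (semi_major >= semi_minor > 0):
        raise ValueError("require semi_major >= semi_minor > 0")
    if n < 16:
        raise ValueError("grid size n must be at least 16")
    a, b = float(semi_major), float(semi_minor)
    m = max(4096, 16 * n)
    theta = np.linspace(0.0, 2.0 * np.pi, m + 1)
    w = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
    s = np.concatenate(([0.0], cumulative_trapezoid(w, theta)))
    perimeter = s[-1]
    s_grid = np.arange(n) * (perimeter / n)
    theta_grid = np.interp(s_grid, s, theta)
    w_grid = np.sqrt((a * np.sin(theta_grid)) ** 2 + (b * np.cos(theta_grid)) ** 2)
    curv = a * b / w_grid**3
    # enforce the ellipse's exact mirror symmetry about the pole axis, which
    # arc-length interpolation would otherwise break at the 1e-6 level
    idx = (-np.arange(n)) % n
    curv = 0.5 * (curv + curv[idx])
    return CurvatureProfile(
        positions=s_grid,
        curvature=curv,
        baseline=b / a**2,
        peaks=(0.0, perimeter / 2.0),
    )


def triangle_curvature(
    side: float,
    corner_radius: float | tuple[float, float, float],
    n: int,
) -> CurvatureProfile:
    """Curvature of a rounded equilateral triangle (micro-chamber contour).

    Curvature is ``1/r_i`` on the three corner arcs (each subtending 2*pi/3)
    and 0 on the flat sides; the baseline is 0.  ``corner_radius`` may be a
    single value (three identical corners) or one radius per corner, which
    models an embryo conforming more tightly to one corner than the others.
    Position 0 is the start of the first corner arc.
    """
    if n < 16:
        raise ValueError("grid size n must be at least 16")
    radii = np.broadcast_to(np.asarray(corner_radius, dtype=float), (3,)).copy()
    if np.any(radii <= 0):
        raise ValueError("corner radii must be positive")
    limit = side / (2.0 * np.sqrt(3.0))
    if np.any(radii >= limit):
        raise ValueError(
            f"corner radius must be < side/(2*sqrt(3)) = {limit:.4g} for side {side}"
        )
    # tangent length removed from each side end: r*sqrt(3) (interior angle 60 deg)
    flats = [side - np.sqrt(3.0) * (radii[i] + radii[(i + 1) % 3]) for i in range(3)]
    if min(flats) <= 0:
        raise ValueError("corner rounding leaves no flat side; reduce radii")
    arcs = [r * 2.0 * np.pi / 3.0 for r in radii]
    # segment sequence: arc0, flat0, arc1, flat1, arc2, flat2
    seg_len = [arcs[0], flats[0], arcs[1], flats[1], arcs[2], flats[2]]
    seg_curv = [1.0 / radii[0], 0.0, 1.0 / radii[1], 0.0, 1.0 / radii[2], 0.0]
    bounds = np.concatenate(([0.0], np.cumsum(seg_len)))
    perimeter = bounds[-1]
    s_grid = np.arange(n) * (perimeter / n)
    idx = np.searchsorted(bounds, s_grid, side="right") - 1
    idx = np.clip(idx, 0, 5)
    curv = np.asarray(seg_curv, dtype=float)[idx]
    peaks = tuple((bounds[2 * i] + bounds[2 * i + 1]) / 2.0 for i in range(3))
    # baseline is the flat-side curvature (0); in the degenerate inscribed-
    # circle limit no flat point remains on the grid and the baseline rises
    # to the uniform corner curvature, so the excess vanishes
    return CurvatureProfile(
        positions=s_grid, curvature=curv, baseline=float(curv.min()), peaks=peaks
    )


def attachment_profile(
    curv: CurvatureProfile,
    kon_P: float,
    alpha: float,
    smooth_sigma: float = 0.0,
    weights: np.ndarray | None = None,
    boost_cap: float | None = None,
) -> np.ndarray:
    """Spatially varying posterior attachment rate from excess curvature.

    ``kon_P(x) = kon_P + alpha * max(curvature(x) - baseline, 0)``, with the
    clamped excess optionally multiplied by per-position ``weights`` and
    smoothed circularly with a Gaussian of width ``smooth_sigma`` (um),
    representing the finite length scale over which the membrane senses
    curvature.  With the default ``smooth_sigma = 0`` the rule is the strict
    clamped-linear form.

    ``boost_cap``, if given, saturates the relative enhancement smoothly at
    ``boost_cap`` times the base rate (``delta = kon_P * cap *
    (1 - exp(-alpha*excess/(kon_P*cap)))``), modelling the finite density of
    curvature-sensitive binding sites.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    excess = np.clip(curv.curvature - curv.baseline, 0.0, None)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != excess.shape:
            raise ValueError("weights must match the curvature grid")
        excess = excess * weights
    if smooth_sigma > 0:
        excess = gaussian_filter1d(excess, smooth_sigma / curv.spacing, mode="wrap")
    delta = alpha * excess
    if boost_cap is not None:
        if boost_cap <= 0:
            raise ValueError("boost_cap must be positive")
        scale = kon_P * boost_cap
        delta = scale * (1.0 - np.exp(-delta / scale))
    return kon_P + delta


def circular_distance(x: np.ndarray | float, center: float, circumference: float):
    """Signed shortest distance from ``x`` to ``center`` on a ring."""
    return (np.asarray(x) - center + circumference / 2.0) % circumference - circumference / 2.0
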