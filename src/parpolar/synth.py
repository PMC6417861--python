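"""Synthetic fixtures: noisy intensity profiles and advected speckle movies.

These generators stand in for the raw imaging data the measurement operators
were designed for: straightened-circumference fluorescence traces with one
or two posterior-protein domains of known position and extent, and cortical
speckle movies (myosin puncta) advected by a prescribed velocity field.
Every output is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import circular_distance


@dataclass(frozen=True)
class FlowSpec:
    """Prescribed in-plane velocity field for speckle movies (px/frame).

    kinds: ``uniform`` (constant (ux, uy)), ``sinusoidal``
    (``ux = amplitude * sin(2*pi*x/wavelength)``, uy = 0), and
    ``bipolar_inward`` (``ux = amplitude * sin(2*pi*x/W)``: flow from both
    lateral edges toward the image centre, antisymmetric about the midline).
    """

    kind: str = "uniform"
    ux: float = 0.0
    uy: float = 0.0
    amplitude: float = 2.0
    wavelength: float | None = None

    def displacement(self, x: np.ndarray, y: np.ndarray, width: int):
        """Per-position (dx, dy) displacement in pixels per frame."""
        if self.kind == "uniform":
            return (np.full_like(x, self.ux, dtype=float),
                    np.full_like(y, self.uy, dtype=float))
        if self.kind == "sinusoidal":
            lam = self.wavelength or width
            return (self.amplitude * np.sin(2.0 * np.pi * x / lam),
                    np.zeros_like(y, dtype=float))
        if self.kind == "bipolar_inward":
            return (self.amplitude * np.sin(2.0 * np.pi * x / width),
                    np.zeros_like(y, dtype=float))
        raise ValueError(f"unknown flow kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic fixture (profile and/or movie)."""

    seed: int = 0
    # --- profile geometry ---
    circumference: float = 127.5  # um
    n: int = 512
    domains: tuple[tuple[float, float, float], ...] = ()  # (center, width, amp)
    shoulder: float = 2.0  # um, half-cosine edge width
    noise: float = 0.0  # additive Gaussian sigma, fluorescence units
    background: float = 0.0
    # --- movie ---
    flow: FlowSpec = field(default_factory=FlowSpec)
    image_shape: tuple[int, int] = (128, 128)  # (height, width) px
    speckle_density: float = 0.02  # particles per px^2
    psf_sigma: float = 1.2  # px
    photon_noise: float = 0.0  # additive Gaussian sigma on images

    def __post_init__(self) -> None:
        if self.noise < 0 or self.photon_noise < 0:
            raise ValueError("noise levels must be nonnegative")
        if sum(w for _, w, _ in self.domains) >= self.circumference:
            raise ValueError("domain widths must sum to less than the circumference")


@dataclass
class ProfileTruth:
    """Ground truth accompanying a synthetic intensity trace."""

    domains: list[tuple[float, float, float]]  # (center, width FWHM, amplitude)
    circumference: float
    noise: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _domain_shape(dist: np.ndarray, width: float, shoulder: float) -> np.ndarray:
    """Smooth top-hat: plateau with half-cosine shoulders, FWHM = width."""
    half = width / 2.0
    s = max(shoulder, 1e-9)
    inner = half - s / 2.0
    outer = half + s / 2.0
    d = np.abs(dist)
    out = np.zeros_like(d)
    out[d <= inner] = 1.0
    ramp = (d > inner) & (d < outer)
    out[ramp] = 0.5 * (1.0 + np.cos(np.pi * (d[ramp] - inner) / s))
    return out


def make_profile(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, ProfileTruth]:
    """Synthesize a periodic intensity trace with known domain structure.

    Returns ``(positions, trace, truth)``; the trace is the sum of smooth
    top-hat domains (FWHM equal to each requested width) on a constant
    background plus seeded Gaussian noise.
    """
    x = np.arange(spec.n) * (spec.circumference / spec.n)
    trace = np.full(spec.n, float(spec.background))
    for center, width, amp in spec.domains:
        d = circular_distance(x, center, spec.circumference)
        trace = trace + amp * _domain_shape(d, width, spec.shoulder)
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        trace = trace + spec.noise * rng.standard_normal(spec.n)
    truth = ProfileTruth(
        domains=[tuple(map(float, d)) for d in spec.domains],
        circumference=spec.circumference,
        noise=spec.noise,
        seed=spec.seed,
    )
    return x, trace, truth


def make_speckle_movie(
    spec: SyntheticSpec, n_frames: int
) -> tuple[np.ndarray, np.ndarray]:
    """Render a speckle movie advected by the prescribed flow.

    Particles are placed uniformly at random (seeded), rendered as Gaussian
    spots of width ``psf_sigma`` and advected each frame by the flow
    evaluated at the particle position, with periodic wrap-around.  Returns
    ``(frames, truth)`` where ``frames`` has shape ``(n_frames, H, W)`` and
    ``truth[k]`` is the (2, H, W) array of (dx, dy) pixel displacements from
    frame ``k`` to ``k+1`` evaluated on the pixel grid.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if spec.speckle_density <= 0:
        raise ValueError("particle density must be positive")
    H, W = spec.image_shape
    rng = np.random.default_rng(spec.seed)
    n_part = max(1, int(round(spec.speckle_density * H * W)))
    px = rng.uniform(0, W, n_part)
    py = rng.uniform(0, H, n_part)

    frames = np.empty((n_frames, H, W), dtype=float)
    for k in range(n_frames):
        frames[k] = _render(px, py, H, W, spec.psf_sigma)
        dx, dy = spec.flow.displacement(px, py, W)
        px = (px + dx) % W
        py = (py + dy) % H
    if spec.photon_noise > 0:
        frames = frames + spec.photon_noise * rng.standard_normal(frames.shape)

    yy, xx = np.mgrid[0:H, 0:W]
    ux, uy = spec.flow.displacement(
        xx.astype(float).ravel(), yy.astype(float).ravel(), W
    )
    field_step = np.stack([ux.reshape(H, W), uy.reshape(H, W)])
    truth = np.repeat(field_step[None, ...], max(n_frames - 1, 1), axis=0)
    return frames, truth


def _render(px: np.ndarray, py: np.ndarray, H: int, W: int, sigma: float) -> np.ndarray:
    """Sum of Gaussian spots with periodic wrap, via local stamps."""
    img = np.zeros((H, W), dtype=float)
    r = max(2, int(np.ceil(3.0 * sigma)))
    offs = np.arange(-r, r + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    for x0, y0 in zip(px, py):
        ix, iy = int(np.floor(x0)), int(np.floor(y0))
        ddx = ix + ox - x0
        ddy = iy + oy - y0
        stamp = np.exp(-(ddx * ddx + ddy * ddy) / (2.0 * sigma * sigma))
        rows = (iy + oy) % H
        cols = (ix + ox) % W
        np.add.at(img, (rows, cols), stamp)
    return img
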