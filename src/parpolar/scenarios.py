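"""Simulation scenarios: geometry, trigger and initial-condition recipes.

A scenario bundles (i) the embryo contour (ellipse or rounded triangle),
(ii) the symmetry-breaking trigger, if any -- a local transient reduction of
cortical active stress standing in for the centrosome-derived cue -- and
(iii) optional seeded noise on the initial membrane fields.

Orientation convention: arc position 0 is the anterior pole and
circumference/2 the posterior pole (ellipse); for the triangle, position 0
lies in the first corner arc and the scenario's "favored" corner is the one
the embryo conforms to most tightly (highest corner weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    CurvatureProfile,
    attachment_profile,
    circular_distance,
    ellipse_curvature,
    triangle_curvature,
)
from .model import CortexState, homogeneous_steady_state
from .params import ModelParams

#: width (um) of the Gaussian weighting window applied around each triangle
#: corner when corner weights are unequal
_CORNER_WEIGHT_SIGMA = 6.0

#: default length scale (um) over which the membrane senses contour curvature
DEFAULT_ATTACHMENT_SIGMA = 4.5

#: saturation of the curvature-dependent attachment enhancement (relative to
#: the base rate): the pool of curvature-sensitive binding sites is finite
DEFAULT_BOOST_CAP = 8.0


@dataclass(frozen=True)
class Trigger:
    """Transient local weakening of the cortex.

    ``pi0(x, t) = pi_active_0 * (1 - depth * g(x) * exp(-t/decay_time))``
    with ``g`` a unit-amplitude Gaussian of width ``sigma`` (um) centred at
    arc position ``center`` (um).
    """

    center: float
    sigma: float = 15.0
    depth: float = 0.8
    decay_time: float = 300.0


@dataclass(frozen=True)
class GeometrySpec:
    shape: str = "ellipse"  # 'ellipse' | 'triangle'
    semi_major: float = 25.0
    semi_minor: float = 15.0
    side: float = 40.0
    corner_radius: float | tuple[float, float, float] = 5.0
    corner_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def curvature(self, n: int) -> CurvatureProfile:
        if self.shape == "ellipse":
            return ellipse_curvature(self.semi_major, self.semi_minor, n)
        if self.shape == "triangle":
            return triangle_curvature(self.side, self.corner_radius, n)
        raise ValueError(f"unknown geometry shape {self.shape!r}")

    def weight_profile(self, curv: CurvatureProfile) -> np.ndarray | None:
        """Per-position multiplier on excess curvature (triangle corners).

        Each grid point takes the weight of its nearest corner (the corner
        excess regions are disjoint, so this scales each corner's cue as a
        whole); smoothing in :func:`attachment_profile` rounds the seams.
        """
        if self.shape != "triangle" or all(w == 1.0 for w in self.corner_weights):
            return None
        L = curv.circumference
        dists = np.stack(
            [np.abs(circular_distance(curv.positions, c, L)) for c in curv.peaks]
        )
        nearest = np.argmin(dists, axis=0)
        return np.asarray(self.corner_weights, dtype=float)[nearest]


@dataclass(frozen=True)
class SimProblem:
    """Scenario resolved onto a concrete grid."""

    x: np.ndarray
    dx: float
    curvature: CurvatureProfile
    kon_P_profile: np.ndarray
    trigger_patch: np.ndarray | None
    trigger_decay: float
    scenario: "Scenario"

    def initial_state(
        self,
        params: ModelParams,
        bias: tuple[float, float, float] | None = None,
        rng: np.random.Generator | None = None,
    ) -> CortexState:
        """Uniform aPAR-dominant start, optionally biased or noisy.

        ``bias = (center, width, amplitude)`` adds a Gaussian P bump (in
        units of the reference P0) with a matching local reduction of A --
        used by the phase-diagram multistability panel.  Noise, if the
        scenario requests it, perturbs P with seeded Gaussian deviates.
        """
        p = params.with_scales()
        A0, P0m, _, _ = homogeneous_steady_state(p)
        A = np.full(self.x.size, A0)
        P = np.full(self.x.size, P0m)
        L = self.x.size * self.dx
        if bias is not None:
            center, width, amp = bias
            d = circular_distance(self.x, center, L)
            bump = np.exp(-(d * d) / (2.0 * width * width))
            P = P + amp * p.scales.P0 * bump
            A = A * (1.0 - 0.9 * bump)
        sc = self.scenario
        if sc.noise_amp > 0:
            gen = rng or np.random.default_rng(sc.noise_seed)
            P = np.clip(P + sc.noise_amp * p.scales.P0 * gen.standard_normal(P.size), 0, None)
        A_cyto = p.A_total - p.psi * float(np.mean(A))
        P_cyto = p.P_total - p.psi * float(np.mean(P))
        if A_cyto < 0 or P_cyto < 0:
            raise ValueError("initial bias/noise exhausts a cytoplasmic pool")
        return CortexState(
            x=self.x, A=A, P=P, v=np.zeros_like(A), A_cyto=A_cyto, P_cyto=P_cyto, t=0.0
        )


@dataclass(frozen=True)
class Scenario:
    name: str
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    trigger: Trigger | None = None
    attachment_sigma: float = DEFAULT_ATTACHMENT_SIGMA
    attachment_cap: float = DEFAULT_BOOST_CAP
    noise_amp: float = 0.0
    noise_seed: int | None = None

    def build(self, params: ModelParams, n: int) -> SimProblem:
        p = params.with_scales()
        curv = self.geometry.curvature(n)
        konP = attachment_profile(
            curv,
            p.kon_P,
            p.alpha,
            smooth_sigma=self.attachment_sigma,
            weights=self.geometry.weight_profile(curv),
            boost_cap=self.attachment_cap,
        )
        patch = None
        decay = 300.0
        if self.trigger is not None:
            trig = self.trigger
            d = circular_distance(curv.positions, trig.center, curv.circumference)
            patch = trig.depth * np.exp(-(d * d) / (2.0 * trig.sigma**2))
            decay = trig.decay_time
        return SimProblem(
            x=curv.positions,
            dx=curv.spacing,
            curvature=curv,
            kon_P_profile=konP,
            trigger_patch=patch,
            trigger_decay=decay,
            scenario=self,
        )

    def preferred_sites(self, params: ModelParams, n: int = 256) -> tuple[float, ...]:
        """Arc positions of the curvature peaks (candidate domain sites)."""
        return self.geometry.curvature(n).peaks


# ---------------------------------------------------------------------------
# canonical scenario builders

#: triangle corner weights for an embryo squeezed into the chamber: the
#: cortex engages the three corners to different degrees, so the effective
#: curvature cue is strongest in one corner (real embryos polarize in the
#: corner with the highest pre-break curvature)
DEFAULT_CORNER_WEIGHTS = (1.0, 0.15, 0.10)

_WT_DEPTH = 0.8


def _ellipse() -> GeometrySpec:
    return GeometrySpec(shape="ellipse")


def _triangle() -> GeometrySpec:
    return GeometrySpec(shape="triangle", corner_weights=DEFAULT_CORNER_WEIGHTS)


def _posterior_trigger(geom: GeometrySpec, depth: float = _WT_DEPTH) -> Trigger:
    curv = geom.curvature(256)
    center = curv.circumference / 2.0 if geom.shape == "ellipse" else curv.peaks[0]
    return Trigger(center=center, depth=depth)


def wild_type(geometry: str = "ellipse") -> Scenario:
    """Control embryo: centrosome-derived trigger at the posterior pole
    (or at the favored corner for the triangular chamber)."""
    geom = _ellipse() if geometry == "ellipse" else _triangle()
    return Scenario(
        name=f"wt-{geometry}", geometry=geom, trigger=_posterior_trigger(geom)
    )


def no_trigger(geometry: str = "ellipse") -> Scenario:
    """AIR-1-depleted embryo: no localized stress-reduction cue; symmetry is
    broken by curvature-dependent attachment alone."""
    geom = _ellipse() if geometry == "ellipse" else _triangle()
    return Scenario(name=f"no-trigger-{geometry}", geometry=geom, trigger=None)


def lateral_trigger() -> Scenario:
    """Control embryo with lateral sperm entry: trigger at a lateral site
    (quarter circumference from the anterior pole)."""
    geom = _ellipse()
    L = geom.curvature(256).circumference
    return Scenario(
        name="lateral", geometry=geom, trigger=Trigger(center=0.3 * L, depth=_WT_DEPTH)
    )


def weak_anterior(depth_fraction: float = 0.25) -> Scenario:
    """Meiosis-arrested, AIR-1-depleted embryo: weak trigger at the anterior
    pole with a fraction of the wild-type depth."""
    geom = _ellipse()
    return Scenario(
        name="weak-anterior",
        geometry=geom,
        trigger=Trigger(center=0.0, depth=depth_fraction * _WT_DEPTH),
    )


_BUILDERS = {
    "wt": wild_type,
    "no-trigger": no_trigger,
    "lateral": lateral_trigger,
    "weak-anterior": weak_anterior,
}


def make_scenario(name: str, geometry: str = "ellipse") -> Scenario:
    """Scenario factory used by the CLI (`wt`, `no-trigger`, `lateral`,
    `weak-anterior` crossed with geometry `ellipse`/`triangle`)."""
    if name not in _BUILDERS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_BUILDERS)}")
    if name in ("lateral", "weak-anterior"):
        if geometry != "ellipse":
            raise ValueError(f"scenario {name!r} is defined on the ellipse only")
        return _BUILDERS[name]()
    return _BUILDERS[name](geometry)
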