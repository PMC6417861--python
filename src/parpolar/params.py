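"""Physical parameters of the PAR polarity / active-cortex model.

The model couples two membrane species on a 1D periodic cortex (arc-length
coordinate ``x`` in micrometres, time in seconds):

* ``A`` -- anterior PAR complex (PAR-3/PAR-6/PKC-3), surface density (um^-2)
* ``P`` -- posterior PAR protein (PAR-2), surface density (um^-2)

each exchanging with a well-mixed cytoplasmic pool (volume concentration,
um^-3) and antagonising the other on the membrane, plus a cortical flow field
``v`` (um/s) obtained from an active-gel force balance in which the active
stress decreases with membrane-bound P.

Default kinetic rates follow the established mass-conserved PAR
reaction-diffusion framework for the C. elegans zygote (diffusivities,
attachment/detachment rates, mutual-antagonism coefficients and total protein
pools as measured for PAR-6 and PAR-2).  The mechanical constants enter only
through the hydrodynamic length ``sqrt(eta/gamma)`` and the ratio
``beta/gamma``; stresses are therefore expressed in units where ``gamma = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

#: dimensionless gain linking the ``alpha/l`` phase-diagram coordinate to the
#: dimensional curvature-attachment coupling (see ModelParams.with_nondim)
ALPHA_COUPLING = 2.0


@dataclass(frozen=True)
class NondimScales:
    """Reference scales used to express the two phase-diagram coordinates.

    Attributes
    ----------
    l : float
        Reference length (um).  Defined as the hydrodynamic length
        ``sqrt(eta/gamma)`` of the cortex, the scale over which flows respond
        to stress gradients.
    tau : float
        Reference time (s), the membrane residence time ``1/koff_P`` of the
        posterior species.
    rho : float
        Reference surface density (um^-2); equal to ``P0``.
    P0 : float
        Reference posterior concentration (um^-2): the uniform membrane
        density the posterior species would reach in the absence of
        antagonism, set by its attachment/detachment balance and pool size.
    """

    l: float
    tau: float
    rho: float
    P0: float

    def __post_init__(self) -> None:
        for name in ("l", "tau", "rho", "P0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"NondimScales.{name} must be strictly positive")


@dataclass(frozen=True)
class ModelParams:
    """All rate and mechanical constants of the coupled PAR/flow model.

    Units: lengths in um, times in s, membrane densities in um^-2,
    cytoplasmic concentrations in um^-3, stress in units where gamma = 1.

    ``alpha`` (um^2/s) is the curvature-dependent attachment gain: the local
    posterior attachment rate is ``kon_P + alpha * max(curvature - baseline,
    0)``.  ``beta`` is the active-stress reduction per unit of membrane-bound
    P.  Both are normally set through :meth:`with_nondim` from the
    dimensionless phase-diagram coordinates ``alpha/l`` and
    ``beta*tau/(rho*P0)``.
    """

    D_A: float = 0.28
    D_P: float = 0.15
    kon_A: float = 8.58e-3
    kon_P: float = 4.74e-2
    koff_A: float = 5.4e-3
    koff_P: float = 7.3e-3
    k_AP: float = 0.190
    k_PA: float = 3.25
    eta: float = 196.0
    gamma: float = 1.0
    beta: float = 0.0
    alpha: float = 0.0
    pi_active_0: float = 12.0
    pi_passive: float = 0.0
    A_total: float = 1.56
    P_total: float = 1.0
    psi: float = 0.174
    scales: NondimScales | None = None

    def __post_init__(self) -> None:
        nonneg = (
            "kon_A", "kon_P", "koff_A", "koff_P", "k_AP", "k_PA",
            "eta", "gamma", "beta", "alpha", "psi",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"ModelParams.{name} must be nonnegative")
        for name in ("D_A", "D_P", "A_total", "P_total"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ModelParams.{name} must be strictly positive")

    @property
    def hydrodynamic_length(self) -> float:
        """Length scale ``sqrt(eta/gamma)`` over which stress gradients act."""
        if self.gamma == 0:
            return math.inf
        return math.sqrt(self.eta / self.gamma)

    def with_scales(self) -> "ModelParams":
        """Return a copy whose :class:`NondimScales` are filled in.

        ``l = sqrt(eta/gamma)``, ``tau = 1/koff_P`` and ``rho = P0`` with
        ``P0`` the antagonism-free uniform posterior membrane density.
        """
        if self.scales is not None:
            return self
        P0 = self.kon_P * self.P_total / (self.koff_P + self.kon_P * self.psi)
        scales = NondimScales(
            l=self.hydrodynamic_length,
            tau=1.0 / self.koff_P,
            rho=P0,
            P0=P0,
        )
        return replace(self, scales=scales)

    def with_nondim(self, alpha_over_l: float, beta_scaled: float) -> "ModelParams":
        """Set dimensional ``alpha``/``beta`` from phase-diagram coordinates.

        The dimensional units of the two control axes are fixed model
        constants: ``alpha = (alpha/l) * ALPHA_COUPLING * l * kon_P`` (an
        attachment-rate gain per unit curvature) and
        ``beta = beta_scaled * gamma * D_P / (P0 * l)`` (an active-stress
        reduction per unit membrane density, calibrated so that coordinates
        of order 100 produce cortical flows of a few um/min, the magnitude
        quantified by PIV in the zygote).
        """
        if alpha_over_l < 0 or beta_scaled < 0:
            raise ValueError("nondimensional coordinates must be nonnegative")
        p = self.with_scales()
        s = p.scales
        return replace(
            p,
            alpha=alpha_over_l * ALPHA_COUPLING * s.l * p.kon_P,
            beta=beta_scaled * p.gamma * p.D_P / (s.P0 * s.l),
        )

    def nondim_coords(self) -> tuple[float, float]:
        """Current (alpha/l, beta_scaled) phase-diagram coordinates."""
        p = self.with_scales()
        s = p.scales
        return (
            p.alpha / (ALPHA_COUPLING * s.l * p.kon_P),
            p.beta * s.P0 * s.l / (p.gamma * p.D_P),
        )


def default_params() -> ModelParams:
    """Standard parameter set with reference scales resolved."""
    return ModelParams().with_scales()
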