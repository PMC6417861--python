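"""Reaction-diffusion-advection dynamics of the PAR system on an active cortex.

The membrane densities A(x,t), P(x,t) obey

    dA/dt = D_A d2A/dx2 - d(vA)/dx + kon_A*Acyto - koff_A*A - k_AP*P*A
    dP/dt = D_P d2P/dx2 - d(vP)/dx + kon_P(x)*Pcyto - koff_P*P - k_PA*A^2*P

on a periodic 1D domain (the cortex circumference), with well-mixed
cytoplasmic pools closed by strict mass conservation
(``A_total = A_cyto + psi * <A>``, angle brackets the spatial mean) and the
cortical flow v(x,t) set instantaneously by the over-damped active-gel force
balance

    gamma*v - eta d2v/dx2 = d(Pi_active)/dx,   Pi_active = pi0(x,t) - beta*P.

Flows run toward regions of higher active stress, i.e. away from membrane
regions rich in the posterior species (which lowers contractility) -- the
orientation observed for cortical flows in the zygote.  A "trigger"
(centrosome-derived local weakening of the cortex) enters as a Gaussian
reduction of ``pi0`` that decays exponentially in time.

Numerics: operator splitting per step -- conservative first-order upwind
advection, explicit (Patankar-type, positivity-preserving) reaction update,
and unconditionally stable implicit diffusion via FFT on the periodic grid;
the force balance is re-solved spectrally every step.  The integrator runs
batches of independent states simultaneously (used by the phase-diagram
sweep), each with its own adaptive time step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import fsolve

from .params import ModelParams


class NumericalError(RuntimeError):
    """Raised when the integration blows up (NaN or negative densities)."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class CortexState:
    """Instantaneous state of the 1D cortex."""

    x: np.ndarray
    A: np.ndarray
    P: np.ndarray
    v: np.ndarray
    A_cyto: float
    P_cyto: float
    t: float

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    def total_mass(self, params: ModelParams) -> tuple[float, float]:
        """Conserved totals (cytoplasmic + psi-scaled membrane mean)."""
        return (
            self.A_cyto + params.psi * float(np.mean(self.A)),
            self.P_cyto + params.psi * float(np.mean(self.P)),
        )


@dataclass
class Kymograph:
    """Space-time record of one quantity along the cortex."""

    values: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    quantity: str = "P"

    def __post_init__(self) -> None:
        if self.values.shape != (self.times.size, self.positions.size):
            raise ValueError("kymograph shape must be (len(times), len(positions))")


@dataclass
class SolverOptions:
    """Grid and integration controls.

    ``tol`` is the steady-state criterion on ``max|dP/dt| * tau / P0``;
    ``tail_frac`` is the final fraction of ``t_max`` that is time-averaged to
    classify runs that have not met ``tol`` (oscillatory regimes).
    """

    n: int = 256
    dt_max: float = 0.25
    cfl: float = 0.2
    rate_cap: float = 2.0
    t_max: float = 7200.0
    tol: float = 1e-6
    check_every: int = 200
    save_dt: float = 20.0
    min_time: float | None = None
    tail_frac: float = 0.1
    record: bool = True


@dataclass
class SteadyStateResult:
    state: CortexState
    kymograph: Kymograph | None
    converged: bool
    P_settled: np.ndarray | None = None  # tail-averaged P if not converged

    def classification_profile(self) -> np.ndarray:
        """P profile to use for domain counting (tail average if stalled)."""
        if self.converged or self.P_settled is None:
            return self.state.P
        return self.P_settled


# ---------------------------------------------------------------------------
# elementary operators


def homogeneous_steady_state(
    params: ModelParams, kon_P: float | None = None, branch: str = "anterior"
) -> tuple[float, float, float, float]:
    """Uniform fixed point (A, P, A_cyto, P_cyto) of the well-mixed system.

    ``branch='anterior'`` returns the aPAR-dominant state the cortex occupies
    before symmetry breaking; ``branch='posterior'`` the P-dominant state.
    """
    p = params
    konP = p.kon_P if kon_P is None else kon_P

    def eqs(y):
        A, P = y
        Ac = p.A_total - p.psi * A
        Pc = p.P_total - p.psi * P
        return (
            p.kon_A * Ac - A * (p.koff_A + p.k_AP * P),
            konP * Pc - P * (p.koff_P + p.k_PA * A * A),
        )

    if branch == "anterior":
        A0 = p.kon_A * p.A_total / (p.koff_A + p.kon_A * p.psi)
        guess = (A0, konP * p.P_total / (p.koff_P + p.k_PA * A0 * A0))
    elif branch == "posterior":
        P0 = konP * p.P_total / (p.koff_P + konP * p.psi)
        guess = (1e-3, P0)
    else:
        raise ValueError("branch must be 'anterior' or 'posterior'")
    sol, info, ier, msg = fsolve(eqs, guess, full_output=True)
    if ier != 1 or np.any(np.asarray(sol) < 0):
        raise RuntimeError(f"homogeneous steady state did not converge: {msg}")
    A, P = float(sol[0]), float(sol[1])
    return A, P, p.A_total - p.psi * A, p.P_total - p.psi * P


def solve_force_balance(
    P: np.ndarray,
    params: ModelParams,
    dx: float,
    pi_active0: np.ndarray | float | None = None,
    beta: np.ndarray | float | None = None,
) -> np.ndarray:
    """Cortical flow from the periodic force balance.

    Solves ``gamma*v - eta*v'' = d/dx(pi0 - beta*P + pi_passive)`` spectrally
    on the uniform periodic grid; supports batched input (last axis = space).
    The right-hand side is a pure gradient of a periodic stress, so its mean
    vanishes and a periodic solution exists; for ``gamma = 0`` the flow is
    fixed to zero mean.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[-1]
    if n < 8:
        raise ValueError("force balance needs a periodic grid of at least 8 points")
    if params.eta == 0 and params.gamma == 0:
        raise ValueError("singular force balance: eta and gamma are both zero")
    if not np.all(np.isfinite(P)):
        raise ValueError("P contains non-finite values")
    b = params.beta if beta is None else beta
    pi0 = params.pi_active_0 if pi_active0 is None else pi_active0
    Pi = pi0 - b * P + params.pi_passive
    Pi = np.broadcast_to(Pi, P.shape)
    k = 2.0 * np.pi * np.fft.rfftfreq(n, dx)
    denom = params.gamma + params.eta * k * k
    if params.gamma == 0:
        denom = denom.copy()
        denom[0] = 1.0  # k=0: gradient has zero mean, pick zero-mean flow
    vhat = 1j * k * np.fft.rfft(Pi, axis=-1) / denom
    if n % 2 == 0:
        vhat[..., -1] = 0.0  # Nyquist mode has no well-defined odd derivative
    return np.fft.irfft(vhat, n=n, axis=-1)


def reaction_terms(
    A: np.ndarray,
    P: np.ndarray,
    A_cyto: float | np.ndarray,
    P_cyto: float | np.ndarray,
    kon_P_profile: np.ndarray,
    params: ModelParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Local attachment/detachment/antagonism source terms.

    Every membrane gain is mirrored as a cytoplasmic loss scaled by ``psi``
    (and vice versa), so the reaction step conserves each species' total by
    construction.  Detached protein (including antagonism-induced removal)
    returns to the cytoplasm.
    """
    A = np.asarray(A, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(A < 0) or np.any(P < 0) or np.any(np.asarray(A_cyto) < 0) or np.any(
        np.asarray(P_cyto) < 0
    ):
        raise ValueError("negative concentrations are not admissible")
    p = params
    dA = p.kon_A * np.asarray(A_cyto) - p.koff_A * A - p.k_AP * P * A
    dP = kon_P_profile * np.asarray(P_cyto) - p.koff_P * P - p.k_PA * A * A * P
    dAc = -p.psi * np.mean(dA, axis=-1, keepdims=np.ndim(A_cyto) > 0)
    dPc = -p.psi * np.mean(dP, axis=-1, keepdims=np.ndim(P_cyto) > 0)
    return dA, dP, dAc, dPc


def _upwind_advection(C: np.ndarray, v: np.ndarray, dx: float) -> np.ndarray:
    """Conservative first-order upwind discretisation of -d(vC)/dx."""
    v_face = 0.5 * (v + np.roll(v, -1, axis=-1))
    flux = v_face * np.where(v_face > 0, C, np.roll(C, -1, axis=-1))
    return -(flux - np.roll(flux, 1, axis=-1)) / dx


# ---------------------------------------------------------------------------
# batched integrator


class CortexIntegrator:
    """Advances a batch of independent cortex states to steady state.

    All rows share the grid, the mechanical constants ``eta``/``gamma`` and
    the solver options; the attachment profile, ``beta`` and the trigger
    patch may differ per row.  Rows retire individually on convergence
    (``max|dP/dt| * tau / P0 < tol``) or at ``t_max``.
    """

    def __init__(
        self,
        params: ModelParams,
        dx: float,
        n: int,
        kon_P_profile: np.ndarray,
        *,
        beta: np.ndarray | float | None = None,
        trigger_patch: np.ndarray | None = None,
        trigger_decay: float = 300.0,
        options: SolverOptions | None = None,
    ) -> None:
        self.params = params.with_scales()
        self.dx = float(dx)
        self.n = int(n)
        self.opts = options or SolverOptions()
        self.konP = np.atleast_2d(np.asarray(kon_P_profile, dtype=float))
        self.beta = (
            np.full((self.konP.shape[0], 1), self.params.beta)
            if beta is None
            else np.atleast_2d(np.asarray(beta, dtype=float)).reshape(-1, 1)
        )
        self.patch = (
            None
            if trigger_patch is None
            else np.atleast_2d(np.asarray(trigger_patch, dtype=float))
        )
        self.trigger_decay = float(trigger_decay)
        k = 2.0 * np.pi * np.fft.rfftfreq(self.n, self.dx)
        self.k = k
        self.k2 = k * k
        self.fb_denom = self.params.gamma + self.params.eta * self.k2
        if self.params.gamma == 0:
            self.fb_denom = self.fb_denom.copy()
            self.fb_denom[0] = 1.0

    # -- single step on (B, n) arrays -------------------------------------
    def _flow(self, P: np.ndarray, beta: np.ndarray, pi0: np.ndarray | float):
        Pi = pi0 - beta * P
        Pi = np.broadcast_to(Pi, P.shape)
        vhat = 1j * self.k * np.fft.rfft(Pi, axis=-1) / self.fb_denom
        if self.n % 2 == 0:
            vhat[..., -1] = 0.0
        return np.fft.irfft(vhat, n=self.n, axis=-1)

    def _pi0(self, t: np.ndarray, patch: np.ndarray | None):
        p0 = self.params.pi_active_0
        if patch is None:
            return p0
        return p0 * (1.0 - patch * np.exp(-t / self.trigger_decay))

    def _advance(self, A, P, Ac, Pc, konP, beta, patch, t, dt):
        p = self.params
        v = self._flow(P, beta, self._pi0(t, patch))
        advA = _upwind_advection(A, v, self.dx)
        advP = _upwind_advection(P, v, self.dx)
        lossA = p.koff_A + p.k_AP * P
        lossP = p.koff_P + p.k_PA * A * A
        A1 = (A + dt * (advA + p.kon_A * Ac)) / (1.0 + dt * lossA)
        P1 = (P + dt * (advP + konP * Pc)) / (1.0 + dt * lossP)
        # mirror the realised reaction change into the pools (exact conservation)
        Ac1 = Ac - p.psi * np.mean(A1 - A - dt * advA, axis=-1, keepdims=True)
        Pc1 = Pc - p.psi * np.mean(P1 - P - dt * advP, axis=-1, keepdims=True)
        A2 = np.fft.irfft(np.fft.rfft(A1, axis=-1) / (1.0 + dt * p.D_A * self.k2), n=self.n, axis=-1)
        P2 = np.fft.irfft(np.fft.rfft(P1, axis=-1) / (1.0 + dt * p.D_P * self.k2), n=self.n, axis=-1)
        return A2, P2, Ac1, Pc1, v

    def _dt(self, A, P, v):
        p = self.params
        vmax = np.max(np.abs(v), axis=-1, keepdims=True)
        rmax = np.max(
            np.maximum(p.koff_A + p.k_AP * P, p.koff_P + p.k_PA * A * A),
            axis=-1,
            keepdims=True,
        )
        dt = np.minimum(self.opts.dt_max, self.opts.cfl * self.dx / np.maximum(vmax, 1e-12))
        return np.minimum(dt, self.opts.rate_cap / np.maximum(rmax, 1e-12))

    # -- main loop ---------------------------------------------------------
    def run(
        self,
        A: np.ndarray,
        P: np.ndarray,
        A_cyto: np.ndarray | float,
        P_cyto: np.ndarray | float,
        t0: float = 0.0,
        record: bool = False,
        blowup: str = "raise",
    ) -> dict:
        """Integrate the batch; ``blowup`` selects whether a diverging row
        aborts the whole run (``"raise"``) or is retired individually with a
        failure flag (``"retire"``, used by parameter sweeps)."""
        opts = self.opts
        p = self.params
        scale_P0 = p.scales.P0
        tau = p.scales.tau
        A = np.atleast_2d(np.array(A, dtype=float, copy=True))
        P = np.atleast_2d(np.array(P, dtype=float, copy=True))
        B = A.shape[0]
        Ac = np.broadcast_to(np.asarray(A_cyto, dtype=float).reshape(-1, 1), (B, 1)).copy()
        Pc = np.broadcast_to(np.asarray(P_cyto, dtype=float).reshape(-1, 1), (B, 1)).copy()
        konP = np.broadcast_to(self.konP, (B, self.n)).copy()
        beta = np.broadcast_to(self.beta, (B, 1)).copy()
        patch = None if self.patch is None else np.broadcast_to(self.patch, (B, self.n)).copy()
        t = np.full((B, 1), float(t0))
        min_time = opts.min_time
        if min_time is None:
            min_time = 5.0 * self.trigger_decay if patch is not None else 0.0

        if record and B != 1:
            raise ValueError("kymograph recording requires a single-row batch")

        # output buffers (full batch)
        outA = np.empty_like(A)
        outP = np.empty_like(P)
        outAc = np.empty((B, 1))
        outPc = np.empty((B, 1))
        outT = np.empty((B, 1))
        converged = np.zeros(B, dtype=bool)
        failed = np.zeros(B, dtype=bool)
        tail_sum = np.zeros_like(A)
        tail_cnt = np.zeros((B, 1))
        out_tail = np.zeros_like(A)
        tail_start = (1.0 - opts.tail_frac) * opts.t_max

        active = np.arange(B)
        P_ref = P.copy()
        t_ref = t.copy()
        rows: list[np.ndarray] = []
        times: list[float] = []
        next_save = t0
        steps = 0
        max_steps = int(2e7)

        def retire(mask_local: np.ndarray, conv: bool, fail: bool = False) -> None:
            nonlocal A, P, Ac, Pc, konP, beta, patch, t, P_ref, t_ref, active
            nonlocal tail_sum, tail_cnt
            idx = active[mask_local]
            outA[idx] = A[mask_local]
            outP[idx] = P[mask_local]
            outAc[idx] = Ac[mask_local]
            outPc[idx] = Pc[mask_local]
            outT[idx] = t[mask_local]
            converged[idx] = conv
            failed[idx] = fail
            cnt = tail_cnt[mask_local]
            with np.errstate(invalid="ignore"):
                avg = tail_sum[mask_local] / np.maximum(cnt, 1.0)
            out_tail[idx] = np.where(cnt > 0, avg, P[mask_local])
            keep = ~mask_local
            A, P, Ac, Pc, t = A[keep], P[keep], Ac[keep], Pc[keep], t[keep]
            konP, beta = konP[keep], beta[keep]
            patch = None if patch is None else patch[keep]
            P_ref, t_ref = P_ref[keep], t_ref[keep]
            tail_sum, tail_cnt = tail_sum[keep], tail_cnt[keep]
            active = active[keep]

        while active.size:
            if record and t[0, 0] >= next_save - 1e-9:
                rows.append(P[0].copy())
                times.append(float(t[0, 0]))
                next_save += opts.save_dt
            v = self._flow(P, beta, self._pi0(t, patch))
            dt = self._dt(A, P, v)
            A, P, Ac, Pc, v = self._advance(A, P, Ac, Pc, konP, beta, patch, t, dt)
            t = t + dt
            in_tail = (t > tail_start).ravel()
            if np.any(in_tail):
                tail_sum[in_tail] += P[in_tail]
                tail_cnt[in_tail] += 1.0
            steps += 1
            if steps % opts.check_every == 0 or steps >= max_steps:
                bad = (
                    ~np.all(np.isfinite(P), axis=-1)
                    | np.any(P < -1e-9, axis=-1)
                    | np.any(A < -1e-9, axis=-1)
                )
                if np.any(bad):
                    if blowup == "raise":
                        raise NumericalError(
                            f"integration blew up at t={float(np.min(t)):.3g}s "
                            f"(dt range {float(np.min(dt)):.3g}-{float(np.max(dt)):.3g}s)"
                        )
                    retire(bad, conv=False, fail=True)
                    if not active.size:
                        break
                rate = np.max(np.abs(P - P_ref), axis=-1, keepdims=True) / np.maximum(
                    t - t_ref, 1e-12
                )
                done = ((rate * tau / scale_P0 < opts.tol) & (t >= min_time)).ravel()
                timeout = (t >= opts.t_max).ravel()
                if np.any(done & ~timeout):
                    retire(done & ~timeout, conv=True)
                    timeout = (t >= opts.t_max).ravel()
                if np.any(timeout):
                    retire(timeout, conv=False)
                P_ref = P.copy()
                t_ref = t.copy()
                if steps >= max_steps:
                    if active.size:
                        retire(np.ones(active.size, dtype=bool), conv=False)
                    break

        kymo = None
        if record:
            x = np.arange(self.n) * self.dx
            if rows:
                kymo = Kymograph(
                    values=np.asarray(rows),
                    times=np.asarray(times),
                    positions=x,
                    quantity="P",
                )
        return {
            "A": outA,
            "P": outP,
            "A_cyto": outAc,
            "P_cyto": outPc,
            "t": outT,
            "converged": converged,
            "failed": failed,
            "P_tail": out_tail,
            "kymograph": kymo,
        }


# ---------------------------------------------------------------------------
# convenience wrappers


def step(
    state: CortexState,
    scenario,
    params: ModelParams,
    dt: float,
) -> CortexState:
    """Advance one state by one time step ``dt`` (single-step contract).

    ``scenario`` may be ``None`` (uniform attachment, no trigger) or a
    :class:`parpolar.scenarios.Scenario`.  Raises :class:`NumericalError`
    when ``dt`` violates the scheme's stability contract (detected via
    NaN / negative blow-up).
    """
    params = params.with_scales()
    n, dx = state.n, state.dx
    if scenario is None:
        konP = np.full(n, params.kon_P)
        patch, decay = None, 300.0
    else:
        prob = scenario.build(params, n)
        konP = prob.kon_P_profile
        patch = prob.trigger_patch
        decay = prob.trigger_decay
    integ = CortexIntegrator(
        params, dx, n, konP, trigger_patch=patch, trigger_decay=decay
    )
    t = np.array([[state.t]])
    dt_arr = np.array([[float(dt)]])
    A, P, Ac, Pc, v = integ._advance(
        state.A[None, :],
        state.P[None, :],
        np.array([[state.A_cyto]]),
        np.array([[state.P_cyto]]),
        integ.konP,
        integ.beta,
        integ.patch,
        t,
        dt_arr,
    )
    if not np.all(np.isfinite(P)) or np.any(P < -1e-9) or np.any(A < -1e-9):
        raise NumericalError(f"unstable step with dt={dt:.3g}s")
    return CortexState(
        x=state.x,
        A=A[0],
        P=P[0],
        v=v[0],
        A_cyto=float(Ac[0, 0]),
        P_cyto=float(Pc[0, 0]),
        t=state.t + dt,
    )


def run_to_steady_state(
    scenario,
    params: ModelParams,
    options: SolverOptions | None = None,
    initial: CortexState | None = None,
) -> SteadyStateResult:
    """Integrate a scenario until the posterior field settles.

    Returns the final state, the recorded P kymograph, and whether the
    steady-state tolerance was met before ``t_max`` (non-convergence is
    flagged, never silently dropped).
    """
    opts = options or SolverOptions()
    params = params.with_scales()
    prob = scenario.build(params, opts.n)
    if initial is None:
        initial = prob.initial_state(params)
    integ = CortexIntegrator(
        params,
        prob.dx,
        opts.n,
        prob.kon_P_profile,
        trigger_patch=prob.trigger_patch,
        trigger_decay=prob.trigger_decay,
        options=opts,
    )
    res = integ.run(
        initial.A,
        initial.P,
        initial.A_cyto,
        initial.P_cyto,
        t0=initial.t,
        record=opts.record,
    )
    P = res["P"][0]
    v = solve_force_balance(P, params, prob.dx)
    state = CortexState(
        x=prob.x,
        A=res["A"][0],
        P=P,
        v=v,
        A_cyto=float(res["A_cyto"][0, 0]),
        P_cyto=float(res["P_cyto"][0, 0]),
        t=float(res["t"][0, 0]),
    )
    return SteadyStateResult(
        state=state,
        kymograph=res["kymograph"],
        converged=bool(res["converged"][0]),
        P_settled=res["P_tail"][0],
    )
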