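# Methods

## The model

`parpolar` simulates anterior–posterior symmetry breaking of the *C. elegans*
zygote cortex as a mass-conserving reaction–diffusion–advection system on a 1D
periodic domain (the embryo circumference, arc-length coordinate `x`), coupled
to an active-gel description of cortical flow.

Membrane densities `A(x,t)` (anterior PAR complex, PAR-3/PAR-6/PKC-3) and
`P(x,t)` (posterior PAR protein, PAR-2) obey

```
∂t A = D_A ∂x²A − ∂x(vA) + kon_A·A_cyto − koff_A·A − k_AP·P·A
∂t P = D_P ∂x²P − ∂x(vP) + kon_P(x)·P_cyto − koff_P·P − k_PA·A²·P
```

with well-mixed cytoplasmic pools closed by strict mass conservation
(`A_total = A_cyto + ψ⟨A⟩`, ψ the surface-to-volume factor, ⟨·⟩ the spatial
mean).  Antagonism-induced detachment returns protein to the cytoplasm.  The
`A²` dependence of the attack on `P` makes the local kinetics bistable: an
anterior-dominant and a posterior-dominant membrane state coexist for a range
of pool levels.

Cortical flow is instantaneous (over-damped) and driven by gradients of
active stress:

```
γ v − η ∂x²v = ∂x Π_active ,   Π_active = π0(x,t) − β P
```

so that flow runs *toward* regions of higher contractility — away from
membrane regions rich in `P`, which weakens the cortex via its antagonism with
the anterior complex's control of myosin.  This orientation reproduces both
the anterior-directed flows of triggered embryos and the pole-to-center flows
of untriggered (AIR-1-depleted) ones.  A constant passive (osmotic) stress
contribution drops out of the gradient and is retained only as a parameter.

Two couplings close the feedback loops:

* **Curvature-dependent attachment.**  The posterior attachment rate is
  enhanced by the excess of contour curvature over the flattest ("central")
  cortex: `kon_P(x) = kon_P + α·max(κ(x) − κ_ref, 0)`.  The excess is
  smoothed over a curvature-sensing length (default 4.5 µm, the width of a
  domain wall `√(D_P/koff_P)`) and saturates smoothly at 8× the base rate,
  reflecting a finite density of curvature-sensitive binding sites.  The
  saturation matters only far above the anchor parameters; without it a very
  strongly boosted site hoards the entire cytoplasmic pool.
* **Contractility feedback.**  Membrane `P` lowers active stress by `βP`,
  so a nascent posterior domain drives flows that sweep `A` away from it,
  relieving the `k_PA A²` suppression — the advective positive feedback that
  sharpens and accelerates polarization.

### Triggers

The centrosome-derived cue of the wild type is modeled as a local transient
weakening of the cortex: `π0(x,t) = π_active,0 (1 − depth·g(x)·e^{−t/τ_d})`
with `g` a Gaussian patch (width 15 µm) at the posterior pole, depth 0.8 and
decay time τ_d = 300 s.  A strictly instantaneous reduction of an algebraic
stress would not affect the dynamics at all, hence the explicit decay time,
chosen to match the few-minute duration of the flow-establishing phase.  The
meiosis-arrest scenario uses the same patch at the anterior pole with 25% of
the wild-type depth; the lateral-entry scenario places the full patch at 30%
of the circumference.

### Scenario logic

* **Wild type (ellipse).**  The trigger nucleates the posterior domain first;
  its growth depletes the cytoplasmic `P` pool and redistributes displaced
  `A` over the rest of the membrane, raising the nucleation threshold at the
  anterior pole above its curvature boost.  One domain results.
* **No trigger (AIR-1 depleted).**  Both polar caps sit above the nucleation
  threshold of the *fresh* pool and fire simultaneously (deterministically —
  symmetry is broken by curvature alone, not noise); neither gets the head
  start needed to suppress the other.  Two domains result, their summed
  extent comparable to the single wild-type domain because the same pool
  feeds them.
* **Triangular chamber.**  The embryo's cortex engages the three corners to
  different degrees; the corner cues carry per-corner weights (1.0, 0.15,
  0.10), standing in for the corner-curvature inequality scored in real
  squeezed embryos.  At the anchor parameters only the most-engaged corner is
  above threshold once the pool starts draining, giving a single corner
  domain with or without a trigger; at high α (and with flow assistance at
  high β) the weaker corners fire too, producing the abrupt 1 → 2 → 3
  cascade.

## Parameters

Kinetic rates follow the published mass-conserved PAR reaction–diffusion
framework for the zygote: `D_A = 0.28`, `D_P = 0.15` µm²/s; `kon_A =
8.58·10⁻³`, `kon_P = 4.74·10⁻²` µm/s; `koff_A = 5.4·10⁻³`, `koff_P =
7.3·10⁻³` s⁻¹; `k_AP = 0.19` µm²/s; pools `A_total = 1.56`, `P_total = 1.0`
µm⁻³; `ψ = 0.174` µm⁻¹.  The antagonism coefficient of `A` on `P` is set to
`k_PA = 3.25` µm⁴/s, somewhat above the framework's nominal value, which
places the base (unboosted) cortex on the anterior-favoring side of the
bistable front balance: posterior fronts then *pin at the edge of the
curvature-boosted caps* instead of invading the whole ring, and a domain
cannot persist without a curvature (or trigger) cue — the regime all four
scenario outcomes require.

Mechanics: stresses are expressed in units where the membrane friction is
`γ = 1`; the cortex viscosity `η = 196` sets the hydrodynamic length
`√(η/γ) = 14 µm`.  The baseline active stress `π_active,0 = 12` makes the
wild-type trigger drive peak flows of several µm/min, the magnitude measured
by PIV in control embryos.

### Control-plane mapping

The two phase-diagram coordinates are dimensionless; their dimensional units
are fixed model constants:

```
α = (α/l) · 2.0 · l · kon_P          l = √(η/γ) = 14 µm
β = β̄ · γ·D_P / (P0·l)               P0 = kon_P·P_total/(koff_P + kon_P·ψ) ≈ 3.05 µm⁻²
```

with reference time `τ = 1/koff_P ≈ 137 s` and reference density `ρ = P0`.
The coupling constant 2.0 and the `γD_P/(P0 l)` stress-per-density unit were
calibrated once so that the printed anchor point `(α/l, β̄) = (1.2, 100)`
falls in the model's operating regime — the nucleation threshold in `α/l`
lies below the anchor (≈0.8 on the ellipse), and flows at the anchor are a
few µm/min — and were frozen thereafter.  At the anchor the polar attachment
enhancement is ≈2.3× on the ellipse poles and ≈5× at the favored triangle
corner.

## Numerics

Operator splitting per step on a uniform periodic grid (default 256 points):

1. force balance re-solved spectrally (rFFT; the k = 0 mode vanishes because
   the right-hand side is a pure gradient; the even-n Nyquist mode is zeroed,
   having no well-defined odd derivative);
2. conservative first-order upwind advection on face-centred velocities
   (telescoping fluxes conserve membrane mass to round-off);
3. reaction terms with a Patankar-type update — gains explicit, losses
   implicit in the denominator — which preserves positivity for any `dt` and
   leaves fixed points unchanged; the *realised* reaction change is mirrored
   into the cytoplasmic pools, so conservation is exact by construction;
4. implicit (unconditionally stable) diffusion via rFFT.

The time step adapts per run: `dt = min(0.25 s, 0.2·dx/max|v|,
2/max(loss rate))`.  Steady state is declared when `max|∂tP|·τ/P0 < 10⁻⁶`
(with a minimum time of five trigger decay constants when a trigger is
present); runs that do not converge by `t_max` are flagged and classified
from the time-average of the final 10% of the run (oscillatory tie-break).
Blow-up (NaN or negative density) raises an error naming the offending `dt`.

The integrator advances whole batches of independent states at once (each
with its own `dt` and retirement time); the phase-diagram sweep exploits this
to integrate all grid cells × initial conditions as one array program.

Problem sizes used by the shipped studies: scenario runs on 256 points with
`t_max` = 3 h of biological time (they typically converge in 20–60 min);
phase diagrams on 10×10 parameter grids at 128 points with `t_max` = 2.5 h;
the grid-doubling check compares 256 against 512 points.

## Phase-diagram classification

A cell's primary label is the steady-state domain count reached from the
scenario's canonical initial condition — the uniform anterior-dominant
membrane (the state of the cortex before symmetry breaking).  Domains are
counted as periodic runs where `P > 0.5·max(P)`, gated by a floor
(`max(2·P_suppressed, 0.05·P0)`) so that a merely curvature-tilted,
un-nucleated profile (two orders of magnitude below `P0`) is never called a
domain.

Multistability is probed by a panel of additional initial conditions — a
small `P` bump (amplitude 0.12 `P0`, width 8 µm) at each curvature peak,
with a matching local `A` reduction.  Cells where panel members settle into
different counts carry a separate *coexistence* flag.  The flag is kept
separate from the primary label deliberately: over much of the operating
regime a polar state, once seeded, is self-maintaining (the same property
that lets the wild-type trigger select a unique domain), so folding the
panel into the primary label would hide which state the unbiased dynamics
select.  The probe amplitude trades sensitivity (too small misses shallow
attractors) against triviality (a large seed is itself a nascent domain and
finds its own basin everywhere); 0.12 `P0` detects the polar/bipolar
coexistence band without overwhelming the unbiased classification.

## Measurement operators

**Domain extent** on a circular intensity trace: (1) 23-point circular
moving average; (2) noise floor from the smoothed trace's minima — background
level and noise amplitude are first read off the lower quantiles
(q10/q25/q40), then re-estimated from out-of-run samples only (two passes),
which removes contamination by the domain ramps; the floor is the background
plus 5 noise standard deviations; (3) the smoothed data are squared and
candidate domains are runs exceeding the squared floor (reducing
noise-induced threshold crossings); (4) each boundary is refined to the
half-rise point between background and the run's (noise-robust, 90th
percentile) plateau.  The refinement removes the systematic widening that
the moving average would otherwise add, recovers a noiseless sharp-edged
domain to within one grid step, and keeps the rule scale-covariant.  Whether
the squaring precedes or follows the boundary search is not determinate from
the original description; squaring-then-thresholding at the squared floor is
this package's reading, and since both quantities are positive at the
crossing the two orders give identical boundaries.

**Multipass PIV**: four coarse-to-fine passes with interrogation windows
64→32→16→8 px, half-window overlap and a final grid step of 4 px.  Each pass
shifts the second frame's search window by the rounded previous estimate, so
a pure integer translation is recovered *exactly* (the correlation becomes an
autocorrelation, whose 3-point Gaussian sub-pixel fit is symmetric; offsets
below 10⁻⁶ px are snapped to zero).  Flat (texture-free) windows are flagged
invalid and filled from neighbouring vectors; a 3×3 median test replaces
outliers.  Correlation is FFT-based on mean-subtracted windows with wrap
padding.

**Velocity kymographs**: PIV on each consecutive frame pair, x-velocity
averaged along y, stacked over time; physical units (µm/min) require pixel
size and frame interval, otherwise px/frame is emitted with a warning.  The
per-movie peak velocity is the movie maximum of the per-frame spatial
maximum of |y-averaged Vx| after a 3-frame temporal moving average.

## Synthetic data

The generator emulates (i) straightened-circumference fluorescence traces —
smooth top-hat domains (FWHM equal to the requested width, half-cosine
shoulders of 2 µm) on a constant background with additive Gaussian noise —
and (ii) cortical speckle movies: Poisson-placed particles rendered as
Gaussian spots (σ = 1.2 px, density 0.02 px⁻²) and advected per frame by a
prescribed uniform, sinusoidal, or bipolar-inward velocity field with
periodic wrap.  Every output is a deterministic function of the seed.

What these fixtures do *not* emulate: autofluorescence gradients, bleaching,
embryo-outline segmentation errors, anisotropic PSFs, or flow fields with
out-of-plane components.  Passing the recovery harness therefore shows the
operators are correct and well-conditioned on clean, known-truth inputs —
not that their absolute accuracy transfers to any particular microscope.

## Known limitations

* The analysis is 1D; 2D cortical dynamics, explicit centrosome mechanics
  and microtubule-dependent protection of `P` are outside scope.
* The Maxwell (front-stall) balance makes some phase-boundary cells converge
  only slowly; they are classified from the tail average and flagged.
* Absolute flow speeds and domain extents depend on the calibrated scale
  constants above; only the dimensionless topology of the phase diagrams and
  the scenario domain counts are claimed as robust.
* The triangle scenario encodes corner engagement phenomenologically
  (weights), not via contact mechanics of the squeezed embryo.
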