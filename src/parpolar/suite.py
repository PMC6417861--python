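"""End-to-end study suite: scenario runs, phase diagrams, measurement checks.

:func:`run_paper_suite` reproduces the package's headline results in one
call -- the four scenario simulations at the anchor point (alpha/l = 1.2,
beta_scaled = 100), coarse phase diagrams for the five scenarios, the
lateral-trigger relaxation, the numerical invariants, and the
measurement-operator recovery harness on synthetic fixtures -- and writes a
single report with pass/fail per check.  The quantities it computes are also
the ones the repository's acceptance script reports.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from .geometry import circular_distance
from .measure import domain_extent, flow_kymograph, piv_multipass
from .model import SolverOptions, run_to_steady_state, solve_force_balance
from .params import default_params
from .phase import COEXIST, count_domains, default_policy, sweep
from .scenarios import make_scenario
from .synth import FlowSpec, SyntheticSpec, make_profile, make_speckle_movie

ANCHOR = (1.2, 100.0)


# ---------------------------------------------------------------------------
# individual studies


def scenario_domain_counts(
    n: int = 256, t_max: float = 10800.0, keep: dict | None = None
) -> dict[str, int]:
    """Steady-state domain counts of the four anchor-point scenarios."""
    p = default_params().with_nondim(*ANCHOR)
    policy = default_policy(p)
    opts = SolverOptions(n=n, t_max=t_max, record=False)
    out: dict[str, int] = {}
    for key, (name, geom) in {
        "wt": ("wt", "ellipse"),
        "no_trigger": ("no-trigger", "ellipse"),
        "triangular_no_trigger": ("no-trigger", "triangle"),
        "triangular_wt": ("wt", "triangle"),
    }.items():
        res = run_to_steady_state(make_scenario(name, geom), p, opts)
        out[key] = count_domains(res.classification_profile(), policy)
        if keep is not None:
            keep[key] = res
    return out


def lateral_relaxation_offset(n: int = 256, t_max: float = 10800.0) -> float:
    """Distance (um) from the lateral-trigger domain centre to the nearer pole.

    The trigger sits between the poles; the measured offset is the circular
    distance between the settled domain's centre of mass and the nearer
    polar curvature peak.
    """
    p = default_params().with_nondim(*ANCHOR)
    sc = make_scenario("lateral", "ellipse")
    opts = SolverOptions(n=n, t_max=t_max, record=False)
    res = run_to_steady_state(sc, p, opts)
    prof = res.classification_profile()
    x = res.state.x
    L = x.size * (x[1] - x[0])
    # circular centre of mass of the P distribution
    ang = 2.0 * np.pi * x / L
    c = np.sum(prof * np.cos(ang))
    s = np.sum(prof * np.sin(ang))
    center = (np.arctan2(s, c) % (2.0 * np.pi)) * L / (2.0 * np.pi)
    peaks = sc.geometry.curvature(n).peaks
    trig = sc.trigger.center
    nearer = min(peaks, key=lambda q: abs(circular_distance(trig, q, L)))
    return float(abs(circular_distance(center, nearer, L)))


def phase_metrics(
    grid_n: int = 10,
    n: int = 128,
    t_max: float = 9000.0,
    out_dir: Path | None = None,
) -> dict:
    """Topology metrics of the five coarse phase diagrams."""
    p = default_params()
    alpha_grid = np.linspace(0.0, 12.0, grid_n)
    beta_grid = np.logspace(1.0, 3.0, grid_n)
    opts = SolverOptions(n=n, t_max=t_max, record=False)
    diagrams = {}
    for key, (name, geom) in {
        "wt": ("wt", "ellipse"),
        "no_trigger": ("no-trigger", "ellipse"),
        "triangular_wt": ("wt", "triangle"),
        "triangular_no_trigger": ("no-trigger", "triangle"),
        "weak_anterior": ("weak-anterior", "ellipse"),
    }.items():
        diagrams[key] = sweep(
            make_scenario(name, geom), alpha_grid, beta_grid, p, options=opts
        )
    nt = diagrams["no_trigger"]
    wt = diagrams["wt"]
    metrics = {
        "nt_bipolar_cells": nt.region_size(2),
        "wt_bipolar_cells": wt.region_size(2),
        "bipolar_containment": bool(
            np.all(wt.region_mask(2) <= nt.region_mask(2))
            and nt.region_size(2) > wt.region_size(2)
        ),
        "nt_coexist_cells": nt.region_size(COEXIST),
        "tri_nt_three_domain_cells": diagrams["triangular_no_trigger"].region_size(3),
        "weak_anterior_single_cells": diagrams["weak_anterior"].region_size(1),
        "nt_single_cells": nt.region_size(1),
        "wt_single_cells": wt.region_size(1),
    }
    if out_dir is not None:
        from .io import render_phase_diagram, write_phase_diagram

        out_dir.mkdir(parents=True, exist_ok=True)
        for key, d in diagrams.items():
            write_phase_diagram(d, out_dir / f"phase_{key}.tsv")
            render_phase_diagram(d, out_dir / f"phase_{key}.png")
    return metrics


def numerics_metrics(n: int = 256, t_max: float = 3600.0) -> dict:
    """Conservation, force-balance and symmetry diagnostics."""
    p = default_params().with_nondim(*ANCHOR)

    # force balance vs closed-form single Fourier mode
    L = 127.5
    nn = 256
    x = np.arange(nn) * (L / nn)
    k = 2.0 * np.pi / L
    eps = 0.37
    P = p.scales.P0 + eps * np.cos(k * x)
    v = solve_force_balance(P, p, L / nn)
    v_exact = eps * p.beta * k * np.sin(k * x) / (p.eta * k * k + p.gamma)
    fb_err = float(np.max(np.abs(v - v_exact)) / np.max(np.abs(v_exact)))

    # mass conservation over a wild-type run
    sc = make_scenario("wt", "ellipse")
    opts = SolverOptions(n=n, t_max=t_max, record=False)
    prob = sc.build(p, n)
    st0 = prob.initial_state(p)
    tot0 = st0.total_mass(p)
    res = run_to_steady_state(sc, p, opts)
    tot1 = res.state.total_mass(p)
    drift = max(
        abs(tot1[0] - tot0[0]) / tot0[0], abs(tot1[1] - tot0[1]) / tot0[1]
    )

    # reflection symmetry of a no-trigger run (mirror-symmetric inputs)
    sc2 = make_scenario("no-trigger", "ellipse")
    res2 = run_to_steady_state(sc2, p, SolverOptions(n=n, t_max=1800.0, record=False))
    P2 = res2.state.P
    mirrored = np.concatenate(([P2[0]], P2[1:][::-1]))
    sym_err = float(np.max(np.abs(P2 - mirrored)) / max(np.max(np.abs(P2)), 1e-12))

    # grid doubling leaves the anchor domain counts unchanged
    policy = default_policy(p)
    counts = []
    for ng in (n, 2 * n):
        r = run_to_steady_state(
            make_scenario("no-trigger", "ellipse"),
            p,
            SolverOptions(n=ng, t_max=10800.0, record=False),
        )
        counts.append(count_domains(r.classification_profile(), policy))
    return {
        "force_balance_rel_err": fb_err,
        "mass_drift_rel": float(drift),
        "reflection_asymmetry": sym_err,
        "grid_doubling_count_change": abs(counts[1] - counts[0]),
    }


def measurement_metrics(seed: int = 0, n_noise: int = 500) -> dict:
    """Recovery of known truth by the measurement operators."""
    rng = np.random.default_rng(seed)

    # --- domain extent recovery at SNR = 5 (two domains) ---
    amp, snr = 10.0, 5.0
    worst = 0.0
    for rep in range(3):
        spec = SyntheticSpec(
            seed=int(rng.integers(2**31 - 1)),
            domains=((30.0, 28.0, amp), (95.0, 20.0, amp)),
            noise=amp / snr,
        )
        x, trace, truth = make_profile(spec)
        meas = domain_extent(trace, x)
        want = sum(w for _, w, _ in truth.domains)
        worst = max(worst, abs(meas.extent - want) / want)
    extent_err_pct = 100.0 * worst

    # --- false-positive rate on flat noise ---
    false_hits = 0
    for rep in range(n_noise):
        spec = SyntheticSpec(
            seed=int(rng.integers(2**31 - 1)), domains=(), noise=1.0, background=5.0
        )
        _, trace, _ = make_profile(spec)
        if domain_extent(trace).extent > 0:
            false_hits += 1
    false_rate_pct = 100.0 * false_hits / n_noise

    # --- PIV: exact integer translation ---
    spec = SyntheticSpec(seed=seed, image_shape=(128, 128))
    frames, _ = make_speckle_movie(spec, 1)
    a = frames[0]
    b = np.roll(a, 3, axis=1)
    f = piv_multipass(a, b)
    int_err = float(
        max(
            np.max(np.abs(f.u[f.valid] - 3.0)) if f.valid.any() else np.inf,
            np.max(np.abs(f.v[f.valid])) if f.valid.any() else np.inf,
        )
    )

    # --- PIV: sinusoidal displacement field, RMS error ---
    spec = SyntheticSpec(
        seed=seed + 1,
        image_shape=(128, 256),
        flow=FlowSpec(kind="sinusoidal", amplitude=2.0, wavelength=256.0),
    )
    frames, truth = make_speckle_movie(spec, 2)
    f = piv_multipass(frames[0], frames[1])
    ux_true = truth[0, 0][np.ix_(f.y, f.x)]
    rms = float(np.sqrt(np.mean((f.u - ux_true) ** 2)))

    # --- flow kymograph units on constant advection ---
    spec = SyntheticSpec(
        seed=seed + 2, image_shape=(128, 128), flow=FlowSpec(kind="uniform", ux=5.0)
    )
    frames, _ = make_speckle_movie(spec, 3)
    vk = flow_kymograph(frames, frame_interval=10.0, pixel_size=0.1)
    kymo_speed_err = float(abs(np.mean(vk.values) - 3.0) / 3.0)  # 3 um/min expected

    return {
        "extent_recovery_err_pct": extent_err_pct,
        "false_domain_rate_pct": false_rate_pct,
        "piv_integer_max_err_px": int_err,
        "piv_sine_rms_px": rms,
        "kymo_speed_rel_err": kymo_speed_err,
    }


# ---------------------------------------------------------------------------
# the suite


def run_paper_suite(out_dir: Path, quick: bool = False, seed: int = 0) -> dict:
    """Run every study and write ``report.json`` (+ diagrams) to ``out_dir``.

    ``quick`` shrinks grids and horizons for smoke testing; the pass/fail
    checks are only meaningful at full size.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if quick:
        sim_n, sim_t = 64, 900.0
        grid_n, ph_n, ph_t = 2, 48, 900.0
        n_noise = 25
    else:
        sim_n, sim_t = 256, 10800.0
        grid_n, ph_n, ph_t = 10, 128, 9000.0
        n_noise = 500

    report: dict = {"quick": quick, "seed": seed}
    keep: dict = {}
    report["scenario_domains"] = scenario_domain_counts(sim_n, sim_t, keep=keep)
    from .io import render_kymograph, write_kymograph

    for key in ("wt", "no_trigger"):
        p = default_params().with_nondim(*ANCHOR)
        res = run_to_steady_state(
            make_scenario("wt" if key == "wt" else "no-trigger", "ellipse"),
            p,
            SolverOptions(n=sim_n, t_max=sim_t, record=True, save_dt=60.0),
        )
        if res.kymograph is not None:
            write_kymograph(res.kymograph, out_dir / f"kymograph_{key}.tsv")
            render_kymograph(res.kymograph, out_dir / f"kymograph_{key}.png", title=key)

    report["lateral_offset_um"] = lateral_relaxation_offset(sim_n, sim_t)
    report["phase"] = phase_metrics(grid_n, ph_n, ph_t, out_dir=out_dir)
    report["numerics"] = numerics_metrics(n=sim_n, t_max=min(sim_t, 3600.0))
    report["measurement"] = measurement_metrics(seed=seed, n_noise=n_noise)

    sd = report["scenario_domains"]
    ph = report["phase"]
    nm = report["numerics"]
    ms = report["measurement"]
    report["checks"] = {
        "wt_single_domain": sd["wt"] == 1,
        "no_trigger_bipolar": sd["no_trigger"] == 2,
        "triangular_no_trigger_single": sd["triangular_no_trigger"] == 1,
        "triangular_wt_single": sd["triangular_wt"] == 1,
        "lateral_relaxes_to_pole": report["lateral_offset_um"] < 15.0,
        "bipolar_region_containment": ph["bipolar_containment"],
        "coexistence_region_exists": ph["nt_coexist_cells"] > 0,
        "triangular_three_domain_region": ph["tri_nt_three_domain_cells"] > 0,
        "weak_anterior_shifts_to_single": ph["weak_anterior_single_cells"]
        > ph["nt_single_cells"],
        "mass_conserved": nm["mass_drift_rel"] < 1e-6,
        "force_balance_exact": nm["force_balance_rel_err"] < 1e-8,
        "reflection_symmetric": nm["reflection_asymmetry"] < 1e-8,
        "grid_doubling_stable": nm["grid_doubling_count_change"] == 0,
        "extent_recovery_5pct": ms["extent_recovery_err_pct"] < 5.0,
        "false_domain_rate_5pct": ms["false_domain_rate_pct"] <= 5.0,
        "piv_integer_exact": ms["piv_integer_max_err_px"] == 0.0,
        "piv_sine_rms": ms["piv_sine_rms_px"] < 0.2,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
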