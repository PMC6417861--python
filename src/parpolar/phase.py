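"""Phase-diagram construction: domain counting and parameter sweeps.

Each point of the (alpha/l, beta*tau/(rho*P0)) plane carries the number of
posterior-protein domains the dynamics settle into from the scenario's
canonical initial condition (the uniform anterior-dominant cortex).  In
parallel, a panel of weakly biased initial conditions (a small bump at each
candidate site) probes multistability: where panel members settle into
different domain counts, the cell is flagged as a coexistence point (e.g.
polar and bipolar states both stable).  The flag is deliberately separate
from the primary label: over much of the operating regime a polar state,
once seeded, is self-maintaining through pool depletion, so a panel-only
labelling would hide which state the unbiased dynamics select.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import CortexIntegrator, SolverOptions, homogeneous_steady_state
from .params import ModelParams
from .scenarios import Scenario

#: label codes beyond plain domain counts
COEXIST = -2
NONCONVERGED = -1

#: bias bump used by the multistability panel: (width um, amplitude in P0)
PANEL_BIAS_WIDTH = 8.0
PANEL_BIAS_AMP = 0.12


@dataclass(frozen=True)
class ThresholdPolicy:
    """Domain-calling rule for a concentration profile.

    A grid point is inside a domain when ``P > frac * max(P)``, and domains
    are only called at all when ``max(P)`` exceeds ``floor`` -- the guard
    that prevents calling domains on an essentially flat profile.
    """

    frac: float = 0.5
    floor: float = 0.0


def default_policy(params: ModelParams) -> ThresholdPolicy:
    """Policy with the floor tied to the model's reference scales.

    The floor is the larger of twice the suppressed (aPAR-dominant
    homogeneous) P level and 5% of the reference posterior density P0: an
    un-nucleated, merely curvature-tilted profile stays two orders of
    magnitude below P0, while any true domain reaches order P0.
    """
    p = params.with_scales()
    _, P_hom, _, _ = homogeneous_steady_state(p)
    return ThresholdPolicy(frac=0.5, floor=max(2.0 * P_hom, 0.05 * p.scales.P0))


def count_domains(P: np.ndarray, policy: ThresholdPolicy) -> int:
    """Number of contiguous above-threshold runs on the periodic grid.

    A run wrapping the seam counts once; an entirely above-threshold profile
    counts as a single domain.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 1:
        raise ValueError("P must be one-dimensional")
    if not np.any(np.isfinite(P)):
        raise ValueError("all-NaN profile")
    pmax = np.nanmax(P)
    if not pmax > policy.floor:
        return 0
    mask = P > policy.frac * pmax
    if mask.all():
        return 1
    return int(np.sum(mask & ~np.roll(mask, 1)))


@dataclass
class PhaseDiagram:
    """Grid of domain-count labels over the two control parameters.

    ``labels[i, j]`` is the steady-state domain count reached from the
    scenario's canonical (uniform) initial condition; ``coexist[i, j]``
    flags cells where the multistability panel found additional attractors
    with a different count.
    """

    alpha_grid: np.ndarray
    beta_grid: np.ndarray
    labels: np.ndarray  # (len(alpha_grid), len(beta_grid)) int
    coexist: np.ndarray  # same shape, bool
    converged: np.ndarray  # same shape, bool: all panel members met tol
    scenario: str = ""
    panel_counts: np.ndarray | None = None  # (na, nb, n_panel) raw counts

    def region_size(self, label: int) -> int:
        """Number of grid cells carrying ``label`` (COEXIST counts flags)."""
        if label == COEXIST:
            return int(np.sum(self.coexist))
        return int(np.sum(self.labels == label))

    def region_mask(self, label: int) -> np.ndarray:
        if label == COEXIST:
            return self.coexist.copy()
        return self.labels == label

    def to_table(self) -> list[dict]:
        out = []
        for i, a in enumerate(self.alpha_grid):
            for j, b in enumerate(self.beta_grid):
                out.append(
                    {
                        "alpha_over_l": float(a),
                        "beta_scaled": float(b),
                        "label": int(self.labels[i, j]),
                        "coexist": bool(self.coexist[i, j]),
                        "converged": bool(self.converged[i, j]),
                    }
                )
        return out


def _panel(scenario: Scenario, params: ModelParams, n: int):
    """Initial-condition panel: uniform + one biased bump per candidate site."""
    sites = scenario.preferred_sites(params, n)
    panel = [None]
    panel.extend((s, PANEL_BIAS_WIDTH, PANEL_BIAS_AMP) for s in sites)
    return panel


def _counts_for_rows(P_rows, policy) -> list[int]:
    return [count_domains(row, policy) for row in P_rows]


def classify_point(
    alpha_over_l: float,
    beta_scaled: float,
    scenario: Scenario,
    params: ModelParams,
    options: SolverOptions | None = None,
) -> int:
    """Domain-count label of one parameter point (canonical start).

    Runs the full initial-condition panel; returns the count reached from
    the uniform start.  Use :func:`sweep` to obtain the coexistence flag and
    per-member counts as well.
    """
    diagram = sweep(
        scenario,
        np.array([alpha_over_l]),
        np.array([beta_scaled]),
        params,
        options=options,
    )
    return int(diagram.labels[0, 0])


def sweep(
    scenario: Scenario,
    alpha_grid: np.ndarray,
    beta_grid: np.ndarray,
    params: ModelParams,
    options: SolverOptions | None = None,
    cache_dir: str | Path | None = None,
) -> PhaseDiagram:
    """Classify every (alpha/l, beta_scaled) grid cell for one scenario.

    All cells and panel members are integrated as one batch.  With
    ``cache_dir`` set, per-cell results are written as JSON and reused on a
    subsequent identical sweep (interrupted sweeps resume).
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    if alpha_grid.size == 0 or beta_grid.size == 0:
        raise ValueError("parameter grids must be nonempty")
    if np.any(np.diff(alpha_grid) < 0) or np.any(np.diff(beta_grid) < 0):
        raise ValueError("parameter grids must be sorted ascending")
    opts = options or SolverOptions(n=128, record=False)
    params = params.with_scales()
    policy = default_policy(params)
    panel = _panel(scenario, params, opts.n)
    npan = len(panel)
    na, nb = alpha_grid.size, beta_grid.size

    cache = None
    if cache_dir is not None:
        cache = Path(cache_dir)
        cache.mkdir(parents=True, exist_ok=True)

    def cell_key(a: float, b: float) -> str:
        blob = f"{scenario.name}|{a:.8g}|{b:.8g}|{opts.n}|{opts.t_max}|{npan}"
        return hashlib.sha1(blob.encode()).hexdigest()[:16]

    labels = np.zeros((na, nb), dtype=int)
    coex = np.zeros((na, nb), dtype=bool)
    conv = np.zeros((na, nb), dtype=bool)
    counts_out = np.zeros((na, nb, npan), dtype=int)
    todo: list[tuple[int, int]] = []
    for i in range(na):
        for j in range(nb):
            if cache is not None:
                f = cache / f"{cell_key(alpha_grid[i], beta_grid[j])}.json"
                if f.exists():
                    rec = json.loads(f.read_text())
                    labels[i, j] = rec["label"]
                    coex[i, j] = rec["coexist"]
                    conv[i, j] = rec["converged"]
                    counts_out[i, j] = rec["counts"]
                    continue
            todo.append((i, j))

    if todo:
        # assemble batch rows: cells x panel members
        A_rows, P_rows, Ac_rows, Pc_rows = [], [], [], []
        konP_rows, beta_rows = [], []
        prob_cache: dict[float, object] = {}
        patch = None
        decay = 300.0
        for (i, j) in todo:
            a, b = alpha_grid[i], beta_grid[j]
            p_ab = params.with_nondim(a, b)
            if a not in prob_cache:
                prob_cache[a] = p_ab, scenario.build(p_ab, opts.n)
            _, prob = prob_cache[a]
            patch = prob.trigger_patch
            decay = prob.trigger_decay
            for bias in panel:
                st = prob.initial_state(p_ab, bias=bias)
                A_rows.append(st.A)
                P_rows.append(st.P)
                Ac_rows.append(st.A_cyto)
                Pc_rows.append(st.P_cyto)
                konP_rows.append(prob.kon_P_profile)
                beta_rows.append(p_ab.beta)
        any_prob = next(iter(prob_cache.values()))[1]
        integ = CortexIntegrator(
            params,
            any_prob.dx,
            opts.n,
            np.asarray(konP_rows),
            beta=np.asarray(beta_rows),
            trigger_patch=patch,
            trigger_decay=decay,
            options=opts,
        )
        res = integ.run(
            np.asarray(A_rows),
            np.asarray(P_rows),
            np.asarray(Ac_rows),
            np.asarray(Pc_rows),
            blowup="retire",  # a diverging cell is recorded, not fatal
        )
        for m, (i, j) in enumerate(todo):
            sl = slice(m * npan, (m + 1) * npan)
            rows_conv = res["converged"][sl]
            rows_fail = res["failed"][sl]
            counts = []
            for r in range(m * npan, (m + 1) * npan):
                if res["failed"][r]:
                    counts.append(NONCONVERGED)
                    continue
                prof = res["P"][r] if res["converged"][r] else res["P_tail"][r]
                counts.append(count_domains(prof, policy))
            labels[i, j] = counts[0]  # canonical (uniform) start
            coex[i, j] = len({c for c in counts if c != NONCONVERGED}) > 1
            conv[i, j] = bool(np.all(rows_conv)) and not np.any(rows_fail)
            counts_out[i, j] = counts
            if cache is not None:
                f = cache / f"{cell_key(alpha_grid[i], beta_grid[j])}.json"
                f.write_text(
                    json.dumps(
                        {
                            "label": int(labels[i, j]),
                            "coexist": bool(coex[i, j]),
                            "converged": bool(conv[i, j]),
                            "counts": [int(c) for c in counts],
                        }
                    )
                )

    return PhaseDiagram(
        alpha_grid=alpha_grid,
        beta_grid=beta_grid,
        labels=labels,
        coexist=coex,
        converged=conv,
        scenario=scenario.name,
        panel_counts=counts_out,
    )
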