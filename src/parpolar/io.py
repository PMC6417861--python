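"""File formats: run configuration, kymograph tables, state tables, figures.

Kymographs are written as tab-separated tables with one row per time step,
the first column the time stamp and the remaining columns the arc-length
positions (given in a comment header).  Phase diagrams are written as long
tables (one row per grid cell).  All figures use the Agg backend.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .model import Kymograph, CortexState  # noqa: E402
from .phase import PhaseDiagram, COEXIST  # noqa: E402


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    except FileNotFoundError as e:
        raise ConfigError(f"config file not found: {path}") from e
    except yaml.YAMLError as e:
        raise ConfigError(f"malformed config {path}: {e}") from e
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def apply_overrides(cfg: dict, overrides: list[str]) -> dict:
    """Apply ``--set key.sub=value`` overrides (YAML-parsed values)."""
    out = json.loads(json.dumps(cfg))  # deep copy
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key=value")
        key, val = item.split("=", 1)
        node = out
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
            if not isinstance(node, dict):
                raise ConfigError(f"cannot descend into {part!r} in {key!r}")
        node[parts[-1]] = yaml.safe_load(val)
    return out


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# tables


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    header = (
        f"# kymograph quantity={kymo.quantity}\n"
        "# columns: time then values at the positions listed below\n"
        "# positions: " + " ".join(f"{p:.6g}" for p in kymo.positions) + "\n"
    )
    body = np.column_stack([kymo.times, kymo.values])
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, delimiter="\t", fmt="%.8g")


def read_kymograph(path: str | Path) -> Kymograph:
    positions = None
    quantity = "P"
    with open(path) as fh:
        for line in fh:
            if line.startswith("# positions:"):
                positions = np.array([float(v) for v in line.split(":", 1)[1].split()])
            elif line.startswith("# kymograph"):
                for tok in line.split():
                    if tok.startswith("quantity="):
                        quantity = tok.split("=", 1)[1]
            elif not line.startswith("#"):
                break
    data = np.loadtxt(path, delimiter="\t")
    data = np.atleast_2d(data)
    times, values = data[:, 0], data[:, 1:]
    if positions is None:
        positions = np.arange(values.shape[1], dtype=float)
    return Kymograph(values=values, times=times, positions=positions, quantity=quantity)


def write_state(state: CortexState, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# final state at t={state.t:.6g} s; columns: x A P v\n")
        np.savetxt(
            fh,
            np.column_stack([state.x, state.A, state.P, state.v]),
            delimiter="\t",
            fmt="%.8g",
        )


def write_phase_diagram(diagram: PhaseDiagram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# phase diagram scenario={diagram.scenario}\n")
        fh.write("alpha_over_l\tbeta_scaled\tlabel\tcoexist\tconverged\n")
        for rec in diagram.to_table():
            fh.write(
                f"{rec['alpha_over_l']:.8g}\t{rec['beta_scaled']:.8g}\t"
                f"{rec['label']}\t{int(rec['coexist'])}\t{int(rec['converged'])}\n"
            )


# ---------------------------------------------------------------------------
# figures


def render_kymograph(kymo: Kymograph, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    extent = [
        kymo.positions[0],
        kymo.positions[-1],
        kymo.times[-1] / 60.0,
        kymo.times[0] / 60.0,
    ]
    im = ax.imshow(kymo.values, aspect="auto", extent=extent, cmap="viridis")
    ax.set_xlabel("arc position (um)")
    ax.set_ylabel("time (min)")
    ax.set_title(title or f"{kymo.quantity} kymograph")
    fig.colorbar(im, ax=ax, label=kymo.quantity)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_phase_diagram(diagram: PhaseDiagram, path: str | Path) -> None:
    from matplotlib.colors import BoundaryNorm, ListedColormap

    cmap = ListedColormap(["#8c6d31", "#f7d154", "#9ecae1", "#3182bd"])
    norm = BoundaryNorm([-0.5, 0.5, 1.5, 2.5, 3.5], cmap.N)
    fig, ax = plt.subplots(figsize=(5.2, 4.2))
    im = ax.pcolormesh(
        diagram.beta_grid,
        diagram.alpha_grid,
        np.clip(diagram.labels, 0, 3),
        cmap=cmap,
        norm=norm,
        shading="nearest",
    )
    ys, xs = np.where(diagram.coexist)
    if ys.size:
        ax.plot(
            diagram.beta_grid[xs],
            diagram.alpha_grid[ys],
            "x",
            color="#31a354",
            ms=6,
            mew=2,
            label="coexistence",
        )
        ax.legend(loc="upper left", fontsize=8)
    ax.set_xscale("log")
    ax.set_xlabel(r"$\beta\tau/\rho P_0$")
    ax.set_ylabel(r"$\alpha/l$")
    ax.set_title(f"domain count: {diagram.scenario}")
    fig.colorbar(im, ax=ax, ticks=[0, 1, 2, 3], label="domains")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# manifest


def write_manifest(
    out_dir: str | Path,
    cfg: dict,
    outputs: list[str],
    seeds: dict | None = None,
) -> Path:
    from . import __version__

    manifest = {
        "config_hash": config_hash(cfg),
        "code_version": __version__,
        "seeds": seeds or {},
        "outputs": sorted(outputs),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
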