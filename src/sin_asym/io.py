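"""Tidy writers and plotting conveniences for trajectories and metrics."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .metrics import PhenotypeCall  # noqa: E402
from .simulate import Trajectory  # noqa: E402

__all__ = [
    "trajectory_to_frame",
    "write_trajectory",
    "metrics_row",
    "write_metrics",
    "plot_trajectory",
]

#: stable column order of the tidy trajectory table
TRAJECTORY_COLUMNS = ("time", "species", "compartment", "value", "event_phase")
METRIC_COLUMNS = ("run_id", "model", "phenotype", "asymmetry_time",
                  "sin_old", "sin_new", "byr4_old", "byr4_new", "ai_sin")


def _phase_labels(traj: Trajectory) -> np.ndarray:
    labels = np.zeros(len(traj.t), dtype=int)
    for k, (t_ev, _) in enumerate(traj.events, start=1):
        labels[traj.t >= t_ev] = k
    return labels


def trajectory_to_frame(traj: Trajectory,
                        compartments: tuple[str, ...] = ("old", "new", "cyt")
                        ) -> pd.DataFrame:
    """Long-format table: one row per (time, species, compartment)."""
    phases = _phase_labels(traj)
    rows = []
    for sp in traj.model.species:
        comps = compartments if sp in traj.model.mobile_species else ("old", "new")
        for comp in comps:
            series = traj.series(sp, comp)
            rows.append(pd.DataFrame({
                "time": traj.t,
                "species": sp,
                "compartment": comp,
                "value": series,
                "event_phase": phases,
            }))
    return pd.concat(rows, ignore_index=True)[list(TRAJECTORY_COLUMNS)]


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trajectory_to_frame(traj).to_csv(path, sep="\t", index=False,
                                     float_format="%.8g")
    return path


def metrics_row(run_id: str, model_id: str, call: PhenotypeCall) -> dict:
    d = call.diagnostics
    return {
        "run_id": run_id,
        "model": model_id,
        "phenotype": call.label,
        "asymmetry_time": call.asymmetry_time,
        "sin_old": d.get("sin_old"),
        "sin_new": d.get("sin_new"),
        "byr4_old": d.get("byr4_old"),
        "byr4_new": d.get("byr4_new"),
        "ai_sin": d.get("ai_sin"),
    }


def write_metrics(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=list(METRIC_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.8g")
    return path


def plot_trajectory(traj: Trajectory, path: str | Path,
                    species: tuple[str, ...] | None = None,
                    title: str = "") -> Path:
    """SPB time courses: solid for the old SPB, dashed for the new SPB."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if species is None:
        species = traj.model.mobile_species
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for c, sp in zip(colors, species):
        ax.plot(traj.t, traj.series(sp, "old"), color=c, label=f"{sp} old SPB")
        ax.plot(traj.t, traj.series(sp, "new"), color=c, linestyle="--",
                label=f"{sp} new SPB")
    for t_ev, kind in traj.events:
        ax.axvline(t_ev, color="grey", linestyle=":", linewidth=1)
    ax.set_xlabel("time (a.u.)")
    ax.set_ylabel("concentration (a.u.)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
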