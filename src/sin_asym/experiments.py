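"""Scripted end-to-end reproduction of each figure-level experiment.

Every recipe runs from packaged defaults, writes tidy TSVs (and a PNG
where a time course is the point), and checks the qualitative assertion
the corresponding experiment makes.  The returned bundle carries the
numbers; the ``passed`` flag distinguishes an assertion failure from a
runtime error (which raises).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import metrics_row, plot_trajectory, write_metrics, write_trajectory
from .metrics import (MULTINUCLEATE, MULTISEPTATE, WILDTYPE, asymmetry_index,
                      classify_phenotype, inflection_time)
from .models import get_model
from .scans import (apply_mutants, find_pitchfork, find_steady_states,
                    scan_parameter, symmetric_steady_states)
from .simulate import EventSpec, default_initial_state, integrate

__all__ = ["EXPERIMENTS", "run_experiment", "ExperimentResult"]

LOG2_GRID = tuple(float(2.0 ** e) for e in np.linspace(-2, 2, 9))


@dataclass
class ExperimentResult:
    name: str
    passed: bool
    summary: dict
    outputs: list


def _finish(name, outdir, passed, summary, outputs):
    return ExperimentResult(name, bool(passed), summary,
                            [str(p) for p in outputs])


def fig1b(outdir: Path) -> ExperimentResult:
    """Minimal model: a 0.1 % binding bias suffices to break symmetry."""
    model = get_model("minimal")
    p = model.default_params()          # k_bias = 0.001
    traj = integrate(model, p, t_end=600.0)
    call = classify_phenotype(traj)
    ai_x = asymmetry_index(traj, "X", traj.t[-1])
    outputs = [write_trajectory(traj, outdir / "fig1B_trajectory.tsv"),
               plot_trajectory(traj, outdir / "fig1B.png",
                               title="minimal model, 0.1% bias"),
               write_metrics([metrics_row("fig1B", "minimal", call)],
                             outdir / "fig1B_metrics.tsv")]
    passed = call.label == WILDTYPE and ai_x < -0.8   # X wins the old SPB
    return _finish("fig1B", outdir, passed,
                   {"phenotype": call.label, "ai_x": ai_x,
                    "asymmetry_time": call.asymmetry_time}, outputs)


def fig2a(outdir: Path) -> ExperimentResult:
    """Molecular model wild type: SIN to the new SPB, Byr4 to the old."""
    model = get_model("molecular")
    traj = integrate(model, model.default_params(), t_end=600.0)
    call = classify_phenotype(traj)
    fs = traj.final_state
    outputs = [write_trajectory(traj, outdir / "fig2A_trajectory.tsv"),
               plot_trajectory(traj, outdir / "fig2A.png",
                               title="molecular model, wild type"),
               write_metrics([metrics_row("fig2A", "molecular", call)],
                             outdir / "fig2A_metrics.tsv")]
    passed = (call.label == WILDTYPE
              and fs.get("SIN", "new") > fs.get("SIN", "old")
              and fs.get("Byr4", "old") > fs.get("Byr4", "new"))
    return _finish("fig2A", outdir, passed,
                   {"phenotype": call.label,
                    "asymmetry_time": call.asymmetry_time,
                    "sin_new": fs.get("SIN", "new"),
                    "byr4_old": fs.get("Byr4", "old")}, outputs)


def fig2be(outdir: Path) -> ExperimentResult:
    """Molecular model total-level scans and their terminal phenotypes."""
    model = get_model("molecular")
    frames = []
    for param in ("sin_total", "byr4_total", "cdc11_per_spb", "e_pp"):
        res = scan_parameter(model, param, LOG2_GRID, t_end=1500.0)
        frames.append(res.to_frame())
    table = pd.concat(frames, ignore_index=True)
    out = outdir / "fig2BE_scans.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, sep="\t", index=False, float_format="%.8g")

    def label(param, mult):
        row = table[(table.param == param) & np.isclose(table.multiplier, mult)]
        return row.phenotype.iloc[0]

    passed = (label("sin_total", 2.0) == MULTISEPTATE
              and label("sin_total", 0.5) == MULTINUCLEATE
              and label("byr4_total", 2.0) == MULTINUCLEATE
              and label("sin_total", 1.0) == WILDTYPE)
    return _finish("fig2BE", outdir, passed,
                   {"sin_x2": label("sin_total", 2.0),
                    "sin_x05": label("sin_total", 0.5),
                    "byr4_x2": label("byr4_total", 2.0)}, [out])


def fig3bc(outdir: Path) -> ExperimentResult:
    """Extended model: terminal Cdc11 phosphoform composition per SPB."""
    model = get_model("extended")
    traj = integrate(model, model.default_params(), t_end=800.0)
    call = classify_phenotype(traj)
    fs = traj.final_state
    u_old = fs.get("Cdc11U", "old")
    cp_old = fs.get("Cdc11CP", "old")
    sin_phos_new = fs.get("Cdc11SP", "new") + fs.get("Cdc11PP", "new")
    outputs = [write_trajectory(traj, outdir / "fig3BC_trajectory.tsv"),
               plot_trajectory(traj, outdir / "fig3BC.png",
                               title="extended model, wild type"),
               write_metrics([metrics_row("fig3BC", "extended", call)],
                             outdir / "fig3BC_metrics.tsv")]
    passed = (call.label == WILDTYPE
              and abs(u_old - 0.75) < 0.10 and abs(cp_old - 0.25) < 0.10
              and sin_phos_new > 0.5)
    return _finish("fig3BC", outdir, passed,
                   {"u_old_frac": u_old, "cp_old_frac": cp_old,
                    "sin_phos_new_frac": sin_phos_new,
                    "asymmetry_time": call.asymmetry_time}, outputs)


def fig4ab(outdir: Path) -> ExperimentResult:
    """Extended model: kinase/phosphatase efficiency scans (Byr4_old timing)."""
    model = get_model("extended")
    frames = []
    for param in ("e_sin", "e_cdk", "e_ppc", "e_pps"):
        res = scan_parameter(model, param, LOG2_GRID, t_end=1500.0,
                             timing_species="Byr4", timing_compartment="old")
        frames.append(res.to_frame())
    table = pd.concat(frames, ignore_index=True)
    out = outdir / "fig4AB_scans.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, sep="\t", index=False, float_format="%.8g")

    def row(param, mult):
        r = table[(table.param == param) & np.isclose(table.multiplier, mult)]
        return r.phenotype.iloc[0], r.asymmetry_time.iloc[0]

    wt_label, wt_t = row("e_sin", 1.0)
    s5a_label, s5a_t = row("e_sin", 0.5)
    cdk_ok = all(
        row("e_cdk", m)[0] == WILDTYPE
        and abs(row("e_cdk", m)[1] - wt_t) / wt_t < 0.05
        for m in (0.25, 0.5))
    ppc_ok = all(row("e_ppc", m)[0] == WILDTYPE for m in (1.0, 2.0, 4.0))
    passed = (wt_label == WILDTYPE and s5a_label == WILDTYPE
              and s5a_t < wt_t and cdk_ok and ppc_ok
              and row("e_sin", 0.25)[0] == MULTINUCLEATE)
    return _finish("fig4AB", outdir, passed,
                   {"wt_time": wt_t, "s5a_time": s5a_t,
                    "cdk_insensitive": cdk_ok, "ppc_no_phenotype": ppc_ok},
                   [out])


def _mutant_time(model, names, t_end=4000.0):
    p = apply_mutants(model.default_params(), names)
    traj = integrate(model, p, t_end=t_end, n_points=4001)
    call = classify_phenotype(traj, timing_species="Byr4",
                              timing_compartment="old")
    return call.label, call.asymmetry_time


def fig5a(outdir: Path) -> ExperimentResult:
    """cdc16-116 at 36C and its predicted compensation by cdc11 phosphomutants."""
    model = get_model("extended")
    rows = []
    times = {}
    for tag, names in [("cdc16-116@36", ["cdc16-116@36"]),
                       ("cdc16-116@36 cdc11-S5A", ["cdc16-116@36", "cdc11-S5A"]),
                       ("cdc16-116@36 cdc11-S8A", ["cdc16-116@36", "cdc11-S8A"]),
                       ("wild type", [])]:
        label, t = _mutant_time(model, names)
        times[tag] = t
        rows.append({"genotype": tag, "phenotype": label, "asymmetry_time": t})
    out = outdir / "fig5A_mutants.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, float_format="%.8g")
    t16 = times["cdc16-116@36"]
    t5 = times["cdc16-116@36 cdc11-S5A"]
    t8 = times["cdc16-116@36 cdc11-S8A"]
    twt = times["wild type"]
    passed = (None not in (t16, t5, t8, twt)
              and t5 < t8 < t16 and t16 > twt)
    return _finish("fig5A", outdir, passed, {k: v for k, v in times.items()},
                   [out])


def fig5c(outdir: Path) -> ExperimentResult:
    """Additivity of cdc16-ts and SIP loss; compensation by phosphomutants."""
    model = get_model("extended")
    rows = []
    times = {}
    for tag, names in [("wild type", []),
                       ("cdc16-ts", ["cdc16-ts(mild)"]),
                       ("csc1D", ["csc1D"]),
                       ("cdc16-ts csc1D", ["cdc16-ts(mild)", "csc1D"]),
                       ("cdc16-ts csc1D cdc11-S5A",
                        ["cdc16-ts(mild)", "csc1D", "cdc11-S5A"]),
                       ("cdc16-ts csc1D cdc11-S8A",
                        ["cdc16-ts(mild)", "csc1D", "cdc11-S8A"])]:
        label, t = _mutant_time(model, names, t_end=3000.0)
        times[tag] = t
        rows.append({"genotype": tag, "phenotype": label, "asymmetry_time": t})
    out = outdir / "fig5C_mutants.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, float_format="%.8g")
    passed = (None not in times.values()
              and times["cdc16-ts csc1D"] > times["cdc16-ts"]
              and times["cdc16-ts csc1D"] > times["csc1D"]
              and times["cdc16-ts csc1D cdc11-S5A"] < times["cdc16-ts csc1D"]
              and times["cdc16-ts csc1D cdc11-S8A"] <= times["cdc16-ts csc1D"])
    return _finish("fig5C", outdir, passed, {k: v for k, v in times.items()},
                   [out])


def fig6a(outdir: Path) -> ExperimentResult:
    """Laser ablation of the new SPB: SIN re-activates at the old SPB."""
    model = get_model("molecular")
    traj = integrate(model, model.default_params(), t_end=2000.0,
                     events=[EventSpec(200.0, "ablate_new_spb")])
    pre = traj.state_at(199.0)
    fs = traj.final_state
    outputs = [write_trajectory(traj, outdir / "fig6A_trajectory.tsv"),
               plot_trajectory(traj, outdir / "fig6A.png",
                               title="new-SPB ablation at t=200")]
    passed = (pre.get("SIN", "old") < 0.1 and pre.get("Byr4", "old") > 0.5
              and fs.get("SIN", "old") > 0.5 and fs.get("Byr4", "old") < 0.3)
    return _finish("fig6A", outdir, passed,
                   {"sin_old_pre": pre.get("SIN", "old"),
                    "sin_old_final": fs.get("SIN", "old"),
                    "byr4_old_final": fs.get("Byr4", "old")}, outputs)


def fig6b(outdir: Path, induction_rate: float = 0.01) -> ExperimentResult:
    """Byr4 induction with separated vs non-separated SPBs."""
    model = get_model("molecular")
    p = model.default_params()
    results = {}
    outputs = []
    for tag, events in [
            ("separated", [EventSpec(200.0, "separate_cytoplasm"),
                           EventSpec(200.0, "induce_byr4",
                                     {"rate": induction_rate})]),
            ("non-separated", [EventSpec(200.0, "induce_byr4",
                                         {"rate": induction_rate})])]:
        traj = integrate(model, p, t_end=1500.0, events=events)
        s = traj.series("SIN", "new")
        mask = (s < 0.3) & (traj.t > 200.0)
        results[tag] = float(traj.t[mask][0]) if mask.any() else None
        outputs.append(write_trajectory(
            traj, outdir / f"fig6B_{tag.replace('-', '_')}.tsv"))
        outputs.append(plot_trajectory(
            traj, outdir / f"fig6B_{tag.replace('-', '_')}.png",
            title=f"Byr4 induction, {tag}"))
    sep, non = results["separated"], results["non-separated"]
    passed = sep is not None and (non is None or sep < non)
    return _finish("fig6B", outdir, passed,
                   {"sin_new_off_separated": sep,
                    "sin_new_off_non_separated": non}, outputs)


def figs1(outdir: Path) -> ExperimentResult:
    """Extended-model level scans and the Byr4:SIN crossover of the
    early-mitotic state (more SPB-bound Byr4 than SIN above ~2.5x Byr4)."""
    model = get_model("extended")
    frames = []
    for param in ("sin_total", "byr4_total", "cdc11_per_spb"):
        res = scan_parameter(model, param, LOG2_GRID, t_end=1500.0)
        frames.append(res.to_frame())
    table = pd.concat(frames, ignore_index=True)
    out = outdir / "figS1_scans.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, sep="\t", index=False, float_format="%.8g")

    base = model.default_params()

    def bound_gap(mult):
        st = default_initial_state(model, base.scaled("byr4_total", mult))
        return ((st.get("Byr4", "old") + st.get("Byr4", "new"))
                - (st.get("SIN", "old") + st.get("SIN", "new")))

    crossover = brentq(bound_gap, 0.5, 20.0, xtol=1e-6)
    passed = 2.0 < crossover < 3.0
    return _finish("figS1", outdir, passed,
                   {"byr4_crossover_multiplier": crossover}, [out])


def figs2(outdir: Path) -> ExperimentResult:
    """Minimal-model symmetric steady states: pitchfork structure."""
    model = get_model("minimal")
    grid = [0.5, 0.75, 1.0, 1.25, 1.5, 2.0]
    branches = symmetric_steady_states(model, "x_total", grid, n_starts=40)
    rows = []
    for b in branches:
        for v, st in zip(b.control_values, b.states):
            rows.append({
                "control_param": b.control_param,
                "multiplier": v,
                "symmetry": b.symmetry,
                "stable": st.stable,
                "x_old": st.state.get("X", "old"),
                "x_new": st.state.get("X", "new"),
                "residual": st.residual,
            })
    out = outdir / "figS2_steady_states.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False, float_format="%.8g")

    p0 = model.default_params().updated(k_bias=0.0)
    wt_states = find_steady_states(model, p0)
    n_sym_unstable = sum(1 for s in wt_states
                         if s.symmetry == "symmetric" and not s.stable)
    n_asym_stable = sum(1 for s in wt_states
                        if s.symmetry != "symmetric" and s.stable)
    pf = find_pitchfork(branches)
    passed = (len(wt_states) == 3 and n_sym_unstable == 1
              and n_asym_stable == 2 and pf is not None)
    return _finish("figS2", outdir, passed,
                   {"n_steady_states_wt": len(wt_states),
                    "pitchfork_bracket": pf}, [out])


EXPERIMENTS: dict[str, Callable[[Path], ExperimentResult]] = {
    "fig1B": fig1b,
    "fig2A": fig2a,
    "fig2BE": fig2be,
    "fig3BC": fig3bc,
    "fig4AB": fig4ab,
    "fig5A": fig5a,
    "fig5C": fig5c,
    "fig6A": fig6a,
    "fig6B": fig6b,
    "figS1": figs1,
    "figS2": figs2,
}


def run_experiment(name: str, outdir: str | Path = "results") -> ExperimentResult:
    """Run one named figure-level experiment, writing outputs under ``outdir``."""
    if name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; known: {sorted(EXPERIMENTS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return EXPERIMENTS[name](outdir)
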