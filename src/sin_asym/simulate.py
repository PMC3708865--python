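"""Time integration with mid-run events (ablation, separation, induction).

Simulations start at the metaphase-anaphase transition and run in arbitrary
time units.  Events are applied by stop-modify-restart: integration halts at
the event time, the state and/or parameter set is transformed discretely,
and integration resumes with the new configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .models import (
    MINIMAL,
    MOBILE_COMPARTMENTS,
    CompartmentState,
    ModelDefinition,
    ParameterSet,
    _cdc11_square,
    byr4_gate,
    gk_switch,
)

__all__ = [
    "EventSpec",
    "Trajectory",
    "IntegrationError",
    "default_initial_state",
    "integrate",
    "apply_event",
]

EVENT_KINDS = ("ablate_new_spb", "separate_cytoplasm", "induce_byr4",
               "scale_parameter")


class IntegrationError(RuntimeError):
    """Raised when the solver fails or produces a non-finite state."""

    def __init__(self, message: str, time: float, params: ParameterSet):
        super().__init__(f"{message} (t={time:g})")
        self.time = time
        self.params = params


@dataclass(frozen=True)
class EventSpec:
    """A discrete mid-run perturbation.

    kind ∈ {ablate_new_spb, separate_cytoplasm, induce_byr4,
    scale_parameter}; payload keys depend on the kind (``spill_frac``,
    ``split_frac``, ``rate``, ``name``/``multiplier``).
    """

    time: float
    kind: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class Trajectory:
    """Dense solution of one run: time grid, state matrix, event log."""

    model: ModelDefinition
    t: np.ndarray                     # (n,), strictly increasing
    y: np.ndarray                     # (n_state, n)
    params: ParameterSet              # parameter snapshot at t_end
    events: list = field(default_factory=list)        # (time, kind)
    phase_params: list = field(default_factory=list)  # (t_start, ParameterSet)

    def series(self, species: str, compartment: str) -> np.ndarray:
        if compartment == "cyt":
            i = self.model.index(species, "cyt_old")
            return self.y[i] + self.y[i + 1]
        return self.y[self.model.index(species, compartment)]

    def state_at(self, t: float) -> CompartmentState:
        if not (self.t[0] <= t <= self.t[-1]):
            raise ValueError(f"t={t} outside trajectory span")
        vals = np.array([np.interp(t, self.t, row) for row in self.y])
        return CompartmentState(self.model, vals)

    @property
    def final_state(self) -> CompartmentState:
        return CompartmentState(self.model, self.y[:, -1].copy())


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def _binding_equilibrium(total: float, r_old: float, r_new: float
                         ) -> tuple[float, float, float]:
    """Partition a mobile species between the SPBs and the cytoplasm.

    ``r`` is the ratio of effective on-rate (per cytoplasmic half-pool) to
    effective off-rate at each SPB; with equilibrated half-pools the bound
    amount at an SPB is ``r/2`` times the total cytoplasmic amount.
    Returns (bound_old, bound_new, cyt_total).
    """
    cyt = total / (1.0 + 0.5 * (r_old + r_new))
    return 0.5 * r_old * cyt, 0.5 * r_new * cyt, cyt


def _mitotic_square(p: ParameterSet) -> tuple[float, float, float, float]:
    """Metaphase steady state of the four-form Cdc11 square at one SPB.

    Uses the frozen metaphase activities (high Cdk, nascent SIN-site
    phosphorylation), so the distribution is Cdk-phosphorylated dominant.
    """
    ct = p.cdc11_per_spb

    def resid(v):
        U, CP, SP = v
        PP = ct - U - CP - SP
        dU, dCP, dSP, _ = _cdc11_square(
            U, CP, SP, PP, p.mito_cdk, p.mito_sin, p.mito_ppc, p.mito_pps, p)
        return [dU, dCP, dSP]

    guess = [0.2 * ct, 0.7 * ct, 0.05 * ct]
    sol = root(resid, guess, method="hybr", tol=1e-12)
    U, CP, SP = np.clip(sol.x, 0.0, ct)
    PP = max(ct - U - CP - SP, 0.0)
    return float(U), float(CP), float(SP), float(PP)


def default_initial_state(model: ModelDefinition, params: ParameterSet
                          ) -> CompartmentState:
    """Metaphase-anaphase transition state for the given parameters.

    SIN (or X) sits predominantly and symmetrically on the SPBs at its
    binding equilibrium (the GAP-driven removal is inactive before
    anaphase); Byr4 (or Y) is low but strictly nonzero at both SPBs, at
    the binding equilibrium allowed by the metaphase Cdc11 phosphoform
    distribution; Cdc11 is mostly phosphorylated, reflecting the mitotic
    kinase history.
    """
    params.validate()
    p = params
    y = np.zeros(model.n_state)

    if model.model_id == MINIMAL:
        r_o = p.k_on_x * (1.0 + p.k_bias) * p.gate_old / p.k_off_x
        r_n = p.k_on_x * p.gate_new / p.k_off_x
        Xo, Xn, Xc = _binding_equilibrium(p.x_total, r_o, r_n)
        r_o = p.k_on_y * p.gate_old / p.k_off_y
        r_n = p.k_on_y * p.gate_new / p.k_off_y
        Yo_eq, Yn_eq, _ = _binding_equilibrium(p.y_total, r_o, r_n)
        Yo = p.y_init_frac * Yo_eq
        Yn = p.y_init_frac * Yn_eq
        Yc = p.y_total - Yo - Yn
        y[:] = [Xo, Xn, 0.5 * Xc, 0.5 * Xc, Yo, Yn, 0.5 * Yc, 0.5 * Yc]
        return CompartmentState(model, y)

    # molecular / extended: SIN binding equilibrium (no GAP removal yet)
    r_s_o = p.k_on_sin * p.gate_old / p.k_off_sin
    r_s_n = p.k_on_sin * p.gate_new / p.k_off_sin
    So, Sn, Sc = _binding_equilibrium(p.sin_total, r_s_o, r_s_n)

    ct = p.cdc11_per_spb
    if model.model_id == MINIMAL:  # pragma: no cover - handled above
        raise AssertionError
    if len(model.form_species) == 2:
        # two-form model: lumped metaphase kinase vs phosphatase balance
        u0 = gk_switch(p.mito_pp, p.mito_kin, p.J_pp, p.J_sin)
        forms_old = forms_new = (u0 * ct, (1.0 - u0) * ct)
    else:
        U, CP, SP, PP = _mitotic_square(p)
        u0 = U / ct if ct > 0 else 0.0
        forms_old = forms_new = (U, CP, SP, PP)

    off_eff = p.k_off_byr4 + p.k_boff * (1.0 - u0)
    gate = byr4_gate(u0, p)
    r_b_o = p.k_on_byr4 * (1.0 + p.k_bias) * p.gate_old * gate / off_eff
    r_b_n = p.k_on_byr4 * p.gate_new * gate / off_eff
    Bo, Bn, Bc = _binding_equilibrium(p.byr4_total, r_b_o, r_b_n)

    i = model.index("SIN", "old")
    y[i:i + 4] = [So, Sn, 0.5 * Sc, 0.5 * Sc]
    i = model.index("Byr4", "old")
    y[i:i + 4] = [Bo, Bn, 0.5 * Bc, 0.5 * Bc]
    nf = len(model.form_species)
    i = model.index(model.form_species[0], "old")
    y[i:i + nf] = forms_old
    i = model.index(model.form_species[0], "new")
    y[i:i + nf] = forms_new
    return CompartmentState(model, y)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def apply_event(state: CompartmentState, params: ParameterSet, event: EventSpec
                ) -> tuple[CompartmentState, ParameterSet]:
    """Apply one discrete event, returning the transformed state/parameters."""
    model = state.model
    s = state.copy()
    y = s.values
    if event.kind == "ablate_new_spb":
        spill = float(event.payload.get("spill_frac", 1.0))
        for sp in model.mobile_species:
            i_new = model.index(sp, "new")
            i_cyb = model.index(sp, "cyt_new")
            y[i_cyb] += spill * y[i_new]
            y[i_new] = 0.0
        for sp in model.form_species:
            y[model.index(sp, "new")] = 0.0
        params = params.updated(gate_new=0.0)
    elif event.kind == "separate_cytoplasm":
        if params.k_diff == 0.0:
            raise ValueError("cytoplasm already separated")
        f = float(event.payload.get("split_frac", 0.5))
        for sp in model.mobile_species:
            i = model.index(sp, "cyt_old")
            tot = y[i] + y[i + 1]
            y[i] = f * tot
            y[i + 1] = (1.0 - f) * tot
        params = params.updated(k_diff=0.0)
    elif event.kind == "induce_byr4":
        params = params.updated(k_syn=float(event.payload["rate"]))
    elif event.kind == "scale_parameter":
        params = params.scaled(event.payload["name"],
                               float(event.payload["multiplier"]))
    else:  # pragma: no cover - EventSpec already validates
        raise ValueError(f"unknown event kind {event.kind!r}")
    return s, params


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate(model: ModelDefinition,
              params: ParameterSet,
              init: CompartmentState | None = None,
              t_end: float = 600.0,
              events: Sequence[EventSpec] = (),
              method: str = "LSODA",
              rtol: float = 1e-8,
              atol: float = 1e-10,
              n_points: int = 2001) -> Trajectory:
    """Integrate one model over [0, t_end] with optional mid-run events.

    Output is dense (``n_points`` uniformly spaced samples plus the event
    times) so that inflection-point detection downstream has adequate
    resolution.  Identical inputs give bitwise-identical trajectories.
    """
    params.validate()
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if init is None:
        init = default_initial_state(model, params)
    if init.model.model_id != model.model_id:
        raise ValueError("initial state does not match the model layout")
    times = [e.time for e in events]
    if any(not (0.0 < et < t_end) for et in times):
        raise ValueError("event times must lie strictly inside (0, t_end)")
    if sorted(times) != times:
        raise ValueError("events must be sorted by time")

    grid = np.linspace(0.0, t_end, n_points)
    boundaries = [0.0, *times, t_end]

    t_out: list[np.ndarray] = []
    y_out: list[np.ndarray] = []
    log: list[tuple[float, str]] = []
    phase_params: list[tuple[float, ParameterSet]] = [(0.0, params)]
    y0 = init.values.copy()
    p = params

    for k in range(len(boundaries) - 1):
        t0, t1 = boundaries[k], boundaries[k + 1]
        if t1 > t0:
            pts = grid[(grid > t0) & (grid < t1)]
            t_eval = np.concatenate(([t0], pts, [t1]))
            sol = solve_ivp(lambda t, y: model.rhs(y, p), (t0, t1), y0,
                            method=method, t_eval=t_eval, rtol=rtol, atol=atol)
            if not sol.success or not np.all(np.isfinite(sol.y)):
                raise IntegrationError(
                    f"integration failed for model {model.model_id!r}: "
                    f"{sol.message}", t1, p)
            last = len(sol.t) if k == len(boundaries) - 2 else len(sol.t) - 1
            t_out.append(sol.t[:last])
            y_out.append(sol.y[:, :last])
            y0 = sol.y[:, -1].copy()
        # t1 == t0: simultaneous events, apply the next one immediately
        if k < len(events):
            ev = events[k]
            st, p = apply_event(CompartmentState(model, y0), p, ev)
            y0 = st.values
            log.append((ev.time, ev.kind))
            phase_params.append((ev.time, p))

    t = np.concatenate(t_out)
    y = np.concatenate(y_out, axis=1)
    return Trajectory(model=model, t=t, y=y, params=p, events=log,
                      phase_params=phase_params)
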