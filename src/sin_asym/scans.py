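"""Parameter scans, in-silico mutants, and symmetric steady-state analysis.

Total-level and efficiency scans reproduce the sensitivity analyses of the
asymmetry-establishment models: each grid point multiplies one parameter
(wild type = 1), re-derives the metaphase initial state, simulates, and
records the asymmetry time and terminal phenotype.  The mutant catalog
maps named fission-yeast alleles onto parameter transforms (composable
multiplicatively for double/triple mutants).  Symmetric steady states and
the pitchfork bifurcation are located by multi-start root finding on the
shared-cytoplasm reduced system with ``k_bias`` forced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from .models import (
    EXTENDED,
    MINIMAL,
    MOLECULAR,
    CompartmentState,
    ModelDefinition,
    ParameterSet,
)
from .metrics import classify_phenotype, PhenotypeCall
from .simulate import IntegrationError, default_initial_state, integrate

__all__ = [
    "ScanResult",
    "SteadyState",
    "SteadyStateBranch",
    "scan_parameter",
    "mutant_catalog",
    "apply_mutants",
    "reduced_rhs",
    "find_steady_states",
    "symmetric_steady_states",
    "find_pitchfork",
]


# ---------------------------------------------------------------------------
# parameter scans
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Outcome of a one-parameter multiplier scan."""

    model_id: str
    param: str
    multipliers: np.ndarray
    asymmetry_times: list          # float | None per point
    calls: list                    # PhenotypeCall | None per point
    errors: dict = field(default_factory=dict)   # index -> message

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.multipliers):
            call = self.calls[i]
            rows.append({
                "model": self.model_id,
                "param": self.param,
                "multiplier": float(m),
                "log2_multiplier": float(np.log2(m)),
                "phenotype": None if call is None else call.label,
                "asymmetry_time": self.asymmetry_times[i],
                "error": self.errors.get(i),
            })
        return pd.DataFrame(rows)


def scan_parameter(model: ModelDefinition,
                   param: str,
                   multipliers: Sequence[float],
                   base: ParameterSet | None = None,
                   t_end: float = 800.0,
                   timing_species: str | None = None,
                   timing_compartment: str | None = None,
                   **integrate_kw) -> ScanResult:
    """Simulate one run per multiplier of ``param`` and score each run.

    The initial state is re-derived from the scaled parameter set at every
    grid point, so total-level scans start from the correspondingly scaled
    metaphase state while efficiency scans share the wild-type metaphase
    history (the ``mito_*`` activities are frozen).  Integration failures
    are recorded per point, not fatal to the scan.
    """
    mults = np.asarray(list(multipliers), dtype=float)
    if np.any(np.diff(mults) <= 0):
        raise ValueError("multiplier grid must be strictly increasing")
    if base is None:
        base = model.default_params()
    times: list = []
    calls: list = []
    errors: dict[int, str] = {}
    for i, m in enumerate(mults):
        p = base.scaled(param, float(m))
        try:
            traj = integrate(model, p, t_end=t_end, **integrate_kw)
            call = classify_phenotype(traj, timing_species=timing_species,
                                      timing_compartment=timing_compartment)
            calls.append(call)
            times.append(call.asymmetry_time)
        except (IntegrationError, ValueError) as exc:
            errors[i] = str(exc)
            calls.append(None)
            times.append(None)
    return ScanResult(model.model_id, param, mults, times, calls, errors)


# ---------------------------------------------------------------------------
# mutant catalog
# ---------------------------------------------------------------------------

#: named alleles as multiplicative parameter transforms
_MUTANTS: dict[str, dict[str, float]] = {
    # cdc16 temperature-sensitive alleles act through the Byr4-Cdc16 GAP
    # efficiency on SIN removal
    "cdc16-116@36": {"k_soff": 0.2},
    "cdc16-ts(mild)": {"k_soff": 0.5},
    # SIP complex loss: both hypothetical phosphatases at 75 %
    "csc1D": {"e_ppc": 0.75, "e_pps": 0.75},
    # SIN (Sid2) phosphosite removal on Cdc11: half SIN efficiency
    "cdc11-S5A": {"e_sin": 0.5},
    # Cdk phosphosite removal on Cdc11
    "cdc11-S8A": {"e_cdk": 0.0},
}
_ALIASES = {
    "csc1Δ": "csc1D",          # csc1Δ
    "cdc16-ts-mild": "cdc16-ts(mild)",
}


def mutant_catalog() -> dict[str, dict[str, float]]:
    """Named mutants as parameter->multiplier transforms (wild type = 1)."""
    return {name: dict(tf) for name, tf in _MUTANTS.items()}


def apply_mutants(params: ParameterSet, names: Sequence[str]) -> ParameterSet:
    """Compose one or more mutant transforms multiplicatively."""
    p = params
    for raw in names:
        name = _ALIASES.get(raw, raw)
        if name not in _MUTANTS:
            raise KeyError(f"unknown mutant {raw!r}; known: {sorted(_MUTANTS)}")
        for param, mult in _MUTANTS[name].items():
            p = p.scaled(param, mult)
    return p


# ---------------------------------------------------------------------------
# reduced system and steady states
# ---------------------------------------------------------------------------

def _reduced_layout(model: ModelDefinition) -> tuple[list[int], list[str]]:
    """Indices of the independent variables of the shared-cytoplasm system.

    SPB-bound pools of the mobile species plus all-but-one phosphoform per
    SPB; cytoplasm follows from conservation and the fast-diffusion limit
    (equal half-pools), the last phosphoform from the per-SPB Cdc11 pool.
    """
    idx: list[int] = []
    names: list[str] = []
    for sp in model.mobile_species:
        for comp in ("old", "new"):
            idx.append(model.index(sp, comp))
            names.append(f"{sp}_{comp}")
    nf = len(model.form_species)
    for comp in ("old", "new"):
        for sp in model.form_species[:-1]:
            idx.append(model.index(sp, comp))
            names.append(f"{sp}_{comp}")
    return idx, names


def _expand(model: ModelDefinition, v: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Full state vector from reduced variables (equal cytoplasm halves)."""
    y = np.zeros(model.n_state)
    idx, _ = _reduced_layout(model)
    y[idx] = v
    totals = {sp: tot for sp, tot in
              zip(("X", "Y"), (p.x_total, p.y_total))} if model.model_id == MINIMAL \
        else {"SIN": p.sin_total, "Byr4": p.byr4_total}
    for sp in model.mobile_species:
        bound = y[model.index(sp, "old")] + y[model.index(sp, "new")]
        cyt = totals[sp] - bound
        y[model.index(sp, "cyt_old")] = 0.5 * cyt
        y[model.index(sp, "cyt_new")] = 0.5 * cyt
    if model.form_species:
        last = model.form_species[-1]
        for comp in ("old", "new"):
            others = sum(y[model.index(sp, comp)]
                         for sp in model.form_species[:-1])
            y[model.index(last, comp)] = p.cdc11_per_spb - others
    return y


def reduced_rhs(model: ModelDefinition, v: np.ndarray, p: ParameterSet
                ) -> np.ndarray:
    """Time derivatives of the reduced variables on the fast-diffusion manifold."""
    idx, _ = _reduced_layout(model)
    return model.rhs(_expand(model, v, p), p)[idx]


@dataclass
class SteadyState:
    """One steady state of the reduced system with its stability."""

    state: CompartmentState
    residual: float
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool
    symmetry: str       # "symmetric" | "asymmetric-upper" | "asymmetric-lower"


@dataclass
class SteadyStateBranch:
    """Steady states sharing a symmetry tag along a control-parameter grid."""

    symmetry: str
    control_param: str
    control_values: list = field(default_factory=list)
    states: list = field(default_factory=list)       # SteadyState
    stability: list = field(default_factory=list)    # bool


def _fd_jacobian(fun: Callable[[np.ndarray], np.ndarray], v: np.ndarray,
                 eps: float = 1e-7) -> np.ndarray:
    f0 = fun(v)
    J = np.empty((len(f0), len(v)))
    for j in range(len(v)):
        dv = v.copy()
        h = eps * max(1.0, abs(v[j]))
        dv[j] += h
        J[:, j] = (fun(dv) - f0) / h
    return J


def _start_points(model: ModelDefinition, p: ParameterSet, n_starts: int,
                  seed: int = 0) -> list[np.ndarray]:
    """Deterministic multi-start grid spanning the conserved-pool simplex."""
    idx, names = _reduced_layout(model)
    totals = []
    for name in names:
        sp = name.rsplit("_", 1)[0]
        if sp in ("X",):
            totals.append(p.x_total)
        elif sp in ("Y",):
            totals.append(p.y_total)
        elif sp == "SIN":
            totals.append(p.sin_total)
        elif sp == "Byr4":
            totals.append(p.byr4_total)
        else:
            totals.append(p.cdc11_per_spb)
    totals = np.array(totals)
    rng = np.random.default_rng(seed)
    starts = []
    first = model.mobile_species[0]
    # handcrafted corners: symmetric splits plus the two antagonistic
    # extremes (first species at one SPB, everything else at the other)
    for fo, fn in ((0.45, 0.45), (0.3, 0.3), (0.05, 0.05)):
        v = np.empty(len(names))
        for j, name in enumerate(names):
            v[j] = totals[j] * (fo if name.endswith("_old") else fn)
        starts.append(v)
    for hi, lo in ((0.85, 0.05), (0.6, 0.1)):
        v = np.empty(len(names))
        for j, name in enumerate(names):
            sp, comp = name.rsplit("_", 1)
            at_old = comp == "old"
            # the antagonist(s) pile up opposite the first species
            heavy = at_old if sp == first else not at_old
            v[j] = totals[j] * (hi if heavy else lo)
        starts.append(v)
        starts.append(v[_swap_perm_reduced(model)])
    while len(starts) < n_starts:
        u = rng.random(len(names))
        starts.append(0.9 * totals * u / (1.0 + u.sum() / len(u)))
    return starts[:n_starts]


def _swap_perm_reduced(model: ModelDefinition) -> np.ndarray:
    _, names = _reduced_layout(model)
    perm = []
    for name in names:
        sp, comp = name.rsplit("_", 1)
        other = f"{sp}_{'new' if comp == 'old' else 'old'}"
        perm.append(names.index(other))
    return np.array(perm)


def find_steady_states(model: ModelDefinition,
                       params: ParameterSet,
                       n_starts: int = 60,
                       dedup_tol: float = 1e-6,
                       residual_tol: float = 1e-9,
                       marginal_tol: float = 1e-7,
                       seed: int = 0) -> list[SteadyState]:
    """All steady states of the shared-cytoplasm system, with stability.

    Multi-start root finding from a deterministic grid over the
    conserved-pool simplex; solutions are deduplicated at ``dedup_tol``
    (max-norm) and classified by the eigenvalues of a finite-difference
    Jacobian of the reduced dynamics.
    """
    fun = lambda v: reduced_rhs(model, v, params)  # noqa: E731
    swap = _swap_perm_reduced(model)
    found: list[np.ndarray] = []
    for v0 in _start_points(model, params, n_starts, seed):
        sol = root(fun, v0, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        v = sol.x
        if np.any(v < -1e-9):
            continue
        y = _expand(model, v, params)
        if np.any(y < -1e-9):
            continue
        if np.max(np.abs(fun(v))) > residual_tol:
            continue
        v = np.clip(v, 0.0, None)
        # the swap image of a root is a root by the exchange symmetry
        # (exact when k_bias = 0; polish it when the bias breaks the tie)
        candidates = [v]
        vs = v[swap]
        if np.max(np.abs(fun(vs))) > residual_tol:
            pol = root(fun, vs, method="hybr", tol=1e-12)
            vs = pol.x if pol.success else None
        if vs is not None and np.max(np.abs(fun(vs))) <= residual_tol \
                and np.all(vs > -1e-9):
            candidates.append(np.clip(vs, 0.0, None))
        for w in candidates:
            if any(np.max(np.abs(w - u)) < dedup_tol for u in found):
                continue
            found.append(w)
    out: list[SteadyState] = []
    for v in found:
        J = _fd_jacobian(fun, v)
        lam = np.linalg.eigvals(J)
        lead = float(np.max(lam.real))
        stable = lead < -marginal_tol
        marginal = abs(lead) <= marginal_tol
        if np.max(np.abs(v - v[swap])) < dedup_tol:
            tag = "symmetric"
        else:
            sin_old = v[0]
            sin_new = v[1]
            tag = "asymmetric-upper" if sin_old > sin_new else "asymmetric-lower"
        out.append(SteadyState(
            state=CompartmentState(model, _expand(model, v, params)),
            residual=float(np.max(np.abs(fun(v)))),
            eigenvalues=lam,
            stable=stable,
            marginal=marginal,
            symmetry=tag,
        ))
    return out


def symmetric_steady_states(model: ModelDefinition,
                            control_param: str,
                            multipliers: Sequence[float],
                            base: ParameterSet | None = None,
                            n_starts: int = 60,
                            **kwargs) -> list[SteadyStateBranch]:
    """Steady-state branches along a control parameter with ``k_bias = 0``.

    The bias is forced to zero so the system is exactly symmetric under
    the old/new SPB exchange; asymmetric states then come in mirror pairs
    and the symmetric branch loses stability at the pitchfork.
    """
    if base is None:
        base = model.default_params()
    base = replace(base, k_bias=0.0)
    branches: dict[str, SteadyStateBranch] = {}
    for m in multipliers:
        p = base.scaled(control_param, float(m))
        states = find_steady_states(model, p, n_starts=n_starts, **kwargs)
        for st in states:
            br = branches.setdefault(
                st.symmetry,
                SteadyStateBranch(st.symmetry, control_param))
            br.control_values.append(float(m))
            br.states.append(st)
            br.stability.append(st.stable)
    return list(branches.values())


def find_pitchfork(branches: Sequence[SteadyStateBranch]
                   ) -> tuple[float, float] | None:
    """Bracket of the pitchfork along the control grid.

    Returns the adjacent control values ``(stable_side, broken_side)``
    straddling the loss of stability of the symmetric branch, provided
    the asymmetric mirror pair is present on the unstable side; ``None``
    when the grid does not straddle such a point.
    """
    sym = next((b for b in branches if b.symmetry == "symmetric"), None)
    if sym is None:
        return None
    values = sorted(set(v for b in branches for v in b.control_values))
    asym_count = {v: 0 for v in values}
    for b in branches:
        if b.symmetry != "symmetric":
            for v in b.control_values:
                asym_count[v] += 1
    sym_stable = {v: False for v in values}
    for v, s in zip(sym.control_values, sym.stability):
        sym_stable[v] = sym_stable[v] or s
    for a, b in zip(values[:-1], values[1:]):
        if sym_stable[a] != sym_stable[b]:
            stable_side, broken_side = (a, b) if sym_stable[a] else (b, a)
            if asym_count[broken_side] >= 2:
                return (stable_side, broken_side)
    return None
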