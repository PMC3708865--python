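"""Trajectory metrics: asymmetry timing, asymmetry index, phenotype calls.

Asymmetry-establishment time is the inflection point of a sigmoid-like
transition curve (e.g. Byr4 at the old SPB, or SIN at the new SPB), i.e.
the time of maximum absolute slope.  The terminal phenotype mirrors the
fission-yeast failure modes: SIN collapse at both SPBs corresponds to a
multinucleate-like outcome (no division), SIN hyperactivation / failure of
Byr4 to establish corresponds to a multiseptate-like outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .simulate import Trajectory

__all__ = [
    "PhenotypeCall",
    "inflection_time",
    "asymmetry_index",
    "classify_phenotype",
    "WILDTYPE",
    "MULTINUCLEATE",
    "MULTISEPTATE",
]

WILDTYPE = "wildtype_asymmetric"
MULTINUCLEATE = "multinucleate_like"
MULTISEPTATE = "multiseptate_like"


@dataclass
class PhenotypeCall:
    """Terminal classification of one run."""

    label: str
    asymmetry_time: float | None = None
    diagnostics: dict = field(default_factory=dict)


def inflection_time(traj: Trajectory, species: str, compartment: str,
                    min_amplitude: float = 0.05,
                    settle_frac: float = 0.1,
                    refine: int = 10) -> float | None:
    """Time of the inflection point of a sigmoid-like transition curve.

    The transition of interest is the one that carries the curve to its
    final plateau; fast relaxation transients just after anaphase onset
    (or after an event) are not part of it.  The curve is interpolated
    with a monotone cubic (PCHIP), which cannot introduce spurious
    oscillations between samples; the inflection is the maximum slope
    towards the final value within the contiguous stretch that contains
    the last crossing of the half-amplitude level, located on a
    ``refine``-times finer grid.

    Returns ``None`` for flat curves (total range below ``min_amplitude``,
    in absolute concentration units) and for transitions that have not
    settled by ``t_end`` (terminal slope above ``settle_frac`` times the
    peak slope).
    """
    c = traj.series(species, compartment)
    t = traj.t
    if float(c.max() - c.min()) < min_amplitude:
        return None
    c0, c1 = float(c[0]), float(c[-1])
    sign = 1.0 if c1 >= c0 else -1.0
    interp = PchipInterpolator(t, c)
    dinterp = interp.derivative()
    tf = np.linspace(t[0], t[-1], refine * len(t))
    cf = interp(tf)
    slope = sign * dinterp(tf)  # positive where moving towards the plateau

    mid = 0.5 * (c0 + c1)
    above = sign * (cf - mid) > 0.0
    if not above.any() or above.all():
        return None  # no crossing of the half-amplitude level
    i_mid = int(len(above) - np.argmax(above[::-1] == False))  # noqa: E712
    if i_mid >= len(tf):
        i_mid = len(tf) - 1
    # contiguous stretch around the last crossing where the curve still
    # moves towards the plateau
    moving = slope > 0.0
    lo = i_mid
    while lo > 0 and moving[lo - 1]:
        lo -= 1
    hi = i_mid
    while hi < len(tf) - 1 and moving[hi + 1]:
        hi += 1
    window = slope[lo:hi + 1]
    if window.size == 0:
        return None
    i = lo + int(np.argmax(window))
    peak = float(slope[i])
    if peak <= 0.0:
        return None
    if abs(float(dinterp(t[-1]))) > settle_frac * peak:
        return None  # transition incomplete at t_end
    return float(tf[i])


def asymmetry_index(traj: Trajectory, species: str, t: float) -> float:
    """(s_new - s_old) / (s_new + s_old) at time t; 0 for two empty pools.

    +1 means the species is entirely at the new SPB, -1 entirely at the
    old SPB; antisymmetric under relabelling the SPBs.
    """
    st = traj.state_at(t)
    s_old = st.get(species, "old")
    s_new = st.get(species, "new")
    tot = s_old + s_new
    if tot == 0.0:
        return 0.0
    return (s_new - s_old) / tot


def classify_phenotype(traj: Trajectory,
                       ai_threshold: float = 0.8,
                       low_frac: float = 0.10,
                       high_frac: float = 0.25,
                       timing_species: str | None = None,
                       timing_compartment: str | None = None) -> PhenotypeCall:
    """Call the terminal phenotype of a completed run.

    wildtype_asymmetric
        the transition completed (inflection found) and the terminal SIN
        asymmetry index exceeds ``ai_threshold`` in magnitude;
    multinucleate_like
        SIN inactivation at both SPBs: SIN below ``low_frac`` of its total
        at both SPBs, or Byr4 established (above ``high_frac``) at both;
    multiseptate_like
        SIN hyperactive: SIN high at both SPBs (each above ``high_frac``
        of total) or Byr4 fails to establish at either SPB.

    Timing defaults to the inflection of the Byr4-like species at the SPB
    where it ends up highest (the old SPB in a wild-type run).
    """
    model = traj.model
    sin = model.sin_like
    byr = model.byr4_like
    t_end = float(traj.t[-1])
    st = traj.final_state
    s_tot = max(st.total(sin), 1e-300)
    b_tot = max(st.total(byr), 1e-300)
    s_old, s_new = st.get(sin, "old"), st.get(sin, "new")
    b_old, b_new = st.get(byr, "old"), st.get(byr, "new")
    ai_sin = asymmetry_index(traj, sin, t_end)

    if timing_species is None:
        timing_species = byr
        timing_compartment = "old" if b_old >= b_new else "new"
    t_asym = inflection_time(traj, timing_species, timing_compartment)

    diag = {
        "sin_old": s_old, "sin_new": s_new,
        "byr4_old": b_old, "byr4_new": b_new,
        "ai_sin": ai_sin,
    }
    s_hi = max(s_old, s_new) / s_tot
    s_lo = min(s_old, s_new) / s_tot
    b_hi = max(b_old, b_new) / b_tot
    b_lo = min(b_old, b_new) / b_tot

    if t_asym is not None and abs(ai_sin) >= ai_threshold \
            and s_hi >= low_frac and b_hi >= low_frac:
        return PhenotypeCall(WILDTYPE, asymmetry_time=t_asym, diagnostics=diag)
    if s_hi < low_frac or b_lo > high_frac:
        return PhenotypeCall(MULTINUCLEATE, diagnostics=diag)
    if b_hi < low_frac or s_lo > high_frac:
        return PhenotypeCall(MULTISEPTATE, diagnostics=diag)
    # unresolved transition with both antagonists still on the SPBs: the
    # run sits on the delayed flank of a scan; side with the dominant
    # antagonist decides the call
    if b_new + b_old > s_new + s_old:
        return PhenotypeCall(MULTINUCLEATE, diagnostics=diag)
    return PhenotypeCall(MULTISEPTATE, diagnostics=diag)
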