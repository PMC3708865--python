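"""Synthetic inputs: noisy initial conditions, bias variants, ensembles.

Symmetry breaking needs a seed — either a deterministic binding bias at
the old SPB or a little noise in the initial SPB-bound amounts.  This
module generates both, reproducibly: multiplicative log-normal noise on
the SPB-bound pools (cytoplasm adjusted to conserve totals) and replicate
ensembles with independent per-replicate sub-seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import CompartmentState, ModelDefinition, ParameterSet, get_model
from .simulate import default_initial_state

__all__ = ["EnsembleSpec", "noisy_initial_conditions", "ensemble"]


@dataclass(frozen=True)
class EnsembleSpec:
    """Reproducible recipe for a replicate ensemble.

    ``sigma`` is the log-scale standard deviation of the multiplicative
    noise applied to every SPB-bound pool of the initial state (for small
    sigma this is the relative noise amplitude); ``bias`` is the k_bias
    value shared by all replicates.
    """

    model_id: str
    n_replicates: int
    sigma: float = 0.0
    bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def noisy_initial_conditions(base: CompartmentState,
                             sigma: float,
                             seed: int | np.random.Generator) -> CompartmentState:
    """Perturb every SPB-bound pool by independent log-normal factors.

    Mobile species keep their totals exactly: the net amount added to the
    SPB pools is removed from the cytoplasm (split equally over the two
    half-pools).  Immobile Cdc11 phosphoforms are left untouched — their
    per-SPB pools are conserved and the mobile pools carry the symmetry
    breaking.  Deterministic under a fixed seed; ``sigma = 0`` returns an
    identical copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = base.copy()
    if sigma == 0.0:
        return out
    model = base.model
    for sp in model.mobile_species:
        delta = 0.0
        for comp in ("old", "new"):
            i = model.index(sp, comp)
            factor = float(np.exp(sigma * rng.standard_normal()))
            new_val = out.values[i] * factor
            delta += new_val - out.values[i]
            out.values[i] = new_val
        ia = model.index(sp, "cyt_old")
        ib = model.index(sp, "cyt_new")
        cyt = out.values[ia] + out.values[ib]
        if cyt - delta < 0.0:
            raise ValueError(
                f"noise sigma={sigma} would drive the {sp} cytoplasm pool "
                "negative; reduce sigma or the bound fraction")
        out.values[ia] -= 0.5 * delta
        out.values[ib] -= 0.5 * delta
    return out


def ensemble(spec: EnsembleSpec,
             base_params: ParameterSet | None = None
             ) -> list[tuple[int, ParameterSet, CompartmentState]]:
    """Replicate configurations: (replicate index, parameters, initial state).

    Each replicate draws its noise from an independent child of the spec
    seed (`numpy` ``SeedSequence.spawn``), so ensembles are reproducible
    as a whole and replicates are independent of each other.
    """
    model = get_model(spec.model_id)
    if base_params is None:
        base_params = model.default_params()
    params = replace(base_params, k_bias=spec.bias)
    base_state = default_initial_state(model, params)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        state = noisy_initial_conditions(base_state, spec.sigma, rng)
        out.append((i, params, state))
    return out
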