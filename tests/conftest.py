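"""Shared fixtures: models, default parameters, cached wild-type runs."""

from __future__ import annotations

import numpy as np
import pytest

from sin_asym import default_parameters, get_model, integrate
from sin_asym.models import MODEL_IDS


@pytest.fixture(params=MODEL_IDS)
def model(request):
    return get_model(request.param)


@pytest.fixture(scope="session")
def wt_trajectories():
    """One wild-type run per model, shared across the suite."""
    out = {}
    for mid in MODEL_IDS:
        m = get_model(mid)
        out[mid] = integrate(m, default_parameters(mid), t_end=800.0)
    return out


def random_states(model, n, seed=0, zero_frac=0.0):
    """Random admissible states: non-negative, conserved totals.

    ``zero_frac`` empties a random subset of pools (boundary states),
    renormalising the remainder so the conserved totals still hold.
    """
    p = default_parameters(model.model_id)
    rng = np.random.default_rng(seed)
    totals = model.conserved_totals(p)
    states = []
    for _ in range(n):
        y = np.zeros(model.n_state)
        for pool, idx in model.pool_indices.items():
            w = rng.random(len(idx))
            if zero_frac > 0.0:
                w[rng.random(len(idx)) < zero_frac] = 0.0
            s = w.sum()
            if s == 0.0:
                w[0] = 1.0
                s = 1.0
            y[idx] = totals[pool] * w / s
        states.append(y)
    return states
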