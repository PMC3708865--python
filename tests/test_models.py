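"""Structural properties of the three right-hand sides."""

import numpy as np
import pytest

from sin_asym import default_parameters, get_model, integrate
from sin_asym.models import byr4_gate

from conftest import random_states


def test_exchange_symmetry_without_bias(model):
    """With k_bias = 0 the RHS commutes with the old/new SPB swap."""
    p = default_parameters(model.model_id).updated(k_bias=0.0)
    perm = model.swap_perm
    for y in random_states(model, 100, seed=11):
        d = model.rhs(y, p)
        d_swapped = model.rhs(y[perm], p)
        assert np.array_equal(d[perm], d_swapped)


def test_conserved_pool_derivatives_sum_to_zero(model):
    p = default_parameters(model.model_id)
    for y in random_states(model, 50, seed=7):
        d = model.rhs(y, p)
        for pool, idx in model.pool_indices.items():
            assert abs(d[idx].sum()) < 1e-13, pool


def test_no_flux_out_of_empty_pools(model):
    """Boundary states: a pool at zero never has a negative derivative."""
    p = default_parameters(model.model_id)
    for y in random_states(model, 60, seed=3, zero_frac=0.4):
        d = model.rhs(y, p)
        zero = y == 0.0
        assert np.all(d[zero] >= -1e-12)


def test_absent_species_stays_absent_minimal():
    """No spontaneous creation: Y empty everywhere keeps all Y rates at 0."""
    model = get_model("minimal")
    p = default_parameters("minimal")
    rng = np.random.default_rng(5)
    for _ in range(100):
        y = np.zeros(model.n_state)
        x = rng.random(4)
        y[model.pool_indices["X"]] = p.x_total * x / x.sum()
        d = model.rhs(y, p)
        assert np.all(d[model.pool_indices["Y"]] == 0.0)


def test_phosphorylated_cdc11_blocks_byr4_binding():
    """Fully phosphorylated Cdc11 at an SPB shuts Byr4 binding off there."""
    model = get_model("molecular")
    p = default_parameters("molecular")
    y = np.zeros(model.n_state)
    y[model.index("SIN", "old")] = 0.3
    y[model.index("Byr4", "cyt_old")] = 0.4
    y[model.index("Byr4", "cyt_new")] = 0.4
    y[model.index("Byr4", "old")] = 0.1
    y[model.index("Cdc11P", "old")] = p.cdc11_per_spb  # no U at the old SPB
    y[model.index("Cdc11U", "new")] = p.cdc11_per_spb
    d = model.rhs(y, p)
    # old-SPB Byr4 derivative is pure (enhanced) unbinding, no binding term
    expected = -(p.k_off_byr4 + p.k_boff) * 0.1
    assert d[model.index("Byr4", "old")] == pytest.approx(expected, rel=1e-12)


def test_no_sin_drives_cdc11_to_unphosphorylated():
    """Without SIN the lumped phosphatase returns all Cdc11 to the U form."""
    model = get_model("molecular")
    p = default_parameters("molecular").updated(sin_total=0.0)
    init = np.zeros(model.n_state)
    init[model.index("Byr4", "cyt_old")] = 0.5
    init[model.index("Byr4", "cyt_new")] = 0.5
    init[model.index("Cdc11P", "old")] = 1.0
    init[model.index("Cdc11P", "new")] = 1.0
    traj = integrate(model, p, model.state(init), t_end=200.0,
                     method="Radau", rtol=1e-10, atol=1e-12)
    fs = traj.final_state
    assert fs.get("Cdc11U", "old") == pytest.approx(1.0, abs=1e-6)
    assert fs.get("Cdc11U", "new") == pytest.approx(1.0, abs=1e-6)


def test_no_kinases_collapse_square_to_u():
    """Extended model with both kinases off: only dephosphorylation remains."""
    model = get_model("extended")
    p = default_parameters("extended").updated(e_cdk=0.0, e_sin=0.0)
    init = np.zeros(model.n_state)
    for comp in ("old", "new"):
        init[model.index("Cdc11CP", comp)] = 0.4
        init[model.index("Cdc11SP", comp)] = 0.3
        init[model.index("Cdc11PP", comp)] = 0.3
    traj = integrate(model, p, model.state(init), t_end=400.0,
                     method="Radau", rtol=1e-10, atol=1e-12)
    fs = traj.final_state
    for comp in ("old", "new"):
        assert fs.get("Cdc11U", comp) == pytest.approx(1.0, abs=1e-6)


def test_byr4_gate_limits():
    p0 = default_parameters("molecular")          # gate_sat = 0: power law
    assert byr4_gate(0.0, p0) == 0.0
    assert byr4_gate(1.0, p0) == 1.0
    p1 = default_parameters("extended")           # saturating gate
    assert byr4_gate(0.0, p1) == 0.0
    assert byr4_gate(1.0, p1) == pytest.approx(1.0)
    u = np.linspace(0, 1, 30)
    g = [byr4_gate(x, p1) for x in u]
    assert all(b >= a for a, b in zip(g, g[1:]))


def test_parameter_validation():
    p = default_parameters("molecular")
    with pytest.raises(ValueError):
        p.updated(k_soff=-1.0).validate()
    with pytest.raises(ValueError):
        p.updated(J_sin=0.0).validate()
    with pytest.raises(KeyError):
        p.scaled("not_a_parameter", 2.0)


def test_state_layout_and_swap(model):
    p = default_parameters(model.model_id)
    y = random_states(model, 1, seed=1)[0]
    st = model.state(y)
    sp = model.mobile_species[0]
    assert st.get(sp, "cyt") == pytest.approx(
        st.get(sp, "cyt_old") + st.get(sp, "cyt_new"))
    sw = st.swapped()
    assert sw.get(sp, "old") == st.get(sp, "new")
    assert sw.swapped().values == pytest.approx(st.values)
    with pytest.raises(ValueError):
        model.state(y[:-1])
    with pytest.raises(KeyError):
        st.get("nonexistent", "old")
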