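"""Integration, initial conditions and mid-run events."""

import dataclasses

import numpy as np
import pytest

from sin_asym import (EventSpec, apply_event, default_initial_state,
                      default_parameters, get_model, integrate)


class TestDefaultInitialState:
    def test_byr4_present_but_low_at_both_spbs(self, model):
        p = default_parameters(model.model_id)
        st = default_initial_state(model, p)
        byr = model.byr4_like
        sin = model.sin_like
        for comp in ("old", "new"):
            assert st.get(byr, comp) > 0.0
            assert st.get(byr, comp) < st.get(sin, comp)

    def test_symmetric_without_bias(self, model):
        p = default_parameters(model.model_id).updated(k_bias=0.0)
        st = default_initial_state(model, p)
        assert st.values == pytest.approx(st.swapped().values, abs=1e-14)

    def test_totals_match_parameters(self, model):
        p = default_parameters(model.model_id)
        st = default_initial_state(model, p)
        for pool, total in model.conserved_totals(p).items():
            idx = model.pool_indices[pool]
            assert st.values[idx].sum() == pytest.approx(total, rel=1e-12)

    def test_sin_predominantly_spb_bound(self, model):
        p = default_parameters(model.model_id)
        st = default_initial_state(model, p)
        sin = model.sin_like
        bound = st.get(sin, "old") + st.get(sin, "new")
        assert bound > 2 * st.get(sin, "cyt")


class TestIntegrate:
    def test_symmetric_configuration_never_breaks_symmetry(self):
        """No bias, no noise: the swap-symmetric manifold is invariant.

        Checked with an explicit solver over ten times the wild-type
        asymmetry time; the pitchfork instability would amplify any
        asymmetry the integrator injected.
        """
        model = get_model("minimal")
        p = default_parameters("minimal").updated(k_bias=0.0)
        traj = integrate(model, p, t_end=1100.0, method="RK45")
        asym = np.abs(traj.y - traj.y[model.swap_perm, :])
        assert float(asym.max()) < 1e-9

    def test_bitwise_determinism(self):
        model = get_model("molecular")
        p = default_parameters("molecular")
        t1 = integrate(model, p, t_end=300.0)
        t2 = integrate(model, p, t_end=300.0)
        assert np.array_equal(t1.y, t2.y) and np.array_equal(t1.t, t2.t)

    def test_conservation_drift_below_1e6(self, model):
        p = default_parameters(model.model_id)
        traj = integrate(model, p, t_end=800.0)
        for pool, total in model.conserved_totals(p).items():
            idx = model.pool_indices[pool]
            drift = np.abs(traj.y[idx, :].sum(axis=0) - total) / total
            assert float(drift.max()) < 1e-6, pool

    def test_time_rescaling_invariance(self):
        """Halving every rate constant and doubling t_end rescales time."""
        model = get_model("minimal")
        p = default_parameters("minimal")
        rates = ("k_on_x", "k_off_x", "k_on_y", "k_off_y", "k_xy", "k_yx",
                 "k_diff")
        slow = dataclasses.replace(
            p, **{r: 0.5 * getattr(p, r) for r in rates})
        fast_traj = integrate(model, p, t_end=400.0, rtol=1e-10, atol=1e-12)
        slow_traj = integrate(model, slow, t_end=800.0, rtol=1e-10,
                              atol=1e-12)
        for t in (50.0, 150.0, 333.0):
            a = fast_traj.state_at(t).values
            b = slow_traj.state_at(2 * t).values
            assert a == pytest.approx(b, abs=1e-6)

    def test_dense_output_and_event_grid(self):
        model = get_model("molecular")
        p = default_parameters("molecular")
        traj = integrate(model, p, t_end=100.0, n_points=1001,
                         events=[EventSpec(30.0, "scale_parameter",
                                           {"name": "k_soff",
                                            "multiplier": 1.0})])
        assert len(traj.t) >= 1001
        assert np.all(np.diff(traj.t) > 0)
        assert traj.t[0] == 0.0 and traj.t[-1] == 100.0
        assert traj.events == [(30.0, "scale_parameter")]

    def test_rejects_bad_event_times(self):
        model = get_model("minimal")
        p = default_parameters("minimal")
        with pytest.raises(ValueError):
            integrate(model, p, t_end=100.0,
                      events=[EventSpec(150.0, "induce_byr4", {"rate": 1.0})])


class TestEvents:
    def test_ablation_moves_content_and_conserves(self):
        model = get_model("molecular")
        p = default_parameters("molecular")
        traj = integrate(model, p, t_end=400.0,
                         events=[EventSpec(200.0, "ablate_new_spb")])
        # after ablation: new-SPB pools empty, mobile totals conserved in
        # (old SPB + cytoplasm), Cdc11 removed from the new SPB
        fs = traj.final_state
        assert fs.get("SIN", "new") == 0.0
        assert fs.get("Byr4", "new") == 0.0
        assert fs.get("Cdc11U", "new") == 0.0
        sin_left = fs.get("SIN", "old") + fs.get("SIN", "cyt")
        assert sin_left == pytest.approx(p.sin_total, rel=1e-6)

    def test_partial_spill_destroys_remainder(self):
        model = get_model("molecular")
        p = default_parameters("molecular")
        st = default_initial_state(model, p)
        new_sin = st.get("SIN", "new")
        out, p2 = apply_event(st, p, EventSpec(
            1.0, "ablate_new_spb", {"spill_frac": 0.25}))
        assert out.get("SIN", "new") == 0.0
        assert out.total("SIN") == pytest.approx(
            p.sin_total - 0.75 * new_sin)
        assert p2.gate_new == 0.0

    def test_separation_splits_cytoplasm_and_cuts_exchange(self):
        model = get_model("molecular")
        p = default_parameters("molecular")
        st = default_initial_state(model, p)
        out, p2 = apply_event(st, p, EventSpec(
            1.0, "separate_cytoplasm", {"split_frac": 0.7}))
        assert p2.k_diff == 0.0
        tot = st.get("SIN", "cyt")
        assert out.get("SIN", "cyt_old") == pytest.approx(0.7 * tot)
        with pytest.raises(ValueError):
            apply_event(out, p2, EventSpec(2.0, "separate_cytoplasm"))

    def test_byr4_induction_grows_total(self):
        model = get_model("molecular")
        p = default_parameters("molecular")
        traj = integrate(model, p, t_end=300.0,
                         events=[EventSpec(100.0, "induce_byr4",
                                           {"rate": 0.02})])
        fs = traj.final_state
        assert fs.total("Byr4") == pytest.approx(
            p.byr4_total + 0.02 * 200.0, rel=1e-6)

    def test_unknown_event_kind_rejected(self):
        with pytest.raises(ValueError):
            EventSpec(1.0, "teleport_spb")
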