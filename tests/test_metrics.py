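"""Asymmetry timing, asymmetry index and phenotype classification."""

import numpy as np
import pytest

from sin_asym import (WILDTYPE, asymmetry_index, classify_phenotype,
                      default_parameters, get_model, inflection_time,
                      integrate)
from sin_asym.simulate import Trajectory


def synthetic_trajectory(curve, t_end=100.0, n=1001):
    """Wrap an analytic old-SPB curve of the minimal model's X species."""
    model = get_model("minimal")
    t = np.linspace(0.0, t_end, n)
    y = np.zeros((model.n_state, n))
    y[model.index("X", "old")] = curve(t)
    return Trajectory(model=model, t=t, y=y,
                      params=default_parameters("minimal"))


class TestInflectionTime:
    def test_logistic_midpoint(self):
        traj = synthetic_trajectory(lambda t: 1.0 / (1.0 + np.exp(-(t - 50))))
        t_inf = inflection_time(traj, "X", "old")
        assert t_inf == pytest.approx(50.0, abs=0.1)

    def test_falling_logistic_midpoint(self):
        traj = synthetic_trajectory(lambda t: 1.0 / (1.0 + np.exp(t - 40)))
        assert inflection_time(traj, "X", "old") == pytest.approx(40.0,
                                                                  abs=0.1)

    def test_flat_curve_returns_none(self):
        traj = synthetic_trajectory(lambda t: np.full_like(t, 0.7))
        assert inflection_time(traj, "X", "old") is None

    def test_incomplete_transition_returns_none(self):
        traj = synthetic_trajectory(
            lambda t: 1.0 / (1.0 + np.exp(-(t - 99) / 3.0)), t_end=100.0)
        assert inflection_time(traj, "X", "old") is None

    def test_early_transient_is_ignored(self):
        """A fast relaxation bump must not masquerade as the transition."""
        def curve(t):
            bump = 0.25 * np.exp(-t / 2.0)
            return 0.2 + bump + 0.6 / (1.0 + np.exp(-(t - 60) / 3.0))
        traj = synthetic_trajectory(curve)
        assert inflection_time(traj, "X", "old") == pytest.approx(60.0,
                                                                  abs=1.0)

    def test_matches_finite_difference_oracle_on_wildtype(self):
        """PCHIP inflection vs centred differences on a 10x finer grid."""
        model = get_model("extended")
        p = default_parameters("extended")
        coarse = integrate(model, p, t_end=300.0, n_points=1001)
        fine = integrate(model, p, t_end=300.0, n_points=10001)
        t_pchip = inflection_time(coarse, "Byr4", "old")
        c = fine.series("Byr4", "old")
        slope = np.gradient(c, fine.t)
        # oracle restricted to the transition (after the binding transient)
        mask = fine.t > 10.0
        t_fd = float(fine.t[mask][np.argmax(slope[mask])])
        assert t_pchip == pytest.approx(t_fd, rel=0.02)

    def test_invariant_under_grid_refinement(self):
        model = get_model("molecular")
        p = default_parameters("molecular")
        t_a = inflection_time(integrate(model, p, t_end=300.0,
                                        n_points=1001), "Byr4", "old")
        t_b = inflection_time(integrate(model, p, t_end=300.0,
                                        n_points=4001), "Byr4", "old")
        assert t_a == pytest.approx(t_b, abs=0.3)


class TestAsymmetryIndex:
    def test_trivial_values(self):
        model = get_model("minimal")
        t = np.linspace(0, 10, 11)
        y = np.zeros((model.n_state, 11))
        y[model.index("X", "old")] = 0.4
        y[model.index("X", "new")] = 0.4
        traj = Trajectory(model=model, t=t, y=y,
                          params=default_parameters("minimal"))
        assert asymmetry_index(traj, "X", 5.0) == 0.0
        assert asymmetry_index(traj, "Y", 5.0) == 0.0  # both pools empty
        y[model.index("X", "old")] = 0.0
        assert asymmetry_index(traj, "X", 5.0) == 1.0

    def test_antisymmetric_under_relabelling(self, wt_trajectories):
        traj = wt_trajectories["molecular"]
        swapped = Trajectory(model=traj.model, t=traj.t,
                             y=traj.y[traj.model.swap_perm, :],
                             params=traj.params)
        for t in (10.0, 100.0, 700.0):
            assert asymmetry_index(traj, "SIN", t) == pytest.approx(
                -asymmetry_index(swapped, "SIN", t))

    def test_wildtype_terminal_separation(self, wt_trajectories):
        traj = wt_trajectories["molecular"]
        t_end = float(traj.t[-1])
        assert asymmetry_index(traj, "SIN", t_end) > 0.9
        assert asymmetry_index(traj, "Byr4", t_end) < -0.9


class TestClassifyPhenotype:
    def test_wildtype_for_every_model(self, wt_trajectories):
        for mid, traj in wt_trajectories.items():
            call = classify_phenotype(traj)
            assert call.label == WILDTYPE, mid
            assert call.asymmetry_time is not None
            assert call.asymmetry_time <= traj.t[-1]
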