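"""Scans, mutant transforms, and steady-state / pitchfork analysis."""

import numpy as np
import pytest

from sin_asym import default_parameters, get_model, integrate
from sin_asym.scans import (apply_mutants, find_pitchfork, find_steady_states,
                            mutant_catalog, reduced_rhs, scan_parameter,
                            symmetric_steady_states)


class TestScanParameter:
    def test_result_table_shape_and_wildtype_point(self):
        model = get_model("molecular")
        res = scan_parameter(model, "sin_total", [0.5, 1.0, 2.0],
                             t_end=1500.0)
        df = res.to_frame()
        assert list(df.multiplier) == [0.5, 1.0, 2.0]
        assert (df.param == "sin_total").all()
        wt = df[df.multiplier == 1.0].iloc[0]
        assert wt.phenotype == "wildtype_asymmetric"

    def test_rejects_non_increasing_grid(self):
        with pytest.raises(ValueError):
            scan_parameter(get_model("minimal"), "x_total", [1.0, 1.0, 2.0])

    def test_asymmetry_delay_monotone_in_gap_efficiency(self):
        """Deeper cdc16 defect (smaller k_soff) never speeds asymmetry."""
        model = get_model("extended")
        res = scan_parameter(model, "k_soff", [0.2, 0.35, 0.5, 1.0],
                             t_end=4000.0, n_points=4001,
                             timing_species="Byr4", timing_compartment="old")
        times = res.asymmetry_times
        assert all(t is not None for t in times)
        assert all(a >= b for a, b in zip(times, times[1:]))


class TestMutantCatalog:
    def test_catalog_contents(self):
        cat = mutant_catalog()
        assert cat["cdc16-116@36"] == {"k_soff": 0.2}
        assert cat["cdc16-ts(mild)"] == {"k_soff": 0.5}
        assert cat["csc1D"] == {"e_ppc": 0.75, "e_pps": 0.75}
        assert cat["cdc11-S5A"] == {"e_sin": 0.5}
        assert cat["cdc11-S8A"] == {"e_cdk": 0.0}

    def test_transforms_compose_multiplicatively(self):
        p = default_parameters("extended")
        q = apply_mutants(p, ["cdc16-ts(mild)", "csc1D", "csc1D"])
        assert q.k_soff == pytest.approx(0.5 * p.k_soff)
        assert q.e_ppc == pytest.approx(0.75 * 0.75 * p.e_ppc)

    def test_unknown_mutant_rejected(self):
        with pytest.raises(KeyError):
            apply_mutants(default_parameters("extended"), ["wee1-50"])


class TestSteadyStates:
    def test_bistable_regime_has_exactly_three_states(self):
        model = get_model("minimal")
        p = default_parameters("minimal").updated(k_bias=0.0)
        states = find_steady_states(model, p)
        assert len(states) == 3
        by_tag = {s.symmetry: s for s in states}
        assert not by_tag["symmetric"].stable
        assert by_tag["asymmetric-upper"].stable
        assert by_tag["asymmetric-lower"].stable

    def test_asymmetric_pair_is_swap_equivalent(self):
        model = get_model("minimal")
        p = default_parameters("minimal").updated(k_bias=0.0)
        states = find_steady_states(model, p)
        pair = [s for s in states if s.symmetry != "symmetric"]
        assert len(pair) == 2
        mismatch = np.max(np.abs(pair[0].state.values
                                 - pair[1].state.swapped().values))
        assert mismatch < 1e-6

    def test_residuals_verify_against_full_rhs(self):
        """Every reported steady state satisfies |RHS| < 1e-8 on re-evaluation."""
        for mid in ("minimal", "molecular"):
            model = get_model(mid)
            p = default_parameters(mid).updated(k_bias=0.0)
            for s in find_steady_states(model, p):
                resid = model.rhs(s.state.values, p)
                assert float(np.max(np.abs(resid))) < 1e-8, (mid, s.symmetry)

    def test_stable_states_are_reached_by_forward_integration(self):
        """Basin consistency at five control values of the X total."""
        model = get_model("minimal")
        base = default_parameters("minimal").updated(k_bias=0.0)
        rng = np.random.default_rng(42)
        for mult in (0.5, 0.75, 1.0, 1.25, 1.5):
            p = base.scaled("x_total", mult)
            stable = [s for s in find_steady_states(model, p) if s.stable]
            assert stable, mult
            s = stable[0]
            y0 = s.state.values * (1.0 + 1e-3 * rng.standard_normal(
                model.n_state))
            y0 = np.clip(y0, 0.0, None)
            traj = integrate(model, p, model.state(y0), t_end=600.0)
            assert traj.final_state.values == pytest.approx(
                s.state.values, abs=5e-3)

    def test_pitchfork_bracketed_along_total_ratio(self):
        model = get_model("minimal")
        branches = symmetric_steady_states(
            model, "x_total", [0.75, 1.0, 1.25, 1.5], n_starts=40)
        bracket = find_pitchfork(branches)
        assert bracket is not None
        stable_side, broken_side = bracket
        assert broken_side < stable_side  # symmetry broken at lower X totals

    def test_reduced_rhs_matches_full_rhs_on_manifold(self):
        model = get_model("molecular")
        p = default_parameters("molecular").updated(k_bias=0.0)
        states = find_steady_states(model, p)
        for s in states:
            v = np.concatenate([
                [s.state.get("SIN", "old"), s.state.get("SIN", "new"),
                 s.state.get("Byr4", "old"), s.state.get("Byr4", "new"),
                 s.state.get("Cdc11U", "old"), s.state.get("Cdc11U", "new")]])
            assert np.max(np.abs(reduced_rhs(model, v, p))) < 1e-8
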