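"""ODE engine: closed forms, equilibria, stability, scenario classification."""

import math

import numpy as np
import pytest

from microlag import (
    InitialCondition,
    PopulationParams,
    classify_scenario,
    equilibria,
    integrate,
)


class TestIntegrate:
    def test_logistic_closed_form(self, single_species_pop):
        p = single_species_pop
        N0 = p.Kn / 100
        traj = integrate(p, InitialCondition(N0=N0, i0=1e-12), t_end=12.0, dt_out=0.01)
        t = traj.times
        exact = p.Kn * N0 * np.exp(p.rn * t) / (p.Kn + N0 * (np.exp(p.rn * t) - 1))
        assert np.max(np.abs(traj.N - exact) / exact) < 1e-6

    def test_negative_ri_monotone_decay(self):
        p = PopulationParams(ri=-0.2, alpha_ni=0.0)
        traj = integrate(p, InitialCondition(N0=p.Kn, i0=10.0), t_end=70.0)
        assert np.all(np.diff(traj.I0) <= 1e-12)
        assert traj.I0[-1] < 10.0 * math.exp(-0.2 * 70.0) * 1.01
        assert traj.extinct["I0"]

    def test_abundances_never_negative(self, preset_c):
        traj = integrate(preset_c.pop, preset_c.init, t_end=100.0)
        assert traj.N.min() >= 0 and traj.I0.min() >= 0 and traj.Im.min() >= 0

    def test_rejects_nonpositive_horizon(self, preset_a):
        with pytest.raises(ValueError):
            integrate(preset_a.pop, preset_a.init, t_end=0.0)


class TestEquilibria:
    def test_uncoupled_logistics(self):
        p = PopulationParams(alpha_in=0.0, alpha_ni=0.0)
        eqs = equilibria(p, "N-I0")
        assert len(eqs) == 4
        by_kind = {e.kind: e for e in eqs}
        assert by_kind["coexistence"].state == pytest.approx((p.Kn, p.Ki))
        assert by_kind["coexistence"].stability == "stable"
        assert by_kind["extinction"].stability == "unstable"

    def test_residuals_vanish(self, preset_a, preset_b, preset_c):
        for preset in (preset_a, preset_b, preset_c):
            for pair in ("N-I0", "N-Im"):
                for e in equilibria(preset.pop, pair):
                    assert e.residual < 1e-8

    def test_scenario_a_interior_stable_boundaries_not(self, preset_a):
        eqs = {e.kind: e for e in equilibria(preset_a.pop, "N-I0")}
        assert eqs["coexistence"].stability == "stable"
        assert eqs["native-only"].stability == "saddle"
        assert eqs["invader-only"].stability == "saddle"

    def test_scenario_a_integration_converges_to_interior(self, preset_a, rng):
        """Long-horizon flow from random interior starts reaches the
        coexistence equilibrium computed independently from the nullclines."""
        interior = next(
            e for e in equilibria(preset_a.pop, "N-I0") if e.kind == "coexistence"
        )
        p = preset_a.pop
        for _ in range(5):
            init = InitialCondition(
                N0=rng.uniform(5, p.Kn), i0=rng.uniform(1, p.Ki), Im0=0.0
            )
            traj = integrate(p, init, t_end=300.0)
            assert traj.N[-1] == pytest.approx(interior.state[0], rel=1e-4)
            assert traj.I0[-1] == pytest.approx(interior.state[1], rel=1e-4)

    def test_scenario_c_invader_wins(self, preset_c):
        eqs = {e.kind: e for e in equilibria(preset_c.pop, "N-I0")}
        assert eqs["invader-only"].stability == "stable"
        assert eqs["native-only"].stability == "saddle"
        # integration oracle: natives die out, invader reaches Ki
        traj = integrate(preset_c.pop, preset_c.init, t_end=300.0)
        assert traj.N[-1] < 1e-3
        assert traj.I0[-1] == pytest.approx(preset_c.pop.Ki, rel=1e-3)

    def test_intrinsic_decline_pair(self):
        # ri<0: no invader-only equilibrium, native-only is globally stable
        p = PopulationParams(ri=-0.2, alpha_ni=0.0)
        eqs = {e.kind: e for e in equilibria(p, "N-I0")}
        assert set(eqs) == {"extinction", "native-only"}
        assert eqs["native-only"].stability == "stable"

    def test_unknown_pair_rejected(self, preset_a):
        with pytest.raises(ValueError, match="pair"):
            equilibria(preset_a.pop, "N-X")


class TestScenarioClassification:
    def test_printed_inequalities(self):
        # Kn < ri/alpha_ni and Ki < rn/alpha_in -> A
        p = PopulationParams(rn=1, ri=0.5, Kn=100, Ki=30,
                             alpha_ni=0.004, alpha_in=0.01)
        assert classify_scenario(p).label == "A"
        # Kn > ri/alpha_ni and Ki < rn/alpha_in -> B
        p = PopulationParams(rn=1, ri=0.3, Kn=100, Ki=30,
                             alpha_ni=0.005, alpha_in=0.008)
        assert classify_scenario(p).label == "B"
        # Ki > rn/alpha_in and Kn < ri/alpha_ni -> C
        p = PopulationParams(rn=1, ri=1.2, Kn=50, Ki=100,
                             alpha_ni=0.004, alpha_in=0.012)
        assert classify_scenario(p).label == "C"

    def test_negative_ri_is_b_regardless(self):
        p = PopulationParams(ri=-0.1, Kn=50, Ki=100, alpha_ni=0.0, alpha_in=0.012)
        assert classify_scenario(p).label == "B"

    def test_bistable_is_other(self):
        p = PopulationParams(rn=1, ri=1.0, Kn=200, Ki=200,
                             alpha_ni=0.05, alpha_in=0.05)
        sc = classify_scenario(p)
        assert sc.label == "other"
        assert sc.pre_transfer_regime == "bistable"

    def test_preset_labels(self, preset_a, preset_b, preset_c):
        assert classify_scenario(preset_a.pop).label == "A"
        assert classify_scenario(preset_b.pop).label == "B"
        assert classify_scenario(preset_c.pop).label == "C"

    def test_classification_matches_integration_outcome(self, rng):
        """On random non-degenerate draws the label's pre-transfer regime
        agrees with which species persists under long integration."""
        from microlag.presets import random_lv_draw

        checked = 0
        while checked < 40:
            p = random_lv_draw(rng)
            margin1 = p.rn - p.alpha_in * p.Ki
            margin2 = p.ri - p.alpha_ni * p.Kn
            if min(abs(margin1), abs(margin2)) < 0.05:
                continue  # near-degenerate: outcome decided too slowly
            sc = classify_scenario(p)
            if sc.pre_transfer_regime == "bistable":
                checked += 1
                continue  # initial-condition dependent by design
            traj = integrate(
                p, InitialCondition(N0=p.Kn / 2, i0=p.Ki / 2), t_end=400.0
            )
            n_alive = traj.N[-1] > 1.0
            i_alive = traj.I0[-1] > 1.0
            expected = {
                "coexistence": (True, True),
                "N-excludes-I": (True, False),
                "I-excludes-N": (False, True),
            }[sc.pre_transfer_regime]
            assert (n_alive, i_alive) == expected, (p, sc)
            checked += 1
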