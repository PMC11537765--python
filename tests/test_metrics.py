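"""Lag estimator, establishment probability, analytic thresholds."""

import math

import numpy as np
import pytest

from microlag import (
    InitialCondition,
    PopulationParams,
    RegimeError,
    SpatialParams,
    StochasticRunConfig,
    TransferParams,
    establishment_probability,
    integrate,
    invasion_lag,
    lambda_min_establishment,
    lambda_min_spatial,
    simulate,
)


class TestInvasionLag:
    def test_logistic_inflexion_recovered(self):
        # inflexion of a logistic at I=K/2: t* = ln(K/I0 - 1)/r
        p = PopulationParams(ri=1.0, Ki=100.0, alpha_in=0, alpha_mn=0,
                             alpha_ni=0, alpha_nm=0)
        traj = integrate(p, InitialCondition(N0=0.0, i0=1.0), t_end=12.0, dt_out=0.01)
        res = invasion_lag(traj)
        assert res.inflexion_found
        assert res.lag_time == pytest.approx(math.log(99.0), rel=0.02)

    def test_flat_trajectory_no_inflexion(self, preset_a, no_transfer):
        # resting at the pre-transfer coexistence equilibrium forever
        cfg = StochasticRunConfig(dt_jump=0.05, t_end=200.0, seed=1)
        traj = simulate(preset_a.pop, no_transfer, preset_a.init, cfg)
        assert not invasion_lag(traj).inflexion_found

    def test_monotone_decline_no_inflexion(self):
        p = PopulationParams(ri=-0.2, alpha_ni=0.0)
        traj = integrate(p, InitialCondition(N0=p.Kn, i0=10.0), t_end=60.0)
        assert not invasion_lag(traj).inflexion_found

    def test_short_trajectory_raises(self, preset_a):
        from microlag.trajectory import Trajectory

        t = np.linspace(0, 1, 4)
        traj = Trajectory(times=t, N=t, I0=t, Im=t)
        with pytest.raises(ValueError):
            invasion_lag(traj)

    def test_lag_positive_in_scenario_a(self, preset_a):
        cfg = StochasticRunConfig(dt_jump=0.05, t_end=150.0, seed=3)
        traj = simulate(preset_a.pop, preset_a.tr, preset_a.init, cfg)
        res = invasion_lag(traj)
        assert res.inflexion_found
        # growth cannot inflect before the first transfer event
        assert res.lag_time > traj.events[0].t - res.window


class TestEstablishmentProbability:
    def test_no_rescue_channel_probability_zero(self):
        pop = PopulationParams(ri=-0.2, alpha_ni=0.0)
        cfg = StochasticRunConfig(dt_jump=0.05, t_end=50.0)
        res = establishment_probability(
            pop, TransferParams(0.0, 0.0), InitialCondition(N0=pop.Kn, i0=10.0),
            cfg, n_reps=30, base_seed=1,
        )
        assert res.probability == 0.0

    def test_certain_rescue_probability_one(self, preset_b):
        tr = TransferParams(lambda_n=5e-3, lambda_m=0.0)
        cfg = StochasticRunConfig(dt_jump=0.01, t_end=60.0)
        res = establishment_probability(
            preset_b.pop, tr, preset_b.init, cfg, n_reps=30, base_seed=2
        )
        assert res.probability == 1.0

    def test_se_formula(self, preset_b):
        cfg = StochasticRunConfig(dt_jump=0.05, t_end=40.0)
        res = establishment_probability(
            preset_b.pop, preset_b.tr, preset_b.init, cfg, n_reps=50, base_seed=3
        )
        p = res.probability
        assert res.se == pytest.approx(math.sqrt(p * (1 - p) / 50))


class TestEstablishmentThreshold:
    def test_competition_regime_value(self):
        pop = PopulationParams(ri=0.3, Kn=100.0, alpha_ni=0.005)
        init = InitialCondition(i0=10.0)
        res = lambda_min_establishment(pop, init)
        expect = (0.005 * 100 - 0.3) / (100 * 10 * math.log(10))
        assert res.lambda_n_min == pytest.approx(expect)
        assert res.regime == "nonspatial"

    def test_intrinsic_regime_value(self):
        pop = PopulationParams(ri=-0.2, alpha_ni=0.0, Kn=100.0)
        res = lambda_min_establishment(pop, InitialCondition(i0=10.0))
        assert res.lambda_n_min == pytest.approx(0.2 / (100 * 10 * math.log(10)))
        assert res.regime == "nonspatial-no-competition"

    def test_no_regime_applies(self):
        pop = PopulationParams(ri=0.5, alpha_ni=0.0)
        with pytest.raises(RegimeError, match="neither regime"):
            lambda_min_establishment(pop, InitialCondition(i0=10.0))

    def test_wrong_competition_regime_named(self):
        # invader can invade: Kn < ri/alpha_ni
        pop = PopulationParams(ri=1.2, Kn=50.0, alpha_ni=0.004)
        with pytest.raises(RegimeError, match="Kn > ri/alpha_ni"):
            lambda_min_establishment(pop, InitialCondition(i0=10.0))

    def test_diverges_as_i0_to_one(self):
        pop = PopulationParams(ri=0.3, Kn=100.0, alpha_ni=0.005)
        lam = [
            lambda_min_establishment(pop, InitialCondition(i0=i0)).lambda_n_min
            for i0 in (1.0001, 1.01, 2.0)
        ]
        assert lam[0] > lam[1] > lam[2]
        assert lam[0] > 100 * lam[2]

    def test_i0_of_one_rejected(self):
        pop = PopulationParams(ri=0.3, Kn=100.0, alpha_ni=0.005)
        with pytest.raises(RegimeError, match="i0"):
            lambda_min_establishment(pop, InitialCondition(i0=1.0))


class TestSpatialThreshold:
    pop = PopulationParams(ri=1.2, Kn=50.0, alpha_ni=0.004)
    sp = SpatialParams(Di=1.0, dx_patch=20.0, n_tilde=25.0, j_tilde=50.0)

    def test_value_and_linearity(self):
        base = lambda_min_spatial(self.pop, self.sp).lambda_n_min
        expect = 2 * 1.0 * (1.2 - 0.004 * 50) / (20 * 25 * 50)
        assert base == pytest.approx(expect)
        # doubling patch size halves it; doubling dispersal doubles it
        double_dx = lambda_min_spatial(
            self.pop, SpatialParams(Di=1, dx_patch=40, n_tilde=25, j_tilde=50)
        ).lambda_n_min
        double_di = lambda_min_spatial(
            self.pop, SpatialParams(Di=2, dx_patch=20, n_tilde=25, j_tilde=50)
        ).lambda_n_min
        assert double_dx == pytest.approx(base / 2)
        assert double_di == pytest.approx(2 * base)

    def test_vanishes_as_competition_balances_growth(self):
        # alpha_ni -> ri/Kn from below: natives stall the front completely
        lam = [
            lambda_min_spatial(
                PopulationParams(ri=1.2, Kn=50.0, alpha_ni=a), self.sp
            ).lambda_n_min
            for a in (0.004, 0.02, 0.0239)
        ]
        assert lam[0] > lam[1] > lam[2]
        assert lam[2] < 0.01 * lam[0]

    def test_wrong_regime_named(self):
        pop = PopulationParams(ri=0.3, Kn=100.0, alpha_ni=0.005)
        with pytest.raises(RegimeError, match="Kn < ri/alpha_ni"):
            lambda_min_spatial(pop, self.sp)

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(RegimeError, match="dx_patch"):
            lambda_min_spatial(
                self.pop,
                SpatialParams(Di=1.0, dx_patch=0.0, n_tilde=25.0, j_tilde=50.0),
            )
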