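"""Solute-tempering replica exchange on 1-D toy systems: scaled
potentials, the Metropolis swap rule, ensemble correctness of the ground
replica, ladder tuning and campaign accounting."""

import numpy as np
import pytest

from permeapath.errors import ValidationError
from permeapath.rest3 import (
    ReplicaLadder,
    ToyTemperedSystem,
    exchange_accept_probability,
    plan_campaign,
    run_toy_rest3,
    scaled_potential,
    tune_ladder,
)
from permeapath.synthetic import LangevinConfig, simulate_window
from permeapath.thermo import ThermoState

THERMO = ThermoState()
RT = THERMO.rt


def double_well(height, z0=1.0, width=0.5):
    """Quartic double well with minima at z0 +/- width and given barrier."""
    def u(z):
        x = (np.asarray(z, float) - z0) / width
        return height * (x ** 2 - 1.0) ** 2
    return u


def toy(height=8.0, env_curv=2.0):
    return ToyTemperedSystem(
        u_env=lambda z: env_curv * (np.asarray(z, float) - 1.0) ** 2,
        u_int=double_well(height),
        z_min=0.0,
        z_max=2.0,
        diffusivity=1e-3,
    )


class TestScaledPotential:
    def test_ground_replica_is_full_potential(self):
        system = toy()
        z = np.linspace(0, 2, 11)
        full = system.u_env(z) + system.u_int(z)
        assert np.allclose(scaled_potential(system, 1.0, z), full)

    def test_half_scaling_arithmetic(self):
        system = ToyTemperedSystem(
            u_env=lambda z: np.full_like(np.asarray(z, float), 2.0),
            u_int=lambda z: np.full_like(np.asarray(z, float), 10.0),
            z_min=0.0, z_max=1.0)
        assert scaled_potential(system, 0.5, 0.3,
                                u_bias=lambda z: np.ones_like(np.asarray(z, float))
                                ) == pytest.approx(8.0)

    def test_decoupled_limit_independent_of_lambda(self):
        system = ToyTemperedSystem(
            u_env=lambda z: np.sin(np.asarray(z, float)),
            u_int=lambda z: np.zeros_like(np.asarray(z, float)),
            z_min=0.0, z_max=2.0)
        z = 0.7
        assert scaled_potential(system, 1.0, z) == scaled_potential(system, 0.2, z)

    def test_lambda_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            scaled_potential(toy(), 0.0, 0.5)
        with pytest.raises(ValidationError):
            scaled_potential(toy(), 1.5, 0.5)


class TestExchangeProbability:
    def test_equal_lambdas_always_accept(self):
        assert exchange_accept_probability(toy(), 0.6, 0.6, 0.3, 1.7, THERMO) == 1.0

    def test_energy_lowering_swap_always_accepts(self):
        system = toy()
        # configuration with high U_int at the strong-coupling rung:
        # swapping it down in coupling lowers the total energy
        z_high, z_low = 1.0, 0.5  # barrier top vs near-minimum
        p = exchange_accept_probability(system, 1.0, 0.4, z_high, z_low, THERMO)
        assert p == 1.0

    def test_symmetry_between_rungs(self):
        system = toy()
        a = exchange_accept_probability(system, 0.9, 0.5, 0.4, 1.1, THERMO)
        b = exchange_accept_probability(system, 0.5, 0.9, 1.1, 0.4, THERMO)
        assert a == pytest.approx(b, rel=1e-12)

    def test_monte_carlo_average_matches_analytic(self):
        # draw 1e5 configuration pairs from Gaussians, compare the
        # empirical acceptance rate with the mean analytic probability
        system = toy(height=6.0)
        rng = np.random.default_rng(9)
        z_i = np.clip(rng.normal(0.6, 0.15, 100_000), 0.0, 2.0)
        z_j = np.clip(rng.normal(1.2, 0.15, 100_000), 0.0, 2.0)
        lam_i, lam_j = 1.0, 0.5
        du = system.u_int(z_j) - system.u_int(z_i)
        p_analytic = np.minimum(1.0, np.exp(-THERMO.beta * (lam_i - lam_j) * du))
        accepted = rng.random(z_i.size) < p_analytic
        scalar = [
            exchange_accept_probability(system, lam_i, lam_j, a, b, THERMO)
            for a, b in zip(z_i[:100], z_j[:100])
        ]
        assert scalar == pytest.approx(p_analytic[:100], rel=1e-12)
        assert abs(accepted.mean() - p_analytic.mean()) < 0.01


def _tv_against_boltzmann(window, system, center, k, n_bins=30):
    edges = np.linspace(system.z_min, system.z_max, n_bins + 1)
    counts, _ = np.histogram(window.positions, bins=edges)
    p_emp = counts / counts.sum()
    zf = np.linspace(system.z_min, system.z_max, 4001)
    u = (np.asarray(system.u_env(zf)) + np.asarray(system.u_int(zf))
         + 0.5 * k * (zf - center) ** 2)
    dens = np.exp(-(u - u.min()) / RT)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(zf))])
    p_true = np.diff(np.interp(edges, zf, cdf))
    p_true /= p_true.sum()
    return 0.5 * np.abs(p_emp - p_true).sum()


class TestRunToyRest3:
    CFG = LangevinConfig(dt=0.01, n_steps=400_000, sample_stride=10,
                         equilibration_steps=40_000, seed=33)

    def test_single_rung_reduces_to_plain_window(self):
        system = toy(height=3.0)
        ladder = ReplicaLadder(lambdas=(1.0,))
        w_rest, stats = run_toy_rest3(system, ladder, 1.0, 100.0, self.CFG)
        w_plain = simulate_window(system.landscape_at(1.0), 1.0, 100.0, self.CFG)
        assert np.array_equal(w_rest.positions, w_plain.positions)
        assert stats.attempts.size == 0

    # fast-mixing toy (D = 5e-3 nm^2/ps) so the slow inter-well hop rate
    # does not dominate the total-variation estimate
    MIX_CFG = LangevinConfig(dt=0.01, n_steps=600_000, sample_stride=10,
                             equilibration_steps=40_000, seed=33)

    def _fast_toy(self, height):
        system = toy(height=height)
        system.diffusivity = 5e-3
        return system

    def test_ground_replica_boltzmann_with_exchanges(self):
        # detailed balance: exchanging with tempered rungs must not
        # perturb the ground ensemble
        system = self._fast_toy(5.0)
        ladder = ReplicaLadder(lambdas=(1.0, 0.6, 0.35, 0.2))
        w, stats = run_toy_rest3(system, ladder, 1.0, 20.0, self.MIX_CFG)
        tv = _tv_against_boltzmann(w, system, 1.0, 20.0)
        assert tv < 0.08
        assert np.all(stats.accepts <= stats.attempts)

    def test_near_identity_ladder_matches_plain_ensemble(self):
        # lambdas within 1e-9 of each other: every swap accepted, and the
        # ground ensemble must match a plain run statistically
        system = self._fast_toy(3.0)
        ladder = ReplicaLadder(lambdas=(1.0, 1.0 - 1e-9, 1.0 - 2e-9))
        w, stats = run_toy_rest3(system, ladder, 1.0, 20.0, self.MIX_CFG)
        assert np.all(stats.acceptance_fractions == 1.0)
        tv = _tv_against_boltzmann(w, system, 1.0, 20.0)
        assert tv < 0.08

    def test_tempering_accelerates_barrier_crossing(self):
        # deep-trap double well: median first passage from the left well
        # past the barrier is shorter with a 4-rung ladder (>= 20 seeds)
        system = ToyTemperedSystem(
            u_env=lambda z: np.zeros_like(np.asarray(z, float)),
            u_int=double_well(14.0, z0=1.0, width=0.5),
            z_min=0.0, z_max=2.0, diffusivity=1e-3)
        ladder = ReplicaLadder(lambdas=(1.0, 0.55, 0.3, 0.15))
        single = ReplicaLadder(lambdas=(1.0,))

        def first_crossing(window):
            # walkers start in the left well (z = 0.5); crossing = z > 1.4
            hits = np.flatnonzero(window.positions > 1.4)
            return window.times[hits[0]] if hits.size else np.inf

        t_plain, t_rest = [], []
        for seed in range(20):
            cfg = LangevinConfig(dt=0.01, n_steps=120_000, sample_stride=10, seed=seed)
            wp, _ = run_toy_rest3(system, single, 0.5, 0.0, cfg)
            wr, _ = run_toy_rest3(system, ladder, 0.5, 0.0, cfg)
            t_plain.append(first_crossing(wp))
            t_rest.append(first_crossing(wr))
        assert np.median(t_rest) < np.median(t_plain)


class TestTuneLadder:
    PILOT = LangevinConfig(dt=0.01, n_steps=60_000, sample_stride=20,
                           equilibration_steps=10_000, seed=44)

    def test_decoupled_system_returns_minimal_ladder_flagged(self):
        system = ToyTemperedSystem(
            u_env=lambda z: 2.0 * (np.asarray(z, float) - 1.0) ** 2,
            u_int=lambda z: np.zeros_like(np.asarray(z, float)),
            z_min=0.0, z_max=2.0, diffusivity=1e-3)
        tuning = tune_ladder(system, 1.0, 100.0, self.PILOT)
        assert tuning.ladder.n_rungs == 2
        assert tuning.status == "above_target"
        assert np.all(tuning.pilot_stats.acceptance_fractions == 1.0)

    def test_stronger_coupling_needs_more_rungs(self):
        rungs = []
        for height in (10.0, 30.0, 90.0):
            tuning = tune_ladder(toy(height=height), 1.0, 100.0, self.PILOT,
                                 lambda_min=0.2, max_rungs=24)
            rungs.append(tuning.ladder.n_rungs)
        assert rungs[0] <= rungs[1] <= rungs[2]
        assert rungs[2] > rungs[0]

    def test_unattainable_band_raises(self):
        # steep linear coupling: neighbour ensembles sample disjoint
        # U_int ranges, so a 2-rung ladder cannot reach the band
        tilted = ToyTemperedSystem(
            u_env=lambda z: np.zeros_like(np.asarray(z, float)),
            u_int=lambda z: 200.0 * np.asarray(z, float),
            z_min=0.0, z_max=2.0, diffusivity=1e-3)
        with pytest.raises(ValidationError, match="unattainable"):
            tune_ladder(tilted, 1.0, 0.0, self.PILOT,
                        lambda_min=0.01, max_rungs=2)


class TestPlanCampaign:
    def test_full_campaign_totals(self):
        # 20 tempered windows totalling 176 rungs plus 3 plain bulk-water
        # windows, 250 ns per replica -> 44,750 ns
        centers = np.round(np.arange(0.0, 4.41, 0.2), 9)
        tempered = centers[centers <= 3.8 + 1e-9]
        rungs = [9] * 16 + [8] * 4  # 16*9 + 4*8 = 176
        schemes = dict(zip(tempered.tolist(), rungs))
        plan = plan_campaign(centers.tolist(), schemes, 250.0,
                             rest3_windows=tempered.tolist())
        assert plan.n_replicas == 176 + 3
        assert plan.total_time_ns == pytest.approx(44_750.0)

    def test_single_plain_window(self):
        plan = plan_campaign([4.2], {}, 250.0, rest3_windows=[])
        assert plan.n_replicas == 1
        assert plan.total_time_ns == 250.0

    def test_total_time_linear_in_run_length(self):
        schemes = {0.0: 8, 0.2: 8}
        a = plan_campaign([0.0, 0.2], schemes, 100.0)
        b = plan_campaign([0.0, 0.2], schemes, 200.0)
        assert b.total_time_ns == 2 * a.total_time_ns

    def test_missing_scheme_raises(self):
        with pytest.raises(ValidationError, match="scheme"):
            plan_campaign([0.0, 0.2], {0.0: 8}, 250.0, rest3_windows=[0.0, 0.2])


class TestLadderValidation:
    def test_ground_rung_must_be_unity(self):
        with pytest.raises(ValidationError, match="1.0"):
            ReplicaLadder(lambdas=(0.9, 0.5))

    def test_strictly_decreasing(self):
        with pytest.raises(ValidationError, match="decreasing"):
            ReplicaLadder(lambdas=(1.0, 0.5, 0.5))
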