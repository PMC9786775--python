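"""WHAM: histogramming, the self-consistent solve against an independent
brute-force oracle, zero-referencing, block convergence and bootstrap."""

import numpy as np
import pytest

from conftest import SPRING_K, flat_landscape, window_seed
from permeapath.errors import ConvergenceError, ValidationError
from permeapath.synthetic import LangevinConfig, UmbrellaWindow, simulate_window
from permeapath.thermo import ThermoState
from permeapath.wham import (
    FreeEnergyProfile,
    WindowHistogram,
    bootstrap_pmf,
    convergence_blocks,
    declare_convergence,
    histogram_window,
    make_edges,
    wham_solve,
    zero_reference,
)

THERMO = ThermoState()
RT = THERMO.rt


def _window(positions, center=0.0, k=0.0, dt=1.0):
    positions = np.asarray(positions, float)
    return UmbrellaWindow(center, k, dt * (np.arange(positions.size) + 1.0), positions)


class TestHistogram:
    def test_direct_counts(self):
        h = histogram_window(_window([0.1, 0.1, 0.3, 0.5]), np.array([0, 0.2, 0.4, 0.6]))
        assert h.counts.tolist() == [2, 1, 1]
        assert h.n_total == 4

    def test_all_samples_one_bin(self):
        h = histogram_window(_window([0.25] * 5), np.array([0, 0.2, 0.4, 0.6]))
        assert h.counts.tolist() == [0, 5, 0]

    def test_interior_edge_sample_goes_right(self):
        h = histogram_window(_window([0.2]), np.array([0, 0.2, 0.4]))
        assert h.counts.tolist() == [0, 1]

    def test_outside_samples_reported(self):
        h = histogram_window(_window([-1.0, 0.1]), np.array([0, 0.2]))
        assert h.n_outside == 1 and h.n_total == 1

    def test_empty_series_raises(self):
        with pytest.raises(ValidationError, match="empty"):
            histogram_window(_window([]), np.array([0, 0.2]))


def brute_force_wham(hist_counts, centers, ks, edges, rt, max_iter=20_000):
    """Independent direct-iteration WHAM in plain real-space arithmetic.

    Deliberately naive (explicit loops, exp weights) so it shares no
    code path with the package solver.
    """
    zb = 0.5 * (edges[:-1] + edges[1:])
    w = np.diff(edges)
    n_w = len(hist_counts)
    n_i = [sum(c) for c in hist_counts]
    bias = [[0.5 * ks[i] * (z - centers[i]) ** 2 for z in zb] for i in range(n_w)]
    f = [1.0] * n_w  # exp(beta f_i)
    for _ in range(max_iter):
        p = []
        for b in range(len(zb)):
            num = sum(hist_counts[i][b] for i in range(n_w))
            den = sum(n_i[i] * f[i] * np.exp(-bias[i][b] / rt) for i in range(n_w))
            p.append(num / den if den > 0 else 0.0)
        f_new = []
        for i in range(n_w):
            z_i = sum(p[b] * w[b] * np.exp(-bias[i][b] / rt) for b in range(len(zb)))
            f_new.append(1.0 / z_i)
        scale = f_new[0]
        f_new = [v / scale for v in f_new]
        drift = max(abs(a - b) for a, b in zip(f, f_new))
        f = f_new
        if drift < 1e-13:
            break
    p = np.array(p) / w
    with np.errstate(divide="ignore"):
        dg = -rt * np.log(p)
    return zb, dg - dg[np.isfinite(dg)].min()


class TestWhamSolve:
    def test_unbiased_flat_window_gives_flat_profile(self):
        rng = np.random.default_rng(0)
        w = _window(rng.uniform(0, 1, 200_000))
        sol = wham_solve([histogram_window(w, make_edges(0, 1, 0.05))], THERMO)
        dg = sol.profile.dg
        # multinomial noise: ~1e4 counts/bin -> ~0.03 kJ/mol per bin
        assert np.nanmax(dg) - np.nanmin(dg) < 0.15

    def test_two_window_linear_landscape_against_brute_force_oracle(self):
        # Exact biased-Boltzmann samples of G(z) = a z under a harmonic
        # bias are Gaussian with mean z_c - a/k and variance RT/k.
        a, k = 10.0, SPRING_K
        rng = np.random.default_rng(1)
        centers, n = [1.0, 1.3], 100_000
        edges = make_edges(0.5, 1.8, 0.02)
        hists = []
        for zc in centers:
            samples = rng.normal(zc - a / k, np.sqrt(RT / k), n)
            hists.append(histogram_window(_window(samples, center=zc, k=k), edges))
        sol = wham_solve(hists, THERMO, tol=1e-10)
        zb, dg_oracle = brute_force_wham(
            [h.counts.tolist() for h in hists], centers, [k, k], edges, RT)
        m = sol.profile.support & np.isfinite(dg_oracle)
        # same equations, independent implementations: sub-0.1 kJ/mol
        d = (sol.profile.dg - dg_oracle)[m]
        assert np.max(np.abs(d - d.mean())) < 0.1
        # recovered slope within 2% of the ground truth
        zfit = sol.profile.z[m]
        sel = (zfit > 0.8) & (zfit < 1.5)
        slope = np.polyfit(zfit[sel], sol.profile.dg[m][sel], 1)[0]
        assert slope == pytest.approx(a, rel=0.02)

    def test_profile_translation_invariance(self):
        # shifting every window center and the grid by a constant shifts
        # the profile's support but not its shape (gauge freedom)
        a, k, shift = 8.0, SPRING_K, 0.7
        sol = {}
        for s in (0.0, shift):
            rng2 = np.random.default_rng(2)  # same draws in both frames
            hists = [
                histogram_window(
                    _window(rng2.normal(zc - a / k, np.sqrt(RT / k), 50_000),
                            center=zc, k=k),
                    make_edges(0.5 + s, 1.8 + s, 0.02),
                )
                for zc in (1.0 + s, 1.3 + s)
            ]
            sol[s] = wham_solve(hists, THERMO, tol=1e-10)
        m = sol[0.0].profile.support & sol[shift].profile.support
        d = sol[0.0].profile.dg[m] - sol[shift].profile.dg[m]
        assert np.max(np.abs(d - d.mean())) < 1e-6

    def test_bin_halving_stability(self, me5ala_recovery_windows):
        windows = me5ala_recovery_windows[:6]
        profiles = {}
        for bw in (0.02, 0.01):
            hists = [histogram_window(w, make_edges(0, 1.2, bw)) for w in windows]
            profiles[bw] = wham_solve(hists, THERMO, tol=1e-8).profile
        fine_on_coarse = profiles[0.01].interp(profiles[0.02].z[profiles[0.02].support])
        d = profiles[0.02].dg[profiles[0.02].support] - fine_on_coarse
        assert np.max(np.abs(d - d.mean())) < 0.35  # kJ/mol

    def test_non_convergence_raises_with_residual(self):
        rng = np.random.default_rng(3)
        hists = [
            histogram_window(
                _window(rng.normal(zc, 0.05, 10_000), center=zc, k=SPRING_K),
                make_edges(0.0, 1.0, 0.02),
            )
            for zc in (0.3, 0.5)
        ]
        with pytest.raises(ConvergenceError) as exc:
            wham_solve(hists, THERMO, tol=1e-12, max_iter=3)
        assert exc.value.residual is not None

    def test_disjoint_windows_warn(self):
        rng = np.random.default_rng(4)
        edges = make_edges(0.0, 2.0, 0.02)
        hists = [
            histogram_window(
                _window(rng.normal(zc, 0.02, 5_000), center=zc, k=SPRING_K), edges)
            for zc in (0.2, 1.8)
        ]
        with pytest.warns(UserWarning, match="overlap"):
            wham_solve(hists, THERMO, max_iter=50_000, tol=1e-6)


class TestZeroReference:
    def _profile(self, offset=0.0):
        z = np.linspace(0, 4.4, 221)
        dg = np.where(z < 4.0, np.sin(z), 0.0) + offset
        return FreeEnergyProfile(z=z, dg=dg)

    def test_shift_invariance(self):
        a = zero_reference(self._profile(), 4.0)
        b = zero_reference(self._profile(offset=37.0), 4.0)
        assert np.allclose(a.dg, b.dg)

    def test_idempotence(self):
        a = zero_reference(self._profile(), 4.0)
        b = zero_reference(a, 4.0)
        assert np.allclose(a.dg, b.dg)

    def test_bulk_plateau_maps_to_zero(self):
        p = zero_reference(self._profile(offset=-3.0), 4.0)
        assert np.allclose(p.dg[p.z >= 4.0], 0.0, atol=1e-12)

    def test_empty_reference_region_raises(self):
        with pytest.raises(ValidationError, match="reference"):
            zero_reference(self._profile(), 10.0)


def _stationary_windows(duration=250.0, dt=1.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration / dt)
    return [
        _window(rng.normal(zc, np.sqrt(RT / SPRING_K), n), center=zc, k=SPRING_K, dt=dt)
        for zc in (0.3, 0.5, 0.7)
    ]


class TestConvergenceBlocks:
    def test_block_count_for_sliding_schedule(self):
        blocks = convergence_blocks(_stationary_windows(250.0), 50.0, 10.0,
                                    THERMO, zero_from=None)
        assert len(blocks) == 21
        assert blocks[0][0] == 0.0 and blocks[-1][0] == pytest.approx(200.0)

    def test_single_block_when_block_equals_duration(self):
        blocks = convergence_blocks(_stationary_windows(50.0), 50.0, 10.0,
                                    THERMO, zero_from=None)
        assert len(blocks) == 1

    def test_block_longer_than_series_raises(self):
        with pytest.raises(ValidationError, match="duration"):
            convergence_blocks(_stationary_windows(40.0), 50.0, 10.0, THERMO)

    def test_stationary_data_declared_converged_at_first_block(self):
        # stationary unbiased sampling: every block sees the same flat
        # landscape, so convergence is declared at the first block
        rng = np.random.default_rng(5)
        windows = [
            _window(rng.uniform(0, 1, 20_000), center=c, k=0.0, dt=0.1)
            for c in (0.3, 0.5, 0.7)
        ]
        blocks = convergence_blocks(windows, 400.0, 200.0, THERMO,
                                    bin_width=0.05, zero_from=None)
        assert len(blocks) == 9
        t = declare_convergence(blocks, criterion_kjmol=1.0)
        assert t == 0.0


class TestDeclareConvergence:
    def _p(self, dg):
        return FreeEnergyProfile(z=np.arange(4.0), dg=np.asarray(dg, float))

    def test_identical_profiles_converge_immediately(self):
        blocks = [(10.0 * i, self._p([0, 1, 2, 3])) for i in range(5)]
        assert declare_convergence(blocks, 0.5) == 0.0

    def test_monotone_drift_never_converges(self):
        blocks = [(10.0 * i, self._p([0, 1, 2, 3 + 2.0 * i])) for i in range(5)]
        assert declare_convergence(blocks, 0.5) is None

    def test_late_convergence_reports_first_stable_start(self):
        dgs = [[0, 9, 0, 0], [0, 5, 0, 0], [0, 1, 0, 0], [0, 1.1, 0, 0], [0, 0.9, 0, 0]]
        blocks = [(10.0 * i, self._p(dg)) for i, dg in enumerate(dgs)]
        assert declare_convergence(blocks, 0.5) == 20.0

    def test_requires_two_profiles(self):
        with pytest.raises(ValidationError):
            declare_convergence([(0.0, self._p([0, 0, 0, 0]))], 1.0)


class TestBootstrap:
    def test_zero_variance_input_gives_zero_std(self):
        w = _window([0.5] * 2_000)
        prof = bootstrap_pmf([w], THERMO, n_boot=10, seed=0,
                             bin_width=0.02, zero_from=None)
        assert np.all(prof.dg_sd[np.isfinite(prof.dg_sd)] == 0.0)

    def test_deterministic_given_seed(self):
        windows = _stationary_windows(400.0, seed=6)
        a = bootstrap_pmf(windows, THERMO, n_boot=8, seed=3, zero_from=None)
        b = bootstrap_pmf(windows, THERMO, n_boot=8, seed=3, zero_from=None)
        assert np.array_equal(a.dg_sd, b.dg_sd, equal_nan=True)

    def test_error_shrinks_with_more_data(self):
        small = _stationary_windows(300.0, seed=7)
        big = _stationary_windows(1200.0, seed=7)
        sd_small = bootstrap_pmf(small, THERMO, n_boot=25, seed=4, zero_from=None).dg_sd
        sd_big = bootstrap_pmf(big, THERMO, n_boot=25, seed=4, zero_from=None).dg_sd
        assert (np.median(sd_big[np.isfinite(sd_big)])
                < np.median(sd_small[np.isfinite(sd_small)]))

    def test_window_shorter_than_block_raises(self):
        t = np.arange(1, 41.0)
        pos = np.sin(t / 4.0) * 0.2 + 0.5
        w = UmbrellaWindow(0.5, SPRING_K, t, pos)
        with pytest.raises(ValidationError, match="block"):
            bootstrap_pmf([w], THERMO, n_boot=5, seed=0, zero_from=None,
                          block_length=100)
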