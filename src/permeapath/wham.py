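"""Weighted histogram analysis method (WHAM) for umbrella-sampling PMFs.

Given per-window biased position histograms, solves the standard WHAM
self-consistency equations

    P(z_b) ∝ Σ_i n_ib / Σ_i N_i exp(β(f_i − U_i(z_b)))
    f_i    = −RT ln Σ_b P(z_b) exp(−β U_i(z_b))

with harmonic biases U_i(z) = ½ k_i (z − z₀ᵢ)², iterated in log-space
until the window constants f_i stabilise.  The PMF is ΔG(z) = −RT ln P(z),
zero-referenced by subtracting its mean over the bulk-water region
(z ≥ 4.0 nm by convention here) so that the profile reports free energy
relative to the solvated permeant.

Also provides the convergence diagnostic used for long enhanced-sampling
runs — PMFs of sliding trajectory blocks (e.g. 50-ns blocks advanced in
10-ns increments) compared pairwise — and per-bin standard deviations by
moving-block bootstrap over each window's trajectory (blocks at least
one integrated autocorrelation time long, 200 resamples by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .diffusivity import integrated_autocorrelation_time
from .errors import ConvergenceError, DegenerateSeriesError, ValidationError
from .synthetic import UmbrellaWindow
from .thermo import ThermoState

__all__ = [
    "WindowHistogram",
    "FreeEnergyProfile",
    "WhamSolution",
    "make_edges",
    "histogram_window",
    "wham_solve",
    "zero_reference",
    "convergence_blocks",
    "declare_convergence",
    "bootstrap_pmf",
]

DEFAULT_BIN_WIDTH = 0.02  # nm; >= 10 bins per 0.2 nm window spacing
DEFAULT_ZERO_FROM = 4.0  # nm; bulk-water reference region
DEFAULT_N_BOOT = 200


@dataclass
class WindowHistogram:
    """Binned biased samples of one umbrella window."""

    center: float
    spring_k: float
    edges: np.ndarray  # strictly increasing bin edges, nm
    counts: np.ndarray  # per-bin counts
    n_outside: int = 0  # samples outside the edge range (reported, not dropped silently)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, float)
        self.counts = np.asarray(self.counts, float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValidationError("histogram edges must be strictly increasing")
        if self.counts.shape[0] != self.edges.shape[0] - 1:
            raise ValidationError("counts length must be len(edges) - 1")
        if np.any(self.counts < 0):
            raise ValidationError("histogram counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class FreeEnergyProfile:
    """ΔG(z) on a bin-center grid with optional bootstrap errors.

    Bins without any sampled support carry NaN rather than an
    extrapolated value.  ``reference_region`` records the z-interval
    whose mean was subtracted during zero-referencing.
    """

    z: np.ndarray  # bin centers, nm
    dg: np.ndarray  # kJ/mol
    dg_sd: np.ndarray | None = None  # kJ/mol
    reference_region: tuple[float, float] | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, float)
        self.dg = np.asarray(self.dg, float)
        if self.z.shape != self.dg.shape:
            raise ValidationError("z and dg must have the same shape")
        if self.dg_sd is not None:
            self.dg_sd = np.asarray(self.dg_sd, float)
            if self.dg_sd.shape != self.z.shape:
                raise ValidationError("dg_sd must match z")

    @property
    def support(self) -> np.ndarray:
        return np.isfinite(self.dg)

    def interp(self, z: np.ndarray) -> np.ndarray:
        """Linear interpolation of ΔG over the supported bins."""
        m = self.support
        if m.sum() < 2:
            raise ValidationError("profile has fewer than 2 supported bins")
        return np.interp(z, self.z[m], self.dg[m])

    def landmarks(self) -> dict:
        """Global minimum, global maximum and midplane (z≈0) values."""
        m = self.support
        z, dg = self.z[m], self.dg[m]
        i_min, i_max = int(np.argmin(dg)), int(np.argmax(dg))
        return {
            "min_dg": float(dg[i_min]),
            "min_z": float(z[i_min]),
            "max_dg": float(dg[i_max]),
            "max_z": float(z[i_max]),
            "dg_at_z0": float(dg[int(np.argmin(np.abs(z)))]),
        }


@dataclass
class WhamSolution:
    profile: FreeEnergyProfile
    f: np.ndarray  # per-window free-energy constants, kJ/mol (f[0] = 0 gauge)
    n_iter: int
    residual: float  # max |Δf| at the last iteration, kJ/mol


def make_edges(z_min: float, z_max: float, bin_width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Uniform bin edges covering [z_min, z_max] (at least one full bin)."""
    if z_max - z_min < bin_width:  # degenerate span: center one bin on it
        mid = 0.5 * (z_min + z_max)
        z_min, z_max = mid - bin_width / 2, mid + bin_width / 2
    n = max(1, int(round((z_max - z_min) / bin_width)))
    return np.linspace(z_min, z_max, n + 1)


def histogram_window(window: UmbrellaWindow, edges: np.ndarray) -> WindowHistogram:
    """Bin one window's positions with half-open [a, b) bins.

    The final bin is right-inclusive (``numpy.histogram`` convention).
    Samples outside the edge range are counted into ``n_outside``.
    """
    if window.positions.size == 0:
        raise ValidationError("cannot histogram an empty series")
    edges = np.asarray(edges, float)
    counts, _ = np.histogram(window.positions, bins=edges)
    n_outside = window.positions.size - int(counts.sum())
    return WindowHistogram(
        center=window.center,
        spring_k=window.spring_k,
        edges=edges,
        counts=counts,
        n_outside=n_outside,
    )


def _common_edges(histograms: Sequence[WindowHistogram]) -> np.ndarray:
    edges = histograms[0].edges
    for h in histograms[1:]:
        if h.edges.shape != edges.shape or not np.allclose(h.edges, edges):
            raise ValidationError("all histograms must share identical bin edges")
    return edges


def _check_overlap(histograms: Sequence[WindowHistogram]) -> None:
    order = np.argsort([h.center for h in histograms])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((histograms[a].counts > 0) & (histograms[b].counts > 0)):
            warnings.warn(
                f"no histogram overlap between adjacent windows at centers "
                f"{histograms[a].center:.3g} and {histograms[b].center:.3g} nm; "
                "bins between them are flagged as gaps",
                stacklevel=2,
            )


def wham_solve(
    histograms: Sequence[WindowHistogram],
    thermo: ThermoState = ThermoState(),
    tol: float = 1e-8,
    max_iter: int = 100_000,
    zero_from: float | None = None,
) -> WhamSolution:
    """Self-consistent WHAM solve on a shared bin grid.

    Iterates the window constants f_i until ``max |Δf| < tol`` (kJ/mol).
    Bins with zero total count across all windows are reported as NaN.
    If ``zero_from`` is given, the profile is zero-referenced over
    z ≥ zero_from; otherwise its minimum is placed at zero.
    """
    if len(histograms) == 0:
        raise ValidationError("need at least one histogram")
    edges = _common_edges(histograms)
    _check_overlap(histograms)
    zb = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    rt, beta = thermo.rt, thermo.beta

    counts = np.array([h.counts for h in histograms])  # (W, B)
    n_i = counts.sum(axis=1)  # (W,)
    if np.any(n_i == 0):
        raise ValidationError("every histogram must contain at least one sample")
    u = 0.5 * np.array([h.spring_k for h in histograms])[:, None] * (
        zb[None, :] - np.array([h.center for h in histograms])[:, None]
    ) ** 2  # (W, B)

    total = counts.sum(axis=0)  # (B,)
    occupied = total > 0
    log_num = np.full(zb.shape, -np.inf)
    log_num[occupied] = np.log(total[occupied])
    log_ni = np.log(n_i)
    log_w = np.log(widths)

    bf = np.zeros(len(histograms))  # β f_i
    residual = np.inf
    for it in range(1, max_iter + 1):
        # log P_b (unnormalised): data over reweighted denominator
        log_den = logsumexp(log_ni[:, None] + bf[:, None] - beta * u, axis=0)
        log_p = log_num - log_den
        # update β f_i = −ln Σ_b P_b w_b exp(−β U_ib)
        bf_new = -logsumexp(log_p[None, :] + log_w[None, :] - beta * u, axis=1)
        bf_new -= bf_new[0]  # gauge: f_0 = 0
        residual = float(np.max(np.abs(bf_new - bf))) * rt
        bf = bf_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last residual {residual:.3g} kJ/mol)",
            residual=residual,
        )

    log_den = logsumexp(log_ni[:, None] + bf[:, None] - beta * u, axis=0)
    with np.errstate(invalid="ignore"):
        dg = np.where(occupied, -rt * (log_num - log_den - log_w), np.nan)
    profile = FreeEnergyProfile(z=zb, dg=dg)
    if zero_from is not None:
        profile = zero_reference(profile, zero_from)
    else:
        profile.dg = profile.dg - np.nanmin(profile.dg)
    return WhamSolution(profile=profile, f=bf * rt, n_iter=it, residual=residual)


def zero_reference(profile: FreeEnergyProfile, bulk_min_z: float = DEFAULT_ZERO_FROM) -> FreeEnergyProfile:
    """Shift ΔG so its mean over supported bins with z ≥ bulk_min_z is zero."""
    mask = (profile.z >= bulk_min_z) & profile.support
    if not np.any(mask):
        raise ValidationError(
            f"no supported bins with z >= {bulk_min_z} to use as the zero reference"
        )
    shift = float(np.mean(profile.dg[mask]))
    return FreeEnergyProfile(
        z=profile.z.copy(),
        dg=profile.dg - shift,
        dg_sd=None if profile.dg_sd is None else profile.dg_sd.copy(),
        reference_region=(float(bulk_min_z), float(profile.z[profile.support].max())),
    )


def _slice_window(window: UmbrellaWindow, t_start: float, t_stop: float) -> UmbrellaWindow:
    t0 = window.times[0]
    mask = (window.times >= t0 + t_start) & (window.times < t0 + t_stop + 1e-9)
    return UmbrellaWindow(
        center=window.center,
        spring_k=window.spring_k,
        times=window.times[mask],
        positions=window.positions[mask],
    )


def convergence_blocks(
    windows: Sequence[UmbrellaWindow],
    block_length: float,
    step: float,
    thermo: ThermoState = ThermoState(),
    bin_width: float = DEFAULT_BIN_WIDTH,
    zero_from: float | None = DEFAULT_ZERO_FROM,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> list[tuple[float, FreeEnergyProfile]]:
    """PMF per sliding trajectory block [t, t + block_length].

    For a 250-ns series analysed in 50-ns blocks advanced by 10 ns this
    yields 21 profiles (0–50 … 200–250).  Block start times are relative
    to each window's first sample.
    """
    if block_length <= 0 or step <= 0:
        raise ValidationError("block_length and step must be positive")
    # one sample at time t covers (t - dt, t], so n samples span n*dt
    duration = min(float(w.times[-1] - w.times[0] + w.dt_sample) for w in windows)
    if block_length > duration * (1 + 1e-9):
        raise ValidationError(
            f"block length {block_length} ps exceeds the series duration {duration} ps"
        )
    n_blocks = int(np.floor((duration - block_length) / step + 1e-9)) + 1
    lo = min(w.positions.min() for w in windows)
    hi = max(w.positions.max() for w in windows)
    edges = make_edges(lo, hi, bin_width)
    out = []
    for b in range(n_blocks):
        t = b * step
        sliced = [_slice_window(w, t, t + block_length) for w in windows]
        hists = [histogram_window(w, edges) for w in sliced]
        sol = wham_solve(hists, thermo, tol=tol, max_iter=max_iter, zero_from=zero_from)
        out.append((t, sol.profile))
    return out


def declare_convergence(
    block_profiles: Sequence[tuple[float, FreeEnergyProfile]],
    criterion_kjmol: float = 1.0,
) -> float | None:
    """Earliest block start after which all later profiles pairwise agree.

    Agreement means the maximum absolute ΔG deviation over jointly
    supported bins is at most ``criterion_kjmol``.  Returns ``None``
    when no tail of at least two blocks satisfies the criterion.
    """
    if len(block_profiles) < 2:
        raise ValidationError("need at least 2 block profiles")

    def max_dev(p: FreeEnergyProfile, q: FreeEnergyProfile) -> float:
        m = p.support & q.support
        if not np.any(m):
            return np.inf
        return float(np.max(np.abs(p.dg[m] - q.dg[m])))

    n = len(block_profiles)
    for start in range(n - 1):
        tail = block_profiles[start:]
        if all(
            max_dev(tail[a][1], tail[b][1]) <= criterion_kjmol
            for a in range(len(tail))
            for b in range(a + 1, len(tail))
        ):
            return float(tail[0][0])
    return None


def _block_resample(positions: np.ndarray, block: int, rng: np.random.Generator) -> np.ndarray:
    n = positions.size
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n - block + 1, size=n_blocks)
    pieces = [positions[s : s + block] for s in starts]
    return np.concatenate(pieces)[:n]


def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    thermo: ThermoState = ThermoState(),
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    bin_width: float = DEFAULT_BIN_WIDTH,
    zero_from: float | None = DEFAULT_ZERO_FROM,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    block_length: int | None = None,
) -> FreeEnergyProfile:
    """PMF with per-bin standard deviation by moving-block bootstrap.

    Each window's series is resampled in contiguous blocks at least one
    integrated autocorrelation time long (so resamples respect the
    series' correlation structure), WHAM is re-solved ``n_boot`` times
    (default 200), and the per-bin standard deviation across resamples
    is attached to the full-data profile.  ``block_length`` (in samples)
    overrides the per-window IACT-derived choice.  Deterministic given
    ``seed``.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    lo = min(w.positions.min() for w in windows)
    hi = max(w.positions.max() for w in windows)
    edges = make_edges(lo, hi, bin_width)

    blocks = []
    for w in windows:
        if block_length is not None:
            b = int(block_length)
        else:
            try:
                tau = integrated_autocorrelation_time(w.positions, w.dt_sample)
                b = max(1, int(np.ceil(tau / w.dt_sample)))
            except DegenerateSeriesError:
                b = 1  # constant series: any block length is equivalent
        if b > w.positions.size:
            raise ValidationError(
                f"window at center {w.center:.3g} nm is shorter than one "
                f"bootstrap block ({b} samples)"
            )
        blocks.append(b)

    hists = [histogram_window(w, edges) for w in windows]
    base = wham_solve(hists, thermo, tol=tol, max_iter=max_iter, zero_from=zero_from)

    rng = np.random.default_rng(seed)
    replicates = np.empty((n_boot, base.profile.z.size))
    for r in range(n_boot):
        rh = []
        for w, b in zip(windows, blocks):
            res = _block_resample(w.positions, b, rng)
            rh.append(
                WindowHistogram(
                    center=w.center,
                    spring_k=w.spring_k,
                    edges=edges,
                    counts=np.histogram(res, bins=edges)[0],
                )
            )
        sol = wham_solve(rh, thermo, tol=tol, max_iter=max_iter, zero_from=zero_from)
        replicates[r] = sol.profile.dg
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        sd = np.nanstd(replicates, axis=0)
    return FreeEnergyProfile(
        z=base.profile.z,
        dg=base.profile.dg,
        dg_sd=sd,
        reference_region=base.profile.reference_region,
    )
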