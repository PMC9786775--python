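"""Selective solute-tempering replica exchange (REST-style) machinery.

Models the bookkeeping of Hamiltonian replica exchange with solute
tempering on 1-D toy systems.  Each rung r of a replica ladder carries a
scaling factor λ_r ∈ (0, 1] applied only to the solute–environment
coupling term, so the total potential at rung r is

    U_λ(z) = U_env(z) + λ·U_int(z) + U_bias(z),

with the ground replica λ₁ = 1.0 holding the unperturbed Hamiltonian
(its samples feed WHAM).  Neighbouring rungs attempt Metropolis
coordinate swaps every exchange interval (default 0.1 ps), alternating
even and odd pairs; since only the λ·U_int term differs between rungs,
the exchange energy reduces to

    Δ = (λ_i − λ_j)·(U_int(z_j) − U_int(z_i)),   p = min(1, e^{−βΔ}).

Practical ladders are tuned so neighbour acceptance sits in the 20–30%
band.  No force-field-level √λ charge scaling is attempted: the
implementable contribution here is the acceptance and campaign
accounting, not an MD engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .synthetic import Landscape, LangevinConfig, UmbrellaWindow, _bd_kernel, _drift_tables, _check_dt, simulate_window
from .thermo import ThermoState

__all__ = [
    "ReplicaLadder",
    "ToyTemperedSystem",
    "ExchangeStats",
    "CampaignPlan",
    "LadderTuning",
    "scaled_potential",
    "exchange_accept_probability",
    "run_toy_rest3",
    "tune_ladder",
    "plan_campaign",
    "TARGET_ACCEPTANCE",
]

#: Neighbour-pair acceptance band practical ladders are tuned into.
TARGET_ACCEPTANCE = (0.20, 0.30)


@dataclass(frozen=True)
class ReplicaLadder:
    """Scaling factors λ₁ = 1.0 > λ₂ > … and the exchange attempt interval."""

    lambdas: tuple[float, ...]
    exchange_interval: float = 0.1  # ps

    def __post_init__(self):
        lams = self.lambdas
        if len(lams) == 0:
            raise ValidationError("ladder needs at least one rung")
        if not math.isclose(lams[0], 1.0):
            raise ValidationError("ground replica must have scaling factor 1.0")
        if any(b >= a for a, b in zip(lams, lams[1:])):
            raise ValidationError("scaling factors must be strictly decreasing")
        if any(not (0 < l <= 1) for l in lams):
            raise ValidationError("scaling factors must lie in (0, 1]")
        if self.exchange_interval <= 0:
            raise ValidationError("exchange interval must be positive")

    @property
    def n_rungs(self) -> int:
        return len(self.lambdas)


@dataclass
class ToyTemperedSystem:
    """1-D system split into environment, scaled coupling, and bias terms.

    ``u_env`` and ``u_int`` are vectorised callables (kJ/mol) on
    ``[z_min, z_max]``; the umbrella bias is supplied separately when
    running.  ``diffusivity`` is the constant D (nm²/ps) used by the
    toy Langevin walkers.
    """

    u_env: Callable[[np.ndarray], np.ndarray]
    u_int: Callable[[np.ndarray], np.ndarray]
    z_min: float = 0.0
    z_max: float = 4.4
    diffusivity: float = 1e-3

    def __post_init__(self):
        if not self.z_max > self.z_min:
            raise ValidationError("need z_max > z_min")
        if self.diffusivity <= 0:
            raise ValidationError("diffusivity must be positive")

    def landscape_at(self, lam: float) -> Landscape:
        """The rung-λ effective landscape U_env + λ·U_int with constant D."""
        d0 = self.diffusivity
        return Landscape(
            g_of_z=lambda z, l=lam: np.asarray(self.u_env(z), float) + l * np.asarray(self.u_int(z), float),
            d_of_z=lambda z: np.full_like(np.asarray(z, float), d0),
            z_min=self.z_min,
            z_max=self.z_max,
            name=f"toy-lambda-{lam:g}",
        )


def scaled_potential(system: ToyTemperedSystem, lam: float, z, u_bias=None):
    """Total potential U_env(z) + λ·U_int(z) + U_bias(z) in kJ/mol."""
    if not (0 < lam <= 1):
        raise ValidationError(f"scaling factor must be in (0, 1], got {lam}")
    z = np.asarray(z, float)
    total = np.asarray(system.u_env(z), float) + lam * np.asarray(system.u_int(z), float)
    if u_bias is not None:
        total = total + np.asarray(u_bias(z), float)
    return float(total) if total.ndim == 0 else total


def exchange_accept_probability(
    system: ToyTemperedSystem,
    lam_i: float,
    lam_j: float,
    z_i: float,
    z_j: float,
    thermo: ThermoState = ThermoState(),
) -> float:
    """Metropolis probability of swapping configurations between rungs.

    Only the λ·U_int term differs between rungs (environment and bias
    cancel), so Δ = (λ_i − λ_j)·(U_int(z_j) − U_int(z_i)).  Symmetric in
    (i, j) by construction.
    """
    for lam in (lam_i, lam_j):
        if not (0 < lam <= 1):
            raise ValidationError(f"scaling factor must be in (0, 1], got {lam}")
    du = float(system.u_int(np.asarray(z_j, float))) - float(system.u_int(np.asarray(z_i, float)))
    delta = (lam_i - lam_j) * du
    return min(1.0, math.exp(-thermo.beta * delta))


@dataclass
class ExchangeStats:
    """Per neighbour pair: attempts, acceptances; plus rung visitation.

    ``visitation[c, r]`` counts exchange intervals configuration ``c``
    (identified by its starting rung) spent at rung ``r``.
    """

    attempts: np.ndarray  # (n_rungs - 1,)
    accepts: np.ndarray  # (n_rungs - 1,)
    visitation: np.ndarray  # (n_rungs, n_rungs)

    def __post_init__(self):
        if np.any(self.accepts > self.attempts):
            raise ValidationError("acceptances cannot exceed attempts")

    @property
    def acceptance_fractions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.attempts > 0, self.accepts / self.attempts, np.nan)


def run_toy_rest3(
    system: ToyTemperedSystem,
    ladder: ReplicaLadder,
    center: float,
    spring_k: float,
    cfg: LangevinConfig,
) -> tuple[UmbrellaWindow, ExchangeStats]:
    """Simulate one umbrella window with a solute-tempering ladder.

    One Langevin walker runs per rung on its scaled potential; every
    exchange interval, neighbouring rungs attempt a Metropolis
    coordinate swap (alternating even/odd pairs).  Returns the
    ground-replica trajectory (the unperturbed ensemble, suitable for
    WHAM) and the exchange statistics.  A single-rung ladder reduces
    exactly to :func:`simulate_window` on the λ = 1 landscape, with the
    same seed path.
    """
    m = ladder.n_rungs
    if ladder.exchange_interval < cfg.dt:
        raise ValidationError("exchange interval must be at least one time step")
    if m == 1:
        window = simulate_window(system.landscape_at(1.0), center, spring_k, cfg)
        empty = ExchangeStats(
            attempts=np.zeros(0, int), accepts=np.zeros(0, int), visitation=np.ones((1, 1), int)
        )
        return window, empty

    steps_per_seg = max(1, int(round(ladder.exchange_interval / cfg.dt)))
    n_segments = cfg.n_steps // steps_per_seg

    tables = []
    for lam in ladder.lambdas:
        scape = system.landscape_at(lam)
        zg, _, d_t, dgdz_t, dddz_t = _drift_tables(scape)
        _check_dt(scape, spring_k, cfg, dgdz_t, d_t, dddz_t)
        tables.append((zg, dgdz_t, d_t, dddz_t))

    seq = np.random.SeedSequence(cfg.seed)
    children = seq.spawn(m + 1)
    rung_rngs = [np.random.default_rng(c) for c in children[:m]]
    swap_rng = np.random.default_rng(children[m])

    beta = cfg.thermo.beta
    z = np.full(m, float(center))
    config_at = np.arange(m)  # which configuration id occupies each rung
    n_post = cfg.n_steps - cfg.equilibration_steps
    n_samples = n_post // cfg.sample_stride
    ground = np.empty(max(n_samples, 1))
    g_count = 0

    attempts = np.zeros(m - 1, dtype=int)
    accepts = np.zeros(m - 1, dtype=int)
    visitation = np.zeros((m, m), dtype=int)

    global_step = 0
    for seg in range(n_segments):
        for r in range(m):
            zg, dgdz_t, d_t, dddz_t = tables[r]
            normals = rung_rngs[r].standard_normal(steps_per_seg)
            if r == 0:
                offset = global_step - cfg.equilibration_steps
                z_new, g_count = _bd_kernel(
                    z[0], zg, dgdz_t, d_t, dddz_t, beta, spring_k, center,
                    system.z_min, system.z_max, cfg.dt, normals,
                    cfg.sample_stride, offset, ground, g_count,
                )
                z[0] = z_new
            else:
                scratch = np.empty(1)
                z_new, _ = _bd_kernel(
                    z[r], zg, dgdz_t, d_t, dddz_t, beta, spring_k, center,
                    system.z_min, system.z_max, cfg.dt, normals,
                    steps_per_seg + 1, 0, scratch, 0,
                )
                z[r] = z_new
        global_step += steps_per_seg
        # alternating even/odd neighbour swap attempts
        first = 0 if seg % 2 == 0 else 1
        for i in range(first, m - 1, 2):
            p = exchange_accept_probability(
                system, ladder.lambdas[i], ladder.lambdas[i + 1], z[i], z[i + 1], cfg.thermo
            )
            attempts[i] += 1
            if swap_rng.random() <= p:
                accepts[i] += 1
                z[i], z[i + 1] = z[i + 1], z[i]
                config_at[i], config_at[i + 1] = config_at[i + 1], config_at[i]
        for r in range(m):
            visitation[config_at[r], r] += 1

    times = cfg.dt * (cfg.equilibration_steps + cfg.sample_stride * (np.arange(g_count) + 1.0))
    window = UmbrellaWindow(
        center=float(center), spring_k=float(spring_k),
        times=times, positions=ground[:g_count],
    )
    return window, ExchangeStats(attempts=attempts, accepts=accepts, visitation=visitation)


@dataclass
class LadderTuning:
    """Result of ladder tuning: the ladder, pilot stats, and a status flag.

    ``status`` is ``"ok"`` when every neighbour acceptance landed in the
    target band, or ``"above_target"`` when even the minimal two-rung
    ladder exceeds the band (weak coupling; harmless).
    """

    ladder: ReplicaLadder
    pilot_stats: ExchangeStats
    status: str


def _geometric_ladder(m: int, lambda_min: float, interval: float) -> ReplicaLadder:
    lams = tuple(float(lambda_min ** (r / (m - 1))) for r in range(m))
    return ReplicaLadder(lambdas=lams, exchange_interval=interval)


def tune_ladder(
    system: ToyTemperedSystem,
    center: float,
    spring_k: float,
    cfg: LangevinConfig,
    target_acceptance: tuple[float, float] = TARGET_ACCEPTANCE,
    lambda_min: float = 0.3,
    max_rungs: int = 16,
    exchange_interval: float = 0.1,
) -> LadderTuning:
    """Find the smallest geometric ladder meeting the acceptance band.

    Bisects on the rung count between 2 and ``max_rungs``: acceptance
    between geometric neighbours increases with rung count, so the
    smallest count whose *minimum* neighbour acceptance reaches the
    band's lower edge is located by bisection on short pilot runs.
    Raises when even ``max_rungs`` rungs stay below the band.
    """
    lo_t, hi_t = target_acceptance
    if not (0 < lo_t < hi_t < 1):
        raise ValidationError("target acceptance interval must satisfy 0 < lo < hi < 1")

    def pilot(m: int) -> tuple[ReplicaLadder, ExchangeStats, float]:
        ladder = _geometric_ladder(m, lambda_min, exchange_interval)
        _, stats = run_toy_rest3(system, ladder, center, spring_k, cfg)
        return ladder, stats, float(np.min(stats.acceptance_fractions))

    ladder, stats, acc = pilot(max_rungs)
    if acc < lo_t:
        raise ValidationError(
            f"target acceptance {target_acceptance} unattainable with <= {max_rungs} "
            f"rungs down to lambda_min={lambda_min} (best min acceptance {acc:.3f}); "
            "raise max_rungs or lambda_min"
        )
    lo, hi = 2, max_rungs  # smallest m with min-acceptance >= lo_t lies in [lo, hi]
    best = (ladder, stats, acc)
    while lo < hi:
        mid = (lo + hi) // 2
        ladder, stats, acc = pilot(mid)
        if acc >= lo_t:
            best = (ladder, stats, acc)
            hi = mid
        else:
            lo = mid + 1
    ladder, stats, acc = best
    status = "above_target" if (ladder.n_rungs == 2 and acc > hi_t) else "ok"
    return LadderTuning(ladder=ladder, pilot_stats=stats, status=status)


@dataclass
class CampaignPlan:
    """Replica-count and simulation-time accounting for a window campaign."""

    centers: tuple[float, ...]
    rungs_per_window: tuple[int, ...]  # 1 for plain (non-tempered) windows
    run_length_ns: float
    tempered: tuple[bool, ...]

    @property
    def n_replicas(self) -> int:
        return int(sum(self.rungs_per_window))

    @property
    def total_time_ns(self) -> float:
        return self.n_replicas * self.run_length_ns


def plan_campaign(
    centers: Sequence[float],
    schemes: dict[float, int],
    run_length_ns: float,
    rest3_windows: Sequence[float] | None = None,
) -> CampaignPlan:
    """Totals for an umbrella campaign with tempering on selected windows.

    ``schemes`` maps each tempered window center to its rung count;
    windows not in ``rest3_windows`` run as single plain replicas.  By
    default every center with a scheme entry is treated as tempered.
    """
    if run_length_ns <= 0:
        raise ValidationError("run length must be positive")
    key = lambda c: round(float(c), 9)  # tolerate float-arithmetic centers
    schemes = {key(c): n for c, n in schemes.items()}
    if rest3_windows is None:
        rest3_windows = tuple(schemes)
    rest3_set = {key(c) for c in rest3_windows}
    rungs, tempered = [], []
    for c0 in centers:
        c = key(c0)
        if c in rest3_set:
            if c not in schemes:
                raise ValidationError(f"no replica scheme assigned to tempered window {c:g}")
            if schemes[c] < 1:
                raise ValidationError("rung counts must be >= 1")
            rungs.append(int(schemes[c]))
            tempered.append(True)
        else:
            rungs.append(1)
            tempered.append(False)
    return CampaignPlan(
        centers=tuple(float(c) for c in centers),
        rungs_per_window=tuple(rungs),
        run_length_ns=float(run_length_ns),
        tempered=tuple(tempered),
    )
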