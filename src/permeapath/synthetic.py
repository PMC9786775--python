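"""Synthetic umbrella-window generator: 1-D overdamped Langevin dynamics.

Stands in for the MD engine.  A permeant's reaction coordinate z (its
centre-of-mass distance from the bilayer midplane, nm) is propagated by
Itô–Euler Brownian dynamics on a prescribed free-energy landscape G(z)
with position-dependent diffusivity D(z), under a harmonic umbrella bias
U_b(z) = ½k(z−z₀)²:

    z' = z + [−βD(z)·(G'(z) + k(z−z₀)) + D'(z)]·dt + √(2·D(z)·dt)·η

with η ~ N(0,1) and β = 1/(RT).  The explicit ∇D drift term (Itô
convention) guarantees the stationary density is the Boltzmann weight
exp(−β(G + U_b)) even when D varies with position, which is exactly what
the downstream WHAM/diffusivity parameter-recovery tests rely on.
Boundaries are reflecting at the landscape's domain edges (a stand-in
for the bulk-water slab, avoiding periodic free-energy surfaces).

The built-in :func:`sc_bilayer_landscape` fixtures interpolate the
free-energy landmarks of 5-ALA-like and Me-5-ALA-like permeation through
a stratum-corneum ceramide/cholesterol/free-fatty-acid bilayer at 305 K
(headgroup minimum, tail-region barrier, midplane offset, zero plateau
in bulk water for z ≥ 4.0 nm) with diffusivities dropping about two
orders of magnitude from bulk water into the dense tail region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit
from scipy.interpolate import PchipInterpolator

from .errors import ValidationError
from .hbonds import Frame, ROLE_ACCEPTOR, ROLE_DONOR, ROLE_HYDROGEN
from .thermo import ThermoState

__all__ = [
    "Landscape",
    "LangevinConfig",
    "UmbrellaWindow",
    "simulate_window",
    "plan_windows",
    "sc_bilayer_landscape",
    "make_hbond_frame",
    "DEFAULT_SPRING_K",
]

#: Umbrella force constant used throughout (kJ mol⁻¹ nm⁻²).
DEFAULT_SPRING_K = 500.0


@dataclass
class Landscape:
    """Ground-truth free energy G(z) (kJ/mol) and diffusivity D(z) (nm²/ps).

    ``g_of_z`` and ``d_of_z`` are vectorised callables on the domain
    ``[z_min, z_max]`` (nm); D must be strictly positive everywhere.
    """

    g_of_z: Callable[[np.ndarray], np.ndarray]
    d_of_z: Callable[[np.ndarray], np.ndarray]
    z_min: float = 0.0
    z_max: float = 4.4
    name: str = "landscape"

    def __post_init__(self):
        if not self.z_max > self.z_min:
            raise ValidationError("landscape domain must have z_max > z_min")
        z = np.linspace(self.z_min, self.z_max, 512)
        g = np.asarray(self.g_of_z(z), dtype=float)
        d = np.asarray(self.d_of_z(z), dtype=float)
        if not np.all(np.isfinite(g)):
            raise ValidationError("G(z) must be finite on the domain")
        if not (np.all(np.isfinite(d)) and np.all(d > 0)):
            raise ValidationError("D(z) must be strictly positive on the domain")

    def tabulate(self, n: int = 4096) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fine tables (z, G, D) used by the integrator and by oracles."""
        z = np.linspace(self.z_min, self.z_max, n)
        return z, np.asarray(self.g_of_z(z), float), np.asarray(self.d_of_z(z), float)

    @classmethod
    def from_tables(
        cls,
        z: Sequence[float],
        g: Sequence[float],
        d: Sequence[float],
        name: str = "tabulated",
    ) -> "Landscape":
        """Monotone-cubic (PCHIP) landscape through tabulated points.

        D is interpolated in log-space so it stays positive even when it
        spans orders of magnitude.
        """
        z = np.asarray(z, float)
        if np.any(np.diff(z) <= 0):
            raise ValidationError("landscape table z values must be strictly increasing")
        d = np.asarray(d, float)
        if np.any(d <= 0):
            raise ValidationError("tabulated D must be strictly positive")
        g_i = PchipInterpolator(z, np.asarray(g, float))
        logd_i = PchipInterpolator(z, np.log(d))
        return cls(
            g_of_z=g_i,
            d_of_z=lambda x: np.exp(logd_i(x)),
            z_min=float(z[0]),
            z_max=float(z[-1]),
            name=name,
        )


# Free-energy landmarks (z nm, G kJ/mol) for the two permeant-like
# fixtures: midplane offset, tail-region barrier, headgroup minimum and
# a flat bulk-water plateau (G ≡ 0 for z ≥ 4.0 nm).
_G_LANDMARKS = {
    "me5ala": [(0.0, 3.4), (0.7, 24.5), (2.4, -21.1), (4.0, 0.0), (4.2, 0.0), (4.4, 0.0)],
    "5ala": [(0.0, 20.3), (0.7, 30.2), (2.2, -23.0), (4.0, 0.0), (4.2, 0.0), (4.4, 0.0)],
}

# log10 D anchors (nm²/ps): bulk-water diffusivity ~1e-3 nm²/ps for a
# small organic solute, dropping ~2 orders of magnitude (Me-5-ALA-like)
# or almost 3 (5-ALA-like) in the dense tail region, with a partial
# recovery in the low-density interdigitating region near the midplane.
_LOGD_ANCHORS = {
    "me5ala": [(0.0, -3.4), (0.2, -3.1), (0.8, -5.0), (1.6, -4.3), (2.4, -3.9),
               (2.8, -3.3), (4.0, -3.0), (4.2, -3.0), (4.4, -3.0)],
    "5ala": [(0.0, -3.9), (0.2, -3.6), (0.6, -5.8), (1.6, -4.5), (2.6, -4.0),
             (2.8, -3.4), (4.0, -3.0), (4.2, -3.0), (4.4, -3.0)],
}


def sc_bilayer_landscape(species: str = "me5ala") -> Landscape:
    """Built-in stratum-corneum-like landscape fixture.

    ``species`` is ``"me5ala"`` (shallower headgroup well, lower tail
    barrier, higher core diffusivity) or ``"5ala"``.
    """
    key = species.lower().replace("-", "").replace("_", "")
    if key not in _G_LANDMARKS:
        raise ValidationError(f"unknown landscape fixture {species!r}; use 'me5ala' or '5ala'")
    gz, gv = zip(*_G_LANDMARKS[key])
    dz, dv = zip(*_LOGD_ANCHORS[key])
    g_i = PchipInterpolator(np.array(gz), np.array(gv))
    logd_i = PchipInterpolator(np.array(dz), np.array(dv))
    return Landscape(
        g_of_z=g_i,
        d_of_z=lambda x: 10.0 ** logd_i(x),
        z_min=0.0,
        z_max=4.4,
        name=f"sc-bilayer-{key}",
    )


@dataclass(frozen=True)
class LangevinConfig:
    """Integrator settings: dt (ps), step counts, sampling and seed.

    ``sample_stride`` controls the saved-sample spacing; with the
    default dt = 0.01 ps, strides of 10–100 give the intended 0.1–1 ps
    spacing.  ``equilibration_steps`` are discarded before sampling.
    """

    dt: float = 0.01
    n_steps: int = 100_000
    sample_stride: int = 10
    temperature: float = 305.0
    seed: int = 0
    equilibration_steps: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if not self.n_steps > self.equilibration_steps >= 0:
            raise ValidationError("need n_steps > equilibration_steps >= 0")
        if self.sample_stride < 1:
            raise ValidationError("sample_stride must be >= 1")

    @property
    def thermo(self) -> ThermoState:
        return ThermoState(temperature=self.temperature)


@dataclass
class UmbrellaWindow:
    """One biased simulation: window metadata plus its z(t) series."""

    center: float  # nm
    spring_k: float  # kJ mol^-1 nm^-2
    times: np.ndarray  # ps, strictly increasing, uniform
    positions: np.ndarray  # nm

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        if self.times.shape != self.positions.shape or self.times.ndim != 1:
            raise ValidationError("times and positions must be matching 1-D arrays")
        if self.spring_k < 0:
            raise ValidationError("spring constant must be >= 0")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("positions must be finite")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValidationError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
                raise ValidationError("times must be uniformly spaced")

    @property
    def dt_sample(self) -> float:
        """Spacing of the saved series in ps."""
        if self.times.size < 2:
            raise ValidationError("window has fewer than 2 samples")
        return float(self.times[1] - self.times[0])

    @property
    def n_samples(self) -> int:
        return self.times.size


@njit(cache=True)
def _bd_kernel(z0, zg, dgdz_t, d_t, dddz_t, beta, k, zc, zlo, zhi, dt,
               normals, stride, offset, out, start_idx):  # pragma: no cover - numba
    z = z0
    m = start_idx
    sqrt2dt = math.sqrt(2.0 * dt)
    for i in range(normals.shape[0]):
        d = np.interp(z, zg, d_t)
        dgdz = np.interp(z, zg, dgdz_t)
        dddz = np.interp(z, zg, dddz_t)
        force = -(dgdz + k * (z - zc))
        z = z + (beta * d * force + dddz) * dt + math.sqrt(d) * sqrt2dt * normals[i]
        while z < zlo or z > zhi:
            if z < zlo:
                z = 2.0 * zlo - z
            else:
                z = 2.0 * zhi - z
        j = offset + i
        if j >= 0 and (j + 1) % stride == 0 and m < out.shape[0]:
            out[m] = z
            m += 1
    return z, m


def _drift_tables(landscape: Landscape, n: int = 4096):
    z, g, d = landscape.tabulate(n)
    dgdz = np.gradient(g, z)
    dddz = np.gradient(d, z)
    return z, g, d, dgdz, dddz


def _check_dt(landscape, spring_k, cfg, dgdz, d, dddz):
    width = landscape.z_max - landscape.z_min
    beta = cfg.thermo.beta
    f_max = np.max(np.abs(dgdz)) + spring_k * width
    drift_max = beta * np.max(d) * f_max + np.max(np.abs(dddz))
    if drift_max * cfg.dt > width:
        raise ValidationError(
            f"dt={cfg.dt} ps is too large: worst-case drift step "
            f"{drift_max * cfg.dt:.3g} nm exceeds the domain width {width:.3g} nm; "
            "use a smaller dt"
        )


def simulate_window(
    landscape: Landscape,
    center: float,
    spring_k: float,
    cfg: LangevinConfig,
) -> UmbrellaWindow:
    """Run one umbrella window by Itô–Euler Brownian dynamics.

    The walker starts at the bias center, runs
    ``cfg.equilibration_steps`` discarded steps, then records one sample
    every ``cfg.sample_stride`` steps.  Bit-identical for equal seeds.
    """
    if not (landscape.z_min <= center <= landscape.z_max):
        raise ValidationError(
            f"window center {center} outside landscape domain "
            f"[{landscape.z_min}, {landscape.z_max}]"
        )
    zg, _, d_t, dgdz_t, dddz_t = _drift_tables(landscape)
    _check_dt(landscape, spring_k, cfg, dgdz_t, d_t, dddz_t)
    n_post = cfg.n_steps - cfg.equilibration_steps
    n_samples = n_post // cfg.sample_stride
    if n_samples < 1:
        raise ValidationError("configuration yields no saved samples")
    rng = np.random.default_rng(cfg.seed)
    normals = rng.standard_normal(cfg.n_steps)
    out = np.empty(n_samples)
    _bd_kernel(
        float(center), zg, dgdz_t, d_t, dddz_t, cfg.thermo.beta, float(spring_k),
        float(center), landscape.z_min, landscape.z_max, cfg.dt,
        normals, cfg.sample_stride, -cfg.equilibration_steps, out, 0,
    )
    times = cfg.dt * (cfg.equilibration_steps + cfg.sample_stride * (np.arange(n_samples) + 1.0))
    return UmbrellaWindow(center=float(center), spring_k=float(spring_k),
                          times=times, positions=out)


def plan_windows(z_min: float, z_max: float, spacing: float) -> np.ndarray:
    """Inclusive arithmetic ladder of umbrella centers.

    The standard schedule (0.0, 4.4, 0.2) yields 23 windows from the
    bilayer midplane to bulk water.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    if z_max < z_min:
        raise ValidationError("z_max must be >= z_min")
    n_float = (z_max - z_min) / spacing
    n = round(n_float)
    if abs(n_float - n) > 1e-9:
        raise ValidationError(
            f"range [{z_min}, {z_max}] is not commensurate with spacing {spacing}"
        )
    return z_min + spacing * np.arange(n + 1)


def make_hbond_frame(
    spec: Sequence[tuple[str, str, Sequence[float], Sequence[float], Sequence[float]]],
    focus: str = "permeant",
) -> Frame:
    """Build a labelled frame from explicit donor/hydrogen/acceptor triplets.

    Each entry is ``(donor_species, acceptor_species, donor_pos,
    hydrogen_pos, acceptor_pos)`` with positions as 3-vectors in nm; the
    two species labels allow hetero-molecular bonds (e.g. permeant donor
    to water acceptor).  The frame contains exactly the requested
    geometry and nothing else.
    """
    positions, species, roles, parents = [], [], [], []
    for donor_sp, acceptor_sp, d_pos, h_pos, a_pos in spec:
        d_idx = len(positions)
        positions.extend([list(map(float, d_pos)), list(map(float, h_pos)),
                          list(map(float, a_pos))])
        species.extend([donor_sp, donor_sp, acceptor_sp])
        roles.extend([ROLE_DONOR, ROLE_HYDROGEN, ROLE_ACCEPTOR])
        parents.extend([-1, d_idx, -1])
    return Frame(
        positions=np.array(positions).reshape(-1, 3),
        species=species,
        roles=roles,
        parents=np.array(parents, dtype=int),
    )
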