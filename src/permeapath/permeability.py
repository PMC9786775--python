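"""Membrane and transdermal permeability.

The inhomogeneous solubility-diffusion model gives the permeability
coefficient of a single leaflet from the free-energy profile ΔG(z) and
the position-dependent diffusivity D(z):

    1/P = ∫_{z₁}^{z₂} exp(ΔG(z)/RT) / D(z) dz                 (leaflet)

with ΔG zero-referenced in bulk water so the integrand tends to 1/D_bulk
outside the membrane.  The stratum corneum is then modelled as 100
stacked lipid bilayers — 200 leaflets — whose resistances add in series:

    1/P_trans = Σ_{i=1}^{200} 1/P_i                            (stack)

Units: with ΔG in kJ/mol, z in nm and D in nm²/ps, P emerges in nm/ps.

Numerical choices: ΔG is interpolated linearly between supported PMF
bins; D is interpolated linearly in ln D between window centers (it
varies over orders of magnitude); the trapezoidal quadrature grid is at
least twice as fine as either input grid.  The default bounds
z₁ = 0, z₂ = 4.4 nm follow the simulated one-leaflet reaction
coordinate, and that one-sided P is used for every leaflet of the
stack.  The bulk tail (z ≥ the reference region) may extend past the
profile's last supported bin; there ΔG is taken as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .diffusivity import DiffusivityProfile
from .errors import CoverageError, ValidationError
from .thermo import ThermoState
from .wham import FreeEnergyProfile

__all__ = [
    "PermeabilityResult",
    "LayerStack",
    "resistance_integrand",
    "permeability",
    "transdermal_permeability",
    "build_uniform_stack",
    "N_LEAFLETS_SC",
]

#: Leaflet count of the stratum-corneum stack model (100 bilayers).
N_LEAFLETS_SC = 200


@dataclass
class PermeabilityResult:
    """Single-leaflet permeability with its resistance integrand table."""

    p: float  # nm/ps
    resistance: float  # ps/nm
    z1: float
    z2: float
    thermo: ThermoState
    grid: np.ndarray  # quadrature grid, nm
    integrand: np.ndarray  # e^{dG/RT}/D on the grid, ps/nm^2

    def __post_init__(self):
        if not self.p > 0:
            raise ValidationError("permeability must be positive")
        if not np.isclose(self.p * self.resistance, 1.0, rtol=1e-9):
            raise ValidationError("P and 1/P are inconsistent")


@dataclass(frozen=True)
class LayerStack:
    """Per-leaflet permeabilities composing a multilayer membrane."""

    permeabilities: tuple[float, ...]

    def __post_init__(self):
        if len(self.permeabilities) == 0:
            raise ValidationError("stack must contain at least one layer")
        if any(p <= 0 for p in self.permeabilities):
            raise ValidationError("all layer permeabilities must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.permeabilities)


def resistance_integrand(
    dg: float | np.ndarray,
    d: float | np.ndarray,
    thermo: ThermoState = ThermoState(),
) -> float | np.ndarray:
    """Local resistance density e^{ΔG/RT}/D (ps/nm²)."""
    d = np.asarray(d, float)
    if np.any(d <= 0):
        raise ValidationError("diffusivity must be strictly positive")
    out = np.exp(np.asarray(dg, float) * thermo.beta) / d
    return float(out) if out.ndim == 0 else out


def permeability(
    profile: FreeEnergyProfile,
    diff: DiffusivityProfile,
    z1: float = 0.0,
    z2: float = 4.4,
    thermo: ThermoState = ThermoState(),
    grid_spacing: float | None = None,
) -> PermeabilityResult:
    """Single-leaflet permeability by the solubility-diffusion integral.

    ``profile`` should be zero-referenced in bulk water.  Raises
    ``CoverageError`` when either input fails to cover [z1, z2] (the
    free-energy profile may stop short of z2 only inside its declared
    bulk reference region, where ΔG is taken as zero).
    """
    if not z2 > z1:
        raise ValidationError("need z2 > z1")
    m = profile.support
    pz, pdg = profile.z[m], profile.dg[m]
    if pz.size < 2:
        raise ValidationError("free-energy profile has fewer than 2 supported bins")
    bin_w = float(np.min(np.diff(pz)))
    # ΔG coverage: allow the bulk tail to be implicit (ΔG = 0) only past
    # the zero-reference region's start.
    bulk_from = profile.reference_region[0] if profile.reference_region else np.inf
    g_hi_needed = z2 if bulk_from > z2 else min(z2, max(bulk_from, pz[-1]))
    if pz[0] - bin_w > z1 or pz[-1] + bin_w < g_hi_needed:
        raise CoverageError(
            f"free-energy profile covers [{pz[0]:.3g}, {pz[-1]:.3g}] nm but the "
            f"integral needs [{z1:.3g}, {z2:.3g}] nm"
        )
    centers, dvals = diff.centers, diff.d
    c_space = float(np.min(np.diff(centers))) if centers.size > 1 else np.inf
    if centers[0] - c_space / 2 > z1 or centers[-1] + c_space / 2 < z2:
        raise CoverageError(
            f"diffusivity profile covers [{centers[0]:.3g}, {centers[-1]:.3g}] nm "
            f"but the integral needs [{z1:.3g}, {z2:.3g}] nm"
        )

    if grid_spacing is None:
        grid_spacing = min(bin_w, c_space) / 2
    n = max(2, int(np.ceil((z2 - z1) / grid_spacing)) + 1)
    grid = np.linspace(z1, z2, n)

    dg = np.interp(grid, pz, pdg)
    dg[grid > pz[-1]] = 0.0  # implicit bulk tail

    ln_d = np.interp(grid, centers, np.log(dvals))
    integrand = resistance_integrand(dg, np.exp(ln_d), thermo)
    resistance = float(np.trapezoid(integrand, grid))
    return PermeabilityResult(
        p=1.0 / resistance,
        resistance=resistance,
        z1=float(z1),
        z2=float(z2),
        thermo=thermo,
        grid=grid,
        integrand=integrand,
    )


def transdermal_permeability(stack: LayerStack) -> float:
    """Series-resistance composition: P = (Σ 1/Pᵢ)⁻¹ (nm/ps)."""
    return 1.0 / float(np.sum(1.0 / np.asarray(stack.permeabilities)))


def build_uniform_stack(p_layer: float, n_layers: int = N_LEAFLETS_SC) -> LayerStack:
    """A stack of identical leaflets (default 200, the SC model)."""
    if p_layer <= 0:
        raise ValidationError("layer permeability must be positive")
    if n_layers < 1:
        raise ValidationError("need at least one layer")
    return LayerStack(permeabilities=(float(p_layer),) * n_layers)
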