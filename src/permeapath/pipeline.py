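"""End-to-end driver: simulate → WHAM → diffusivity → permeability.

``run_pipeline`` executes the full desk-scale permeation analysis on a
synthetic landscape: plan the umbrella ladder, run Brownian-dynamics
windows, recover the PMF by WHAM (optionally with block-convergence
diagnostics and bootstrap errors), estimate per-window diffusivities,
and integrate the solubility-diffusion permeability plus the 200-leaflet
transdermal composition.  Everything is deterministic given the seeds
recorded in the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__ as _version
from .diffusivity import DiffusivityProfile, diffusivity_profile
from .errors import PermeapathError, PipelineError, ValidationError
from .permeability import N_LEAFLETS_SC, build_uniform_stack, permeability, transdermal_permeability
from .synthetic import (
    DEFAULT_SPRING_K,
    Landscape,
    LangevinConfig,
    plan_windows,
    sc_bilayer_landscape,
    simulate_window,
)
from .thermo import ThermoState
from .wham import (
    DEFAULT_ZERO_FROM,
    FreeEnergyProfile,
    bootstrap_pmf,
    convergence_blocks,
    declare_convergence,
    histogram_window,
    make_edges,
    wham_solve,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Settings for one full synthetic permeation analysis.

    ``landscape`` names a built-in fixture (``me5ala`` / ``5ala``) or a
    CSV path with columns z, G, D.  Units: nm / ps / kJ/mol / K.
    """

    landscape: str = "me5ala"
    z_min: float = 0.0
    z_max: float = 4.4
    spacing: float = 0.2
    spring_k: float = DEFAULT_SPRING_K
    # Langevin settings
    dt: float = 0.05
    n_steps: int = 200_000
    sample_stride: int = 10
    equilibration_steps: int = 20_000
    temperature: float = 305.0
    seed: int = 0
    # WHAM settings
    bin_width: float = 0.02
    wham_tol: float = 1e-8
    wham_max_iter: int = 200_000
    zero_from: float = DEFAULT_ZERO_FROM
    n_boot: int = 0  # 0 disables bootstrap; the field default keeps runs fast
    boot_seed: int = 1
    # convergence diagnostic (0 disables)
    block_length: float = 0.0
    block_step: float = 0.0
    convergence_criterion: float = 1.0
    # permeability
    z1: float = 0.0
    z2: float = 4.4
    n_layers: int = N_LEAFLETS_SC

    def thermo(self) -> ThermoState:
        return ThermoState(temperature=self.temperature)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**data)


@dataclass
class RunReport:
    """Summary of one pipeline run: PMF landmarks, D(z), P and P_trans."""

    landmarks: dict
    centers: list[float]
    d_per_window: list[float]
    p_leaflet: float
    p_transdermal: float
    n_layers: int
    convergence_time: float | None
    config_hash: str
    seeds: dict
    version: str
    profile: FreeEnergyProfile = field(repr=False)
    diffusivity: DiffusivityProfile = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "landmarks": self.landmarks,
            "centers": self.centers,
            "d_per_window": self.d_per_window,
            "p_leaflet": self.p_leaflet,
            "p_transdermal": self.p_transdermal,
            "n_layers": self.n_layers,
            "convergence_time": self.convergence_time,
            "config_hash": self.config_hash,
            "seeds": self.seeds,
            "version": self.version,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def _load_landscape(spec: str) -> Landscape:
    if spec.lower().replace("-", "").replace("_", "") in ("me5ala", "5ala"):
        return sc_bilayer_landscape(spec)
    path = Path(spec)
    if not path.exists():
        raise ValidationError(f"landscape {spec!r} is neither a fixture name nor a file")
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("z", "G", "D"):
        if col not in df.columns:
            raise ValidationError(f"{path}: landscape CSV needs columns z, G, D")
    return Landscape.from_tables(df["z"], df["G"], df["D"], name=path.stem)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full synthetic permeation analysis described by ``config``."""
    thermo = config.thermo()
    landscape = _load_landscape(config.landscape)

    centers = plan_windows(config.z_min, config.z_max, config.spacing)
    cfg0 = LangevinConfig(
        dt=config.dt,
        n_steps=config.n_steps,
        sample_stride=config.sample_stride,
        temperature=config.temperature,
        seed=config.seed,
        equilibration_steps=config.equilibration_steps,
    )
    try:
        windows = [
            simulate_window(
                landscape, c, config.spring_k,
                LangevinConfig(
                    dt=cfg0.dt, n_steps=cfg0.n_steps, sample_stride=cfg0.sample_stride,
                    temperature=cfg0.temperature, equilibration_steps=cfg0.equilibration_steps,
                    seed=int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31)),
                ),
            )
            for i, c in enumerate(centers)
        ]
    except PermeapathError as exc:
        raise PipelineError("simulate", str(exc)) from exc

    try:
        edges = make_edges(config.z_min, config.z_max, config.bin_width)
        hists = [histogram_window(w, edges) for w in windows]
        sol = wham_solve(hists, thermo, tol=config.wham_tol,
                         max_iter=config.wham_max_iter, zero_from=config.zero_from)
        profile = sol.profile
        if config.n_boot >= 2:
            profile = bootstrap_pmf(
                windows, thermo, n_boot=config.n_boot, seed=config.boot_seed,
                bin_width=config.bin_width, zero_from=config.zero_from,
                tol=max(config.wham_tol, 1e-6), max_iter=config.wham_max_iter,
            )
    except PermeapathError as exc:
        raise PipelineError("wham", str(exc)) from exc

    convergence_time = None
    if config.block_length > 0 and config.block_step > 0:
        try:
            blocks = convergence_blocks(
                windows, config.block_length, config.block_step, thermo,
                bin_width=config.bin_width, zero_from=config.zero_from,
                tol=max(config.wham_tol, 1e-6), max_iter=config.wham_max_iter,
            )
            convergence_time = declare_convergence(blocks, config.convergence_criterion)
        except PermeapathError as exc:
            raise PipelineError("convergence", str(exc)) from exc

    try:
        dprof = diffusivity_profile(windows, min_samples=min(10_000, windows[0].n_samples))
    except PermeapathError as exc:
        raise PipelineError("diffusivity", str(exc)) from exc

    try:
        perm = permeability(profile, dprof, config.z1, config.z2, thermo)
        p_trans = transdermal_permeability(build_uniform_stack(perm.p, config.n_layers))
    except PermeapathError as exc:
        raise PipelineError("permeability", str(exc)) from exc

    return RunReport(
        landmarks=profile.landmarks(),
        centers=[float(c) for c in centers],
        d_per_window=[float(v) for v in dprof.d],
        p_leaflet=perm.p,
        p_transdermal=p_trans,
        n_layers=config.n_layers,
        convergence_time=convergence_time,
        config_hash=config.config_hash(),
        seeds={"langevin": config.seed, "bootstrap": config.boot_seed},
        version=_version,
        profile=profile,
        diffusivity=dprof,
    )
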