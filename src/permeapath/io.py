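"""File formats: xvg-style window series, manifests, and profile CSVs.

Window time series use the two-column text convention of pull-coordinate
files (time in ps, position in nm), with ``#`` and ``@`` lines ignored.
A YAML manifest lists the windows of a campaign::

    spring_k: 500.0          # optional default, kJ/mol/nm^2
    windows:
      - {file: win_00.xvg, center: 0.0}
      - {file: win_01.xvg, center: 0.2, spring_k: 500.0}

Free-energy profiles round-trip through CSV with columns
``z, dG, dG_sd``; diffusivity profiles through ``center, variance, tau, D``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .diffusivity import DiffusivityEstimate, DiffusivityProfile
from .errors import ValidationError
from .synthetic import UmbrellaWindow
from .wham import FreeEnergyProfile

__all__ = [
    "read_window_series",
    "write_window_series",
    "read_manifest",
    "profile_to_csv",
    "profile_from_csv",
    "diffusivity_to_csv",
    "diffusivity_from_csv",
]


def read_window_series(
    path: str | Path,
    center: float = 0.0,
    spring_k: float = 0.0,
) -> UmbrellaWindow:
    """Parse an xvg-style (time ps, z nm) series into an UmbrellaWindow.

    Lines starting with ``#`` or ``@`` are ignored.  Raises with the
    line number on non-numeric rows, and rejects non-uniform time
    spacing (relative tolerance 1e-6).
    """
    path = Path(path)
    times, positions = [], []
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ValidationError(f"{path}:{ln}: expected two columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                positions.append(float(parts[1]))
            except ValueError:
                raise ValidationError(f"{path}:{ln}: non-numeric row {s!r}") from None
    if not times:
        raise ValidationError(f"{path}: no data rows")
    return UmbrellaWindow(
        center=float(center),
        spring_k=float(spring_k),
        times=np.array(times),
        positions=np.array(positions),
    )


def write_window_series(window: UmbrellaWindow, path: str | Path, comment: str = "") -> None:
    """Write a window as two-column text (full double precision)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# umbrella window center={window.center:.6g} nm "
                 f"spring_k={window.spring_k:.6g} kJ/mol/nm^2\n")
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("@    xaxis  label \"Time (ps)\"\n")
        fh.write("@    yaxis  label \"z (nm)\"\n")
        for t, z in zip(window.times, window.positions):
            fh.write(f"{t:.12g} {z:.17g}\n")


def read_manifest(path: str | Path) -> list[UmbrellaWindow]:
    """Load all windows listed in a YAML manifest (paths relative to it)."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict) or "windows" not in data:
        raise ValidationError(f"{path}: manifest must be a mapping with a 'windows' list")
    default_k = float(data.get("spring_k", 0.0))
    windows = []
    for entry in data["windows"]:
        try:
            fname = entry["file"]
            center = float(entry["center"])
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"{path}: each window needs 'file' and 'center': {exc}") from exc
        k = float(entry.get("spring_k", default_k))
        fpath = path.parent / fname
        if not fpath.exists():
            raise ValidationError(f"{path}: window file {fpath} does not exist")
        windows.append(read_window_series(fpath, center=center, spring_k=k))
    return windows


def profile_to_csv(profile: FreeEnergyProfile, path: str | Path) -> None:
    df = pd.DataFrame({"z": profile.z, "dG": profile.dg})
    df["dG_sd"] = profile.dg_sd if profile.dg_sd is not None else np.nan
    df.to_csv(path, index=False, float_format="%.10g")


def profile_from_csv(path: str | Path) -> FreeEnergyProfile:
    df = pd.read_csv(path)
    for col in ("z", "dG"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    sd = df["dG_sd"].to_numpy() if "dG_sd" in df.columns else None
    if sd is not None and np.all(np.isnan(sd)):
        sd = None
    return FreeEnergyProfile(z=df["z"].to_numpy(), dg=df["dG"].to_numpy(), dg_sd=sd)


def diffusivity_to_csv(profile: DiffusivityProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "center": profile.centers,
            "variance": [e.variance for e in profile.estimates],
            "tau": [e.tau for e in profile.estimates],
            "D": profile.d,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def diffusivity_from_csv(path: str | Path) -> DiffusivityProfile:
    df = pd.read_csv(path)
    for col in ("center", "variance", "tau", "D"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    est = [
        DiffusivityEstimate(
            center=float(r.center),
            variance=float(r.variance),
            tau=float(r.tau),
            d=float(r.variance) / float(r.tau),
            truncation_lag=0,
        )
        for r in df.itertuples()
    ]
    return DiffusivityProfile(estimates=est)
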