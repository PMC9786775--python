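"""Geometric hydrogen-bond detection and per-window partner profiles.

A hydrogen bond is scored between a donor heavy atom D (carrying a
hydrogen H) and an acceptor heavy atom A when

* the donor–acceptor distance |D−A| is at most the distance cutoff
  (default 0.35 nm), and
* the hydrogen–donor–acceptor angle — the angle at D between the D→H
  and D→A directions — is at most the angle cutoff (default 37°).

Both boundaries are inclusive, so fixtures built exactly at a cutoff are
scored deterministically.  Distances are heavy-atom to heavy-atom, not
H–A.  Frames are assumed pre-wrapped: the detector applies no
minimum-image convention, which is a documented limitation for raw
periodic trajectories.

Per-window averages attribute each bond involving the focus species
(by default the permeant) to the partner's species — ceramide (CER),
cholesterol (CHOL), free fatty acid (FFA), water — or to ``self`` when
both ends belong to the focus molecule, mirroring the usual breakdown of
permeant H-bond profiles across a stratum-corneum bilayer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Frame",
    "HBondCriteria",
    "HBond",
    "HBondProfile",
    "detect_hbonds",
    "hbond_window_average",
    "hbond_profile",
    "read_frame_xyz",
    "write_frame_xyz",
]

LIPID_SPECIES = ("CER", "CHOL", "FFA")

ROLE_DONOR = "donor"
ROLE_HYDROGEN = "hydrogen"
ROLE_ACCEPTOR = "acceptor"
ROLE_OTHER = "other"
_ROLES = (ROLE_DONOR, ROLE_HYDROGEN, ROLE_ACCEPTOR, ROLE_OTHER)


@dataclass
class Frame:
    """One labelled coordinate frame.

    positions : (N, 3) float array, nm
    species   : length-N labels (e.g. permeant/CER/CHOL/FFA/water)
    roles     : length-N, each one of donor / hydrogen / acceptor / other
    parents   : length-N int; for a hydrogen the index of its donor heavy
                atom, −1 otherwise
    elements  : optional length-N element symbols (for file round-trips)
    """

    positions: np.ndarray
    species: list[str]
    roles: list[str]
    parents: np.ndarray
    elements: list[str] | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        n = self.positions.shape[0]
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must be an (N, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("positions must be finite")
        if len(self.species) != n or len(self.roles) != n or self.parents.shape[0] != n:
            raise ValidationError("species/roles/parents lengths must match positions")
        for idx, role in enumerate(self.roles):
            if role not in _ROLES:
                raise ValidationError(f"atom {idx}: unknown role {role!r}")
            if role == ROLE_HYDROGEN:
                p = self.parents[idx]
                if not (0 <= p < n) or self.roles[p] != ROLE_DONOR:
                    raise ValidationError(
                        f"hydrogen atom {idx} has no valid donor parent (parent={p})"
                    )

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric cutoffs: donor–acceptor distance (nm) and H–D–A angle (deg)."""

    distance_cutoff: float = 0.35
    angle_cutoff_deg: float = 37.0

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff_deg <= 0:
            raise ValidationError("H-bond cutoffs must be positive")


class HBond(NamedTuple):
    donor: int
    hydrogen: int
    acceptor: int
    donor_species: str
    acceptor_species: str


def detect_hbonds(frame: Frame, criteria: HBondCriteria = HBondCriteria()) -> list[HBond]:
    """All hydrogen bonds in one frame under the geometric criteria."""
    acceptors = np.flatnonzero([r == ROLE_ACCEPTOR for r in frame.roles])
    hydrogens = np.flatnonzero([r == ROLE_HYDROGEN for r in frame.roles])
    if acceptors.size == 0 or hydrogens.size == 0:
        return []
    pos = frame.positions
    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff_deg))
    bonds: list[HBond] = []
    for h in hydrogens:
        d = int(frame.parents[h])
        da = pos[acceptors] - pos[d]
        dist = np.linalg.norm(da, axis=1)
        dh = pos[h] - pos[d]
        dh_norm = np.linalg.norm(dh)
        if dh_norm == 0:
            raise ValidationError(f"hydrogen {h} coincides with its donor {d}")
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (da @ dh) / (dist * dh_norm)
        ok = (
            (acceptors != d)
            & (dist <= criteria.distance_cutoff)
            & (dist > 0)
            & (cosang >= cos_cut - 1e-12)
        )
        for a in acceptors[ok]:
            bonds.append(
                HBond(d, int(h), int(a), frame.species[d], frame.species[int(a)])
            )
    return bonds


def hbond_window_average(
    frames: Sequence[Frame],
    criteria: HBondCriteria = HBondCriteria(),
    focus: str = "permeant",
) -> dict[str, float]:
    """Mean per-frame H-bond count of the focus species, by partner species.

    A bond is attributed to the species at its non-focus end; bonds with
    both ends in the focus species are attributed to ``"self"``.  Bonds
    may be counted with the focus as donor or as acceptor (both
    directions).
    """
    if len(frames) == 0:
        raise ValidationError("need at least one frame")
    totals: dict[str, float] = {}
    for frame in frames:
        for b in detect_hbonds(frame, criteria):
            if b.donor_species == focus and b.acceptor_species == focus:
                partner = "self"
            elif b.donor_species == focus:
                partner = b.acceptor_species
            elif b.acceptor_species == focus:
                partner = b.donor_species
            else:
                continue
            totals[partner] = totals.get(partner, 0.0) + 1.0
    return {k: v / len(frames) for k, v in sorted(totals.items())}


@dataclass
class HBondProfile:
    """Per-window average H-bond counts partitioned by partner species.

    ``table`` is indexed by window center (nm) with columns for each
    partner species plus derived columns ``lipids`` (CER+CHOL+FFA),
    ``self`` and ``total``; total = lipids + water + self + any other
    partners, exactly.
    """

    table: pd.DataFrame

    @property
    def centers(self) -> np.ndarray:
        return self.table.index.to_numpy()


def hbond_profile(
    windows: Sequence[tuple[float, Sequence[Frame]]],
    criteria: HBondCriteria = HBondCriteria(),
    focus: str = "permeant",
) -> HBondProfile:
    """Average H-bond partner breakdown per umbrella window."""
    centers = [c for c, _ in windows]
    if len(set(centers)) != len(centers):
        raise ValidationError("window centers must be unique")
    rows = {}
    partners: set[str] = set()
    for center, frames in windows:
        avg = hbond_window_average(frames, criteria, focus)
        rows[center] = avg
        partners.update(avg)
    columns = sorted(partners | set(LIPID_SPECIES) | {"water", "self"})
    table = pd.DataFrame(
        [[rows[c].get(col, 0.0) for col in columns] for c in centers],
        index=pd.Index(centers, name="center"),
        columns=columns,
    ).sort_index()
    table["lipids"] = sum(table[s] for s in LIPID_SPECIES)
    base_cols = [c for c in columns]
    table["total"] = table[base_cols].sum(axis=1)
    return HBondProfile(table=table)


# ---------------------------------------------------------------------
# Extended-XYZ-style text interchange
# ---------------------------------------------------------------------
# One atom per line:  element  x  y  z  species  role  parent
# preceded by an atom-count line and a comment line, as in XYZ files.

def write_frame_xyz(frame: Frame, path: str | Path, comment: str = "") -> None:
    lines = [str(len(frame)), comment.replace("\n", " ")]
    elements = frame.elements or ["X"] * len(frame)
    for i in range(len(frame)):
        x, y, z = frame.positions[i]
        lines.append(
            f"{elements[i]} {x:.9f} {y:.9f} {z:.9f} "
            f"{frame.species[i]} {frame.roles[i]} {frame.parents[i]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_frame_xyz(path: str | Path) -> Frame:
    raw = Path(path).read_text().splitlines()
    if len(raw) < 2:
        raise ValidationError(f"{path}: not an extended-XYZ frame")
    try:
        n = int(raw[0].strip())
    except ValueError as exc:
        raise ValidationError(f"{path}: bad atom count line") from exc
    body = raw[2 : 2 + n]
    if len(body) != n:
        raise ValidationError(f"{path}: expected {n} atom lines, found {len(body)}")
    elements, species, roles, parents, coords = [], [], [], [], []
    for ln, line in enumerate(body, start=3):
        parts = line.split()
        if len(parts) != 7:
            raise ValidationError(f"{path}:{ln}: expected 7 columns, got {len(parts)}")
        elements.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
        species.append(parts[4])
        roles.append(parts[5])
        parents.append(int(parts[6]))
    return Frame(
        positions=np.array(coords),
        species=species,
        roles=roles,
        parents=np.array(parents),
        elements=elements,
    )
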