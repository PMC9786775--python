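"""Small-molecule descriptors for permeants.

Computes the Lipinski-style properties used to rationalise membrane
permeation differences between a drug and its ester prodrug: hydrogen-bond
donor and acceptor counts, Ertl fragment-based topological polar surface
area (TPSA), rotatable-bond count and molecular weight.

Molecules are explicit heavy-atom graphs (:class:`MoleculeGraph`) with
per-atom attached-hydrogen counts; there is no SMILES parsing and no
aromaticity perception — the scope is small aliphatic permeants.  Built-in
graphs for 5-aminolevulinic acid (5-ALA) and its methyl ester (Me-5-ALA)
are provided as :func:`five_ala` and :func:`methyl_five_ala`.

Conventions
-----------
* A donor is a nitrogen or oxygen *heavy atom* bearing at least one
  hydrogen; an NH₂ group counts once (per-atom, not per-hydrogen).
* An acceptor is any neutral N or O atom (adequate for the aliphatic
  molecules in scope; no pyrrole-type exclusion is attempted).
* A rotatable bond is an acyclic single bond between two heavy atoms
  each of which has at least one *other* heavy-atom neighbour (bonds to
  terminal heavy atoms such as O–H, N–H₂ or CH₃ caps are excluded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .errors import ValidationError

__all__ = [
    "MoleculeGraph",
    "DescriptorSet",
    "count_hbond_donors",
    "count_hbond_acceptors",
    "count_rotatable_bonds",
    "ertl_tpsa",
    "molecular_weight",
    "compute_descriptors",
    "five_ala",
    "methyl_five_ala",
    "mol_from_json",
    "mol_to_json",
]

# IUPAC 2021 standard atomic weights, rounded to 3 decimals.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
}


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int = 0
    h: int = 0  # attached (implicit) hydrogens


@dataclass(frozen=True)
class MoleculeGraph:
    """Explicit heavy-atom molecular graph.

    ``atoms`` is a sequence of :class:`Atom` (element symbol, formal
    charge, attached-hydrogen count); ``bonds`` lists each heavy-atom
    bond once as ``(i, j, order)`` with 0-based indices and order in
    {1, 2, 3}.
    """

    name: str
    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"bond ({i},{j}) has out-of-range atom index")
            if i == j:
                raise ValidationError(f"self-bond on atom {i}")
            if order not in (1, 2, 3):
                raise ValidationError(f"bond order must be 1, 2 or 3, got {order}")
            key = frozenset((i, j))
            if key in seen:
                raise ValidationError(f"bond ({i},{j}) listed twice")
            seen.add(key)
        for idx, a in enumerate(self.atoms):
            if a.h < 0:
                raise ValidationError(f"atom {idx} has negative hydrogen count")

    # -- graph views -------------------------------------------------
    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def bond_orders_at(self, i: int) -> list[int]:
        return [o for a, b, o in self.bonds if i in (a, b)]

    def to_networkx(self) -> "nx.Graph":
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((i, j, {"order": o}) for i, j, o in self.bonds)
        return g


@dataclass(frozen=True)
class DescriptorSet:
    """Computed descriptor bundle for one molecule."""

    hbond_donors: int
    hbond_acceptors: int
    rotatable_bonds: int
    tpsa: float  # Å^2
    molecular_weight: float  # g/mol

    def __post_init__(self):
        if min(self.hbond_donors, self.hbond_acceptors, self.rotatable_bonds) < 0:
            raise ValidationError("descriptor counts must be non-negative")
        if self.tpsa < 0:
            raise ValidationError("TPSA must be non-negative")

    def to_dict(self) -> dict:
        return {
            "hbond_donors": self.hbond_donors,
            "hbond_acceptors": self.hbond_acceptors,
            "rotatable_bonds": self.rotatable_bonds,
            "tpsa": round(self.tpsa, 2),
            "molecular_weight": round(self.molecular_weight, 3),
        }


def count_hbond_donors(mol: MoleculeGraph) -> int:
    """Number of N/O heavy atoms bearing at least one hydrogen."""
    return sum(1 for a in mol.atoms if a.element in ("N", "O") and a.h >= 1)


def count_hbond_acceptors(mol: MoleculeGraph) -> int:
    """Number of neutral N/O atoms (all N and O for aliphatic molecules)."""
    return sum(1 for a in mol.atoms if a.element in ("N", "O") and a.charge == 0)


def count_rotatable_bonds(mol: MoleculeGraph) -> int:
    """Acyclic single bonds between two non-terminal heavy atoms.

    A heavy atom is terminal when the bond in question is its only
    heavy-atom bond.  Ring bonds are excluded via cycle detection.
    """
    g = mol.to_networkx()
    ring_edges = {frozenset(e) for cyc in nx.cycle_basis(g) for e in zip(cyc, cyc[1:] + cyc[:1])}
    n_rot = 0
    for i, j, order in mol.bonds:
        if order != 1 or frozenset((i, j)) in ring_edges:
            continue
        if g.degree[i] >= 2 and g.degree[j] >= 2:
            n_rot += 1
    return n_rot


# Ertl fragment contributions (Å^2) for the polar-atom environments in
# scope.  Keys: (element, n_attached_h, n_single_bonds, n_double_bonds).
_TPSA_FRAGMENTS = {
    ("N", 2, 1, 0): 26.02,  # primary amine  -NH2
    ("N", 1, 2, 0): 12.03,  # secondary amine >NH
    ("N", 0, 3, 0): 3.24,   # tertiary amine >N-
    ("N", 0, 1, 1): 12.36,  # imine =N-
    ("O", 0, 0, 1): 17.07,  # carbonyl =O
    ("O", 0, 2, 0): 9.23,   # ether / ester bridge -O-
    ("O", 1, 1, 0): 20.23,  # hydroxyl -OH
}


def ertl_tpsa(mol: MoleculeGraph) -> float:
    """Topological polar surface area by Ertl fragment summation (Å²).

    Every N/O environment present must be covered by the shipped
    fragment table; an unknown environment raises ``ValidationError``
    naming the offending atom rather than silently contributing zero.
    """
    total = 0.0
    for idx, atom in enumerate(mol.atoms):
        if atom.element not in ("N", "O"):
            continue
        orders = mol.bond_orders_at(idx)
        key = (
            atom.element,
            atom.h,
            sum(1 for o in orders if o == 1),
            sum(1 for o in orders if o == 2),
        )
        try:
            total += _TPSA_FRAGMENTS[key]
        except KeyError:
            raise ValidationError(
                f"no TPSA fragment for atom {idx} ({atom.element}, H{atom.h}, "
                f"bond orders {sorted(orders)}) in molecule {mol.name!r}"
            ) from None
    return total


def molecular_weight(mol: MoleculeGraph) -> float:
    """Molecular weight in g/mol including attached hydrogens."""
    mass = 0.0
    for idx, atom in enumerate(mol.atoms):
        try:
            mass += ATOMIC_MASS[atom.element]
        except KeyError:
            raise ValidationError(f"unknown element {atom.element!r} at atom {idx}") from None
        mass += atom.h * ATOMIC_MASS["H"]
    return mass


def compute_descriptors(mol: MoleculeGraph) -> DescriptorSet:
    return DescriptorSet(
        hbond_donors=count_hbond_donors(mol),
        hbond_acceptors=count_hbond_acceptors(mol),
        rotatable_bonds=count_rotatable_bonds(mol),
        tpsa=ertl_tpsa(mol),
        molecular_weight=molecular_weight(mol),
    )


# ---------------------------------------------------------------------
# Built-in permeant graphs
# ---------------------------------------------------------------------

def five_ala() -> MoleculeGraph:
    """5-aminolevulinic acid, H₂N–CH₂–C(=O)–CH₂–CH₂–COOH (C₅H₉NO₃)."""
    return MoleculeGraph(
        name="5ALA",
        atoms=(
            Atom("N", 0, 2),   # 0 amine N
            Atom("C", 0, 2),   # 1 C5
            Atom("C", 0, 0),   # 2 C4 (ketone carbon)
            Atom("O", 0, 0),   # 3 ketone O
            Atom("C", 0, 2),   # 4 C3
            Atom("C", 0, 2),   # 5 C2
            Atom("C", 0, 0),   # 6 C1 (carboxyl carbon)
            Atom("O", 0, 0),   # 7 acid carbonyl O
            Atom("O", 0, 1),   # 8 acid hydroxyl O
        ),
        bonds=(
            (0, 1, 1), (1, 2, 1), (2, 3, 2), (2, 4, 1),
            (4, 5, 1), (5, 6, 1), (6, 7, 2), (6, 8, 1),
        ),
    )


def methyl_five_ala() -> MoleculeGraph:
    """Methyl 5-aminolevulinate, H₂N–CH₂–C(=O)–CH₂–CH₂–C(=O)–O–CH₃ (C₆H₁₁NO₃)."""
    return MoleculeGraph(
        name="Me-5ALA",
        atoms=(
            Atom("N", 0, 2),   # 0 amine N
            Atom("C", 0, 2),   # 1 C5
            Atom("C", 0, 0),   # 2 C4 (ketone carbon)
            Atom("O", 0, 0),   # 3 ketone O
            Atom("C", 0, 2),   # 4 C3
            Atom("C", 0, 2),   # 5 C2
            Atom("C", 0, 0),   # 6 C1 (ester carbonyl carbon)
            Atom("O", 0, 0),   # 7 ester carbonyl O
            Atom("O", 0, 0),   # 8 ester bridge O
            Atom("C", 0, 3),   # 9 methyl C
        ),
        bonds=(
            (0, 1, 1), (1, 2, 1), (2, 3, 2), (2, 4, 1),
            (4, 5, 1), (5, 6, 1), (6, 7, 2), (6, 8, 1), (8, 9, 1),
        ),
    )


# ---------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------

def mol_from_json(source: str | Path | dict) -> MoleculeGraph:
    """Load a molecule graph from the JSON interchange format.

    ``{"name": str, "atoms": [{"element", "charge", "h"}, ...],
    "bonds": [[i, j, order], ...]}`` with 0-based indices.
    """
    if isinstance(source, dict):
        data = source
    else:
        data = json.loads(Path(source).read_text())
    try:
        atoms = tuple(
            Atom(a["element"], int(a.get("charge", 0)), int(a.get("h", 0)))
            for a in data["atoms"]
        )
        bonds = tuple((int(i), int(j), int(o)) for i, j, o in data["bonds"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"malformed molecule JSON: {exc}") from exc
    return MoleculeGraph(name=str(data.get("name", "molecule")), atoms=atoms, bonds=bonds)


def mol_to_json(mol: MoleculeGraph) -> dict:
    return {
        "name": mol.name,
        "atoms": [{"element": a.element, "charge": a.charge, "h": a.h} for a in mol.atoms],
        "bonds": [[i, j, o] for i, j, o in mol.bonds],
    }
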