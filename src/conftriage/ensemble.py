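"""Core containers: molecular graph, conformer ensemble, re-optimized results.

A conformational search produces many geometries of one molecule.  All of
them share a single molecular graph (atoms + bonds); only the coordinates
and the force-field (FF) energy differ.  The ensemble keeps its conformers
sorted by relative FF energy so that index 0 is always the FF global
minimum -- every prioritization method downstream relies on this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from rdkit import Chem

HARTREE_TO_KCAL = 627.5095

MONOVALENT = frozenset({"H", "F", "Cl", "Br", "I"})


@dataclass(frozen=True)
class Bond:
    """A bond between two atom indices.

    ``order`` is the numeric bond order with aromatic kept as its own class
    (the string ``"ar"``); ``ring_size`` is the smallest ring the bond is a
    member of, or ``None`` for acyclic bonds.
    """

    i: int
    j: int
    order: float | str
    ring_size: int | None = None
    conjugated: bool = False

    def other(self, idx: int) -> int:
        return self.j if idx == self.i else self.i


@dataclass
class MolecularGraph:
    """Element-labelled graph shared by all conformers of one ensemble."""

    elements: list[str]
    formal_charges: list[int]
    bonds: list[Bond]
    # per-atom hybridization tag ("sp", "sp2", "sp3", "other"); used by the
    # conjugated-heteroatom bond retention pattern
    hybridizations: list[str] = field(default_factory=list)
    aromatic_atoms: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.elements)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) references invalid atom")
        if not self.hybridizations:
            self.hybridizations = ["other"] * n
        if not self.aromatic_atoms:
            self.aromatic_atoms = [False] * n
        self._adj: list[list[int]] = [[] for _ in range(n)]
        self._bond_lookup: dict[tuple[int, int], Bond] = {}
        for b in self.bonds:
            self._adj[b.i].append(b.j)
            self._adj[b.j].append(b.i)
            key = (min(b.i, b.j), max(b.i, b.j))
            self._bond_lookup[key] = b

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, idx: int) -> list[int]:
        return self._adj[idx]

    def degree(self, idx: int) -> int:
        return len(self._adj[idx])

    def bond_between(self, i: int, j: int) -> Bond | None:
        return self._bond_lookup.get((min(i, j), max(i, j)))

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "MolecularGraph":
        ring_info = mol.GetRingInfo()
        hyb_map = {
            Chem.HybridizationType.SP: "sp",
            Chem.HybridizationType.SP2: "sp2",
            Chem.HybridizationType.SP3: "sp3",
        }
        bonds = []
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if b.GetIsAromatic():
                order: float | str = "ar"
            else:
                order = b.GetBondTypeAsDouble()
            sizes = [s for s in range(3, mol.GetNumAtoms() + 1)
                     if ring_info.IsBondInRingOfSize(b.GetIdx(), s)]
            bonds.append(Bond(i, j, order,
                              ring_size=min(sizes) if sizes else None,
                              conjugated=b.GetIsConjugated()))
        return cls(
            elements=[a.GetSymbol() for a in mol.GetAtoms()],
            formal_charges=[a.GetFormalCharge() for a in mol.GetAtoms()],
            bonds=bonds,
            hybridizations=[hyb_map.get(a.GetHybridization(), "other")
                            for a in mol.GetAtoms()],
            aromatic_atoms=[a.GetIsAromatic() for a in mol.GetAtoms()],
        )


class EnsembleMismatchError(ValueError):
    """Records in one search output disagree on atom count or element order."""


@dataclass
class ConformerEnsemble:
    """Conformers of one molecule, sorted by relative FF energy (ascending).

    ``coords`` has shape (m, n_atoms, 3) in Angstrom; ``u_ff`` holds relative
    FF internal energies in kcal/mol with ``u_ff[0] == 0``.
    """

    mol: Chem.Mol
    coords: np.ndarray
    u_ff: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.u_ff = np.asarray(self.u_ff, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (m, n_atoms, 3)")
        if len(self.u_ff) != self.coords.shape[0]:
            raise ValueError("coords/u_ff length mismatch")
        if len(self.u_ff) and not np.all(np.diff(self.u_ff) >= 0):
            raise ValueError("conformers must be sorted by u_ff ascending")
        if len(self.u_ff) and abs(self.u_ff[0]) > 1e-9:
            raise ValueError("u_ff must be relative to the ensemble minimum")
        self._graph: MolecularGraph | None = None

    @property
    def m(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def graph(self) -> MolecularGraph:
        if self._graph is None:
            self._graph = MolecularGraph.from_rdkit(self.mol)
        return self._graph

    def conformer_mol(self, index: int) -> Chem.Mol:
        """RDKit Mol carrying a single conformer's coordinates."""
        out = Chem.Mol(self.mol)
        out.RemoveAllConformers()
        conf = Chem.Conformer(self.n_atoms)
        for a in range(self.n_atoms):
            conf.SetAtomPosition(a, self.coords[index, a].tolist())
        out.AddConformer(conf, assignId=True)
        return out

    def subset(self, indices: Sequence[int]) -> "ConformerEnsemble":
        idx = np.asarray(list(indices), dtype=int)
        u = self.u_ff[idx]
        return ConformerEnsemble(self.mol, self.coords[idx], u - u.min())

    def __iter__(self) -> Iterator[tuple[np.ndarray, float]]:
        for k in range(self.m):
            yield self.coords[k], float(self.u_ff[k])


@dataclass
class OptimizedResult:
    """One conformer after high-level (e.g. DFT) re-optimization.

    ``source_index`` points back into the FF ensemble; ``g_rel`` is the
    relative free energy in kcal/mol within the batch of converged results.
    """

    source_index: int
    coordinates: np.ndarray
    g_rel: float
    h_rel: float | None = None
    u_rel: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.converged and not np.isfinite(self.g_rel):
            raise ValueError("converged result must carry a finite energy")
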