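"""Dihedral-angle descriptors for conformer clustering.

Each conformer of a flexible molecule is summarized by the torsion angles
around its rotatable bonds.  Bonds that cannot generate conformational
variety are eliminated up front:

A. bonds to monovalent atoms (F, Cl, Br, I, H);
B. bonds to CX3 groups (X = F, Cl, Br, I, H), e.g. methyl and CF3 rotors;
C. bonds in small rings and bonds with order > 1 (aromatic included), with
   an exception for conjugated single bonds between N/O and an sp2 or
   aromatic carbon (amide, ester, enamine, aniline-type), which do show
   meaningful rotation in practice and are kept as candidates.

For each surviving central bond one atom quadruple (a, b, c, d) is chosen,
preferring heteroatoms over carbon and carbon over hydrogen at the ends.
Torsions are then measured for every conformer, and a torsion whose spread
across the ensemble is small -- standard deviation sigma or range eta below
the cutoffs below -- is labelled *fixed* and dropped from the descriptor:

========================  ==============  ==============
ensemble range eta(theta)  sigma cutoff    eta cutoff
------------------------  --------------  --------------
< 300 deg                  8.7 deg         2.4 deg
>= 300 deg (trans)         6.6 (|theta|)   1.5 (|theta|)
========================  ==============  ==============

A torsion with eta(theta) >= 300 deg is *trans-oriented*: its values sit
near +/-180 deg and flip sign between conformers, so the spread statistics
are recomputed on |theta|.  Finally, columns whose values straddle the
+/-180 deg seam are unwrapped (negative values shifted by +360 deg) so that
Euclidean distances in the feature space reflect true angular proximity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .ensemble import MONOVALENT, Bond, ConformerEnsemble, MolecularGraph

SIGMA_CUT = 8.7
ETA_CUT = 2.4
SIGMA_ABS_CUT = 6.6
ETA_ABS_CUT = 1.5
TRANS_ETA = 300.0
SMALL_RING_MAX = 7  # ring bonds up to this size carry no usable torsion


@dataclass
class DihedralDefinition:
    """An atom quadruple (a, b, c, d) with its ensemble spread statistics."""

    a: int
    b: int
    c: int
    d: int
    is_fixed: bool = False
    sigma: float = float("nan")
    eta: float = float("nan")
    sigma_abs: float = float("nan")
    eta_abs: float = float("nan")
    trans_oriented: bool = False

    @property
    def atoms(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class DihedralSet:
    """All candidate dihedrals of an ensemble, fixed ones flagged."""

    dihedrals: list[DihedralDefinition] = field(default_factory=list)

    @property
    def variable(self) -> list[DihedralDefinition]:
        return [d for d in self.dihedrals if not d.is_fixed]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"a": d.a, "b": d.b, "c": d.c, "d": d.d,
              "sigma": d.sigma, "eta": d.eta,
              "sigma_abs": d.sigma_abs, "eta_abs": d.eta_abs,
              "fixed": d.is_fixed, "trans_oriented": d.trans_oriented}
             for d in self.dihedrals])


@dataclass
class FeatureMatrix:
    """m x d matrix of unwrapped torsions (degrees), one column per
    variable dihedral."""

    values: np.ndarray
    columns: list[DihedralDefinition]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def m(self) -> int:
        return self.values.shape[0]


def _is_cx3(graph: MolecularGraph, atom: int, partner: int) -> bool:
    """True if ``atom`` is a carbon whose substituents besides ``partner``
    are three monovalent atoms (a CX3 rotor end)."""
    if graph.elements[atom] != "C":
        return False
    others = [n for n in graph.neighbors(atom) if n != partner]
    return len(others) == 3 and all(
        graph.elements[n] in MONOVALENT for n in others)


def _conjugated_heteroatom_exception(graph: MolecularGraph, bond: Bond) -> bool:
    """Conjugated N/O-to-sp2-carbon single bonds keep their torsional freedom
    (amide, ester, enamine, aniline-type) and are retained as candidates."""
    if not bond.conjugated or bond.order == "ar":
        return False
    for het, carbon in ((bond.i, bond.j), (bond.j, bond.i)):
        if (graph.elements[het] in ("N", "O")
                and graph.degree(het) >= 2
                and graph.elements[carbon] == "C"
                and (graph.hybridizations[carbon] == "sp2"
                     or graph.aromatic_atoms[carbon])):
            return True
    return False


def eliminate_bonds(graph: MolecularGraph) -> list[Bond]:
    """Apply elimination rules A-C; return surviving candidate central bonds."""
    survivors = []
    for bond in graph.bonds:
        i, j = bond.i, bond.j
        # A: a monovalent atom can never be a central-bond atom
        if graph.elements[i] in MONOVALENT or graph.elements[j] in MONOVALENT:
            continue
        # B: CX3 rotors (methyl, CF3, ...) are conformationally degenerate
        if _is_cx3(graph, i, j) or _is_cx3(graph, j, i):
            continue
        # C: small-ring bonds and multiple/aromatic bonds
        if bond.ring_size is not None and bond.ring_size <= SMALL_RING_MAX:
            continue
        is_multiple = bond.order == "ar" or (
            isinstance(bond.order, float) and bond.order > 1.0)
        if is_multiple and not _conjugated_heteroatom_exception(graph, bond):
            continue
        # a torsion needs a terminal atom on each side
        if graph.degree(i) < 2 or graph.degree(j) < 2:
            continue
        survivors.append(bond)
    return survivors


_PT = Chem.GetPeriodicTable()


def _terminal_rank(graph: MolecularGraph, atom: int) -> tuple:
    """Preference key: heteroatom > carbon > hydrogen, then higher atomic
    number, then lower atom index (deterministic tie-break)."""
    elem = graph.elements[atom]
    category = 2 if elem == "H" else (1 if elem == "C" else 0)
    return (category, -_PT.GetAtomicNumber(elem), atom)


def pick_quadruple(bond: Bond, graph: MolecularGraph) -> DihedralDefinition | None:
    """Choose terminal atoms for a central bond; ``None`` if no quadruple
    exists (logged as a warning)."""
    b, c = bond.i, bond.j
    a_cands = [n for n in graph.neighbors(b) if n != c]
    d_cands = [n for n in graph.neighbors(c) if n != b]
    if not a_cands or not d_cands:
        warnings.warn(f"bond ({b},{c}) has no terminal atoms; dropped")
        return None
    a = min(a_cands, key=lambda n: _terminal_rank(graph, n))
    d = min(d_cands, key=lambda n: _terminal_rank(graph, n))
    return DihedralDefinition(a, b, c, d)


def torsion_angle(p0, p1, p2, p3) -> float:
    """Signed torsion in degrees, range (-180, 180] (IUPAC convention)."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("collinear atoms: torsion undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    theta = -np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return 180.0 if theta <= -180.0 + 1e-12 else float(theta)


def measure_dihedrals(
    ens: ConformerEnsemble, dihedrals: list[DihedralDefinition]
) -> np.ndarray:
    """Raw m x d torsion matrix in degrees, range (-180, 180]."""
    out = np.empty((ens.m, len(dihedrals)))
    for col, dh in enumerate(dihedrals):
        a, b, c, d = dh.atoms
        for k in range(ens.m):
            try:
                out[k, col] = torsion_angle(
                    ens.coords[k, a], ens.coords[k, b],
                    ens.coords[k, c], ens.coords[k, d])
            except ValueError as exc:
                raise ValueError(
                    f"conformer {k}, dihedral {dh.atoms}: {exc}") from exc
    return out


def classify_fixed(column: np.ndarray) -> tuple[bool, float, float, float, float, bool]:
    """Classify one torsion column as fixed/variable.

    Returns (is_fixed, sigma, eta, sigma_abs, eta_abs, trans_oriented).
    sigma is the population standard deviation, eta the range (max - min).
    """
    col = np.asarray(column, dtype=float)
    if col.size < 2:
        return True, 0.0, 0.0, 0.0, 0.0, False
    sigma = float(np.std(col))
    eta = float(col.max() - col.min())
    if eta >= TRANS_ETA:
        # sign-flipping torsion near +/-180: judge spread on |theta|
        a = np.abs(col)
        sigma_abs = float(np.std(a))
        eta_abs = float(a.max() - a.min())
        fixed = sigma_abs < SIGMA_ABS_CUT or eta_abs < ETA_ABS_CUT
        return fixed, sigma, eta, sigma_abs, eta_abs, True
    fixed = sigma < SIGMA_CUT or eta < ETA_CUT
    return fixed, sigma, eta, float("nan"), float("nan"), False


def unwrap_column(column: np.ndarray) -> np.ndarray:
    """Shift negative values by +360 deg when the column straddles the
    +/-180 deg seam, so 179 and -179 become numeric neighbours.

    The column straddles the seam when the largest circular gap between
    sorted values does not contain 180 deg; the circular spread is
    unchanged by the shift.
    """
    col = np.asarray(column, dtype=float)
    if col.size < 2:
        return col.copy()
    s = np.sort(col)
    gaps = np.diff(s)
    wrap_gap = s[0] + 360.0 - s[-1]
    widths = np.concatenate([gaps, [wrap_gap]])
    g = int(np.argmax(widths))
    if g == len(gaps):
        lo, hi = s[-1], s[0] + 360.0
    else:
        lo, hi = s[g], s[g + 1]
    gap_contains_180 = lo < 180.0 < hi
    if gap_contains_180:
        return col.copy()
    out = col.copy()
    out[out < 0] += 360.0
    return out


def build_feature_matrix(
    ens: ConformerEnsemble,
) -> tuple[FeatureMatrix, DihedralSet]:
    """End-to-end descriptor extraction.

    Composes bond elimination, quadruple picking, torsion measurement,
    fixed-dihedral classification (fixed columns dropped) and seam
    unwrapping.  A single-conformer or fully rigid ensemble yields d = 0,
    which downstream prioritizers treat as the degenerate one-cluster case.
    """
    quadruples: list[DihedralDefinition] = []
    for bond in eliminate_bonds(ens.graph):
        q = pick_quadruple(bond, ens.graph)
        if q is not None:
            quadruples.append(q)
    if ens.m < 2 or not quadruples:
        return (FeatureMatrix(np.empty((ens.m, 0)), []),
                DihedralSet(quadruples))
    raw = measure_dihedrals(ens, quadruples)
    keep_cols = []
    for col, dh in enumerate(quadruples):
        (dh.is_fixed, dh.sigma, dh.eta,
         dh.sigma_abs, dh.eta_abs, dh.trans_oriented) = classify_fixed(raw[:, col])
        if not dh.is_fixed:
            keep_cols.append(col)
    values = np.column_stack(
        [unwrap_column(raw[:, c]) for c in keep_cols]
    ) if keep_cols else np.empty((ens.m, 0))
    return (FeatureMatrix(values, [quadruples[c] for c in keep_cols]),
            DihedralSet(quadruples))
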