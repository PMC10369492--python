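"""Scoring priority lists against an exhaustive re-optimization reference.

When every FF conformer has been re-optimized, the high-level results can
be deduplicated: two re-optimized structures with a best heavy-atom RMSD
below 0.005 Angstrom are the same structure, and the transitive closure of
that relation partitions the ensemble into *bins* (unique DFT structures).
Bins are ordered by their lowest relative free energy; bin 0 holds the DFT
global minimum.  The ideal priority list -- the *DFT list* -- visits each
bin's lowest-energy member first and relegates duplicates to the tail.

A proposed priority list is scored three ways:

* global minimum test ``P_GMT``: the fraction of the list that must be
  re-optimized before the first member of bin 0 appears (lower is better);
* bins test ``delta_a_bins``: the area between the optimal populated-bins
  curve r*(k) = min(k, B)/B and the achieved r_bins(k) on the rank grid
  (lower is better; zero means no duplicate was prioritized too early);
* overall parameter ``P_overall = P_GMT + 5 * delta_a_bins`` -- the area
  term is scaled by 5 because in practice almost all of its mass lies
  below 0.2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .ensemble import OptimizedResult
from .prioritize import PriorityList

RMSD_DUPLICATE_THRESHOLD = 0.005  # Angstrom, heavy atoms, best atom mapping


def heavy_atom_indices(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() != "H"]


def automorphism_maps(mol: Chem.Mol, max_maps: int = 10000) -> np.ndarray:
    """Graph-automorphism permutations of the heavy atoms of ``mol``.

    Row r is a permutation p with p[i] = j meaning heavy atom i of one copy
    corresponds to heavy atom j of the other.  Found by matching the
    heavy-atom skeleton onto itself.
    """
    heavy = Chem.RemoveHs(Chem.Mol(mol), sanitize=False)
    try:
        Chem.SanitizeMol(heavy, catchErrors=True)
    except Exception:
        pass
    matches = heavy.GetSubstructMatches(
        heavy, uniquify=False, useChirality=False, maxMatches=max_maps)
    if not matches:
        matches = (tuple(range(heavy.GetNumAtoms())),)
    return np.asarray(matches, dtype=int)


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Least-squares RMSD after optimal rigid superposition (Kabsch)."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    u, s, vt = np.linalg.svd(p.T @ q)
    sign = np.sign(np.linalg.det(u @ vt))
    s = s.copy()
    s[-1] *= sign
    # rmsd^2 = (|P|^2 + |Q|^2 - 2 tr(S)) / n
    msd = (np.sum(p * p) + np.sum(q * q) - 2.0 * s.sum()) / len(p)
    return float(np.sqrt(max(msd, 0.0)))


def _coords_of(x) -> np.ndarray:
    return x.coordinates if isinstance(x, OptimizedResult) else np.asarray(x, float)


def best_rmsd(a, b, mol: Chem.Mol, maps: np.ndarray | None = None) -> float:
    """Minimum heavy-atom RMSD over all graph-automorphism atom mappings.

    ``a`` and ``b`` are :class:`OptimizedResult` or raw coordinate arrays
    over all atoms of ``mol``; superposition removes rigid motion, and the
    minimum over symmetry-equivalent mappings removes labelling artifacts
    (e.g. exchanged equivalent branches).
    """
    pa, pb = _coords_of(a), _coords_of(b)
    if pa.shape != pb.shape:
        raise ValueError("coordinate arrays differ in shape")
    heavy = heavy_atom_indices(mol)
    if not heavy:
        raise ValueError("no heavy atoms")
    if maps is None:
        maps = automorphism_maps(mol)
    pa = pa[heavy]
    pb = pb[heavy]
    return min(kabsch_rmsd(pa, pb[perm]) for perm in maps)


@dataclass
class DftReference:
    """Duplicate-bin structure of an exhaustively re-optimized ensemble."""

    bins: list[list[int]]          # source indices, grouped; bin 0 = DFT minimum
    bin_energies: list[float]      # lowest g_rel per bin, ascending
    m: int                         # total conformer count
    dft_list: np.ndarray = field(default=None)  # optimal priority order
    bin_of: dict[int, int] = field(default=None)

    def __post_init__(self) -> None:
        if self.bin_of is None:
            self.bin_of = {idx: b for b, grp in enumerate(self.bins)
                           for idx in grp}
        if self.dft_list is None:
            reps = [grp[0] for grp in self.bins]
            rest = sorted((i for grp in self.bins for i in grp[1:]),
                          key=lambda i: (self.bin_of[i], i))
            self.dft_list = np.asarray(reps + rest, dtype=int)

    @property
    def B(self) -> int:
        return len(self.bins)

    @property
    def duplicate_rate(self) -> float:
        return 1.0 - self.B / self.m


def build_reference(
    results: list[OptimizedResult],
    mol: Chem.Mol,
    rmsd_threshold: float = RMSD_DUPLICATE_THRESHOLD,
) -> DftReference:
    """Group exhaustive re-optimization results into duplicate bins.

    Two results belong to the same bin when their best RMSD is below the
    threshold; bins are the connected components of that relation
    (transitive closure).  Bins and their members are ordered by relative
    free energy ascending.
    """
    if not results:
        raise ValueError("no results to build a reference from")
    if any(not r.converged for r in results):
        raise ValueError("reference requires all results converged")
    n = len(results)
    maps = automorphism_maps(mol)
    heavy = heavy_atom_indices(mol)
    coords = [r.coordinates[heavy] for r in results]
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            r = min(kabsch_rmsd(coords[i], coords[j][perm]) for perm in maps)
            if r < rmsd_threshold:
                rows.append(i)
                cols.append(j)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)

    groups: dict[int, list[int]] = {}
    for pos, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(pos)
    bins = []
    for members in groups.values():
        members = sorted(members, key=lambda p: (results[p].g_rel, p))
        bins.append(members)
    bins.sort(key=lambda grp: (results[grp[0]].g_rel, grp[0]))
    return DftReference(
        bins=[[results[p].source_index for p in grp] for grp in bins],
        bin_energies=[results[grp[0]].g_rel for grp in bins],
        m=n,
    )


def global_minimum_test(priority: PriorityList, ref: DftReference) -> float:
    """P_GMT: fraction of the list re-optimized when the first member of
    the DFT global-minimum bin is reached.  Any member of bin 0 counts."""
    if set(priority.order.tolist()) != set(ref.bin_of):
        raise ValueError("priority list and reference cover different conformers")
    gm = set(ref.bins[0])
    for pos, idx in enumerate(priority.order):
        if int(idx) in gm:
            return (pos + 1) / priority.m
    raise AssertionError("global-minimum bin never reached")  # unreachable


def bins_test(
    priority: PriorityList, ref: DftReference
) -> tuple[np.ndarray, float]:
    """Bins-test curve and area deficit.

    Returns ``(curve, delta_a_bins)`` where ``curve`` has columns
    (k, r_opt, r_bins, r_star) for k = 1..m and ``delta_a_bins`` is the
    left-Riemann step sum (1/m) * sum_k [r*(k) - r_bins(k)].
    """
    if set(priority.order.tolist()) != set(ref.bin_of):
        raise ValueError("priority list and reference cover different conformers")
    m, B = priority.m, ref.B
    populated: set[int] = set()
    rows = np.empty((m, 4))
    delta = 0.0
    for k, idx in enumerate(priority.order, start=1):
        populated.add(ref.bin_of[int(idx)])
        r_bins = len(populated) / B
        r_star = min(k, B) / B
        delta += r_star - r_bins
        rows[k - 1] = (k, k / m, r_bins, r_star)
    return rows, delta / m


def overall(p_gmt: float, delta_a_bins: float) -> float:
    """Combined score: P_GMT + 5 * delta_a_bins (lower is better)."""
    return p_gmt + 5.0 * delta_a_bins


@dataclass
class EvaluationReport:
    """All three scores for one priority list."""

    p_gmt: float
    delta_a_bins: float
    p_overall: float
    bins_curve: np.ndarray
    method: str = ""

    def to_json(self) -> str:
        return json.dumps({
            "method": self.method,
            "p_gmt": self.p_gmt,
            "delta_a_bins": self.delta_a_bins,
            "p_overall": self.p_overall,
            "bins_curve": [
                {"k": int(k), "r_opt": r, "r_bins": rb, "r_star": rs}
                for k, r, rb, rs in self.bins_curve.tolist()],
        }, indent=2)


def evaluate_priority(priority: PriorityList, ref: DftReference) -> EvaluationReport:
    """Run the global-minimum and bins tests and combine them."""
    p_gmt = global_minimum_test(priority, ref)
    curve, delta = bins_test(priority, ref)
    return EvaluationReport(
        p_gmt=p_gmt,
        delta_a_bins=delta,
        p_overall=overall(p_gmt, delta),
        bins_curve=curve,
        method=priority.method,
    )
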