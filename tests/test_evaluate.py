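"""Best-RMSD, duplicate bins, global-minimum test, bins test, overall score."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdMolAlign
from scipy.spatial.transform import Rotation

from conftriage.ensemble import OptimizedResult
from conftriage.evaluate import (
    DftReference,
    best_rmsd,
    bins_test,
    build_reference,
    global_minimum_test,
    heavy_atom_indices,
    overall,
)
from conftriage.prioritize import PriorityList
from conftriage.synthetic import make_rotor_ensemble, simulate_outcomes

from conftest import embedded


def exhaustive_best_rmsd(ca, cb, mol) -> float:
    """Oracle: minimum superposed RMSD over ALL element- and adjacency-
    preserving heavy-atom permutations, alignment via scipy Rotation."""
    heavy = heavy_atom_indices(mol)
    elems = [mol.GetAtomWithIdx(i).GetSymbol() for i in heavy]
    pos = {a: k for k, a in enumerate(heavy)}
    adj = np.zeros((len(heavy), len(heavy)), bool)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in pos and j in pos:
            adj[pos[i], pos[j]] = adj[pos[j], pos[i]] = True
    pa, pb = ca[heavy], cb[heavy]
    best = np.inf
    for perm in itertools.permutations(range(len(heavy))):
        if any(elems[i] != elems[perm[i]] for i in range(len(heavy))):
            continue
        ok = all(adj[i, j] == adj[perm[i], perm[j]]
                 for i in range(len(heavy)) for j in range(i + 1, len(heavy)))
        if not ok:
            continue
        q = pb[list(perm)]
        p0, q0 = pa - pa.mean(0), q - q.mean(0)
        _rot, rssd = Rotation.align_vectors(p0, q0)
        best = min(best, rssd / np.sqrt(len(heavy)))
    return best


class TestBestRmsd:
    def test_identical_is_zero(self):
        mol = embedded("CCCC")
        c = mol.GetConformer().GetPositions()
        assert best_rmsd(c, c, mol) == pytest.approx(0.0, abs=1e-7)

    def test_rigid_motion_removed(self):
        mol = embedded("CCO")
        c = np.array(mol.GetConformer().GetPositions())
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = c @ rot.T + np.array([5.0, -3.0, 1.0])
        assert best_rmsd(c, moved, mol) == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("smiles", ["CCCC", "CC(C)C", "CCO", "OCCO"])
    def test_matches_exhaustive_automorphism_oracle(self, smiles):
        mol = embedded(smiles)
        rng = np.random.default_rng(3)
        c = np.array(mol.GetConformer().GetPositions())
        for _ in range(5):
            other = c + rng.normal(0, 0.3, c.shape)
            perm_heavy = rng.permutation  # noqa: F841  (doc: oracle permutes)
            mine = best_rmsd(c, other, mol)
            assert mine == pytest.approx(
                exhaustive_best_rmsd(c, other, mol), abs=1e-8)

    def test_matches_rdkit_getbestrms(self):
        # independent route through RDKit's own aligner on heavy atoms
        mol = embedded("CC(C)CO")
        rng = np.random.default_rng(8)
        c = np.array(mol.GetConformer().GetPositions())
        other = c + rng.normal(0, 0.2, c.shape)
        heavy = Chem.RemoveHs(Chem.Mol(mol))
        n = heavy.GetNumAtoms()

        def with_coords(m, xyz):
            out = Chem.Mol(m)
            conf = out.GetConformer()
            for a in range(n):
                conf.SetAtomPosition(a, xyz[a].tolist())
            return out

        ref = rdMolAlign.GetBestRMS(with_coords(heavy, other[:n]),
                                    with_coords(heavy, c[:n]))
        assert best_rmsd(c, other, mol) == pytest.approx(ref, abs=1e-6)

    def test_pseudo_metric_properties(self):
        mol = embedded("CCCO")
        rng = np.random.default_rng(5)
        c = np.array(mol.GetConformer().GetPositions())
        xs = [c + rng.normal(0, 0.2, c.shape) for _ in range(3)]
        d = lambda a, b: best_rmsd(a, b, mol)  # noqa: E731
        for a, b in itertools.combinations(range(3), 2):
            assert d(xs[a], xs[b]) == pytest.approx(d(xs[b], xs[a]), abs=1e-9)
        assert d(xs[0], xs[2]) <= d(xs[0], xs[1]) + d(xs[1], xs[2]) + 1e-9


class TestBuildReference:
    def test_duplicate_groups_and_representative(self):
        # three structures coincide, two coincide, bins ordered by energy
        ens, truth = make_rotor_ensemble(2, m=8, seed=11, duplicate_rate=0.25)
        results = simulate_outcomes(ens, truth, seed=12)
        ref = build_reference(results, ens.mol)
        assert {frozenset(b) for b in ref.bins} == truth.bin_partition()
        assert ref.bin_energies == sorted(ref.bin_energies)
        for grp in ref.bins:  # representative = lowest-energy member first
            g = {r.source_index: r.g_rel for r in results}
            assert g[grp[0]] == min(g[i] for i in grp)

    def test_all_distinct_singleton_bins(self):
        ens, truth = make_rotor_ensemble(2, m=6, seed=13, duplicate_rate=0.0)
        results = simulate_outcomes(ens, truth, seed=14)
        ref = build_reference(results, ens.mol)
        assert ref.B == 6 and all(len(b) == 1 for b in ref.bins)

    def test_transitive_closure_chains(self):
        # pairwise-close triple collapses into one bin
        mol = embedded("CCC")
        c = np.array(mol.GetConformer().GetPositions())
        res = [OptimizedResult(i, c + i * 0.001, float(i)) for i in range(3)]
        ref = build_reference(res, mol, rmsd_threshold=0.005)
        assert ref.B == 1 and len(ref.bins[0]) == 3

    def test_nonconverged_rejected(self):
        mol = embedded("CC")
        c = np.array(mol.GetConformer().GetPositions())
        res = [OptimizedResult(0, c, 0.0),
               OptimizedResult(1, c, float("nan"), converged=False)]
        with pytest.raises(ValueError, match="converged"):
            build_reference(res, mol)


def make_ref(bins, m):
    return DftReference(bins=bins, bin_energies=list(range(len(bins))), m=m)


class TestGlobalMinimumTest:
    def test_first_and_last_extremes(self):
        ref = make_ref([[0], [1], [2], [3]], 4)
        assert global_minimum_test(PriorityList([0, 1, 2, 3], "a"), ref) == 0.25
        assert global_minimum_test(PriorityList([1, 2, 3, 0], "a"), ref) == 1.0

    def test_any_bin_member_counts(self):
        bins = [[3, 7]] + [[i] for i in range(10) if i not in (3, 7)]
        ref = make_ref(bins, 10)
        priority = PriorityList([0, 1, 2, 7, 3, 4, 5, 6, 8, 9], "a")
        assert global_minimum_test(priority, ref) == pytest.approx(0.4)


def brute_force_delta(order, bin_of, B):
    m = len(order)
    seen, total = set(), 0.0
    for k, idx in enumerate(order, 1):
        seen.add(bin_of[idx])
        total += min(k, B) / B - len(seen) / B
    return total / m


class TestBinsTest:
    def test_dft_list_order_is_optimal(self):
        ref = make_ref([[0, 2], [1], [3]], 4)
        _curve, delta = bins_test(PriorityList(ref.dft_list, "dft"), ref)
        assert delta == pytest.approx(0.0)

    def test_singleton_bins_any_order_zero(self):
        ref = make_ref([[0], [1], [2], [3]], 4)
        for order in itertools.permutations(range(4)):
            assert bins_test(PriorityList(list(order), "x"), ref)[1] == 0.0

    @pytest.mark.parametrize("m,seed", [(4, 0), (5, 1), (6, 2)])
    def test_step_sum_matches_brute_force_all_permutations(self, m, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, max(2, m - 2), size=m)
        groups = {}
        for i, lab in enumerate(labels):
            groups.setdefault(int(lab), []).append(i)
        bins = sorted(groups.values())
        ref = make_ref(bins, m)
        for order in itertools.permutations(range(m)):
            _c, delta = bins_test(PriorityList(list(order), "x"), ref)
            assert delta == pytest.approx(
                brute_force_delta(order, ref.bin_of, ref.B), abs=1e-12)
            assert delta >= -1e-12

    def test_dominance_of_dft_list(self):
        ref = make_ref([[0, 3], [1, 4], [2]], 5)
        opt_curve, _ = bins_test(PriorityList(ref.dft_list, "dft"), ref)
        for order in itertools.permutations(range(5)):
            curve, _ = bins_test(PriorityList(list(order), "x"), ref)
            assert np.all(opt_curve[:, 2] >= curve[:, 2] - 1e-12)

    def test_curve_monotone_ends_at_one(self):
        ref = make_ref([[0, 2], [1], [3, 4]], 5)
        curve, _ = bins_test(PriorityList([4, 2, 0, 1, 3], "x"), ref)
        r_bins = curve[:, 2]
        assert np.all(np.diff(r_bins) >= 0) and r_bins[-1] == 1.0


class TestOverall:
    def test_linear_combination(self):
        assert overall(0.14, 0.0) == pytest.approx(0.14)
        assert overall(0.0, 0.2) == pytest.approx(1.0)
        # the area term carries a weight of exactly 5
        assert overall(0.1, 0.03) - overall(0.1, 0.02) == pytest.approx(0.05)
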