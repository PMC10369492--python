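"""Ground-truthed synthetic inputs for every pipeline stage.

Real studies pair a force-field conformer search with exhaustive DFT
re-optimization of every structure -- far too expensive to regenerate on
demand.  This module fabricates the same data shapes with known answers:

* torsion-basin ensembles: an alkane-like chain whose backbone torsions
  are set to canonical rotamer states (+/-60, 180 degrees) plus Gaussian
  jitter, with FF energies drawn per basin -- so the true cluster
  partition is known by construction;
* simulated re-optimization outcomes: FF conformers are merged into DFT
  duplicate bins at a requested rate (about 15% of re-optimized structures
  are duplicates in typical organic datasets), with within-bin geometries
  0.001 Angstrom apart and between-bin geometries far beyond the 0.005
  Angstrom duplicate threshold, and DFT energies equal to the FF basin
  energies plus Gaussian rank-reshuffling noise (so the FF and DFT global
  minima can disagree, as they often do in practice);
* labelled trajectory corpora for training the completion model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms

from .completion import assign_label, build_trajectory, extract_features
from .dihedrals import build_feature_matrix
from .ensemble import HARTREE_TO_KCAL, ConformerEnsemble, OptimizedResult
from .prioritize import PriorityList, make_priority_list

# the nine settings used to populate the completion-model training corpus
NINE_APPROACHES: tuple[tuple[str, dict], ...] = (
    ("pipeline_x", {"x": 0.8}),
    ("pipeline_ascent", {}),
    ("pipeline_mix", {"x": 0.8, "q": 0.15}),
    ("pipeline_mix", {"x": 0.8, "q": 0.20}),
    ("pipeline_mix", {"x": 0.8, "q": 0.25}),
    ("every_nth", {"n": 1}),
    ("every_nth", {"n": 2}),
    ("every_nth", {"n": 3}),
    ("every_nth", {"n": 4}),
)

_CANONICAL_STATES = (180.0, 60.0, -60.0)


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    basin_ids: np.ndarray                  # per conformer, ensemble order
    state_vectors: np.ndarray              # per conformer, rotor states
    backbone_quadruples: list[tuple[int, int, int, int]]
    seed: int
    bin_map: dict[int, int] = field(default_factory=dict)   # conformer -> DFT bin
    dft_bin_energies: np.ndarray | None = None
    global_min_bin: int | None = None
    duplicate_rate: float | None = None

    @property
    def n_rotors(self) -> int:
        return self.state_vectors.shape[1]

    def bin_partition(self) -> set[frozenset]:
        out: dict[int, set[int]] = {}
        for conf, b in self.bin_map.items():
            out.setdefault(b, set()).add(conf)
        return {frozenset(v) for v in out.values()}

    def basin_partition(self) -> set[frozenset]:
        out: dict[int, set[int]] = {}
        for conf, b in enumerate(self.basin_ids):
            out.setdefault(int(b), set()).add(conf)
        return {frozenset(v) for v in out.values()}


def _chain_mol(n_carbons: int) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles("C" * n_carbons))
    AllChem.EmbedMolecule(mol, randomSeed=7)
    return mol


def _min_distance(coords: np.ndarray) -> float:
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def _set_backbone(conf0, quads, angles) -> np.ndarray:
    conf = Chem.Conformer(conf0)
    for (a, b, c, d), angle in zip(quads, angles):
        rdMolTransforms.SetDihedralDeg(conf, a, b, c, d, float(angle))
    return np.array(conf.GetPositions())


def _feasible_state_codes(
    conf0, quads, states: np.ndarray, n_rotors: int, states_per_rotor: int,
    clearance: float = 0.55,
) -> np.ndarray:
    """State codes whose ideal (jitter-free) geometry has no atom pair
    closer than ``clearance``; folded-back rotamer combinations (e.g. long
    g+/g- alternations) are excluded."""
    codes = np.stack(np.meshgrid(
        *[np.arange(states_per_rotor)] * n_rotors, indexing="ij"),
        axis=-1).reshape(-1, n_rotors)
    keep = [row for row in codes
            if _min_distance(_set_backbone(conf0, quads, states[row]))
            >= clearance]
    return np.asarray(keep, dtype=int)


def make_rotor_ensemble(
    n_rotors: int,
    states_per_rotor: int = 3,
    jitter_deg: float = 5.0,
    m: int | None = None,
    seed: int = 0,
    basin_energy_scale: float = 8.0,
    within_basin_energy_sd: float = 0.3,
    duplicate_rate: float = 0.0,
    allow_replacement: bool = False,
) -> tuple[ConformerEnsemble, SyntheticGroundTruth]:
    """Alkane-like ensemble with ``n_rotors`` variable backbone torsions.

    Each conformer's backbone torsions are set to one of the canonical
    rotamer states plus N(0, jitter) noise; conformers sharing a state
    vector share a basin.  ``duplicate_rate`` plants repeat visits: a
    fraction of conformers lands in an already-occupied basin, emulating a
    search that revisits the same torsional well -- exactly the conformers
    that will collapse to one structure on re-optimization.  FF energies
    are a per-basin base drawn uniform on [0, basin_energy_scale] plus
    half-normal within-basin noise, then sorted ascending and re-zeroed as
    a real search output would be.
    """
    if not 2 <= states_per_rotor <= 3:
        raise ValueError("states_per_rotor must be 2 or 3")
    if not 0 <= duplicate_rate < 1:
        raise ValueError("duplicate_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    states = np.array(_CANONICAL_STATES[:states_per_rotor])

    n_carbons = n_rotors + 3
    mol = _chain_mol(n_carbons)
    conf0 = mol.GetConformer()
    quads = [(i, i + 1, i + 2, i + 3) for i in range(n_rotors)]

    # only sterically realizable rotamer combinations are valid basins
    feasible = _feasible_state_codes(conf0, quads, states,
                                     n_rotors, states_per_rotor)
    n_states = len(feasible)
    if m is None:
        m = n_states
    n_basins = max(1, m - int(round(duplicate_rate * m)))
    if n_basins > n_states:
        if not allow_replacement:
            raise ValueError(
                f"{n_basins} basins requested but only {n_states} feasible "
                "rotor states; pass allow_replacement=True to reuse states")
        n_basins = n_states
    basin_codes = feasible[rng.choice(n_states, size=n_basins, replace=False)]
    # every basin occupied once; remaining conformers revisit random basins
    basin_ids = np.concatenate([
        np.arange(n_basins),
        rng.integers(0, n_basins, size=m - n_basins)])
    codes = basin_codes[basin_ids]

    coords = np.empty((m, mol.GetNumAtoms(), 3))
    for k in range(m):
        # jitter can push a marginal rotamer into a clash; redraw if so
        for _attempt in range(10):
            angles = states[codes[k]] + rng.normal(0.0, jitter_deg,
                                                   size=n_rotors)
            coords[k] = _set_backbone(conf0, quads, angles)
            if _min_distance(coords[k]) >= 0.35:
                break
        else:
            raise ValueError(f"infeasible geometry in conformer {k} "
                             f"(atoms {_min_distance(coords[k]):.2f} A apart)")

    base = rng.uniform(0.0, basin_energy_scale, size=n_basins)
    u = base[basin_ids] + np.abs(rng.normal(0.0, within_basin_energy_sd, size=m))
    order = np.argsort(u, kind="stable")
    u = u[order] - u[order][0]

    graph_mol = Chem.Mol(mol)
    graph_mol.RemoveAllConformers()
    ens = ConformerEnsemble(graph_mol, coords[order], u)
    truth = SyntheticGroundTruth(
        basin_ids=basin_ids[order],
        state_vectors=states[codes[order]],
        backbone_quadruples=quads,
        seed=seed,
        duplicate_rate=1.0 - n_basins / m,
    )
    return ens, truth


def simulate_outcomes(
    ens: ConformerEnsemble,
    truth: SyntheticGroundTruth,
    energy_reshuffle_sd: float = 2.0,
    duplicate_rate: float | None = None,
    seed: int = 0,
    within_bin_rmsd: float = 0.001,
    between_bin_displacement: float = 0.3,
) -> list[OptimizedResult]:
    """Fabricate an exhaustive set of re-optimization outcomes.

    Re-optimization collapses each torsional basin to one structure, so
    the planted basins become the duplicate bins.  When ``duplicate_rate``
    asks for more duplicates than the ensemble's basin structure provides,
    randomly chosen basins are merged until the rate is met (two wells
    relaxing to the same structure).  Each bin gets a distinct random
    displacement field on top of its founder's FF geometry, members of one
    bin sit within ``within_bin_rmsd`` of each other, and bin energies are
    the founders' FF energies plus N(0, energy_reshuffle_sd) noise
    (re-zeroed).  With zero noise the DFT energy order equals the FF
    order.  ``truth`` is updated in place with the planted bin map.
    """
    rng = np.random.default_rng(seed)
    m = ens.m
    basin_of = {conf: int(b) for conf, b in enumerate(truth.basin_ids)}
    n_basins = int(truth.basin_ids.max()) + 1
    # merge whole basins until the requested duplicate rate is reached
    merge = np.arange(n_basins)
    if duplicate_rate is not None:
        if not 0 <= duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        target_bins = max(1, m - int(round(duplicate_rate * m)))
        alive = list(range(n_basins))
        while len(alive) > target_bins:
            victim, host = rng.choice(len(alive), size=2, replace=False)
            merge[merge == alive[victim]] = alive[host]
            alive.pop(victim)
    relabel = {old: new for new, old in enumerate(dict.fromkeys(merge))}
    bin_of = {conf: relabel[merge[b]] for conf, b in basin_of.items()}
    n_bins = len(relabel)

    # founder = lowest-FF-energy member (smallest index; ensemble is sorted)
    founders = [min(c for c, b in bin_of.items() if b == bb)
                for bb in range(n_bins)]
    bin_energy = np.array([ens.u_ff[f] for f in founders])
    bin_energy = bin_energy + rng.normal(0.0, energy_reshuffle_sd, size=n_bins)

    bin_geom = np.empty((n_bins, ens.n_atoms, 3))
    for b, f in enumerate(founders):
        bin_geom[b] = ens.coords[f] + rng.normal(
            0.0, between_bin_displacement, size=(ens.n_atoms, 3))

    per_coord_sd = within_bin_rmsd / math.sqrt(3.0)
    results = []
    g = np.empty(m)
    for conf in range(m):
        b = bin_of[conf]
        is_founder = founders[b] == conf
        geom = bin_geom[b] if is_founder else bin_geom[b] + rng.normal(
            0.0, per_coord_sd, size=(ens.n_atoms, 3))
        g[conf] = bin_energy[b] + (0.0 if is_founder
                                   else abs(rng.normal(0.0, 0.02)))
        results.append(OptimizedResult(conf, geom, g_rel=0.0))
    g -= g.min()
    for conf, res in enumerate(results):
        res.g_rel = float(g[conf])

    truth.bin_map = bin_of
    truth.dft_bin_energies = bin_energy - bin_energy.min()
    truth.global_min_bin = int(np.argmin(bin_energy))
    truth.duplicate_rate = 1.0 - n_bins / m
    return results


def planted_p_gmt(priority: PriorityList, truth: SyntheticGroundTruth) -> float:
    """P_GMT straight from the planted bin map (no RMSD needed)."""
    gm = truth.global_min_bin
    for pos, idx in enumerate(priority.order):
        if truth.bin_map[int(idx)] == gm:
            return (pos + 1) / priority.m
    raise AssertionError("global-minimum bin not covered")


def duplicate_flags_for(
    priority: PriorityList, truth: SyntheticGroundTruth
) -> list[bool]:
    """Whether each entry of a priority-ordered stream duplicates an
    earlier one, read from the planted bin map."""
    seen: set[int] = set()
    flags = []
    for idx in priority.order:
        b = truth.bin_map[int(idx)]
        flags.append(b in seen)
        seen.add(b)
    return flags


@dataclass
class TrajectoryCorpus:
    """Descriptor rows + labels + molecule ids for completion training."""

    features: np.ndarray
    labels: list[str]
    groups: np.ndarray

    @property
    def n_rows(self) -> int:
        return len(self.labels)


def make_trajectory_corpus(
    n_molecules: int,
    m_range: tuple[int, int] = (15, 40),
    approaches: tuple = NINE_APPROACHES,
    seed: int = 0,
    duplicate_rate: float = 0.15,
    energy_reshuffle_sd: float = 2.0,
) -> TrajectoryCorpus:
    """Labelled descriptor corpus over synthetic molecules x approaches.

    For every molecule and priority-list setting, all m prefixes of the
    full chi_new trajectory yield one (descriptor, label) row; labels come
    from the planted P_GMT, so the corpus is exactly what exhaustive
    re-optimization would have produced.
    """
    if n_molecules < 2:
        raise ValueError("need at least two molecules")
    rng = np.random.default_rng(seed)
    rows, labels, groups = [], [], []
    for mol_id in range(n_molecules):
        m = int(rng.integers(m_range[0], m_range[1] + 1))
        n_rotors = max(2, math.ceil(math.log(m, 3)))
        ens, truth = make_rotor_ensemble(
            n_rotors, m=m, seed=int(rng.integers(2 ** 31)),
            duplicate_rate=duplicate_rate, allow_replacement=True)
        feats, _ = build_feature_matrix(ens)
        results = simulate_outcomes(
            ens, truth, energy_reshuffle_sd=energy_reshuffle_sd,
            seed=int(rng.integers(2 ** 31)))
        for method, params in approaches:
            priority = make_priority_list(ens, method, feats,
                                          seed=int(rng.integers(2 ** 31)),
                                          **params)
            stream = [results[int(i)] for i in priority.order]
            flags = duplicate_flags_for(priority, truth)
            full = build_trajectory(stream, m, duplicate_flags=flags)
            p_gmt = planted_p_gmt(priority, truth)
            for k in range(1, m + 1):
                prefix = type(full)(full.points[:k], m, full.temperature)
                rows.append(extract_features(prefix))
                labels.append(assign_label(prefix, p_gmt))
                groups.append(mol_id)
    return TrajectoryCorpus(np.asarray(rows), labels, np.asarray(groups))


def make_planted_signal_corpus(
    n_rows: int, seed: int = 0
) -> TrajectoryCorpus:
    """Corpus whose label is a known deterministic function of the
    descriptor: stop iff more than half of the last-40% points have
    chi_new = 0.  Used to verify that training recovers a planted rule."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    from .completion import CONTINUE, STOP, CompletionTrajectory
    for _ in range(n_rows):
        k = int(rng.integers(5, 60))
        m = k + int(rng.integers(0, 40))
        p_zero = rng.uniform(0.2, 0.8)
        chi = np.where(rng.random(k) < p_zero, 0.0, rng.random(k))
        chi[0] = 1.0
        traj = CompletionTrajectory(
            [((i + 1) / m, float(c)) for i, c in enumerate(chi)], m)
        x = extract_features(traj)
        rows.append(x)
        labels.append(STOP if x[5] > 0.5 else CONTINUE)  # frac_zero_tail
    return TrajectoryCorpus(
        np.asarray(rows), labels, np.arange(n_rows) % max(2, n_rows // 10))


def write_synthetic_logs(
    results: list[OptimizedResult],
    folder: str | Path,
    dialect: str = "gaussian",
    symbols: list[str] | None = None,
    base_hartree: float = -500.0,
) -> None:
    """Write results as minimal parsable quantum-chemistry text outputs.

    Filenames follow the rank convention (``conf_01.log``, ...), so reading
    the folder back with the matching manifest or priority order restores
    the stream.  Marked synthetic: these are fabricated logs for exercising
    the file-reading path, not real calculation outputs.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    pt = Chem.GetPeriodicTable()
    width = max(2, len(str(len(results))))
    for rank, res in enumerate(results):
        n = len(res.coordinates)
        syms = symbols or ["C"] * n
        e_hartree = base_hartree + res.g_rel / HARTREE_TO_KCAL
        if dialect == "xyz":
            lines = [str(n), f"energy = {e_hartree:.8f}"]
            lines += [f"{s} {x:.6f} {y:.6f} {z:.6f}"
                      for s, (x, y, z) in zip(syms, res.coordinates)]
            (folder / f"conf_{rank + 1:0{width}d}.xyz").write_text(
                "\n".join(lines) + "\n")
            continue
        geom = "\n".join(
            f"{i + 1:7d} {pt.GetAtomicNumber(s):11d} {0:12d}"
            f" {x:15.6f} {y:11.6f} {z:11.6f}"
            for i, (s, (x, y, z)) in enumerate(zip(syms, res.coordinates)))
        text = (
            "                         Standard orientation:\n"
            " ---------------------------------------------------------------------\n"
            " Center     Atomic      Atomic             Coordinates (Angstroms)\n"
            " Number     Number       Type             X           Y           Z\n"
            " ---------------------------------------------------------------------\n"
            f"{geom}\n"
            " ---------------------------------------------------------------------\n"
            f" SCF Done:  E(RB3LYP) =  {e_hartree - 0.1:.9f}     A.U. after    9 cycles\n"
            f" Sum of electronic and thermal Enthalpies=    {e_hartree + 0.01:.6f}\n"
            f" Sum of electronic and thermal Free Energies= {e_hartree:.6f}\n"
            + (" Normal termination of Gaussian 16\n" if res.converged else
               " Error termination via Lnk1e\n"))
        (folder / f"conf_{rank + 1:0{width}d}.log").write_text(text)
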