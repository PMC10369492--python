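"""Shared fixtures: small molecules with controlled torsions, SDF writers."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms

from conftriage.ensemble import ConformerEnsemble


def embedded(smiles: str, seed: int = 11) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    return mol


def ensemble_from_torsions(
    smiles: str,
    quadruples: list[tuple[int, int, int, int]],
    settings: list[tuple[float, ...]],
    energies: list[float] | None = None,
    jitter: float = 0.0,
    seed: int = 0,
) -> ConformerEnsemble:
    """Ensemble of one molecule with backbone torsions set per conformer."""
    rng = np.random.default_rng(seed)
    mol = embedded(smiles)
    conf0 = mol.GetConformer()
    coords = []
    for angles in settings:
        conf = Chem.Conformer(conf0)
        for quad, angle in zip(quadruples, angles):
            rdMolTransforms.SetDihedralDeg(
                conf, *quad, float(angle + rng.normal(0, jitter)))
        coords.append(np.array(conf.GetPositions()))
    if energies is None:
        energies = list(range(len(settings)))
    order = np.argsort(energies, kind="stable")
    u = np.asarray(energies, float)[order]
    graph = Chem.Mol(mol)
    graph.RemoveAllConformers()
    return ConformerEnsemble(graph, np.stack([coords[i] for i in order]),
                             u - u[0])


def write_sdf(path, mols_with_energy, prop="energy"):
    writer = Chem.SDWriter(str(path))
    for mol, e in mols_with_energy:
        mol.SetProp(prop, str(e))
        writer.write(mol)
    writer.close()
    return path


@pytest.fixture(scope="session")
def butane():
    return embedded("CCCC")


@pytest.fixture(scope="session")
def pentane_rotamers():
    """Four ideal rotamers of n-pentane over its two backbone torsions."""
    return ensemble_from_torsions(
        "CCCCC", [(0, 1, 2, 3), (1, 2, 3, 4)],
        [(180, 180), (60, 180), (180, 60), (60, 60)],
        energies=[0.0, 0.8, 0.9, 1.7])


@pytest.fixture(scope="session")
def planted_ensemble():
    """3-rotor synthetic ensemble with duplicates and simulated outcomes."""
    from conftriage.synthetic import make_rotor_ensemble, simulate_outcomes
    ens, truth = make_rotor_ensemble(3, m=20, seed=5, duplicate_rate=0.25)
    results = simulate_outcomes(ens, truth, seed=6)
    return ens, truth, results
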