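"""Extract the dihedral fingerprint of a small conformer ensemble.

Builds a 9-conformer ensemble of an alkane chain with two backbone
rotors, then shows which bonds survive elimination, the spread statistics
(sigma = ensemble standard deviation, eta = range) that separate fixed
from variable torsions, and the resulting feature matrix.
"""

import numpy as np

from conftriage import build_feature_matrix
from conftriage.synthetic import make_rotor_ensemble

ens, truth = make_rotor_ensemble(n_rotors=2, m=9, jitter_deg=5.0, seed=1)
print(f"ensemble: {ens.m} conformers, {ens.n_atoms} atoms, "
      f"relative FF energies 0 .. {ens.u_ff[-1]:.2f} kcal/mol")

features, dihedral_set = build_feature_matrix(ens)
print("\ncandidate dihedrals (central-bond atom quadruples):")
for d in dihedral_set.dihedrals:
    tag = "fixed" if d.is_fixed else "variable"
    print(f"  {d.atoms}  sigma = {d.sigma:6.1f} deg  eta = {d.eta:6.1f} deg"
          f"  -> {tag}")

print(f"\nfeature matrix: {features.m} conformers x {features.d} variable "
      "torsions (degrees, unwrapped)")
print(np.round(features.values, 1))
# Each row is one conformer; well-separated rows correspond to different
# rotamer basins, which is what the clustering step exploits.
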