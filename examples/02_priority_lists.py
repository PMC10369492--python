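"""Generate priority lists for DFT re-optimization, five ways.

A priority list is a permutation of the conformer indices (which are
energy-sorted, so index 0 is the force-field minimum).  The clustering
pipelines front-load one representative per torsional cluster, pushing
probable duplicates toward the tail.
"""

from conftriage import build_feature_matrix
from conftriage.prioritize import (
    ascent,
    every_nth,
    pipeline_ascent,
    pipeline_mix,
    pipeline_x,
)
from conftriage.synthetic import make_rotor_ensemble

# 12 conformers over 3 rotors; 25% are repeat visits to an occupied basin
ens, truth = make_rotor_ensemble(n_rotors=3, m=12, duplicate_rate=0.25,
                                 seed=4)
features, _ = build_feature_matrix(ens)

print(f"{ens.m} conformers; planted torsional basins per conformer:")
print(" ", truth.basin_ids.tolist())

for pri in (ascent(ens),
            every_nth(ens, 2),
            pipeline_x(ens, features),             # x = 0.8
            pipeline_ascent(ens, features),
            pipeline_mix(ens, features)):          # x = 0.8, Q = 0.2
    print(f"{pri.method:16s} {pri.order.tolist()}")

# Note how the pipeline lists visit every basin before returning to an
# already-seen one, while plain ascent happily queues duplicates early.
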