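# Methods

This note records the models, parameter choices and numerical conventions
behind `conftriage`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Dihedral fingerprint

A conformer is represented by the torsions around bonds that can actually
generate conformational variety. Bond elimination is rule-based:

* **A — monovalent atoms.** A bond to H, F, Cl, Br or I cannot be a
  torsion axis.
* **B — CX₃ rotors.** Methyl/CF₃-type tops are threefold-degenerate;
  their torsion says nothing about which basin a conformer occupies.
* **C — small rings and multiple bonds.** Ring bonds up to ring size 7
  are treated as torsionally locked; ring bonds in macrocycles (size ≥ 8)
  are kept as candidates, since large rings do flex. Double, triple and
  aromatic bonds are locked. Exception: conjugated single bonds between
  an N/O (degree ≥ 2) and an sp² or aromatic carbon — amides, esters,
  enamines, anilines — are *retained*, because their hindered rotation
  still separates conformer families. The size-7 boundary and the
  retention pattern are this package's conventions for behaviour that is
  usually dataset-derived; both are deliberately simple and documented
  here so they can be audited.

Terminal atoms of each quadruple are picked by preference heteroatom >
carbon > hydrogen, then higher atomic number, then lower atom index —
fully deterministic.

**Fixed-torsion classification.** With per-column spread statistics
σ (population standard deviation) and η (range = max − min), a torsion is
fixed when σ(θ) < 8.7° **or** η(θ) < 2.4°. Columns with η(θ) ≥ 300° are
*trans-oriented*: their values sit near ±180° and flip sign, so the
statistics are recomputed on |θ| with cutoffs σ(|θ|) < 6.6° or
η(|θ|) < 1.5°. The two cutoffs within a row combine with OR: either a
small standard deviation or a small range is enough evidence of rigidity
(with AND, the tighter range cutoff would make the σ cutoff unreachable).
A single-conformer column is fixed by convention.

**Seam unwrapping.** Torsions are periodic on (−180°, 180°]; a cluster
sitting at ±179° would appear 358° wide to Euclidean distance. When the
largest circular gap between a column's sorted values does not contain
180° (i.e. the data straddle the seam), negative values are shifted by
+360°. The circular spread is invariant under this shift; only the linear
representation changes.

## Clustering

Agglomerative clustering with Ward's variance-increase criterion on
Euclidean distances over the raw angle columns. One linkage tree serves
all cluster counts, so partitions are nested — the `pipeline_ascent`
sweep over n_clusters = 1..m costs one tree build plus m cuts. Angles are
left in degrees and unscaled: all columns share a unit, and rescaling
would silently change the Ward geometry. K-means, BIRCH and Gaussian
mixtures are exposed behind the same contract for comparison; they are
not hierarchical and are not used by the pipelines.

With no variable torsions (rigid molecule or m = 1) clustering degenerates
to a single cluster and the pipeline methods fall back to the energy
ascent order with a warning.

## Priority lists

All six methods return a full permutation so that evaluation curves are
defined over the whole list. Conventions the contracts leave open are
fixed as follows: n_clusters = round-half-up(x·m) with x = 0.8; the
pipeline-mix prefix is ⌈Q·m⌉ entries (guaranteeing a non-empty prefix for
any Q > 0) with Q = 0.2; within a pipeline-ascent step, newly appearing
cluster minima are appended in ascending FF energy; the non-representative
tail of pipeline-x is ascending FF energy; every-nth back-fills skipped
conformers in ascending energy. x = 0.8 reflects that roughly 85% of
re-optimized structures are unique in typical organic ensembles, so one
cluster per unique structure wants slightly fewer clusters than
conformers.

## Evaluation

Two re-optimized structures are the same when their heavy-atom RMSD,
minimized both over rigid superposition (Kabsch) and over
graph-automorphism atom mappings, is below **0.005 Å** — a deliberately
tight threshold, well under geometric convergence noise. Duplicate
grouping is the transitive closure of this pairwise relation (the only
partition-consistent choice). Bins and members are ordered by relative
free energy; finding *any* member of bin 0 counts as finding the global
minimum.

Δa_bins integrates the gap between the optimal curve r*(k) = min(k, B)/B
and the achieved r_bins(k) as a left-Riemann step sum on the rank grid
(spacing 1/m) — the curves are step functions of rank, so no finer
quadrature is meaningful. The combined score is

    P_overall = P_GMT + 5 · Δa_bins.

The linear form with the factor 5 reflects the empirical scale of the two
terms: area deficits rarely exceed 0.2 while P_GMT spans (0, 1], so the
scaling gives both tests comparable force.

## Completion model

χ_new = exp(−ΔG_new/RT) with R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹ and
T = 298.15 K (configurable), ΔG_new measured against the minimum among
structures seen so far; duplicates score 0, a new running minimum scores
exactly 1. Non-converged attempts advance r_opt but contribute χ_new = 0
and do not move the running minimum.

The 13-feature descriptor of a k-point trajectory: fractions of points
with χ_new = 0, = 1, ≤ 0.1, ≤ 0.2, ≤ 0.5 over the whole trajectory and
over its last ⌈0.4·k⌉ points (a point-count window stays well-defined for
short trajectories), the highest r_opt with χ_new = 1, the final r_opt,
and k.

Training labels compare the final r_opt to the (training-time-known)
P_GMT: *stop* iff last r_opt ≥ P_GMT — at equality the global minimum has
just been processed. The classifier is an L2-regularized logistic
regression; the held-out split is group-aware (leave molecules out) when
molecule ids are supplied, so reported accuracy refers to unseen
molecules. At prediction time p_LR ≥ 0.5 means stop (the boundary counts
as stop).

**Confidence calibration.** %Conf(p) = 100/(1 + exp(−(a·p + b))) is
least-squares fitted to decile-binned outcome fractions on the held-out
set. The outcome being calibrated is the *stop event itself* (the true
label is stop), not prediction-correctness: correctness is high at both
ends of the p scale and cannot be represented by a monotone sigmoid,
whereas the stop-event fraction rises monotonically through ~50% at the
decision margin, which is exactly the semantics of "percentage confidence
to terminate". A fitted a < 0 is flagged as a calibration failure. Sparse
bins are widened; the fit's mean absolute error is reported in percentage
points.

Recommended usage loop: re-optimize in 5% batches, re-predict after each
batch, and stop once %Conf exceeds 80% (predictions at r_opt < 0.2 rest
on very little data and are the least reliable; the CLI prints a caution
in that regime).

## Synthetic ground truth

The generator emulates the *shape* of an FF→DFT study, not its physics:

* **Ensembles.** An alkane-like chain with n_rotors backbone torsions set
  to canonical rotamer states (180°, ±60°) plus N(0, 5°) jitter.
  Rotamer combinations whose ideal geometry brings atoms closer than
  0.55 Å (folded g+/g− alternations) are excluded from sampling, and
  jittered geometries are redrawn against a hard 0.35 Å overlap floor.
  FF energies are a per-basin base drawn uniform on [0, 8] kcal/mol plus
  half-normal within-basin noise (sd 0.3), then sorted and re-zeroed.
* **Duplicates.** A requested fraction of conformers (default matching
  the ~15% seen in organic datasets) revisits an already-occupied
  torsional basin; re-optimization collapses each basin to one structure,
  so planted basins become duplicate bins. Within-bin geometries are
  0.001 Å apart and between-bin geometries far beyond the 0.005 Å
  threshold — an order of magnitude of margin on each side, so recovery
  tests are exact rather than statistical.
* **FF/DFT discordance.** Bin energies are the founders' FF energies plus
  N(0, 2.0 kcal/mol) noise. Against the [0, 8] kcal/mol basin spread this
  reshuffling puts the energy-ascent P_GMT in the ~0.1–0.15 regime
  reported for real organic datasets, and guarantees both stop and
  continue labels occur in trajectory corpora. With zero noise the DFT
  order reduces to the FF order exactly.

What passing tests on this fixture **do** show: the descriptor, the
clustering, the list constructions, the scoring identities, the bin
recovery and the learning machinery are all correct, and the pipelines'
advantage over energy-ascent ordering follows from torsional duplicates
being clusterable. What they do **not** show: performance on real
molecules, where basins are anharmonic and unevenly jittered, duplicate
geometry margins are not constructed, FF error is not Gaussian, and
flexible rings/conjugated linkers blur the fixed/variable boundary. The
reported held-out accuracies and calibration errors are properties of the
synthetic corpus, not transferable estimates.

## Problem sizes

The shipped study and acceptance computations use 20 ensembles of
m = 60–120 conformers (five rotors, 8-carbon chains) and trajectory
corpora of 20–25 molecules × 9 priority settings × all prefixes
(~5–7 thousand descriptor rows) — small enough to regenerate from seeds
in seconds while keeping every pipeline stage non-trivial (duplicates
present, FF/DFT disagreement present, both labels populated).

## Known limitations

* Ring-flip conformers of macrocycles are clustered only through their
  retained backbone torsions; puckering coordinates are not modelled.
* The graph-automorphism RMSD enumerates self-matches of the heavy-atom
  skeleton (capped at 10⁴ mappings); pathological highly symmetric
  molecules could exceed the cap and fall back to a subset of mappings.
* The energy-unit heuristic (median |E| ≥ 100 ⇒ Hartree) can misread
  exotic inputs; pass units explicitly in that case.
* The completion model ships as a training procedure plus synthetic
  corpus, not as frozen weights; users with real exhaustive datasets
  should retrain on them.
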