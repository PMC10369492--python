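"""Priority-list generation: which conformer to re-optimize next.

Re-optimizing a whole force-field ensemble at the DFT level is expensive,
and many FF conformers collapse to the same DFT structure.  A priority
list is a permutation of all m conformer indices, ordered so that the
structures most likely to be the DFT global minimum -- and least likely to
be duplicates -- come first.

Baselines order by FF energy alone (*ascent*), by stride (*every nth*) or
at random.  The clustering pipelines use the dihedral feature matrix:

* ``pipeline_x``   -- cluster once at n_clusters = round(x * m) and put the
  per-cluster energy minima first (default x = 0.8, chosen because roughly
  85% of re-optimized structures are unique);
* ``pipeline_ascent`` -- sweep n_clusters from 1 to m on one linkage tree,
  appending each newly isolated cluster minimum as it appears;
* ``pipeline_mix`` -- the first ceil(Q * m) entries of pipeline-x followed
  by the pipeline-ascent order (default Q = 0.2, the recommended overall
  setting).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterModel, representatives
from .dihedrals import FeatureMatrix
from .ensemble import ConformerEnsemble

DEFAULT_X = 0.8
DEFAULT_Q = 0.2


@dataclass
class PriorityList:
    """A permutation of conformer indices with provenance metadata."""

    order: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        m = len(self.order)
        if sorted(self.order.tolist()) != list(range(m)):
            raise ValueError("priority order must be a permutation of 0..m-1")

    @property
    def m(self) -> int:
        return len(self.order)

    def __iter__(self):
        return iter(self.order.tolist())


def ascent(ens: ConformerEnsemble) -> PriorityList:
    """Re-optimize in order of increasing FF energy (identity permutation)."""
    return PriorityList(np.arange(ens.m), "ascent")


def every_nth(ens: ConformerEnsemble, n: int) -> PriorityList:
    """Stride through the energy-sorted list (0, n, 2n, ...), then append
    the skipped conformers in ascending energy so the list stays a full
    permutation.  n = 1 reduces to the ascent order."""
    if n < 1:
        raise ValueError("stride must be >= 1")
    picked = list(range(0, ens.m, n))
    skipped = [i for i in range(ens.m) if i % n != 0]
    return PriorityList(picked + skipped, "every_nth", {"n": n})


def random_order(ens: ConformerEnsemble, seed: int) -> PriorityList:
    """Uniform random permutation, reproducible for a fixed seed."""
    rng = np.random.default_rng(seed)
    return PriorityList(rng.permutation(ens.m), "random", {"seed": seed})


def _n_clusters_for_x(x: float, m: int) -> int:
    if not 0 < x <= 1:
        raise ValueError("x must be in (0, 1]")
    # round-half-up so x = 0.8, m = 10 gives exactly 8
    return min(m, max(1, math.floor(x * m + 0.5)))


def pipeline_x(
    ens: ConformerEnsemble,
    features: FeatureMatrix,
    x: float = DEFAULT_X,
) -> PriorityList:
    """Single clustering at n_clusters = round(x*m); cluster minima first
    (ascending FF energy), remaining conformers after (ascending energy)."""
    model = ClusterModel(features)
    if model.degenerate:
        warnings.warn("degenerate features: pipeline-x falls back to ascent")
        return PriorityList(np.arange(ens.m), "pipeline_x", {"x": x})
    n_clusters = _n_clusters_for_x(x, ens.m)
    reps = representatives(model.cut(n_clusters), ens)
    chosen = set(reps)
    rest = [i for i in range(ens.m) if i not in chosen]
    return PriorityList(reps + rest, "pipeline_x", {"x": x})


def pipeline_ascent(
    ens: ConformerEnsemble, features: FeatureMatrix
) -> PriorityList:
    """Sweep n_clusters = 1..m; at each step append the cluster minima not
    yet listed (ascending FF energy within a step).

    The first entry is always the FF global minimum (the n_clusters = 1
    step), and at n_clusters = m every conformer is its own representative,
    so the sweep terminates with a full permutation.
    """
    model = ClusterModel(features)
    order: list[int] = []
    seen: set[int] = set()
    for k in range(1, ens.m + 1):
        if model.degenerate:
            reps = [0]
        else:
            reps = representatives(model.cut(k), ens)
        for rep in reps:  # already ascending in u_ff
            if rep not in seen:
                seen.add(rep)
                order.append(rep)
        if len(order) == ens.m:
            break
    if model.degenerate:
        order += [i for i in range(ens.m) if i not in seen]
    return PriorityList(order, "pipeline_ascent")


def pipeline_mix(
    ens: ConformerEnsemble,
    features: FeatureMatrix,
    x: float = DEFAULT_X,
    q: float = DEFAULT_Q,
) -> PriorityList:
    """Blend: the first ceil(Q*m) entries of pipeline-x, completed in
    pipeline-ascent order (skipping entries already chosen)."""
    if not 0 <= q <= 1:
        raise ValueError("Q must be in [0, 1]")
    px = pipeline_x(ens, features, x)
    pa = pipeline_ascent(ens, features)
    n_head = math.ceil(q * ens.m)
    head = px.order[:n_head].tolist()
    chosen = set(head)
    tail = [i for i in pa.order.tolist() if i not in chosen]
    return PriorityList(head + tail, "pipeline_mix", {"x": x, "Q": q})


def make_priority_list(
    ens: ConformerEnsemble,
    method: str,
    features: FeatureMatrix | None = None,
    x: float = DEFAULT_X,
    q: float = DEFAULT_Q,
    n: int = 2,
    seed: int = 0,
) -> PriorityList:
    """Dispatch by method name; pipeline methods require ``features``."""
    if method == "ascent":
        return ascent(ens)
    if method == "every_nth":
        return every_nth(ens, n)
    if method == "random":
        return random_order(ens, seed)
    if features is None:
        raise ValueError(f"method {method!r} requires a feature matrix")
    if method == "pipeline_x":
        return pipeline_x(ens, features, x)
    if method == "pipeline_ascent":
        return pipeline_ascent(ens, features)
    if method == "pipeline_mix":
        return pipeline_mix(ens, features, x, q)
    raise ValueError(f"unknown method {method!r}")
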