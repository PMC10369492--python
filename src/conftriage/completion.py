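"""Predicting when partial re-optimization can stop.

As re-optimizations arrive in priority order we track, for each new
structure, its Boltzmann mole fraction relative to the running global
minimum at temperature T:

    chi_new = exp(-dG_new / RT),   dG_new >= 0,

with chi_new set to 0 for structures that duplicate an earlier one.  A
new running minimum scores exactly 1.  The resulting chi_new-vs-r_opt
trajectory carries the signal of how much of the low-energy landscape has
already been seen: late points with chi_new near 1 mean new important
structures are still turning up, while a long tail of zeros and small
values suggests the global minimum is already in hand.

A 13-value descriptor summarizes a (possibly partial) trajectory -- the
fractions of points with chi_new = 0, = 1, <= 0.1, <= 0.2 and <= 0.5 over
the whole trajectory and over its last 40% of points, the highest r_opt at
which chi_new = 1, the final r_opt, and the point count.  A logistic
regression maps the descriptor to a stop/continue label; its probability
p_LR is converted to a percentage confidence %Conf through a sigmoid
calibration fitted on held-out (p_LR, prediction-correct) pairs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupShuffleSplit, train_test_split

from .ensemble import OptimizedResult
from .evaluate import RMSD_DUPLICATE_THRESHOLD, automorphism_maps, best_rmsd

GAS_CONSTANT_KCAL = 1.987204e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE = 298.15

STOP = "stop"
CONTINUE = "continue"

FEATURE_NAMES = (
    "frac_zero", "frac_one", "frac_le_0.1", "frac_le_0.2", "frac_le_0.5",
    "frac_zero_tail", "frac_one_tail", "frac_le_0.1_tail",
    "frac_le_0.2_tail", "frac_le_0.5_tail",
    "highest_r_opt_chi_one", "last_r_opt", "n_points",
)


def chi_new(
    g_new: float,
    is_duplicate: bool = False,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Boltzmann mole fraction of a newly re-optimized structure relative
    to the running global minimum; 0 for duplicates, 1 for a new minimum."""
    if is_duplicate:
        return 0.0
    if g_new < 0:
        raise ValueError("g_new must be >= 0 (re-zero against the running minimum)")
    return float(math.exp(-g_new / (GAS_CONSTANT_KCAL * temperature)))


@dataclass
class CompletionTrajectory:
    """Ordered (r_opt, chi_new) points from a partial re-optimization."""

    points: list[tuple[float, float]]
    m: int
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        r = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError("r_opt must be strictly increasing")
        if any(not 0 <= p[1] <= 1 for p in self.points):
            raise ValueError("chi_new out of [0, 1]")

    @property
    def r_opt(self) -> float:
        return self.points[-1][0] if self.points else 0.0


def build_trajectory(
    partial: list[OptimizedResult],
    m: int,
    mol=None,
    duplicate_flags: list[bool] | None = None,
    rmsd_threshold: float = RMSD_DUPLICATE_THRESHOLD,
    temperature: float = DEFAULT_TEMPERATURE,
) -> CompletionTrajectory:
    """Compute the chi_new trajectory of a partial result stream.

    ``partial`` is ordered by re-optimization rank.  Each new structure is
    checked for duplication against all earlier ones -- geometrically via
    :func:`best_rmsd` when ``mol`` is given, or via precomputed
    ``duplicate_flags``.  Its energy gap is measured against the minimum
    energy seen so far, so a structure that sets a new running minimum
    scores chi_new = 1.  Non-converged attempts count toward r_opt but
    contribute chi_new = 0 and do not move the running minimum.
    """
    if len(partial) > m:
        raise ValueError("more results than conformers")
    if duplicate_flags is None and mol is None and len(partial) > 1:
        raise ValueError("need mol for geometric duplicate detection "
                         "or explicit duplicate_flags")
    maps = automorphism_maps(mol) if mol is not None else None
    points: list[tuple[float, float]] = []
    seen_energies: list[float] = []
    seen_coords: list[np.ndarray] = []
    for k, res in enumerate(partial):
        r_opt = (k + 1) / m
        if not res.converged:
            points.append((r_opt, 0.0))
            continue
        if duplicate_flags is not None:
            dup = bool(duplicate_flags[k])
        else:
            dup = any(
                best_rmsd(res.coordinates, c, mol, maps) < rmsd_threshold
                for c in seen_coords)
        running_min = min(seen_energies) if seen_energies else res.g_rel
        g_new = max(res.g_rel - min(running_min, res.g_rel), 0.0)
        points.append((r_opt, chi_new(g_new, dup, temperature)))
        seen_energies.append(res.g_rel)
        if mol is not None:
            seen_coords.append(res.coordinates)
    return CompletionTrajectory(points, m, temperature)


def extract_features(traj: CompletionTrajectory) -> np.ndarray:
    """13-value descriptor of a trajectory (see :data:`FEATURE_NAMES`).

    The "last 40%" window holds the last ceil(0.4 * k) points of a
    k-point trajectory.
    """
    if not traj.points:
        raise ValueError("empty trajectory")
    r = np.array([p[0] for p in traj.points])
    chi = np.array([p[1] for p in traj.points])
    k = len(chi)
    tail = chi[k - math.ceil(0.4 * k):]

    def fracs(v: np.ndarray) -> list[float]:
        return [float(np.mean(v == 0.0)), float(np.mean(v == 1.0)),
                float(np.mean(v <= 0.1)), float(np.mean(v <= 0.2)),
                float(np.mean(v <= 0.5))]

    ones = r[chi == 1.0]
    return np.array(
        fracs(chi) + fracs(tail)
        + [float(ones.max()) if len(ones) else 0.0, float(r[-1]), float(k)])


def assign_label(traj: CompletionTrajectory, p_gmt_true: float) -> str:
    """Training label: "stop" when the trajectory already covers the rank
    at which the DFT global minimum appears (last r_opt >= P_GMT)."""
    return STOP if traj.r_opt >= p_gmt_true - 1e-12 else CONTINUE


@dataclass
class SigmoidCalibration:
    """%Conf(p) = 100 / (1 + exp(-(a p + b))); monotone for a > 0."""

    a: float
    b: float
    mae: float  # mean absolute error of the fit, percentage points

    @property
    def monotone(self) -> bool:
        return self.a > 0

    def __call__(self, p: float) -> float:
        return 100.0 / (1.0 + math.exp(-(self.a * p + self.b)))


def calibrate_confidence(
    p_values: np.ndarray,
    correct: np.ndarray,
    n_bins: int = 10,
) -> SigmoidCalibration:
    """Fit the p_LR -> %Conf sigmoid on validation outcomes.

    ``p_values`` are model stop-probabilities and ``correct`` the binary
    outcome being calibrated against -- by convention the event "stopping
    here is right, the global minimum is already in hand".  Probabilities
    are binned (deciles by default), the outcome fraction per bin
    computed, and the two-parameter sigmoid least-squares fitted to the
    binned points.  Bins are widened when too sparse.  An anti-calibrated
    fit (a < 0) is flagged with a warning.
    """
    p_values = np.asarray(p_values, dtype=float)
    correct = np.asarray(correct, dtype=float)
    if len(np.unique(np.round(p_values, 12))) < 2:
        raise ValueError("need at least two distinct probability values")
    while n_bins >= 2:
        edges = np.linspace(0, 1, n_bins + 1)
        idx = np.clip(np.digitize(p_values, edges[1:-1]), 0, n_bins - 1)
        xs, ys = [], []
        for b in range(n_bins):
            mask = idx == b
            if mask.sum() > 0:
                xs.append(p_values[mask].mean())
                ys.append(100.0 * correct[mask].mean())
        if len(xs) >= 2:
            break
        warnings.warn("degenerate calibration bins; widening")
        n_bins //= 2
    xs, ys = np.asarray(xs), np.asarray(ys)

    def model(p, a, b):
        return 100.0 / (1.0 + np.exp(-(a * p + b)))

    try:
        (a, b), _ = curve_fit(model, xs, ys, p0=(5.0, -2.0), maxfev=20000)
    except RuntimeError:
        a, b = 5.0, -2.0
        warnings.warn("calibration fit did not converge; using initial guess")
    mae = float(np.mean(np.abs(model(xs, a, b) - ys)))
    if a < 0:
        warnings.warn("anti-calibrated confidence fit (a < 0)")
    return SigmoidCalibration(float(a), float(b), mae)


@dataclass
class CompletionModel:
    """Fitted stop/continue classifier with its confidence calibration."""

    clf: LogisticRegression
    calibration: SigmoidCalibration | None = None
    holdout_accuracy: float | None = None
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, features: np.ndarray) -> float:
        """Probability of "stop" for one 13-value descriptor."""
        x = np.asarray(features, dtype=float).reshape(1, -1)
        stop_col = int(np.flatnonzero(self.clf.classes_ == 1)[0])
        return float(self.clf.predict_proba(x)[0, stop_col])

    def to_json(self) -> str:
        payload = {
            "coef": self.clf.coef_.tolist(),
            "intercept": self.clf.intercept_.tolist(),
            "classes": self.clf.classes_.tolist(),
            "calibration": None if self.calibration is None else {
                "a": self.calibration.a, "b": self.calibration.b,
                "mae": self.calibration.mae},
            "holdout_accuracy": self.holdout_accuracy,
            "metadata": self.metadata,
            "feature_names": list(FEATURE_NAMES),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CompletionModel":
        payload = json.loads(text)
        clf = LogisticRegression()
        clf.coef_ = np.asarray(payload["coef"])
        clf.intercept_ = np.asarray(payload["intercept"])
        clf.classes_ = np.asarray(payload["classes"])
        clf.n_features_in_ = clf.coef_.shape[1]
        cal = payload.get("calibration")
        return cls(
            clf=clf,
            calibration=None if cal is None else SigmoidCalibration(
                cal["a"], cal["b"], cal.get("mae", float("nan"))),
            holdout_accuracy=payload.get("holdout_accuracy"),
            metadata=payload.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "CompletionModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def train_model(
    features: np.ndarray,
    labels: list[str] | np.ndarray,
    groups: np.ndarray | None = None,
    seed: int = 0,
    calibrate: bool = True,
) -> CompletionModel:
    """Fit the logistic stop/continue classifier on a descriptor corpus.

    ``groups`` (one id per row, e.g. the molecule of origin) makes the
    held-out split group-aware, mimicking leave-molecule-out validation.
    Held-out predictions also feed the %Conf calibration, so the reported
    accuracy and the calibration are both honest about unseen molecules.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray([1 if lab == STOP else 0 for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training corpus must contain both labels")
    if groups is not None:
        splitter = GroupShuffleSplit(n_splits=1, test_size=0.25,
                                     random_state=seed)
        train_idx, test_idx = next(splitter.split(x, y, groups))
    else:
        train_idx, test_idx = train_test_split(
            np.arange(len(y)), test_size=0.25, random_state=seed, stratify=y)
    holdout_clf = LogisticRegression(max_iter=5000, random_state=seed)
    holdout_clf.fit(x[train_idx], y[train_idx])
    acc = float(holdout_clf.score(x[test_idx], y[test_idx]))

    calibration = None
    if calibrate:
        stop_col = int(np.flatnonzero(holdout_clf.classes_ == 1)[0])
        p = holdout_clf.predict_proba(x[test_idx])[:, stop_col]
        # calibrate against the stop event itself: %Conf is the percentage
        # confidence that re-optimization can terminate, so it must be low
        # when p is low and pass 50% at the decision margin
        try:
            calibration = calibrate_confidence(p, y[test_idx] == 1)
        except ValueError as exc:
            warnings.warn(f"calibration skipped: {exc}")

    clf = LogisticRegression(max_iter=5000, random_state=seed)
    clf.fit(x, y)
    return CompletionModel(
        clf=clf,
        calibration=calibration,
        holdout_accuracy=acc,
        metadata={"n_rows": int(len(y)), "seed": int(seed),
                  "grouped_split": groups is not None},
    )


def predict(
    model: CompletionModel, traj: CompletionTrajectory
) -> tuple[str, float, float]:
    """Classify a partial trajectory.

    Returns ``(label, p_LR, %Conf)``.  The label is "stop" when
    p_LR >= 0.5 (the boundary counts as stop: the labelled event is "the
    global minimum has already been found").  %Conf comes from the fitted
    calibration, or defaults to 100 * max(p, 1 - p) when the model was
    trained uncalibrated.
    """
    p = model.predict_proba(extract_features(traj))
    label = STOP if p >= 0.5 else CONTINUE
    if model.calibration is not None:
        conf = model.calibration(p)
    else:
        warnings.warn("model has no calibration; reporting raw probability")
        conf = 100.0 * max(p, 1.0 - p)
    return label, p, conf
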