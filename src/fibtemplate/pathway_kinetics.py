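"""Aggregation-pathway classification and H_H↔H_T transition kinetics.

Trajectories are partitioned into three classes from two observables:

* **nonaggregated** — the joint ligand-pair SASA stays above 250 Å² in
  every frame (no aggregate ever forms);
* **on-pathway** — aggregated (some frame below the SASA threshold) and
  at least one frame sits within 2.0 Å ligand RMSD of the crystal
  reference (a crystal-like pose is visited);
* **off-pathway** — aggregated but never crystal-like.

Boundary conventions: SASA exactly at the threshold counts as NOT
aggregated ("below 250" / "above 250"); RMSD exactly at the threshold
counts as on-pathway (≤ 2.0 Å).

Configurational kinetics are summarized as lag-1 conditional transition
probabilities between the H_H and H_T states, pooled over trajectories
(these are per-frame probabilities, not physical rates in ns⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import DataError, EmptyInputError, ParameterError
from .io_structures import Frame, Trajectory

__all__ = [
    "ClassificationRule",
    "TransitionStats",
    "PathwayClassifier",
    "TransitionEstimator",
    "compute_sasa",
    "classify_trajectory",
    "classify_ensemble",
    "assign_states",
    "transition_probabilities",
    "truncated_onpathway_fraction",
]


@dataclass
class ClassificationRule:
    """Aggregation (SASA) and crystal-likeness (RMSD) thresholds."""

    sasa_threshold: float = 250.0  # Å²
    rmsd_threshold: float = 2.0  # Å

    def __post_init__(self) -> None:
        if self.sasa_threshold <= 0 or self.rmsd_threshold <= 0:
            raise ParameterError("classification thresholds must be positive")


@dataclass
class TransitionStats:
    """Pooled two-state transition counts and conditional probabilities.

    A probability is ``None`` (undefined) when no transition leaves the
    corresponding state; it is never reported as 0 in that case.
    """

    counts: dict  # keys "HH->HT", "HT->HH", "HH->HH", "HT->HT"
    k_hh_to_ht: float | None
    k_ht_to_hh: float | None
    n_trajectories: int
    lag: int


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------

#: van der Waals radii (Å), Bondi
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
}


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden
    spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def compute_sasa(
    coords: np.ndarray,
    elements: list[str],
    target_indices: np.ndarray | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Rolling-ball SASA (Å²) of the target atoms in the context of all
    supplied coordinates (surrounding bodies occlude).

    Shrake–Rupley with a deterministic golden-spiral point set: a test
    point on an atom's solvent-extended sphere counts as accessible when
    it lies strictly outside every other atom's extended sphere.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise EmptyInputError("compute_sasa on empty coordinates")
    try:
        radii = np.array([VDW_RADII[e.upper()] for e in elements])
    except KeyError as exc:
        raise ParameterError(f"no van der Waals radius for element {exc}") from exc
    extended = radii + probe
    unit = _sphere_points(n_points)
    targets = (
        np.arange(len(coords)) if target_indices is None else np.asarray(target_indices)
    )
    # neighbour prescreen: only atoms whose extended spheres can overlap
    dists = cdist(coords, coords)
    total = 0.0
    for i in targets:
        points = coords[i] + extended[i] * unit
        neighbors = np.flatnonzero(
            (dists[i] < extended[i] + extended) & (np.arange(len(coords)) != i)
        )
        accessible = np.ones(n_points, dtype=bool)
        if len(neighbors):
            d = cdist(points, coords[neighbors])
            accessible = (d > extended[neighbors][None, :]).all(axis=1)
        total += 4.0 * np.pi * extended[i] ** 2 * accessible.mean()
    return float(total)


def frame_ligand_sasa(
    frame: Frame, elements: list[str], probe: float = 1.4, n_points: int = 960
) -> float:
    """Joint SASA of all ligands in a frame, occluded by the fibril
    coordinates when present (fibril atoms assumed carbon-like)."""
    if frame.ligand_coords is None:
        raise DataError("frame has no coordinates")
    lig = np.vstack(frame.ligand_coords)
    all_elements = list(elements) * len(frame.ligand_coords)
    coords = lig
    if frame.fibril_coords is not None:
        coords = np.vstack([lig, frame.fibril_coords])
        all_elements = all_elements + ["C"] * len(frame.fibril_coords)
    return compute_sasa(
        coords, all_elements, target_indices=np.arange(len(lig)),
        probe=probe, n_points=n_points,
    )


# ---------------------------------------------------------------------------
# Pathway classification
# ---------------------------------------------------------------------------


class PathwayClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based on/off/non classifier over trajectories.

    The rule has no free parameters to estimate, so ``fit`` only
    validates and stores the thresholds; ``predict`` maps each
    trajectory to ``"on"``, ``"off"`` or ``"non"``.
    """

    def __init__(self, sasa_threshold: float = 250.0, rmsd_threshold: float = 2.0):
        self.sasa_threshold = sasa_threshold
        self.rmsd_threshold = rmsd_threshold

    @property
    def rule(self) -> ClassificationRule:
        return ClassificationRule(self.sasa_threshold, self.rmsd_threshold)

    def fit(self, X=None, y=None):
        self.rule_ = self.rule
        self.classes_ = np.array(["non", "off", "on"])
        return self

    def predict(self, X) -> np.ndarray:
        rule = getattr(self, "rule_", self.rule)
        return np.array([classify_trajectory(traj, rule) for traj in X])

    def class_fractions(self, X) -> dict:
        labels = self.predict(X)
        n = len(labels)
        if n == 0:
            raise EmptyInputError("no trajectories to classify")
        return {c: float((labels == c).sum() / n) for c in ("on", "off", "non")}


def classify_trajectory(
    trajectory: Trajectory, rule: ClassificationRule | None = None
) -> str:
    """Apply the SASA/RMSD rules to one trajectory."""
    rule = rule or ClassificationRule()
    sasa = trajectory.observable_series("sasa").astype(float)
    # aggregated iff some frame is strictly below the threshold: SASA
    # exactly at the threshold counts as NOT aggregated
    if not (sasa < rule.sasa_threshold).any():
        return "non"
    rmsd = trajectory.observable_series("rmsd").astype(float)
    if (rmsd <= rule.rmsd_threshold).any():
        return "on"
    return "off"


def classify_ensemble(
    trajectories, rule: ClassificationRule | None = None
) -> dict:
    """Per-class fractions over an ensemble (sums to 1)."""
    rule = rule or ClassificationRule()
    clf = PathwayClassifier(rule.sasa_threshold, rule.rmsd_threshold).fit()
    return clf.class_fractions(list(trajectories))


def truncated_onpathway_fraction(
    trajectories, truncate_at_ns: float, rule: ClassificationRule | None = None
) -> float:
    """On-pathway fraction when classification sees only frames with
    time ≤ ``truncate_at_ns`` (the finite-observation-window analysis)."""
    truncated = [traj.truncate(truncate_at_ns) for traj in trajectories]
    return classify_ensemble(truncated, rule)["on"]


# ---------------------------------------------------------------------------
# State assignment and transition statistics
# ---------------------------------------------------------------------------


def assign_states(
    trajectory: Trajectory,
    minima: dict | None = None,
    radius: float = 3.0,
    structure=None,
) -> np.ndarray:
    """Per-frame H_H/H_T state series.

    Frames carrying a precomputed ``state`` observable pass through
    unchanged.  Coordinate frames are assigned to the nearest minimum
    center within ``radius`` (Euclidean in the (d1, d2) plane; ties go
    to H_H); frames outside both radii are ``"unassigned"``.
    """
    first = trajectory.frames[0] if trajectory.frames else None
    if first is not None and first.observables and "state" in first.observables:
        return trajectory.observable_series("state").astype(str)
    if minima is None or structure is None:
        raise DataError(
            "coordinate-mode state assignment needs minima centers and a "
            "ligand structure with feature groups"
        )
    from .landscape import feature_distances

    centers = {s: np.asarray(c, dtype=float) for s, c in minima.items()}
    states = []
    for frame in trajectory.frames:
        d = np.array(feature_distances(frame, structure))
        dist_hh = np.linalg.norm(d - centers["H_H"])
        dist_ht = np.linalg.norm(d - centers["H_T"])
        if dist_hh > radius and dist_ht > radius:
            states.append("unassigned")
        elif dist_hh <= dist_ht:  # tie broken toward H_H
            states.append("H_H")
        else:
            states.append("H_T")
    return np.array(states)


class TransitionEstimator(BaseEstimator):
    """Pooled lag-``lag`` two-state transition-probability estimator.

    ``fit`` takes a list of state series (arrays of ``"H_H"``/``"H_T"``/
    ``"unassigned"``).  Transition pairs whose window contains an
    unassigned frame are skipped; counts are pooled across trajectories
    and row-normalized.

    Attributes (after ``fit``)
    ----------
    counts_ : dict of pooled transition counts
    k_hh_to_ht_, k_ht_to_hh_ : conditional probabilities (None when the
        source state is never left nor revisited)
    stats_ : :class:`TransitionStats`
    """

    def __init__(self, lag: int = 1):
        self.lag = lag

    def fit(self, X, y=None):
        series_list = list(X)
        if not series_list:
            raise EmptyInputError("no state series")
        if self.lag < 1:
            raise ParameterError("lag must be >= 1")
        counts = {"HH->HT": 0, "HT->HH": 0, "HH->HH": 0, "HT->HT": 0}
        for series in series_list:
            s = np.asarray(series, dtype=str)
            if len(s) <= self.lag:
                continue
            assigned = np.isin(s, ("H_H", "H_T"))
            # a pair is valid only when every frame in its window is assigned
            windows = np.lib.stride_tricks.sliding_window_view(
                assigned, self.lag + 1
            )
            valid = windows.all(axis=1)
            a = s[: len(s) - self.lag][valid] == "H_T"
            b = s[self.lag :][valid] == "H_T"
            counts["HH->HH"] += int((~a & ~b).sum())
            counts["HH->HT"] += int((~a & b).sum())
            counts["HT->HH"] += int((a & ~b).sum())
            counts["HT->HT"] += int((a & b).sum())
        from_hh = counts["HH->HT"] + counts["HH->HH"]
        from_ht = counts["HT->HH"] + counts["HT->HT"]
        self.counts_ = counts
        self.k_hh_to_ht_ = counts["HH->HT"] / from_hh if from_hh else None
        self.k_ht_to_hh_ = counts["HT->HH"] / from_ht if from_ht else None
        self.stats_ = TransitionStats(
            counts=counts,
            k_hh_to_ht=self.k_hh_to_ht_,
            k_ht_to_hh=self.k_ht_to_hh_,
            n_trajectories=len(series_list),
            lag=self.lag,
        )
        return self


def transition_probabilities(state_series_list, lag: int = 1) -> TransitionStats:
    """Pooled empirical transition probabilities (thin wrapper over
    :class:`TransitionEstimator`)."""
    return TransitionEstimator(lag=lag).fit(state_series_list).stats_
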