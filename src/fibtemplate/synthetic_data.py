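"""Synthetic inputs emulating the fibril-templated dimer study conditions.

Three kinds of data are generated, matching what each downstream stage
consumes:

* **observable-mode dimer trajectories** — per-frame SASA, ligand RMSD,
  H_H/H_T configurational state and H-bond count.  The state series is a
  lag-1 two-state Markov chain with class-specific transition matrices;
  SASA switches from a free-phase to an aggregated-phase distribution at
  a random aggregation-onset frame; RMSD and H-bond counts follow the
  class definitions (on-pathway trajectories visit a crystal-like pose,
  off-pathway trajectories never do).  Class labels mix as
  12.6% on-pathway / 34.6% off-pathway / 52.8% nonaggregated.
* **coordinate-mode dimer geometries** — two toy-ligand copies placed so
  the head–head and head–tail feature distances (d1, d2) sit at a
  requested free-energy minimum plus isotropic Gaussian noise.
* **oligomer configuration ensembles** — multi-ligand coordinate sets
  drawn from fixed template catalogs whose occupancy weights reproduce
  the solution-phase (diverse) vs fibril-surface (concentrated) cluster
  populations, plus small per-atom jitter and a random global rigid
  transform per configuration.

Distribution *shapes* for SASA and RMSD are stand-ins: only the
thresholds (250 Å², 2.0 Å) and the class definitions are pinned by the
study conditions; free/aggregated SASA and native/non-native RMSD draws
are truncated at those thresholds so class membership is exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

from .errors import ParameterError
from .io_structures import Frame, LigandStructure, Trajectory

__all__ = [
    "SyntheticParams",
    "generate_toy_ligand",
    "generate_observable_trajectory",
    "generate_ensemble",
    "generate_coordinate_dimer",
    "generate_oligomer_configs",
    "CLUSTER_WEIGHTS",
]

TRAJECTORY_LENGTH_NS = 100.0  # every synthetic dimer trajectory spans 100 ns


def _default_minima() -> dict:
    return {
        "solution": {"H_H": (7.0, 5.0), "H_T": (12.0, 11.0)},
        "fibril": {"H_H": (7.0, 5.0), "H_T": (9.0, 14.0)},
    }


@dataclass
class SyntheticParams:
    """Study-condition parameters of the synthetic generator.

    Defaults encode the dimer-formation conditions: the on/off/non class
    mixture, the per-class lag-1 H_H↔H_T transition matrices, the
    per-class H-bond count distributions (means 2.01 and 0.74 exactly),
    SASA/RMSD distributions straddling the 250 Å² and 2.0 Å thresholds,
    and the free-energy-minima centers in the (d1, d2) plane.
    """

    class_mixture: dict = field(
        default_factory=lambda: {"on": 0.126, "off": 0.346, "non": 0.528}
    )
    markov_on: dict = field(
        default_factory=lambda: {"p_HH_to_HT": 0.05, "p_HT_to_HH": 0.39}
    )
    markov_off: dict = field(
        default_factory=lambda: {"p_HH_to_HT": 0.28, "p_HT_to_HH": 0.25}
    )
    hbond_dist_on: dict = field(
        default_factory=lambda: {1: 0.08, 2: 0.83, 3: 0.09}
    )
    hbond_dist_off: dict = field(
        default_factory=lambda: {0: 0.41, 1: 0.45, 2: 0.13, 3: 0.01}
    )
    sasa_aggregated: tuple = (200.0, 20.0)  # (mean Å², sd)
    sasa_free: tuple = (320.0, 30.0)
    rmsd_native: tuple = (1.2, 0.3)  # (mean Å, sd)
    rmsd_nonnative: tuple = (4.5, 1.0)
    sasa_threshold: float = 250.0  # Å²; truncation boundary for the two phases
    rmsd_threshold: float = 2.0  # Å; truncation boundary native vs non-native
    minima: dict = field(default_factory=_default_minima)
    noise_sd: float = 0.5  # Å, per-atom coordinate noise of dimer geometries

    def __post_init__(self) -> None:
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-9:
            raise ParameterError("class_mixture must sum to 1")
        for dist in (self.hbond_dist_on, self.hbond_dist_off):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ParameterError("H-bond count distribution must sum to 1")
        for markov in (self.markov_on, self.markov_off):
            for p in markov.values():
                if not 0.0 <= p <= 1.0:
                    raise ParameterError("transition probabilities must be in [0,1]")


def _hbond_mean(dist: dict) -> float:
    return sum(k * p for k, p in dist.items())


# the default H-bond distributions are constructed to have means 2.01 and
# 0.74 exactly
assert abs(_hbond_mean(SyntheticParams().hbond_dist_on) - 2.01) < 1e-12
assert abs(_hbond_mean(SyntheticParams().hbond_dist_off) - 0.74) < 1e-12


# ---------------------------------------------------------------------------
# Toy ligand
# ---------------------------------------------------------------------------

_RING_RADIUS = 1.4  # Å, aromatic-like ring
_RING_SEPARATION = 7.0  # Å between head and tail ring centroids


def _toy_ligand_coords() -> np.ndarray:
    angles = np.arange(6) * np.pi / 3.0
    ring = np.stack(
        [_RING_RADIUS * np.cos(angles), _RING_RADIUS * np.sin(angles), np.zeros(6)],
        axis=1,
    )
    linker = np.array([[2.8, 0.0, 0.0], [4.2, 0.0, 0.0]])
    ring2 = ring + np.array([_RING_SEPARATION, 0.0, 0.0])
    return np.vstack([ring, linker, ring2])


def generate_toy_ligand(rng: np.random.Generator | int | None = None) -> LigandStructure:
    """A planar 14-heavy-atom two-ring ligand mimic.

    Ring 1 (atoms 0–5) is the head feature group, ring 2 (atoms 8–13)
    the tail; their centroids sit 7 Å apart.  A generator adds a small
    (0.05 Å) reproducible pucker; without one the geometry is exact.
    """
    coords = _toy_ligand_coords()
    if rng is not None:
        rng = np.random.default_rng(rng)
        coords = coords + rng.normal(scale=0.05, size=coords.shape)
    n = len(coords)
    return LigandStructure(
        atom_names=[f"C{i + 1}" for i in range(n)],
        elements=["C"] * n,
        coords=coords,
        head_group=frozenset(range(6)),
        tail_group=frozenset(range(8, 14)),
    )


# ---------------------------------------------------------------------------
# Observable-mode trajectories
# ---------------------------------------------------------------------------


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    low: float = -np.inf,
    high: float = np.inf,
) -> np.ndarray:
    if size == 0:
        return np.empty(0)
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _markov_chain(
    rng: np.random.Generator, n: int, p_hh_to_ht: float, p_ht_to_hh: float
) -> np.ndarray:
    """Lag-1 two-state chain (0 = H_H, 1 = H_T), started from the
    stationary distribution (H_H when the chain is degenerate)."""
    u = rng.uniform(size=n)
    states = np.empty(n, dtype=np.int8)
    denom = p_hh_to_ht + p_ht_to_hh
    pi_hh = 1.0 if denom == 0 else p_ht_to_hh / denom
    s = 0 if u[0] < pi_hh else 1
    states[0] = s
    for t in range(1, n):
        p_next_ht = p_hh_to_ht if s == 0 else 1.0 - p_ht_to_hh
        s = 1 if u[t] < p_next_ht else 0
        states[t] = s
    return states


def _sample_counts(rng: np.random.Generator, dist: dict, size: int) -> np.ndarray:
    counts = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[c] for c in counts], dtype=float)
    return rng.choice(counts, size=size, p=probs)


def sample_hbond_counts(
    label: str,
    n: int,
    params: SyntheticParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n`` H-bond counts from the on- or off-pathway class
    distribution."""
    params = params or SyntheticParams()
    rng = np.random.default_rng(rng)
    if label == "on":
        return _sample_counts(rng, params.hbond_dist_on, n)
    if label == "off":
        return _sample_counts(rng, params.hbond_dist_off, n)
    raise ParameterError(f"no H-bond distribution for class {label!r}")


def generate_observable_trajectory(
    label: str,
    n_frames: int,
    params: SyntheticParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """One observable-mode dimer trajectory of the given class.

    ``label`` is ``"on"``, ``"off"`` or ``"non"``.  For on/off
    trajectories an aggregation-onset frame is drawn uniformly over the
    first half of the trajectory; frames before it carry free-phase SASA
    (> threshold) and frames from it on carry aggregated-phase SASA
    (< threshold).  Nonaggregated trajectories stay in the free phase
    throughout and carry no configurational state.  On-pathway
    trajectories draw crystal-like RMSD (≤ threshold) whenever aggregated
    in the H_H state; off-pathway RMSD is truncated above the threshold
    everywhere.
    """
    params = params or SyntheticParams()
    rng = np.random.default_rng(rng)
    if label not in ("on", "off", "non"):
        raise ParameterError(f"unknown trajectory class {label!r}")
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")

    dt = TRAJECTORY_LENGTH_NS / n_frames
    times = np.arange(n_frames) * dt
    thr_sasa = params.sasa_threshold
    thr_rmsd = params.rmsd_threshold

    if label == "non":
        sasa = _truncated_normal(
            rng, *params.sasa_free, n_frames, low=thr_sasa + 1e-9
        )
        rmsd_series = _truncated_normal(
            rng, *params.rmsd_nonnative, n_frames, low=thr_rmsd + 1e-9
        )
        state = np.full(n_frames, "unassigned")
        hbonds = np.zeros(n_frames, dtype=int)
        onset = None
    else:
        onset = int(rng.integers(0, max(1, n_frames // 2)))
        aggregated = np.arange(n_frames) >= onset
        n_agg = int(aggregated.sum())
        sasa = np.empty(n_frames)
        sasa[~aggregated] = _truncated_normal(
            rng, *params.sasa_free, n_frames - n_agg, low=thr_sasa + 1e-9
        )
        sasa[aggregated] = _truncated_normal(
            rng, *params.sasa_aggregated, n_agg, high=thr_sasa - 1e-9
        )

        markov = params.markov_on if label == "on" else params.markov_off
        chain = _markov_chain(
            rng, n_frames, markov["p_HH_to_HT"], markov["p_HT_to_HH"]
        )
        state = np.where(chain == 0, "H_H", "H_T")

        rmsd_series = _truncated_normal(
            rng, *params.rmsd_nonnative, n_frames, low=thr_rmsd + 1e-9
        )
        if label == "on":
            native_frames = aggregated & (chain == 0)
            if not native_frames.any():
                # degenerate chain never visits H_H while aggregated;
                # anchor the crystal-like visit at the onset frame
                native_frames[onset] = True
            rmsd_series[native_frames] = _truncated_normal(
                rng,
                *params.rmsd_native,
                int(native_frames.sum()),
                high=thr_rmsd,
            )

        dist = params.hbond_dist_on if label == "on" else params.hbond_dist_off
        hbonds = np.zeros(n_frames, dtype=int)
        hbonds[aggregated] = _sample_counts(rng, dist, n_agg)

    frames = [
        Frame(
            time=float(times[i]),
            observables={
                "sasa": float(sasa[i]),
                "rmsd": float(rmsd_series[i]),
                "state": str(state[i]),
                "hbond_count": int(hbonds[i]),
            },
        )
        for i in range(n_frames)
    ]
    return Trajectory(
        frames=frames,
        dt=dt,
        ligand_count=2,
        metadata={
            "label": label,
            "onset_frame": onset,
            "_series": {
                "sasa": sasa,
                "rmsd": rmsd_series,
                "state": state,
                "hbond_count": hbonds,
            },
        },
    )


def generate_ensemble(
    n_traj: int,
    n_frames: int,
    params: SyntheticParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[Trajectory, str]]:
    """An ensemble of observable-mode trajectories with ground-truth labels
    drawn i.i.d. from the class mixture."""
    params = params or SyntheticParams()
    rng = np.random.default_rng(rng)
    if n_traj < 1:
        raise ParameterError("n_traj must be >= 1")
    classes = list(params.class_mixture)
    probs = np.array([params.class_mixture[c] for c in classes])
    labels = rng.choice(classes, size=n_traj, p=probs)
    return [
        (generate_observable_trajectory(label, n_frames, params, rng), label)
        for label in labels
    ]


# ---------------------------------------------------------------------------
# Coordinate-mode dimer geometries
# ---------------------------------------------------------------------------


def _place_second_ligand(
    ligand: LigandStructure, d1: float, d2: float
) -> np.ndarray:
    """Coordinates of a rigid ligand copy whose head centroid sits d1 from
    ligand 1's head centroid and whose tail centroid sits d2 from it."""
    head_idx = sorted(ligand.head_group)
    tail_idx = sorted(ligand.tail_group)
    head_c = ligand.coords[head_idx].mean(axis=0)
    tail_c = ligand.coords[tail_idx].mean(axis=0)
    length = float(np.linalg.norm(tail_c - head_c))
    if not (abs(d1 - d2) <= length <= d1 + d2):
        raise ParameterError(
            f"(d1, d2) = ({d1}, {d2}) unreachable for head–tail separation "
            f"{length:.2f} Å (triangle inequality)"
        )
    # target points in the plane spanned by ex, ey around ligand 1's head
    a = (d1**2 + d2**2 - length**2) / (2.0 * d1)
    b = float(np.sqrt(max(d2**2 - a**2, 0.0)))
    head2 = head_c + np.array([d1, 0.0, 0.0])
    tail2 = head_c + np.array([a, b, 0.0])
    # rigid map of the template onto the (head2, tail2) axis; the spin
    # about that axis is fixed by the minimal rotation between the two
    # axis vectors (deterministic)
    v_template = tail_c - head_c
    v_target = tail2 - head2
    rot, _ = Rotation.align_vectors(v_target[None, :], v_template[None, :])
    return (ligand.coords - head_c) @ rot.as_matrix().T + head2


def generate_coordinate_dimer(
    state: str,
    environment: str,
    n_frames: int,
    params: SyntheticParams | None = None,
    rng: np.random.Generator | int | None = None,
    ligand: LigandStructure | None = None,
) -> Trajectory:
    """Coordinate-mode dimer trajectory fluctuating around one free-energy
    minimum.

    The two toy-ligand copies are placed so the (d1, d2) feature
    distances equal the requested minimum's center; isotropic Gaussian
    noise of sd ``params.noise_sd`` is added per atom per frame
    (``noise_sd = 0`` gives the exact center every frame).
    """
    params = params or SyntheticParams()
    rng = np.random.default_rng(rng)
    if environment not in params.minima:
        raise ParameterError(f"unknown environment {environment!r}")
    if state not in params.minima[environment]:
        raise ParameterError(f"unknown state {state!r}")
    ligand = ligand or generate_toy_ligand()
    d1, d2 = params.minima[environment][state]
    lig1 = ligand.coords
    lig2 = _place_second_ligand(ligand, d1, d2)

    dt = TRAJECTORY_LENGTH_NS / n_frames
    frames = []
    for i in range(n_frames):
        noise1 = (
            rng.normal(scale=params.noise_sd, size=lig1.shape)
            if params.noise_sd > 0
            else 0.0
        )
        noise2 = (
            rng.normal(scale=params.noise_sd, size=lig2.shape)
            if params.noise_sd > 0
            else 0.0
        )
        frames.append(
            Frame(time=i * dt, ligand_coords=[lig1 + noise1, lig2 + noise2])
        )
    return Trajectory(
        frames=frames,
        dt=dt,
        ligand_count=2,
        metadata={"state": state, "environment": environment},
    )


# ---------------------------------------------------------------------------
# Oligomer configuration ensembles
# ---------------------------------------------------------------------------


def _pentamer_solution_weights() -> list[float]:
    # top cluster pinned at 6.7%; the remaining 93.3% declines linearly
    # from 6.6% over 19 further templates
    d = (19 * 6.6 - 93.3) / 171.0
    rest = [6.6 - d * k for k in range(19)]
    return [6.7] + rest


#: occupancy percentages of the configuration-template catalogs; the
#: leading entries are pinned to the reported cluster populations, the
#: remainder declines below the last pinned value and sums to 100
CLUSTER_WEIGHTS: dict = {
    ("solution", 2): [21.3, 20.3, 13.0, 10.0, 8.4, 7.0, 6.0, 5.0, 4.5, 4.5],
    ("solution", 3): [12.5, 12.1, 9.9, 9.8, 9.7, 9.6, 9.5, 9.3, 9.0, 8.6],
    ("solution", 4): [11.7, 11.0, 10.6, 10.2, 10.0, 9.8, 9.6, 9.3, 9.0, 8.8],
    ("solution", 5): _pentamer_solution_weights(),
    ("fibril", 2): [41.3, 20.0, 19.0, 7.0, 5.0, 4.0, 3.7],
    ("fibril", 3): [96.6, 2.0, 1.4],
    ("fibril", 4): [100.0],
    ("fibril", 5): [100.0],
}

for _key, _w in CLUSTER_WEIGHTS.items():
    assert abs(sum(_w) - 100.0) < 1e-9, _key

_TEMPLATE_ZONE_RADIUS = 150.0  # Å from ligand 1 to each template zone
_STACK_SPACING = 8.0  # Å between extra ligands within one template
_JITTER_MAX = 0.5  # Å, per-atom displacement bound

# Template geometry vs the 40 Å flat cut: zones sit on a Fibonacci sphere
# so any two templates are >= ~40 degrees apart (inter-template all-ligand
# RMSD > 70 Å), while the per-atom jitter bound keeps the alignment-noise
# scatter of a zone well under the threshold (the first-ligand alignment
# amplifies jitter by the zone lever arm, which sets both bounds).


def _fibonacci_directions(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _template_configs(size: int, n_templates: int) -> list[np.ndarray]:
    """Fixed template catalog: ligand 1 at the canonical pose, the other
    ligands stacked in a template-specific zone on a 150 Å sphere with
    template-specific orientations, so inter-template all-ligand RMSD is
    far above the clustering threshold."""
    base = _toy_ligand_coords()
    centroid = base.mean(axis=0)
    directions = _fibonacci_directions(max(n_templates, 2))
    templates = []
    for k in range(n_templates):
        zone = _TEMPLATE_ZONE_RADIUS * directions[k]
        ligands = [base.copy()]
        for j in range(1, size):
            rot = Rotation.from_euler(
                "xyz", [0.9 * k + 0.3 * j, 0.7 * k + 0.1, 1.1 * j]
            ).as_matrix()
            placed = (base - centroid) @ rot.T + centroid
            placed = placed + zone + np.array([0.0, 0.0, _STACK_SPACING * (j - 1)])
            ligands.append(placed)
        templates.append(np.stack(ligands))
    return templates


def _bounded_jitter(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    """Per-atom displacement with magnitude uniform in [0, _JITTER_MAX)."""
    n_atoms = int(np.prod(shape[:-1]))
    directions = rng.normal(size=(n_atoms, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    magnitudes = rng.uniform(0.0, _JITTER_MAX, size=(n_atoms, 1))
    return (directions * magnitudes).reshape(shape)


def generate_oligomer_configs(
    mode: str,
    size: int,
    n: int,
    params: SyntheticParams | None = None,
    rng: np.random.Generator | int | None = None,
    return_labels: bool = False,
):
    """Multi-ligand configuration ensemble for clustering tests.

    Draws templates with the catalog occupancy weights for
    (``mode``, ``size``), adds bounded per-atom jitter, and applies a
    random global rigid transform per configuration (removed again by
    alignment to the first ligand downstream).
    """
    if size not in (2, 3, 4, 5):
        raise ParameterError("oligomer size must be between 2 and 5")
    if (mode, size) not in CLUSTER_WEIGHTS:
        raise ParameterError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(rng)
    weights = np.array(CLUSTER_WEIGHTS[(mode, size)]) / 100.0
    templates = _template_configs(size, len(weights))
    choices = rng.choice(len(weights), size=n, p=weights)
    configs = []
    for label in choices:
        config = templates[label] + _bounded_jitter(rng, templates[label].shape)
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.uniform(-20.0, 20.0, size=3)
        center = config.reshape(-1, 3).mean(axis=0)
        config = (config - center) @ rot.T + center + shift
        configs.append(config)
    if return_labels:
        return configs, choices
    return configs
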