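"""Random initial-pose library for the second ligand of a dimer.

Rejection sampling builds a library of spatially diverse, clash-free
placements of a copy of the reference ligand:

1. draw a random rotation and rotate the copy about its center of mass;
2. translate the center of mass to a point uniformly distributed over
   the 10–20 Å spherical shell around the reference ligand's center of
   mass (uniform direction, radius uniform over shell *volume*);
3. reject the candidate if any heavy atom comes closer than the clash
   cutoff (default 2.0 Å, strict less-than) to the reference ligand or
   to the fibril surface;
4. repeat until the requested number of poses (default 1000) is
   accepted.

Two rotation-sampling modes are offered: ``euler`` draws three Euler
angles independently uniform on their ranges (z-y-z convention,
α, γ ∈ [0, 2π), β ∈ [0, π]), which is *not* uniform on SO(3) but is the
conventional naive scheme; ``uniform`` samples uniformly on the rotation
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import InfeasibleGeometryError, ParameterError
from .io_structures import LigandStructure, center_of_mass

__all__ = [
    "PoseLibrary",
    "random_rotation",
    "random_translation",
    "detect_clash",
    "generate_pose_library",
]


@dataclass
class PoseLibrary:
    """Accepted poses (coordinate arrays, Å) plus sampling provenance."""

    poses: list[np.ndarray]
    seed: int | None
    attempts: int
    params: dict = field(default_factory=dict)

    @property
    def n_poses(self) -> int:
        return len(self.poses)


def random_rotation(rng: np.random.Generator, mode: str = "euler") -> np.ndarray:
    """A random proper rotation matrix (orthogonal, det +1)."""
    if mode == "euler":
        alpha = rng.uniform(0.0, 2.0 * np.pi)
        beta = rng.uniform(0.0, np.pi)
        gamma = rng.uniform(0.0, 2.0 * np.pi)
        return Rotation.from_euler("zyz", [alpha, beta, gamma]).as_matrix()
    if mode == "uniform":
        return Rotation.random(random_state=rng).as_matrix()
    raise ParameterError(f"unknown rotation mode {mode!r}")


def random_translation(
    rng: np.random.Generator, radius_min: float = 10.0, radius_max: float = 20.0
) -> np.ndarray:
    """A displacement uniform over the [radius_min, radius_max] spherical
    shell volume (Å): direction uniform on the sphere, radius from the
    shell-volume CDF r³ scaling."""
    if not (0 < radius_min <= radius_max):
        raise ParameterError(
            f"require 0 < radius_min <= radius_max, got {radius_min}, {radius_max}"
        )
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    u = rng.uniform()
    radius = (radius_min**3 + u * (radius_max**3 - radius_min**3)) ** (1.0 / 3.0)
    return radius * direction


def detect_clash(
    candidate: np.ndarray, others: list[np.ndarray], cutoff: float = 2.0
) -> bool:
    """True iff any heavy-atom pair between the candidate and any other
    body is closer than ``cutoff`` (strict ``<``: a contact at exactly
    the cutoff is not a clash)."""
    candidate = np.asarray(candidate, dtype=float)
    tree = cKDTree(candidate)
    for other in others:
        other = np.asarray(other, dtype=float)
        if other.size == 0:
            continue
        d, _ = tree.query(other, k=1)
        if (d < cutoff).any():
            return True
    return False


# rejection-rate watchdog: error out when fewer than _MIN_RATE of the
# last _WINDOW attempts were accepted
_WINDOW = 50_000
_MIN_RATE = 1e-4


def generate_pose_library(
    reference: LigandStructure,
    fibril_coords: np.ndarray | None = None,
    n: int = 1000,
    rng: np.random.Generator | int | None = None,
    radius_min: float = 10.0,
    radius_max: float = 20.0,
    clash_cutoff: float = 2.0,
    rotation_mode: str = "euler",
) -> PoseLibrary:
    """Generate exactly ``n`` clash-free poses of a copy of ``reference``.

    Clashes are checked on heavy atoms against the reference ligand and,
    when given, the fibril coordinate set.  Deterministic for a fixed
    seed/generator.
    """
    if n < 1:
        raise ParameterError(f"pose count must be >= 1, got {n}")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)

    heavy = reference.heavy_mask
    ref_heavy = reference.coords[heavy]
    ref_com = center_of_mass(reference.coords)
    bodies = [ref_heavy]
    if fibril_coords is not None and len(fibril_coords):
        bodies.append(np.asarray(fibril_coords, dtype=float))

    poses: list[np.ndarray] = []
    attempts = 0
    window_attempts = 0
    window_accepts = 0
    while len(poses) < n:
        attempts += 1
        window_attempts += 1
        rot = random_rotation(rng, rotation_mode)
        shift = random_translation(rng, radius_min, radius_max)
        candidate = (reference.coords - ref_com) @ rot.T + ref_com + shift
        if clash_cutoff <= 0 or not detect_clash(
            candidate[heavy], bodies, cutoff=clash_cutoff
        ):
            poses.append(candidate)
            window_accepts += 1
        if window_attempts >= _WINDOW:
            if window_accepts / window_attempts < _MIN_RATE:
                raise InfeasibleGeometryError(
                    f"pose acceptance rate {window_accepts / window_attempts:.2e} "
                    f"over the last {window_attempts} attempts "
                    f"({len(poses)}/{n} poses found; cutoff={clash_cutoff} Å, "
                    f"shell=[{radius_min}, {radius_max}] Å)"
                )
            window_attempts = 0
            window_accepts = 0

    return PoseLibrary(
        poses=poses,
        seed=seed,
        attempts=attempts,
        params={
            "radius_min": radius_min,
            "radius_max": radius_max,
            "clash_cutoff": clash_cutoff,
            "rotation_mode": rotation_mode,
        },
    )
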