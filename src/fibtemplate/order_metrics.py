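"""Structural order metrics for ligand aggregates.

Two metrics quantify how aggregated and how crystal-like a multi-ligand
frame is:

* **native contacts** — for each equivalent inter-ligand atom pair
  (atom i of ligand 1 vs atom i of ligand 2) the crystal reference
  distance is stored; a contact counts as formed when the current
  distance is within ±0.2 nm of the reference, and the count is
  normalized by the number of pairs so the metric lies in [0, 1].
* **coordination number** — the smooth contact count
  Σ_i Σ_j s(r_ij) over inter-ligand atom pairs, with the rational
  switching function s(r) = (1 − x^n)/(1 − x^m), x = (r − d0)/r0,
  using n=6, m=8, d0=0 and r0=0.45 nm.

For oligomers (trimer and larger) only the strongest size−1 pairwise
interactions enter: native contacts are averaged over them (keeping the
metric in [0, 1]) while coordination numbers are summed (larger
aggregates legitimately score higher).

Coordinates enter in Å and are converted to nm at the formula boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from .errors import EmptyInputError, ParameterError, StructureMismatchError

__all__ = [
    "SwitchingParams",
    "NativeContactSpec",
    "switching_value",
    "coordination_number",
    "native_contacts",
    "oligomer_order",
]

ANGSTROM_TO_NM = 0.1

# x within this distance of 1 is evaluated at the removable-singularity
# limit n/m instead of the 0/0 expression
_SINGULARITY_TOL = 1e-9


@dataclass
class SwitchingParams:
    """Rational switching function parameters (distances in nm)."""

    n: int = 6
    m: int = 8
    d0: float = 0.0
    r0: float = 0.45

    def __post_init__(self) -> None:
        if not (self.m > self.n > 0):
            raise ParameterError(f"require m > n > 0, got n={self.n}, m={self.m}")
        if self.r0 <= 0:
            raise ParameterError(f"require r0 > 0, got {self.r0}")


def switching_value(r_ij, params: SwitchingParams | None = None):
    """Evaluate s(r) = (1 − x^n)/(1 − x^m), x = (r − d0)/r0, with r in nm.

    The removable singularity at x = 1 is handled analytically (limit
    n/m).  Accepts scalars or arrays; monotone decreasing in r.
    """
    params = params or SwitchingParams()
    r = np.asarray(r_ij, dtype=float)
    if (r < 0).any():
        raise ParameterError("negative distance passed to switching function")
    x = (r - params.d0) / params.r0
    near_one = np.abs(x - 1.0) < _SINGULARITY_TOL
    x_safe = np.where(near_one, 0.0, x)
    with np.errstate(over="ignore"):
        value = (1.0 - x_safe**params.n) / (1.0 - x_safe**params.m)
    value = np.where(near_one, params.n / params.m, value)
    return float(value) if np.isscalar(r_ij) else value


def coordination_number(
    lig_a_coords: np.ndarray,
    lig_b_coords: np.ndarray,
    params: SwitchingParams | None = None,
    heavy_mask_a: np.ndarray | None = None,
    heavy_mask_b: np.ndarray | None = None,
) -> float:
    """Smooth inter-ligand contact count Σ_i Σ_j s(r_ij).

    Coordinates in Å; the hydrogen-free default selection follows the
    convention for contact collective variables.
    """
    a = np.asarray(lig_a_coords, dtype=float)
    b = np.asarray(lig_b_coords, dtype=float)
    if heavy_mask_a is not None:
        a = a[np.asarray(heavy_mask_a, dtype=bool)]
    if heavy_mask_b is not None:
        b = b[np.asarray(heavy_mask_b, dtype=bool)]
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("coordination_number over an empty selection")
    r_nm = cdist(a, b) * ANGSTROM_TO_NM
    return float(np.sum(switching_value(r_nm, params)))


@dataclass
class NativeContactSpec:
    """Reference distances for the equivalent-atom-pair contact map.

    ``reference_distances`` holds, per atom index i, the crystal distance
    (nm) between atom i of ligand 1 and atom i of ligand 2.
    """

    reference_distances: np.ndarray  # (n_pairs,) nm
    tolerance: float = 0.2  # nm
    pair_indices: np.ndarray = field(default=None)  # atom indices used

    def __post_init__(self) -> None:
        self.reference_distances = np.asarray(self.reference_distances, dtype=float)
        if self.tolerance <= 0:
            raise ParameterError("tolerance must be positive")
        if self.pair_indices is None:
            self.pair_indices = np.arange(len(self.reference_distances))
        else:
            self.pair_indices = np.asarray(self.pair_indices, dtype=int)
        if len(self.pair_indices) != len(self.reference_distances):
            raise StructureMismatchError(
                "pair_indices and reference_distances length mismatch"
            )

    @classmethod
    def from_reference(
        cls,
        lig1_coords: np.ndarray,
        lig2_coords: np.ndarray,
        heavy_mask: np.ndarray | None = None,
        tolerance: float = 0.2,
    ) -> "NativeContactSpec":
        """Build the i↔i reference map from a crystal dimer geometry (Å)."""
        a = np.asarray(lig1_coords, dtype=float)
        b = np.asarray(lig2_coords, dtype=float)
        if a.shape != b.shape:
            raise StructureMismatchError("reference ligand shapes differ")
        idx = (
            np.arange(len(a))
            if heavy_mask is None
            else np.flatnonzero(np.asarray(heavy_mask, dtype=bool))
        )
        dists = np.linalg.norm(a[idx] - b[idx], axis=1) * ANGSTROM_TO_NM
        return cls(reference_distances=dists, tolerance=tolerance, pair_indices=idx)


def native_contacts(
    lig1_coords: np.ndarray,
    lig2_coords: np.ndarray,
    spec: NativeContactSpec,
) -> float:
    """Fraction of equivalent atom pairs within ±tolerance of the crystal
    reference distance (closed interval), normalized to a maximum of 1."""
    a = np.asarray(lig1_coords, dtype=float)[spec.pair_indices]
    b = np.asarray(lig2_coords, dtype=float)[spec.pair_indices]
    current_nm = np.linalg.norm(a - b, axis=1) * ANGSTROM_TO_NM
    formed = np.abs(current_nm - spec.reference_distances) <= spec.tolerance
    return float(formed.sum() / len(spec.reference_distances))


def oligomer_order(
    ligand_coords: list[np.ndarray],
    spec: NativeContactSpec,
    params: SwitchingParams | None = None,
    heavy_mask: np.ndarray | None = None,
) -> dict:
    """Order metrics for an oligomer frame of 2–5 ligands.

    All ligand pairs are evaluated; the top ``size − 1`` native-contact
    values are averaged (a trimer contains two key interactions, etc.)
    and the top ``size − 1`` coordination numbers are summed.
    """
    size = len(ligand_coords)
    if size < 2:
        raise ParameterError("oligomer_order needs at least two ligands")
    native_vals, coord_vals = [], []
    for i, j in combinations(range(size), 2):
        native_vals.append(native_contacts(ligand_coords[i], ligand_coords[j], spec))
        coord_vals.append(
            coordination_number(
                ligand_coords[i],
                ligand_coords[j],
                params,
                heavy_mask_a=heavy_mask,
                heavy_mask_b=heavy_mask,
            )
        )
    k = size - 1
    top_native = sorted(native_vals, reverse=True)[:k]
    top_coord = sorted(coord_vals, reverse=True)[:k]
    return {
        "native": float(np.mean(top_native)),
        "coordination": float(np.sum(top_coord)),
    }
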