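"""Two-dimensional free-energy surface over inter-ligand feature distances.

The reaction coordinates are d1, the distance between the head-group
centroids of the two ligands, and d2, the distance between ligand 1's
head centroid and ligand 2's tail centroid.  The joint distribution
P(d1, d2) is histogrammed and Boltzmann-inverted,

    ΔG(d1, d2) = −RT ln[ P(d1, d2) / P0 ],

with R = 1.987×10⁻³ kcal/(mol·K) and P0 the highest observed bin
probability, so the modal bin sits at ΔG = 0 and every occupied bin has
ΔG ≥ 0.  Empty bins are *unobserved* (no value), not infinitely high;
they are excluded from the minima search to avoid fake barriers at the
data boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ConfigError, EmptyInputError
from .io_structures import Frame, LigandStructure, Trajectory

__all__ = [
    "GAS_CONSTANT_KCAL",
    "FreeEnergySurface",
    "FreeEnergyLandscape",
    "feature_distances",
    "trajectory_feature_distances",
    "free_energy_surface",
    "locate_minima",
]

GAS_CONSTANT_KCAL = 1.987e-3  # kcal/(mol·K)


def feature_distances(
    frame: Frame | list[np.ndarray], structure: LigandStructure
) -> tuple[float, float]:
    """(d1, d2) in Å for a two-ligand frame.

    d1 = |head centroid(ligand 1) − head centroid(ligand 2)|;
    d2 = |head centroid(ligand 1) − tail centroid(ligand 2)|.
    """
    if not structure.head_group or not structure.tail_group:
        raise ConfigError(
            "head_group/tail_group must be set on the ligand structure "
            "before computing feature distances"
        )
    coords = frame.ligand_coords if isinstance(frame, Frame) else frame
    if coords is None or len(coords) < 2:
        raise EmptyInputError("feature_distances needs a two-ligand frame")
    head_idx = sorted(structure.head_group)
    tail_idx = sorted(structure.tail_group)
    head1 = np.asarray(coords[0])[head_idx].mean(axis=0)
    head2 = np.asarray(coords[1])[head_idx].mean(axis=0)
    tail2 = np.asarray(coords[1])[tail_idx].mean(axis=0)
    d1 = float(np.linalg.norm(head1 - head2))
    d2 = float(np.linalg.norm(head1 - tail2))
    return d1, d2


def trajectory_feature_distances(
    trajectory: Trajectory, structure: LigandStructure
) -> np.ndarray:
    """(n_frames, 2) array of (d1, d2) samples from a coordinate-mode
    trajectory."""
    return np.array(
        [feature_distances(f, structure) for f in trajectory.frames]
    )


@dataclass
class FreeEnergySurface:
    """Binned 2D probability and ΔG over (d1, d2), with located minima.

    ``delta_g`` is NaN on unobserved bins; ``occupied`` marks bins with
    at least one sample.  ``minima`` is a list of
    ``(d1_center, d2_center, ΔG)`` sorted by increasing ΔG.
    """

    d1_edges: np.ndarray
    d2_edges: np.ndarray
    probability: np.ndarray  # (n_d1_bins, n_d2_bins), sums to 1
    delta_g: np.ndarray  # kcal/mol, NaN where unobserved
    occupied: np.ndarray  # boolean
    temperature: float
    minima: list = None

    @property
    def d1_centers(self) -> np.ndarray:
        return 0.5 * (self.d1_edges[:-1] + self.d1_edges[1:])

    @property
    def d2_centers(self) -> np.ndarray:
        return 0.5 * (self.d2_edges[:-1] + self.d2_edges[1:])


class FreeEnergyLandscape(BaseEstimator):
    """Boltzmann-inversion landscape estimator.

    Parameters
    ----------
    bin_width : float
        Histogram bin width in Å along both coordinates.
    temperature : float
        Temperature in K for the inversion.
    neighborhood : int
        Chebyshev radius (in bins) used by the minima search.

    Attributes (after ``fit``)
    ----------
    surface_ : :class:`FreeEnergySurface`
    minima_ : located minima, ``(d1, d2, ΔG)`` sorted by ΔG
    """

    def __init__(
        self,
        bin_width: float = 0.5,
        temperature: float = 300.0,
        neighborhood: int = 1,
    ):
        self.bin_width = bin_width
        self.temperature = temperature
        self.neighborhood = neighborhood

    def fit(self, X, y=None):
        samples = np.asarray(X, dtype=float)
        if samples.size == 0:
            raise EmptyInputError("no (d1, d2) samples")
        if samples.ndim != 2 or samples.shape[1] != 2:
            raise EmptyInputError("samples must be an (n, 2) array of (d1, d2)")
        self.surface_ = _build_surface(samples, self.bin_width, self.temperature)
        self.minima_ = locate_minima(self.surface_, self.neighborhood)
        self.surface_.minima = self.minima_
        return self


def _build_surface(
    samples: np.ndarray, bin_width: float, temperature: float
) -> FreeEnergySurface:
    def edges(values: np.ndarray) -> np.ndarray:
        lo = np.floor(values.min() / bin_width) * bin_width
        hi = np.ceil(values.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        return np.arange(lo, hi + 0.5 * bin_width, bin_width)

    d1_edges = edges(samples[:, 0])
    d2_edges = edges(samples[:, 1])
    counts, _, _ = np.histogram2d(
        samples[:, 0], samples[:, 1], bins=(d1_edges, d2_edges)
    )
    probability = counts / counts.sum()
    occupied = counts > 0
    p0 = probability.max()
    delta_g = np.full_like(probability, np.nan)
    rt = GAS_CONSTANT_KCAL * temperature
    g = -rt * np.log(probability[occupied] / p0)
    g[g == 0] = 0.0  # normalize -0.0 at the modal bin
    delta_g[occupied] = g
    return FreeEnergySurface(
        d1_edges=d1_edges,
        d2_edges=d2_edges,
        probability=probability,
        delta_g=delta_g,
        occupied=occupied,
        temperature=temperature,
    )


def free_energy_surface(
    samples: np.ndarray, bin_width: float = 0.5, temperature: float = 300.0
) -> FreeEnergySurface:
    """Histogram (d1, d2) samples and Boltzmann-invert (thin wrapper over
    :class:`FreeEnergyLandscape`)."""
    est = FreeEnergyLandscape(bin_width=bin_width, temperature=temperature)
    return est.fit(samples).surface_


def locate_minima(surface: FreeEnergySurface, neighborhood: int = 1) -> list:
    """Occupied bins whose ΔG is strictly below every occupied neighbour
    within the Chebyshev ``neighborhood`` radius, sorted by ΔG."""
    minima = []
    n1, n2 = surface.delta_g.shape
    d1c, d2c = surface.d1_centers, surface.d2_centers
    for i in range(n1):
        for j in range(n2):
            if not surface.occupied[i, j]:
                continue
            g = surface.delta_g[i, j]
            is_min = True
            for di in range(-neighborhood, neighborhood + 1):
                for dj in range(-neighborhood, neighborhood + 1):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < n1 and 0 <= jj < n2 and surface.occupied[ii, jj]:
                        if surface.delta_g[ii, jj] <= g:
                            is_min = False
                            break
                if not is_min:
                    break
            if is_min:
                minima.append((float(d1c[i]), float(d2c[j]), float(g)))
    minima.sort(key=lambda m: m[2])
    return minima
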