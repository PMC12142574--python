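"""Geometric hydrogen-bond detection and per-class count statistics.

A hydrogen bond is detected with a conventional geometric criterion:
donor–acceptor distance ≤ 3.5 Å and D–H···A angle ≥ 135° (both bounds
inclusive); hydrogens are located by proximity to their donor heavy
atom.  Observable-mode trajectories, whose frames already carry an
``hbond_count``, bypass the geometry entirely — the count series passes
through — so distribution statistics are testable without a protein
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, EmptyInputError, ParameterError
from .io_structures import Frame, Trajectory
from .pathway_kinetics import ClassificationRule

__all__ = [
    "HBondCriterion",
    "detect_hbonds",
    "protein_ligand_hbond_counts",
    "hbond_distribution",
    "donor_acceptor_frequency",
]

_MAX_DH_BOND = 1.25  # Å; a hydrogen within this distance belongs to the donor


@dataclass
class HBondCriterion:
    """Distance/angle cutoffs and the donor/acceptor atom selections.

    ``donors`` and ``acceptors`` are index arrays into the frame's
    combined coordinate array.
    """

    da_cutoff: float = 3.5  # Å
    dha_angle_min: float = 135.0  # degrees
    donors: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    acceptors: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0:
            raise ParameterError("da_cutoff must be positive")
        if not (0 < self.dha_angle_min <= 180):
            raise ParameterError("dha_angle_min must be in (0, 180]")
        self.donors = np.asarray(self.donors, dtype=int)
        self.acceptors = np.asarray(self.acceptors, dtype=int)


def _find_hydrogen(coords: np.ndarray, elements, donor: int) -> int | None:
    hydrogens = [
        i
        for i, e in enumerate(elements)
        if e.upper() == "H"
        and np.linalg.norm(coords[i] - coords[donor]) <= _MAX_DH_BOND
    ]
    if not hydrogens:
        return None
    dists = [np.linalg.norm(coords[i] - coords[donor]) for i in hydrogens]
    return hydrogens[int(np.argmin(dists))]


def detect_hbonds(
    coords: np.ndarray,
    elements,
    criterion: HBondCriterion,
) -> list[tuple[int, int, int]]:
    """Hydrogen bonds in one frame as (donor, hydrogen, acceptor) triples.

    A pair is reported iff the donor–acceptor distance is ≤ the cutoff
    and the D–H···A angle (at the hydrogen) is ≥ the minimum, both
    inclusive.  Donors without an attached hydrogen are skipped with a
    warning.
    """
    coords = np.asarray(coords, dtype=float)
    bonds = []
    for donor in criterion.donors:
        hydrogen = _find_hydrogen(coords, elements, int(donor))
        if hydrogen is None:
            warnings.warn(
                f"donor atom {donor} has no attached hydrogen; skipped",
                stacklevel=2,
            )
            continue
        for acceptor in criterion.acceptors:
            if acceptor == donor or acceptor == hydrogen:
                continue
            d_da = np.linalg.norm(coords[int(acceptor)] - coords[donor])
            if d_da > criterion.da_cutoff:
                continue
            v_d = coords[donor] - coords[hydrogen]
            v_a = coords[int(acceptor)] - coords[hydrogen]
            cos_angle = np.dot(v_d, v_a) / (
                np.linalg.norm(v_d) * np.linalg.norm(v_a)
            )
            angle = np.degrees(np.arccos(np.clip(cos_angle, -1.0, 1.0)))
            if angle >= criterion.dha_angle_min:
                bonds.append((int(donor), int(hydrogen), int(acceptor)))
    return bonds


def _frame_cross_bond_count(
    frame: Frame, elements, criterion: HBondCriterion, ligand_mask: np.ndarray
) -> int:
    """Protein↔ligand bonds in a coordinate frame (same-body bonds are
    excluded via the ligand mask)."""
    if frame.ligand_coords is None:
        raise DataError("frame has neither hbond_count observable nor coordinates")
    lig = np.vstack(frame.ligand_coords)
    coords = (
        np.vstack([lig, frame.fibril_coords])
        if frame.fibril_coords is not None
        else lig
    )
    if frame.fibril_coords is None:
        return 0  # no protein present, no protein-ligand bonds
    bonds = detect_hbonds(coords, elements, criterion)
    count = 0
    for donor, _, acceptor in bonds:
        if ligand_mask[donor] != ligand_mask[acceptor]:
            count += 1
    return count


def protein_ligand_hbond_counts(
    trajectory: Trajectory,
    criterion: HBondCriterion | None = None,
    elements=None,
    aggregated_only: bool = True,
    rule: ClassificationRule | None = None,
) -> np.ndarray:
    """Per-frame protein↔ligand H-bond counts.

    Observable-mode frames pass their ``hbond_count`` through unchanged.
    With ``aggregated_only`` only frames meeting the aggregation SASA
    criterion (SASA below threshold) contribute.
    """
    rule = rule or ClassificationRule()
    first = trajectory.frames[0] if trajectory.frames else None
    if first is not None and first.observables and "hbond_count" in first.observables:
        counts = trajectory.observable_series("hbond_count").astype(int)
        if aggregated_only:
            sasa = trajectory.observable_series("sasa").astype(float)
            return counts[sasa < rule.sasa_threshold]
        return counts
    if criterion is None or elements is None:
        raise DataError(
            "coordinate-mode H-bond counting needs a criterion and element list"
        )
    counts = []
    for frame in trajectory.frames:
        n_lig_atoms = sum(len(c) for c in frame.ligand_coords)
        n_total = n_lig_atoms + (
            len(frame.fibril_coords) if frame.fibril_coords is not None else 0
        )
        ligand_mask = np.zeros(n_total, dtype=bool)
        ligand_mask[:n_lig_atoms] = True
        counts.append(_frame_cross_bond_count(frame, elements, criterion, ligand_mask))
    return np.asarray(counts, dtype=int)


def hbond_distribution(count_series_list) -> dict:
    """Normalized histogram and mean over pooled per-frame H-bond counts.

    Returns ``{"histogram": {count: fraction}, "mean": float, "n": int}``;
    the mean equals the histogram-weighted mean exactly.
    """
    pooled = np.concatenate([np.asarray(c, dtype=int) for c in count_series_list])
    if pooled.size == 0:
        raise EmptyInputError("no H-bond counts")
    values, counts = np.unique(pooled, return_counts=True)
    fractions = counts / pooled.size
    return {
        "histogram": {int(v): float(f) for v, f in zip(values, fractions)},
        "mean": float(pooled.mean()),
        "n": int(pooled.size),
    }


def donor_acceptor_frequency(
    trajectory: Trajectory, criterion: HBondCriterion, elements
) -> list[tuple[tuple[int, int], float]]:
    """Per (donor, acceptor) pair: fraction of frames where bonded,
    sorted descending (coordinate-mode trajectories only)."""
    n_frames = trajectory.n_frames
    if n_frames == 0:
        return []
    pair_frames: dict[tuple[int, int], int] = {}
    for frame in trajectory.frames:
        if frame.ligand_coords is None:
            raise DataError("donor_acceptor_frequency needs coordinate frames")
        lig = np.vstack(frame.ligand_coords)
        coords = (
            np.vstack([lig, frame.fibril_coords])
            if frame.fibril_coords is not None
            else lig
        )
        bonds = detect_hbonds(coords, elements, criterion)
        for donor, acceptor in set((d, a) for d, _, a in bonds):
            pair_frames[(donor, acceptor)] = pair_frames.get((donor, acceptor), 0) + 1
    table = [
        (pair, count / n_frames) for pair, count in pair_frames.items()
    ]
    table.sort(key=lambda item: (-item[1], item[0]))
    return table
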