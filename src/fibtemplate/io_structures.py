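"""Structure and trajectory data model, PDB readers/writers, and the
geometry primitives (center of mass, Kabsch RMSD) shared by every stage.

Coordinates are Ångström throughout the package; unit conversions (e.g.
Å → nm inside the coordination-number switching function) happen at the
formula boundary of the operation that needs them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .errors import (
    DataError,
    EmptyInputError,
    FormatError,
    StructureMismatchError,
)

__all__ = [
    "LigandStructure",
    "Frame",
    "Trajectory",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_observable_csv",
    "write_observable_csv",
    "center_of_mass",
    "kabsch_rotation",
    "superpose",
    "rmsd",
]

#: observable-CSV column order used by every stage that serializes
#: observable-mode trajectories
OBSERVABLE_COLUMNS = ["frame", "time_ns", "sasa_A2", "rmsd_A", "state", "hbonds"]

_HYDROGEN_ELEMENTS = {"H", "D", "T"}


@dataclass
class LigandStructure:
    """A small-molecule ligand: atom records plus designated feature groups.

    The head and tail groups are the atom sets between which the two
    inter-ligand feature distances (d1: head–head, d2: head–tail) are
    measured.  They are system-specific and must be supplied by the user
    (config key ``structure.head_atoms`` / ``structure.tail_atoms``);
    they are never guessed from the chemistry.
    """

    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) Å
    head_group: frozenset[int] = frozenset()
    tail_group: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureMismatchError(
                f"coords must be (n_atoms, 3), got {self.coords.shape}"
            )
        if len(self.atom_names) != self.n_atoms or len(self.elements) != self.n_atoms:
            raise StructureMismatchError("atom_names/elements length != coords length")
        if not np.isfinite(self.coords).all():
            raise StructureMismatchError("coordinates contain non-finite values")
        for group in (self.head_group, self.tail_group):
            if group and not all(0 <= i < self.n_atoms for i in group):
                raise StructureMismatchError("feature group index out of range")
        if self.head_group & self.tail_group:
            raise StructureMismatchError("head_group and tail_group must be disjoint")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def heavy_mask(self) -> np.ndarray:
        """Boolean per atom, True for non-hydrogen elements."""
        return np.array(
            [e.upper() not in _HYDROGEN_ELEMENTS for e in self.elements], dtype=bool
        )

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.flatnonzero(self.heavy_mask)

    def with_groups(
        self, head_atoms: list[str] | list[int], tail_atoms: list[str] | list[int]
    ) -> "LigandStructure":
        """Return a copy with head/tail groups resolved from atom names or indices."""
        return LigandStructure(
            atom_names=list(self.atom_names),
            elements=list(self.elements),
            coords=self.coords.copy(),
            head_group=frozenset(self._resolve(head_atoms)),
            tail_group=frozenset(self._resolve(tail_atoms)),
        )

    def _resolve(self, atoms) -> list[int]:
        out = []
        for a in atoms:
            if isinstance(a, (int, np.integer)):
                out.append(int(a))
            else:
                matches = [i for i, n in enumerate(self.atom_names) if n == a]
                if not matches:
                    raise StructureMismatchError(f"atom name {a!r} not in structure")
                out.extend(matches)
        return out


@dataclass(slots=True)
class Frame:
    """One trajectory frame: per-ligand coordinates and/or observables.

    Observable-mode frames (from the synthetic generator or a CSV) carry
    ``observables`` with keys ``sasa`` (Å²), ``rmsd`` (Å), ``hbond_count``
    and ``state`` (``"H_H"``, ``"H_T"`` or ``"unassigned"``) and no
    coordinates.
    """

    time: float  # ns
    ligand_coords: list[np.ndarray] | None = None
    fibril_coords: np.ndarray | None = None
    observables: dict | None = None


@dataclass
class Trajectory:
    """Ordered frames at uniform time spacing ``dt`` (ns per frame)."""

    frames: list[Frame]
    dt: float
    ligand_count: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ligand_count < 1:
            raise StructureMismatchError("ligand_count must be >= 1")
        times = np.array([f.time for f in self.frames])
        if len(times) and (times < 0).any():
            raise StructureMismatchError("frame times must be non-negative")
        if len(times) > 1:
            steps = np.diff(times)
            if (steps <= 0).any() or not np.allclose(steps, self.dt, atol=1e-9):
                raise StructureMismatchError(
                    "frame times must increase uniformly by dt"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def observable_series(self, key: str) -> np.ndarray:
        """Collect one observable across frames as an array.

        Raises :class:`DataError` if any frame lacks the observable.
        """
        cached = self.metadata.get("_series", {}).get(key)
        if cached is not None:
            return cached
        try:
            values = [f.observables[key] for f in self.frames]
        except (TypeError, KeyError) as exc:
            raise DataError(f"observable {key!r} missing from trajectory") from exc
        arr = np.asarray(values)
        self.metadata.setdefault("_series", {})[key] = arr
        return arr

    def truncate(self, max_time_ns: float) -> "Trajectory":
        """Frames with time <= ``max_time_ns`` (classification windows)."""
        kept = [f for f in self.frames if f.time <= max_time_ns + 1e-12]
        if not kept:
            raise DataError("truncation window contains no frames")
        return Trajectory(
            frames=kept,
            dt=self.dt,
            ligand_count=self.ligand_count,
            metadata={k: v for k, v in self.metadata.items() if k != "_series"},
        )


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _load_pdb(path) -> pdb.PDBFile:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        return pdb.PDBFile.read(str(path))
    except Exception as exc:  # biotite raises various subclasses
        raise FormatError(f"cannot parse PDB {path}: {exc}") from exc


def _require_atom_records(pdb_file: pdb.PDBFile, path) -> None:
    if not any(l.startswith(("ATOM", "HETATM")) for l in pdb_file.lines):
        raise EmptyInputError(f"{path} contains zero atoms")


def read_structure(path) -> LigandStructure:
    """Read a single-model PDB into a :class:`LigandStructure`.

    Head/tail feature groups default to empty; callers must set them
    (``with_groups``) before computing d1/d2.
    """
    pdb_file = _load_pdb(path)
    _require_atom_records(pdb_file, path)
    try:
        atoms = pdb_file.get_structure(model=1)
    except Exception as exc:
        raise FormatError(f"cannot interpret PDB records in {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise EmptyInputError(f"{path} contains zero atoms")
    return LigandStructure(
        atom_names=list(atoms.atom_name),
        elements=list(atoms.element),
        coords=np.asarray(atoms.coord, dtype=float),
    )


def _as_atom_array(structure: LigandStructure, coords: np.ndarray,
                   chain_id: str = "A", res_id: int = 1) -> struc.AtomArray:
    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=float)
    arr.atom_name = np.array(structure.atom_names)
    arr.element = np.array(structure.elements)
    arr.res_name = np.full(n, "LIG")
    arr.res_id = np.full(n, res_id, dtype=int)
    arr.chain_id = np.full(n, chain_id)
    arr.hetero = np.full(n, True)
    return arr


def write_structure(path, structure: LigandStructure) -> None:
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_as_atom_array(structure, structure.coords))
    pdb_file.write(str(path))


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def write_trajectory(path, trajectory: Trajectory, structure: LigandStructure) -> None:
    """Write a coordinate-mode trajectory as a multi-model PDB.

    Each ligand gets its own chain identifier so readers can split frames
    back into per-ligand arrays.
    """
    models = []
    for frame in trajectory.frames:
        if frame.ligand_coords is None:
            raise DataError("cannot write an observable-only trajectory as PDB")
        parts = [
            _as_atom_array(structure, c, chain_id=_CHAIN_IDS[i % 26], res_id=i + 1)
            for i, c in enumerate(frame.ligand_coords)
        ]
        model = parts[0]
        for p in parts[1:]:
            model += p
        models.append(model)
    stack = struc.stack(models)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def write_configs(path, configs: list[np.ndarray], structure: LigandStructure) -> None:
    """Write a list of multi-ligand configurations as a multi-model PDB."""
    traj = Trajectory(
        frames=[
            Frame(time=i * 1.0, ligand_coords=[np.asarray(c)[j] for j in range(len(c))])
            for i, c in enumerate(configs)
        ],
        dt=1.0,
        ligand_count=len(configs[0]),
    )
    write_trajectory(path, traj, structure)


def read_trajectory(
    path,
    structure: LigandStructure,
    ligand_count: int,
    dt: float = 0.1,
    split: str = "chain",
) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory`.

    Per-ligand splitting uses chain identifiers when ``split="chain"`` and
    the file has enough distinct chains; otherwise contiguous
    residue-number blocks of the ligand's atom count are used.
    """
    pdb_file = _load_pdb(path)
    _require_atom_records(pdb_file, path)
    try:
        stack = pdb_file.get_structure()
    except Exception as exc:
        raise FormatError(f"cannot interpret PDB records in {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise EmptyInputError(f"{path} contains zero atoms")

    n_atoms_per_ligand = structure.n_atoms
    expected = n_atoms_per_ligand * ligand_count
    if stack.array_length() != expected:
        raise StructureMismatchError(
            f"{path}: {stack.array_length()} atoms per model, expected "
            f"{expected} ({ligand_count} ligands x {n_atoms_per_ligand} atoms)"
        )

    model0 = stack[0]
    chains = list(dict.fromkeys(model0.chain_id))  # preserve order
    if split == "chain" and len(chains) == ligand_count:
        masks = [model0.chain_id == c for c in chains]
    else:
        # contiguous blocks of the ligand atom count, in file order
        masks = [
            np.zeros(expected, dtype=bool) for _ in range(ligand_count)
        ]
        for i in range(ligand_count):
            masks[i][i * n_atoms_per_ligand : (i + 1) * n_atoms_per_ligand] = True

    frames = []
    coords = np.asarray(stack.coord, dtype=float)  # (n_models, n_atoms, 3)
    for m in range(coords.shape[0]):
        frames.append(
            Frame(
                time=m * dt,
                ligand_coords=[coords[m][mask] for mask in masks],
            )
        )
    return Trajectory(frames=frames, dt=dt, ligand_count=ligand_count)


# ---------------------------------------------------------------------------
# Observable-mode CSV I/O
# ---------------------------------------------------------------------------


def write_observable_csv(path, trajectory: Trajectory) -> None:
    """Serialize an observable-mode trajectory to CSV.

    Columns: ``frame, time_ns, sasa_A2, rmsd_A, state, hbonds``.
    """
    df = pd.DataFrame(
        {
            "frame": np.arange(trajectory.n_frames),
            "time_ns": [f.time for f in trajectory.frames],
            "sasa_A2": trajectory.observable_series("sasa"),
            "rmsd_A": trajectory.observable_series("rmsd"),
            "state": trajectory.observable_series("state"),
            "hbonds": trajectory.observable_series("hbond_count"),
        }
    )
    df.to_csv(path, index=False)


def read_observable_csv(path, ligand_count: int = 2) -> Trajectory:
    df = pd.read_csv(path)
    missing = set(OBSERVABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing observable columns {sorted(missing)}")
    if len(df) == 0:
        raise EmptyInputError(f"{path} contains zero frames")
    times = df["time_ns"].to_numpy(dtype=float)
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    frames = [
        Frame(
            time=float(t),
            observables={
                "sasa": float(s),
                "rmsd": float(r),
                "state": str(st),
                "hbond_count": int(h),
            },
        )
        for t, s, r, st, h in zip(
            times, df["sasa_A2"], df["rmsd_A"], df["state"], df["hbonds"]
        )
    ]
    return Trajectory(frames=frames, dt=dt, ligand_count=ligand_count)


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def center_of_mass(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted mean position; uniform masses when none are given."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise EmptyInputError("center_of_mass of an empty coordinate array")
    if masses is None:
        return coords.mean(axis=0)
    masses = np.asarray(masses, dtype=float)
    if masses.shape[0] != coords.shape[0]:
        raise StructureMismatchError("masses length != atom count")
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation mapping centered ``mobile`` onto centered
    ``target`` (least-squares, reflections excluded)."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose(
    mobile: np.ndarray, target: np.ndarray, fit_indices: np.ndarray | None = None
) -> np.ndarray:
    """Rigidly superpose ``mobile`` onto ``target`` using the atoms in
    ``fit_indices`` (all atoms when None); the transform is applied to the
    whole ``mobile`` array."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    idx = np.arange(len(mobile)) if fit_indices is None else np.asarray(fit_indices)
    m_sel, t_sel = mobile[idx], target[idx]
    m_c, t_c = m_sel.mean(axis=0), t_sel.mean(axis=0)
    rot = kabsch_rotation(m_sel - m_c, t_sel - t_c)
    return (mobile - m_c) @ rot.T + t_c


def rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    subset: np.ndarray | None = None,
    superpose_first: bool = False,
) -> float:
    """Root-mean-square deviation between two conformations (Å).

    With ``superpose_first`` the optimal rigid (Kabsch) superposition on
    ``subset`` is applied before measuring.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        a, b = a[subset], b[subset]
    if a.shape != b.shape:
        raise StructureMismatchError(f"shape mismatch {a.shape} vs {b.shape}")
    if a.size == 0:
        raise EmptyInputError("rmsd over an empty subset")
    if superpose_first:
        a = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
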