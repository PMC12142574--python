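"""YAML pipeline configuration and deterministic seed management."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError

__all__ = ["PipelineConfig", "SeedStreams", "load_config"]

#: fixed stage order used for seed expansion; reordering would silently
#: change every stage's random stream
STAGES = ("simulate", "classify", "kinetics", "hbonds", "cluster", "fes", "metrics")


class SeedStreams:
    """One global seed expanded into independent per-stage generators.

    Stage streams are spawned from ``SeedSequence(seed)`` in the fixed
    ``STAGES`` order, so any stage can be rerun in isolation and still
    see the same stream.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        self._streams = dict(zip(STAGES, children))

    def rng(self, stage: str) -> np.random.Generator:
        if stage not in self._streams:
            raise ConfigError(f"unknown pipeline stage {stage!r}")
        return np.random.default_rng(self._streams[stage])


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline, loadable from YAML."""

    # structure block: feature-group atom names (required for d1/d2 stages)
    head_atoms: list = field(default_factory=list)
    tail_atoms: list = field(default_factory=list)
    ligand_path: str | None = None
    fibril_path: str | None = None
    # thresholds
    sasa_threshold: float = 250.0  # Å²
    rmsd_threshold: float = 2.0  # Å
    cluster_threshold: float = 40.0  # Å
    hbond_da_cutoff: float = 3.5  # Å
    hbond_angle_min: float = 135.0  # degrees
    # switching function
    switching_n: int = 6
    switching_m: int = 8
    switching_d0: float = 0.0  # nm
    switching_r0: float = 0.45  # nm
    # landscape
    bin_width: float = 0.5  # Å
    temperature: float = 300.0  # K
    # synthetic simulation sizes
    n_trajectories: int = 1000
    n_frames: int = 1000
    cluster_ensemble_size: int = 2000
    oligomer_sizes: list = field(default_factory=lambda: [2, 3, 4, 5])
    dimer_samples: int = 20000
    # seed
    seed: int = 0

    def validate(self, stages=STAGES) -> None:
        for name in (
            "sasa_threshold",
            "rmsd_threshold",
            "cluster_threshold",
            "hbond_da_cutoff",
            "bin_width",
            "temperature",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if ("fes" in stages or "metrics" in stages) and self.ligand_path is not None:
            # a user-supplied ligand needs explicit feature groups
            if not self.head_atoms or not self.tail_atoms:
                raise ConfigError(
                    "fes/metrics stages on a user ligand require "
                    "structure.head_atoms and structure.tail_atoms"
                )
        for path_attr in ("ligand_path", "fibril_path"):
            path = getattr(self, path_attr)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{path_attr} does not exist: {path}")

    def seeds(self) -> SeedStreams:
        return SeedStreams(self.seed)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


_BLOCK_KEYS = {
    "structure": {"head_atoms", "tail_atoms", "ligand_path", "fibril_path"},
    "thresholds": {
        "sasa_threshold",
        "rmsd_threshold",
        "cluster_threshold",
        "hbond_da_cutoff",
        "hbond_angle_min",
    },
    "switching": {"switching_n", "switching_m", "switching_d0", "switching_r0"},
    "landscape": {"bin_width", "temperature"},
    "simulation": {
        "n_trajectories",
        "n_frames",
        "cluster_ensemble_size",
        "oligomer_sizes",
        "dimer_samples",
    },
}


def load_config(path) -> PipelineConfig:
    """Load a YAML config: flat keys or the documented nested blocks
    (``structure:``, ``thresholds:``, ``switching:``, ``landscape:``,
    ``simulation:``) are both accepted."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    flat: dict = {}
    valid = {f for keys in _BLOCK_KEYS.values() for f in keys} | {"seed"}
    for key, value in raw.items():
        if key in _BLOCK_KEYS:
            if not isinstance(value, dict):
                raise ConfigError(f"{path}: block {key!r} must be a mapping")
            for sub, sub_value in value.items():
                if sub not in _BLOCK_KEYS[key]:
                    raise ConfigError(f"{path}: unknown key {key}.{sub}")
                flat[sub] = sub_value
        elif key in valid:
            flat[key] = value
        else:
            raise ConfigError(f"{path}: unknown key {key!r}")
    return PipelineConfig(**flat)
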