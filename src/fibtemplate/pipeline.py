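"""End-to-end pipeline: synthetic ensemble → classification → kinetics →
H-bond statistics → configurational clustering → free-energy landscape →
order metrics, with full provenance in the report."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cluster_analysis import ConfigurationClusterer, population_table
from .config import PipelineConfig
from .errors import FibtemplateError
from .hbond_analysis import hbond_distribution
from .landscape import FreeEnergyLandscape, trajectory_feature_distances
from .order_metrics import (
    NativeContactSpec,
    SwitchingParams,
    oligomer_order,
)
from .pathway_kinetics import (
    ClassificationRule,
    PathwayClassifier,
    transition_probabilities,
    truncated_onpathway_fraction,
)
from .synthetic_data import (
    SyntheticParams,
    generate_coordinate_dimer,
    generate_ensemble,
    generate_oligomer_configs,
    generate_toy_ligand,
)

__all__ = ["run_pipeline"]


class StageFailure(FibtemplateError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_path=None) -> dict:
    """Execute every stage on the synthetic study conditions and return a
    JSON-serializable report (also written to ``out_path`` if given).

    Reports are bit-reproducible for a fixed config + seed: stage
    generators are spawned deterministically and no timestamps are
    recorded.
    """
    config.validate()
    seeds = config.seeds()
    params = SyntheticParams(
        sasa_threshold=config.sasa_threshold, rmsd_threshold=config.rmsd_threshold
    )
    rule = ClassificationRule(config.sasa_threshold, config.rmsd_threshold)
    report: dict = {"config": config.to_dict(), "stages": {}}

    def run_stage(name, fn):
        try:
            report["stages"][name] = fn()
        except Exception as exc:
            if out_path is not None:  # retain partial outputs
                _write(out_path, report)
            raise StageFailure(name, exc) from exc

    # --- simulate + classify + kinetics + hbonds operate on one ensemble
    ensemble: list = []

    def stage_simulate():
        ensemble.extend(
            generate_ensemble(
                config.n_trajectories, config.n_frames, params, seeds.rng("simulate")
            )
        )
        true_counts = {
            label: sum(1 for _, t in ensemble if t == label)
            for label in ("on", "off", "non")
        }
        return {"n_trajectories": len(ensemble), "true_label_counts": true_counts}

    labels: list = []

    def stage_classify():
        clf = PathwayClassifier(rule.sasa_threshold, rule.rmsd_threshold).fit()
        labels.extend(clf.predict([traj for traj, _ in ensemble]))
        fractions = {
            c: float(np.mean([l == c for l in labels])) for c in ("on", "off", "non")
        }
        early = truncated_onpathway_fraction(
            [traj for traj, _ in ensemble], truncate_at_ns=20.0, rule=rule
        )
        return {
            "fractions_pct": {c: 100.0 * f for c, f in fractions.items()},
            "onpathway_pct_first_20ns": 100.0 * early,
        }

    def stage_kinetics():
        out = {}
        for cls in ("on", "off"):
            series = [
                traj.observable_series("state")
                for (traj, _), label in zip(ensemble, labels)
                if label == cls
            ]
            stats = transition_probabilities(series, lag=1)
            out[cls] = {
                "k_HH_to_HT": stats.k_hh_to_ht,
                "k_HT_to_HH": stats.k_ht_to_hh,
                "counts": stats.counts,
                "n_trajectories": stats.n_trajectories,
            }
        return out

    def stage_hbonds():
        out = {}
        for cls in ("on", "off"):
            counts = [
                traj.observable_series("hbond_count")[
                    traj.observable_series("sasa") < rule.sasa_threshold
                ]
                for (traj, _), label in zip(ensemble, labels)
                if label == cls
            ]
            dist = hbond_distribution(counts)
            out[cls] = {
                "mean": dist["mean"],
                "histogram_pct": {k: 100.0 * v for k, v in dist["histogram"].items()},
            }
        return out

    def stage_cluster():
        rng = seeds.rng("cluster")
        ligand = generate_toy_ligand()
        out = {}
        for mode in ("solution", "fibril"):
            out[mode] = {}
            for size in config.oligomer_sizes:
                configs = generate_oligomer_configs(
                    mode, size, config.cluster_ensemble_size, params, rng
                )
                clusterer = ConfigurationClusterer(
                    threshold=config.cluster_threshold
                ).fit(configs, ligand)
                out[mode][size] = {
                    "n_clusters": clusterer.summary_.n_clusters,
                    "top_populations_pct": [
                        float(p) for p in population_table(clusterer.summary_, 10)
                    ],
                }
        return out

    def stage_fes():
        rng = seeds.rng("fes")
        ligand = generate_toy_ligand()
        out = {}
        for environment in ("solution", "fibril"):
            n_hh = int(round(0.7 * config.dimer_samples))
            n_ht = config.dimer_samples - n_hh
            traj_hh = generate_coordinate_dimer(
                "H_H", environment, n_hh, params, rng, ligand
            )
            traj_ht = generate_coordinate_dimer(
                "H_T", environment, n_ht, params, rng, ligand
            )
            samples = np.vstack(
                [
                    trajectory_feature_distances(traj_hh, ligand),
                    trajectory_feature_distances(traj_ht, ligand),
                ]
            )
            est = FreeEnergyLandscape(
                bin_width=config.bin_width, temperature=config.temperature
            ).fit(samples)
            out[environment] = {
                "minima": [
                    {"d1": m[0], "d2": m[1], "delta_g": m[2]}
                    for m in est.minima_[:2]
                ]
            }
        return out

    def stage_metrics():
        rng = seeds.rng("metrics")
        ligand = generate_toy_ligand()
        switching = SwitchingParams(
            n=config.switching_n,
            m=config.switching_m,
            d0=config.switching_d0,
            r0=config.switching_r0,
        )
        # crystal-like reference: noiseless H_H dimer geometry
        reference = generate_coordinate_dimer(
            "H_H",
            "fibril",
            2,
            SyntheticParams(noise_sd=0.0),
            rng,
            ligand,
        ).frames[0]
        spec = NativeContactSpec.from_reference(
            reference.ligand_coords[0],
            reference.ligand_coords[1],
            ligand.heavy_mask,
        )
        traj = generate_coordinate_dimer("H_H", "fibril", 50, params, rng, ligand)
        values = [
            oligomer_order(f.ligand_coords, spec, switching, ligand.heavy_mask)
            for f in traj.frames
        ]
        return {
            "native_contacts_mean": float(np.mean([v["native"] for v in values])),
            "coordination_mean": float(np.mean([v["coordination"] for v in values])),
        }

    run_stage("simulate", stage_simulate)
    run_stage("classify", stage_classify)
    run_stage("kinetics", stage_kinetics)
    run_stage("hbonds", stage_hbonds)
    run_stage("cluster", stage_cluster)
    run_stage("fes", stage_fes)
    run_stage("metrics", stage_metrics)

    if out_path is not None:
        _write(out_path, report)
    return report


def _write(path, report: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
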