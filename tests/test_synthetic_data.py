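"""The synthetic generator must reproduce its own declared statistics."""

import numpy as np
import pytest

from fibtemplate import (
    SyntheticParams,
    generate_coordinate_dimer,
    generate_ensemble,
    generate_observable_trajectory,
    generate_oligomer_configs,
    generate_toy_ligand,
)
from fibtemplate.errors import ParameterError
from fibtemplate.landscape import feature_distances
from fibtemplate.synthetic_data import CLUSTER_WEIGHTS, _markov_chain


class TestToyLigand:
    def test_geometry(self):
        lig = generate_toy_ligand()
        assert lig.n_atoms == 14
        assert lig.heavy_mask.sum() == 14
        assert not (lig.head_group & lig.tail_group)
        head_c = lig.coords[sorted(lig.head_group)].mean(axis=0)
        tail_c = lig.coords[sorted(lig.tail_group)].mean(axis=0)
        assert np.linalg.norm(head_c - tail_c) > 4.0

    def test_seed_reproducibility(self):
        a = generate_toy_ligand(5)
        b = generate_toy_ligand(5)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestDefaultDistributions:
    def test_hbond_means_exact_by_construction(self, params):
        mean_on = sum(k * p for k, p in params.hbond_dist_on.items())
        mean_off = sum(k * p for k, p in params.hbond_dist_off.items())
        assert mean_on == pytest.approx(2.01, abs=1e-12)
        assert mean_off == pytest.approx(0.74, abs=1e-12)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticParams(class_mixture={"on": 0.5, "off": 0.5, "non": 0.5})

    def test_cluster_weight_catalogs_sum_to_100(self):
        for key, weights in CLUSTER_WEIGHTS.items():
            assert sum(weights) == pytest.approx(100.0, abs=1e-9), key
            # pinned leaders stay the largest entries
            assert max(weights) == weights[0]


class TestObservableTrajectories:
    def test_nonaggregated_never_crosses_sasa_threshold(self, params, rng):
        traj = generate_observable_trajectory("non", 500, params, rng)
        assert (traj.observable_series("sasa") > 250.0).all()

    def test_off_pathway_never_crystal_like(self, params, rng):
        traj = generate_observable_trajectory("off", 500, params, rng)
        assert (traj.observable_series("rmsd") > 2.0).all()
        # but it does aggregate
        assert (traj.observable_series("sasa") < 250.0).any()

    def test_on_pathway_visits_crystal_like_pose(self, params, rng):
        traj = generate_observable_trajectory("on", 500, params, rng)
        assert (traj.observable_series("rmsd") <= 2.0).any()

    def test_degenerate_chain_is_constant(self, rng):
        params = SyntheticParams(
            markov_on={"p_HH_to_HT": 0.0, "p_HT_to_HH": 0.0}
        )
        traj = generate_observable_trajectory("on", 200, params, rng)
        states = traj.observable_series("state")
        assert len(set(states)) == 1

    def test_unknown_label_rejected(self, params, rng):
        with pytest.raises(ParameterError):
            generate_observable_trajectory("sideways", 10, params, rng)

    def test_markov_transition_frequencies_converge(self):
        # long-chain empirical conditional frequencies vs the generating
        # matrix, within 3 binomial sigma
        rng = np.random.default_rng(77)
        p_hh_ht, p_ht_hh = 0.28, 0.25
        chain = _markov_chain(rng, 100_000, p_hh_ht, p_ht_hh)
        a, b = chain[:-1], chain[1:]
        n_hh = (a == 0).sum()
        n_ht = (a == 1).sum()
        f_hh_ht = ((a == 0) & (b == 1)).sum() / n_hh
        f_ht_hh = ((a == 1) & (b == 0)).sum() / n_ht
        assert abs(f_hh_ht - p_hh_ht) < 3 * np.sqrt(p_hh_ht * (1 - p_hh_ht) / n_hh)
        assert abs(f_ht_hh - p_ht_hh) < 3 * np.sqrt(p_ht_hh * (1 - p_ht_hh) / n_ht)


class TestEnsemble:
    def test_label_counts_match_mixture(self, params):
        ensemble = generate_ensemble(1000, 10, params, rng=3)
        labels = [label for _, label in ensemble]
        for cls, frac in params.class_mixture.items():
            count = labels.count(cls)
            # 99% binomial interval (2.58 sigma)
            sigma = np.sqrt(1000 * frac * (1 - frac))
            assert abs(count - 1000 * frac) < 2.58 * sigma

    def test_pure_mixture(self):
        params = SyntheticParams(class_mixture={"on": 1.0, "off": 0.0, "non": 0.0})
        ensemble = generate_ensemble(20, 10, params, rng=0)
        assert all(label == "on" for _, label in ensemble)

    def test_different_seeds_differ(self, params):
        e1 = [l for _, l in generate_ensemble(50, 5, params, rng=1)]
        e2 = [l for _, l in generate_ensemble(50, 5, params, rng=2)]
        assert e1 != e2


class TestCoordinateDimer:
    @pytest.mark.parametrize(
        "state,environment,target",
        [
            ("H_H", "solution", (7.0, 5.0)),
            ("H_T", "solution", (12.0, 11.0)),
            ("H_T", "fibril", (9.0, 14.0)),
        ],
    )
    def test_noiseless_geometry_is_exact(self, toy_ligand, state, environment, target):
        params = SyntheticParams(noise_sd=0.0)
        traj = generate_coordinate_dimer(state, environment, 2, params, 0, toy_ligand)
        d1, d2 = feature_distances(traj.frames[0], toy_ligand)
        assert d1 == pytest.approx(target[0], abs=1e-6)
        assert d2 == pytest.approx(target[1], abs=1e-6)

    def test_noisy_sample_mean_is_centered(self, toy_ligand):
        params = SyntheticParams(noise_sd=0.5)
        traj = generate_coordinate_dimer("H_H", "solution", 10_000, params, 5,
                                         toy_ligand)
        d = np.array([feature_distances(f, toy_ligand) for f in traj.frames])
        # sample mean within 0.1 Å of the target center (covers the small
        # convexity bias of the norm of a noisy vector)
        assert abs(d[:, 0].mean() - 7.0) < 0.1
        assert abs(d[:, 1].mean() - 5.0) < 0.1

    def test_unreachable_targets_rejected(self, toy_ligand):
        params = SyntheticParams(
            minima={"solution": {"H_H": (30.0, 1.0), "H_T": (12.0, 11.0)}}
        )
        with pytest.raises(ParameterError):
            generate_coordinate_dimer("H_H", "solution", 2, params, 0, toy_ligand)


class TestOligomerConfigs:
    def test_fibril_tetramer_single_template(self, params):
        _, labels = generate_oligomer_configs(
            "fibril", 4, 100, params, rng=0, return_labels=True
        )
        assert (labels == 0).all()

    def test_solution_dimer_top_share(self, params):
        n = 3000
        _, labels = generate_oligomer_configs(
            "solution", 2, n, params, rng=1, return_labels=True
        )
        share = (labels == 0).sum() / n
        sigma = np.sqrt(0.213 * (1 - 0.213) / n)
        assert abs(share - 0.213) < 3 * sigma

    def test_single_config_is_valid(self, params):
        configs = generate_oligomer_configs("fibril", 2, 1, params, rng=0)
        assert len(configs) == 1
        assert configs[0].shape == (2, 14, 3)
        assert np.isfinite(configs[0]).all()

    def test_invalid_size_rejected(self, params):
        with pytest.raises(ParameterError):
            generate_oligomer_configs("fibril", 7, 10, params, rng=0)
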