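"""Alignment, pairwise RMSD matrices and centroid-linkage clustering."""

import numpy as np
import pytest

from fibtemplate import (
    ConfigurationClusterer,
    align_to_first_ligand,
    generate_oligomer_configs,
    hierarchical_cluster,
    pairwise_rmsd_matrix,
    population_table,
)
from fibtemplate.errors import EmptyInputError, StructureMismatchError
from fibtemplate.io_structures import rmsd
from fibtemplate.pose_generation import random_rotation


def _rigid(config, rot, shift):
    center = config.reshape(-1, 3).mean(axis=0)
    return (config - center) @ rot.T + center + shift


class TestAlignment:
    def test_pre_aligned_configs_unchanged(self, toy_ligand, rng):
        base = np.stack([toy_ligand.coords, toy_ligand.coords + 30.0])
        configs = [base, base + 0.0]
        aligned = align_to_first_ligand(configs, toy_ligand)
        for orig, out in zip(configs, aligned):
            np.testing.assert_allclose(out, orig, atol=1e-9)

    def test_rigid_copy_aligns_exactly(self, toy_ligand, rng):
        base = np.stack([toy_ligand.coords, toy_ligand.coords + 30.0])
        moved = _rigid(base, random_rotation(rng, "uniform"), np.array([5.0, -3, 8]))
        aligned = align_to_first_ligand([base, moved], toy_ligand)
        assert rmsd(aligned[1][0], base[0]) < 1e-9

    def test_full_system_rmsd_vanishes_after_alignment(self, toy_ligand, rng):
        base = np.stack([toy_ligand.coords, toy_ligand.coords + 30.0])
        configs = [
            _rigid(base, random_rotation(rng, "uniform"), rng.uniform(-10, 10, 3))
            for _ in range(5)
        ]
        aligned = align_to_first_ligand(configs, toy_ligand)
        matrix = pairwise_rmsd_matrix(aligned, toy_ligand)
        assert matrix.max() < 1e-8

    def test_shape_mismatch_raises(self, toy_ligand):
        a = np.stack([toy_ligand.coords, toy_ligand.coords + 30.0])
        b = a[:, :10, :]
        with pytest.raises(StructureMismatchError):
            align_to_first_ligand([a, b], toy_ligand)


class TestPairwiseMatrix:
    def test_identical_configs_zero_matrix(self, toy_ligand):
        base = np.stack([toy_ligand.coords, toy_ligand.coords + 30.0])
        matrix = pairwise_rmsd_matrix([base] * 4, toy_ligand)
        assert np.all(matrix == 0)

    def test_uniform_shift_gives_exact_entry(self, toy_ligand):
        base = np.stack([toy_ligand.coords, toy_ligand.coords + 30.0])
        shifted = base + np.array([0.0, 3.0, 0.0])
        matrix = pairwise_rmsd_matrix([base, shifted], toy_ligand)
        assert matrix[0, 1] == pytest.approx(3.0, abs=1e-12)

    def test_symmetry(self, toy_ligand, rng):
        configs = [
            np.stack(
                [toy_ligand.coords + rng.normal(size=(14, 3)),
                 toy_ligand.coords + 30.0 + rng.normal(size=(14, 3))]
            )
            for _ in range(6)
        ]
        matrix = pairwise_rmsd_matrix(configs, toy_ligand)
        np.testing.assert_allclose(matrix, matrix.T, atol=1e-12)
        assert np.all(np.diag(matrix) == 0)


class TestHierarchicalClustering:
    def test_everything_close_is_one_cluster(self, rng):
        matrix = np.abs(rng.normal(scale=1.0, size=(10, 10)))
        matrix = 0.5 * (matrix + matrix.T)
        np.fill_diagonal(matrix, 0.0)
        summary = hierarchical_cluster(matrix, threshold=40.0)
        assert summary.n_clusters == 1
        np.testing.assert_allclose(summary.populations, [100.0])

    def test_two_well_separated_blobs(self, toy_ligand, rng):
        base = np.stack([toy_ligand.coords, toy_ligand.coords + 30.0])
        far = base + np.array([150.0, 0.0, 0.0])
        configs = [base + rng.normal(scale=0.3, size=base.shape) for _ in range(14)]
        configs += [far + rng.normal(scale=0.3, size=base.shape) for _ in range(6)]
        matrix = pairwise_rmsd_matrix(configs, toy_ligand)
        summary = hierarchical_cluster(matrix, threshold=40.0)
        assert summary.n_clusters == 2
        np.testing.assert_allclose(summary.populations, [70.0, 30.0])
        # medoids drawn from the right blobs
        assert summary.centroid_indices[0] < 14 <= summary.centroid_indices[1]

    def test_fibril_tetramer_ensemble_fully_concentrated(self, toy_ligand, params):
        configs = generate_oligomer_configs("fibril", 4, 300, params, rng=2)
        clusterer = ConfigurationClusterer().fit(configs, toy_ligand)
        np.testing.assert_allclose(clusterer.populations_, [100.0])

    def test_empty_matrix_raises(self):
        with pytest.raises(EmptyInputError):
            hierarchical_cluster(np.empty((0, 0)))

    def test_order_invariance_up_to_relabeling(self, toy_ligand, params):
        configs = generate_oligomer_configs("fibril", 2, 200, params, rng=4)
        c1 = ConfigurationClusterer().fit(configs, toy_ligand)
        perm = np.random.default_rng(0).permutation(len(configs))
        c2 = ConfigurationClusterer().fit([configs[i] for i in perm], toy_ligand)
        np.testing.assert_allclose(
            np.sort(c1.populations_), np.sort(c2.populations_)
        )
        # identical partitions: labels agree after permutation up to renaming
        relabeled = c2.labels_[np.argsort(perm)]
        pairs = set(zip(c1.labels_.tolist(), relabeled.tolist()))
        assert len(pairs) == c1.summary_.n_clusters

    def test_planted_partition_recovery(self, toy_ligand, params):
        n = 2000
        configs, labels = generate_oligomer_configs(
            "solution", 2, n, params, rng=7, return_labels=True
        )
        clusterer = ConfigurationClusterer().fit(configs, toy_ligand)
        # recovered occupancies equal the planted template frequencies
        planted = np.sort(
            np.array([(labels == k).sum() for k in np.unique(labels)])
        )[::-1]
        np.testing.assert_allclose(
            clusterer.populations_, 100.0 * planted / n, atol=1e-9
        )
        # and the planted frequencies sit within 3 sigma of the weights
        top_share = clusterer.populations_[0] / 100.0
        sigma = np.sqrt(0.213 * (1 - 0.213) / n)
        assert abs(top_share - 0.213) < 3 * sigma


class TestPopulationTable:
    def test_single_cluster(self, toy_ligand):
        base = np.stack([toy_ligand.coords, toy_ligand.coords + 30.0])
        clusterer = ConfigurationClusterer().fit([base] * 5, toy_ligand)
        np.testing.assert_allclose(
            population_table(clusterer.summary_), [100.0]
        )

    def test_remainder_aggregated_into_other(self, toy_ligand, params):
        configs = generate_oligomer_configs("solution", 2, 400, params, rng=9)
        clusterer = ConfigurationClusterer().fit(configs, toy_ligand)
        table = population_table(clusterer.summary_, top_k=3)
        assert len(table) == 4
        assert table.sum() == pytest.approx(100.0)

    def test_top_k_larger_than_cluster_count(self, toy_ligand, params):
        configs = generate_oligomer_configs("fibril", 3, 100, params, rng=9)
        clusterer = ConfigurationClusterer().fit(configs, toy_ligand)
        table = population_table(clusterer.summary_, top_k=50)
        assert len(table) == clusterer.summary_.n_clusters
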