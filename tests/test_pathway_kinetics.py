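"""SASA, pathway classification, state assignment and transition kinetics."""

import numpy as np
import pytest

from fibtemplate import (
    ClassificationRule,
    PathwayClassifier,
    SyntheticParams,
    assign_states,
    classify_ensemble,
    classify_trajectory,
    compute_sasa,
    generate_coordinate_dimer,
    generate_ensemble,
    generate_observable_trajectory,
    transition_probabilities,
    truncated_onpathway_fraction,
)
from fibtemplate.errors import DataError, EmptyInputError, ParameterError
from fibtemplate.io_structures import Frame, Trajectory


def _obs_traj(sasa, rmsd):
    frames = [
        Frame(
            time=i * 0.1,
            observables={"sasa": s, "rmsd": r, "state": "H_H", "hbond_count": 0},
        )
        for i, (s, r) in enumerate(zip(sasa, rmsd))
    ]
    return Trajectory(frames=frames, dt=0.1, ligand_count=2)


class TestComputeSasa:
    def test_isolated_carbon_closed_form(self):
        area = compute_sasa(np.zeros((1, 3)), ["C"], probe=1.4)
        assert area == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-9)

    def test_distant_atoms_are_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        single = compute_sasa(np.zeros((1, 3)), ["C"])
        assert compute_sasa(coords, ["C", "C"]) == pytest.approx(2 * single)

    def test_occlusion_reduces_area(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0]])
        single = compute_sasa(np.zeros((1, 3)), ["C"])
        assert compute_sasa(coords, ["C", "C"]) < 2 * single

    def test_unknown_element_rejected(self):
        with pytest.raises(ParameterError):
            compute_sasa(np.zeros((1, 3)), ["Xx"])

    def test_against_independent_shrake_rupley(self):
        mdtraj = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(17)
        coords = rng.uniform(0, 8, size=(10, 3))
        ours = compute_sasa(coords, ["C"] * 10, probe=1.4, n_points=960)
        top = mdtraj.Topology()
        chain = top.add_chain()
        res = top.add_residue("LIG", chain)
        for i in range(10):
            top.add_atom(f"C{i}", mdtraj.element.carbon, res)
        traj = mdtraj.Trajectory(coords[None] / 10.0, top)  # nm
        theirs = mdtraj.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960)
        assert ours == pytest.approx(float(theirs.sum()) * 100.0, rel=0.03)


class TestClassification:
    def test_rule_application(self):
        sasa_hi = [300.0] * 5
        assert classify_trajectory(_obs_traj(sasa_hi, [5.0] * 5)) == "non"
        sasa_mixed = [300.0, 200.0, 300.0]
        assert classify_trajectory(_obs_traj(sasa_mixed, [3.0, 1.5, 3.0])) == "on"
        assert classify_trajectory(_obs_traj(sasa_mixed, [3.0, 3.0, 3.0])) == "off"

    def test_boundary_conventions(self):
        # SASA exactly at threshold counts as NOT aggregated
        assert classify_trajectory(_obs_traj([250.0] * 3, [1.0] * 3)) == "non"
        # RMSD exactly at threshold counts as on-pathway
        assert classify_trajectory(_obs_traj([200.0] * 3, [2.0] * 3)) == "on"

    def test_partition_and_fraction_sum(self, params):
        ensemble = [t for t, _ in generate_ensemble(60, 40, params, rng=2)]
        clf = PathwayClassifier().fit()
        labels = clf.predict(ensemble)
        assert set(labels) <= {"on", "off", "non"}
        fractions = classify_ensemble(ensemble)
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_classifier_recovers_generator_labels(self, params):
        ensemble = generate_ensemble(150, 60, params, rng=8)
        clf = PathwayClassifier().fit()
        predicted = clf.predict([t for t, _ in ensemble])
        truth = np.array([label for _, label in ensemble])
        assert (predicted == truth).all()

    def test_missing_observables_raise(self, toy_ligand):
        frames = [Frame(time=0.0), Frame(time=0.1)]
        traj = Trajectory(frames=frames, dt=0.1, ligand_count=2)
        with pytest.raises(DataError):
            classify_trajectory(traj)


class TestAssignStates:
    MINIMA = {"H_H": (7.0, 5.0), "H_T": (12.0, 11.0)}

    def _coord_traj(self, toy_ligand, d1, d2):
        params = SyntheticParams(
            noise_sd=0.0, minima={"solution": {"H_H": (d1, d2), "H_T": (12.0, 11.0)}}
        )
        return generate_coordinate_dimer("H_H", "solution", 2, params, 0, toy_ligand)

    def test_exact_center_assigned(self, toy_ligand):
        traj = self._coord_traj(toy_ligand, 7.0, 5.0)
        states = assign_states(traj, self.MINIMA, radius=3.0, structure=toy_ligand)
        assert list(states) == ["H_H", "H_H"]

    def test_far_frame_unassigned(self, toy_ligand):
        traj = self._coord_traj(toy_ligand, 30.0, 30.0)
        states = assign_states(traj, self.MINIMA, radius=3.0, structure=toy_ligand)
        assert list(states) == ["unassigned", "unassigned"]

    def test_equidistant_tie_goes_to_hh(self, toy_ligand):
        # coincident minima centers make every frame an exact tie
        traj = self._coord_traj(toy_ligand, 7.0, 5.0)
        tied = {"H_H": (7.0, 5.0), "H_T": (7.0, 5.0)}
        states = assign_states(traj, tied, radius=3.0, structure=toy_ligand)
        assert list(states) == ["H_H", "H_H"]

    def test_precomputed_states_pass_through(self, params, rng):
        traj = generate_observable_trajectory("off", 50, params, rng)
        states = assign_states(traj)
        np.testing.assert_array_equal(states, traj.observable_series("state"))


class TestTransitionProbabilities:
    def test_constant_series(self):
        stats = transition_probabilities([["H_H", "H_H", "H_H"]])
        assert stats.k_hh_to_ht == 0.0
        assert stats.k_ht_to_hh is None  # never in H_T: undefined, not 0

    def test_alternating_series(self):
        stats = transition_probabilities([["H_H", "H_T", "H_H", "H_T"]])
        assert stats.k_hh_to_ht == 1.0
        assert stats.k_ht_to_hh == 1.0

    def test_unassigned_breaks_pairs(self):
        stats = transition_probabilities(
            [["H_H", "unassigned", "H_T", "H_T"]]
        )
        # only the H_T->H_T pair is countable
        assert stats.counts == {
            "HH->HT": 0, "HT->HH": 0, "HH->HH": 0, "HT->HT": 1
        }

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            transition_probabilities([])

    @pytest.mark.parametrize("label,expected", [("on", (0.05, 0.39)),
                                                ("off", (0.28, 0.25))])
    def test_recovery_from_synthetic_chains(self, params, label, expected):
        rng = np.random.default_rng(99)
        series = [
            generate_observable_trajectory(label, 1000, params, rng
                                           ).observable_series("state")
            for _ in range(100)
        ]
        stats = transition_probabilities(series)
        n_hh = stats.counts["HH->HT"] + stats.counts["HH->HH"]
        n_ht = stats.counts["HT->HH"] + stats.counts["HT->HT"]
        p1, p2 = expected
        assert abs(stats.k_hh_to_ht - p1) < 3 * np.sqrt(p1 * (1 - p1) / n_hh)
        assert abs(stats.k_ht_to_hh - p2) < 3 * np.sqrt(p2 * (1 - p2) / n_ht)

    def test_estimator_consistency_over_chain_length(self, params):
        # bias of the pooled estimator shrinks as chains grow
        rng = np.random.default_rng(5)
        errors = []
        for n_frames in (100, 1000, 10000):
            series = [
                generate_observable_trajectory("off", n_frames, params, rng
                                               ).observable_series("state")
                for _ in range(10)
            ]
            stats = transition_probabilities(series)
            errors.append(abs(stats.k_hh_to_ht - 0.28))
        assert errors[-1] < errors[0]
        assert errors[-1] < 0.01


class TestTruncatedWindow:
    def test_full_window_equals_untruncated(self, params):
        trajs = [t for t, _ in generate_ensemble(80, 50, params, rng=6)]
        full = classify_ensemble(trajs)["on"]
        assert truncated_onpathway_fraction(trajs, 100.0) == pytest.approx(full)

    def test_empty_window_raises(self, params, rng):
        traj = generate_observable_trajectory("on", 50, params, rng)
        with pytest.raises(DataError):
            truncated_onpathway_fraction([traj], -1.0)

    def test_monotone_in_window_length(self, params):
        trajs = [t for t, _ in generate_ensemble(150, 100, params, rng=13)]
        fractions = [
            truncated_onpathway_fraction(trajs, w) for w in (20.0, 50.0, 100.0)
        ]
        assert fractions == sorted(fractions)
        # the early window sees fewer on-pathway trajectories
        assert fractions[0] <= fractions[-1]
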