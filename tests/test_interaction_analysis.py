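"""Interaction detection, occurrence tables and model histograms."""

import numpy as np
import pytest

from dynopharm.errors import EmptyWindowError
from dynopharm.feature_perception import (
    ChemFeature,
    FeatureType,
    GroupKind,
    ProteinGroup,
)
from dynopharm.interaction_analysis import (
    GeometricRules,
    InteractionDetector,
    ModelEnsemble,
    InteractionRecord,
    build_model_ensemble,
    detect_frame_interactions,
    last_fraction_window,
    model_histogram,
    occurrence_table,
    select_frequent_models,
)
from dynopharm.geometry import random_rotation
from dynopharm.io_structures import Trajectory
from dynopharm.synthetic_data import OccupancySchedule, generate_complex_trajectory


def ring_feature(center, normal):
    return ChemFeature(FeatureType.AR, center, 1.1, direction=normal)


def ring_group(center, normal, residue=("A", 10, "PHE")):
    return ProteinGroup(GroupKind.AROMATIC, residue, (), np.asarray(center, float),
                        normal=np.asarray(normal, float))


class TestGeometricPredicates:
    def test_parallel_stacked_rings_within_bounds_detected(self):
        records = detect_frame_interactions(
            None, [ring_feature((0, 0, 0), (0, 0, 1))],
            [ring_group((0, 0, 3.8), (0, 0, 1))])
        assert len(records) == 1
        assert records[0].type is FeatureType.AR

    def test_intermediate_ring_angle_rejected(self):
        tilted = np.array([np.sin(np.radians(45)), 0, np.cos(np.radians(45))])
        records = detect_frame_interactions(
            None, [ring_feature((0, 0, 0), (0, 0, 1))],
            [ring_group((0, 0, 3.8), tilted)])
        assert records == []

    def test_tshaped_ring_detected(self):
        records = detect_frame_interactions(
            None, [ring_feature((0, 0, 0), (0, 0, 1))],
            [ring_group((0, 0, 4.9), (1, 0, 0))])
        assert len(records) == 1

    def test_donor_acceptor_beyond_cutoff_rejected(self):
        donor = ChemFeature(FeatureType.HBD, (0, 0, 0), 1.5, direction=(0, 0, 1))
        acceptor = ProteinGroup(GroupKind.ACCEPTOR, ("A", 1, "SER"), (),
                                np.array([0.0, 0.0, 5.0]))
        assert detect_frame_interactions(None, [donor], [acceptor]) == []

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            GeometricRules(hbond_angle_min=200)
        with pytest.raises(ValueError):
            GeometricRules(hydrophobic_dist_max=-1)


class TestPlantedDetection:
    def test_zero_jitter_detection_equals_ground_truth(self, clean_complex):
        traj, truth = clean_complex
        detector = InteractionDetector(traj)
        for i in range(traj.n_frames):
            assert detector.interaction_set(i) == truth[i]

    def test_planted_record_count_matches(self, clean_complex):
        traj, truth = clean_complex
        detector = InteractionDetector(traj)
        for i in (0, 5, 17):
            records = detector.detect(i)
            assert {(r.type.value, r.residue[0], r.residue[1])
                    for r in records} == truth[i]

    def test_rigid_motion_invariance(self, rng):
        schedule = OccupancySchedule(n_frames=30, sigma=0.1, seed=21)
        traj_a, truth_a = generate_complex_trajectory(schedule)
        transform = (random_rotation(rng), rng.normal(scale=10.0, size=3))
        traj_b, truth_b = generate_complex_trajectory(schedule,
                                                      rigid_transform=transform)
        assert truth_a == truth_b
        det_a = InteractionDetector(traj_a)
        det_b = InteractionDetector(traj_b)
        for i in range(30):
            assert det_a.interaction_set(i) == det_b.interaction_set(i)

    def test_loosening_cutoffs_never_removes_records(self, jittered_complex):
        traj, _ = jittered_complex
        tight = InteractionDetector(traj, GeometricRules())
        loose = InteractionDetector(traj, GeometricRules(
            hbond_dist_max=4.0, hydrophobic_dist_max=5.5,
            aromatic_centroid_max=6.5, cation_pi_max=7.0, halogen_dist_max=4.5))
        for i in range(0, 50):
            assert tight.interaction_set(i) <= loose.interaction_set(i)


class TestOccurrenceTable:
    def test_always_on_interaction_reports_100(self):
        schedule = OccupancySchedule(
            probabilities={("HBD", "A", 436): 1.0}, n_frames=60, sigma=0.0, seed=5)
        traj, _ = generate_complex_trajectory(schedule)
        table = occurrence_table(traj)
        assert table.percent("A", 436, FeatureType.HBD) == 100.0

    def test_bernoulli_occupancy_recovered_within_3_sigma(self):
        p = 0.6
        n = 500
        schedule = OccupancySchedule(
            probabilities={("H", "A", 465): p}, n_frames=n, sigma=0.0, seed=7)
        traj, _ = generate_complex_trajectory(schedule)
        table = occurrence_table(traj)
        estimate = table.percent("A", 465, FeatureType.H) / 100.0
        assert abs(estimate - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_empty_window_raises(self, clean_complex):
        traj, _ = clean_complex
        with pytest.raises(EmptyWindowError):
            occurrence_table(traj, window=(5, 5))

    def test_rows_sorted_by_chain_then_resid(self, jittered_complex):
        traj, _ = jittered_complex
        table = occurrence_table(traj).table
        keys = list(zip(table.chain, table.resid))
        assert keys == sorted(keys)


class TestModelHistogram:
    def test_counts_sum_to_window_size(self, jittered_complex):
        traj, _ = jittered_complex
        window = last_fraction_window(traj.n_frames, 0.2)
        hist = model_histogram(traj, window=window)
        assert sum(hist.values()) == window[1] - window[0]

    def test_identical_frames_single_signature(self):
        schedule = OccupancySchedule(
            probabilities={("HBD", "A", 436): 1.0, ("H", "A", 465): 1.0},
            n_frames=25, sigma=0.0, seed=3)
        traj, _ = generate_complex_trajectory(schedule)
        hist = model_histogram(traj)
        assert len(hist) == 1
        assert list(hist.values()) == [25]

    def test_planted_signature_counts(self):
        """Three sub-trajectories with deterministic interaction sets
        concatenate into a histogram with exactly the planted counts."""
        pieces = []
        for n, keys in ((12, {("HBD", "A", 436): 1.0}),
                        (6, {("H", "A", 465): 1.0}),
                        (3, {("HBD", "A", 436): 1.0, ("H", "A", 465): 1.0})):
            schedule = OccupancySchedule(probabilities=keys, n_frames=n,
                                         sigma=0.0, seed=1)
            traj, _ = generate_complex_trajectory(schedule)
            pieces.append(traj)
        combined = Trajectory(
            pieces[0].atom_table,
            np.concatenate([t.coords for t in pieces]),
            pieces[0].ligand_resname,
            ligand_template=pieces[0].ligand_template)
        hist = model_histogram(combined)
        assert sorted(hist.values(), reverse=True) == [12, 6, 3]


class TestSelectFrequentModels:
    def test_top_k_by_count(self, jittered_complex):
        traj, _ = jittered_complex
        ensemble = build_model_ensemble(traj)
        hist = ensemble.histogram
        k = min(4, len(hist))
        models = select_frequent_models(ensemble, k)
        selected_counts = [hist[m.signature] for m in models]
        all_counts = sorted(hist.values(), reverse=True)
        assert selected_counts == all_counts[:k]

    def test_fewer_unique_than_k_warns_and_returns_all(self):
        schedule = OccupancySchedule(
            probabilities={("HBD", "A", 436): 1.0}, n_frames=10, sigma=0.0, seed=4)
        traj, _ = generate_complex_trajectory(schedule)
        ensemble = build_model_ensemble(traj)
        with pytest.warns(UserWarning):
            models = select_frequent_models(ensemble, 4)
        assert len(models) == 1

    def test_tie_broken_by_feature_count(self):
        """At equal frequency the model with more features ranks first."""
        rec = lambda t, res: InteractionRecord(
            0, t, ChemFeature(t, (0.0, 0.0, 0.0), 1.5), res)
        one = [rec(FeatureType.HBD, ("A", 436, "SER"))]
        two = [rec(FeatureType.HBD, ("A", 436, "SER")),
               rec(FeatureType.H, ("A", 465, "ALA"))]
        from dynopharm.pharmacophore_build import signature_of
        from dataclasses import replace

        def sig(records):
            return signature_of([replace(r.ligand_feature, type=r.type,
                                         partner=r.residue) for r in records])

        ensemble = ModelEnsemble(
            frame_indices=list(range(4)),
            frame_records=[one, two, one, two],
            signatures=[sig(one), sig(two), sig(one), sig(two)])
        models = select_frequent_models(ensemble, 1)
        assert len(models[0].features) == 2

    def test_representative_geometry_is_per_feature_centroid(self):
        schedule = OccupancySchedule(
            probabilities={("H", "A", 465): 1.0}, n_frames=30, sigma=0.1, seed=9)
        traj, _ = generate_complex_trajectory(schedule)
        ensemble = build_model_ensemble(traj)
        model = select_frequent_models(ensemble, 1)[0]
        centers = [r.ligand_feature.center for records in ensemble.frame_records
                   for r in records if r.type is FeatureType.H]
        np.testing.assert_allclose(model.features[0].center,
                                   np.mean(centers, axis=0), atol=1e-9)
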