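"""Conformer matching, library screening and retrieval metrics."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from dynopharm.errors import DegenerateLabelsError
from dynopharm.feature_perception import ChemFeature, FeatureType, perceive_ligand_features
from dynopharm.geometry import random_rotation
from dynopharm.pharmacophore_build import ESSENTIAL, PharmacophoreModel
from dynopharm.screening import (
    ScreenRecord,
    ScreenSettings,
    enrichment_metrics,
    match_conformer,
    roc_points,
    screen_library,
)
from dynopharm.synthetic_data import LibrarySpec, build_active, generate_screening_library


def pinned_model():
    """Three non-collinear essential features: the placement is fully
    determined by an exact match."""
    features = [ChemFeature(FeatureType.PI, (0.0, 2.0, 0.0), 1.5),
                ChemFeature(FeatureType.H, (2.5, 0.0, -4.0), 1.5),
                ChemFeature(FeatureType.H, (-3.0, 1.0, 2.0), 1.5)]
    return PharmacophoreModel(features=features,
                              flags=[ESSENTIAL, ESSENTIAL, ESSENTIAL])


class TestMatchConformer:
    def test_exact_conformer_matches_with_zero_rmsd(self):
        model = pinned_model()
        mol = build_active(model, "ref")
        feats = perceive_ligand_features(mol)
        result = match_conformer(feats, model)
        assert result is not None
        assert result.rmsd_feat < 1e-6
        assert len(result.pairs) >= 3

    def test_displaced_essential_feature_prevents_match(self):
        model = pinned_model()
        mol = build_active(model, "ref")
        feats = perceive_ligand_features(mol)
        # move the PI feature of the conformer far beyond its radius
        moved = [f if f.type is not FeatureType.PI
                 else ChemFeature(f.type, f.center + np.array([6.0, 0, 0]),
                                  f.radius, source_atoms=f.source_atoms)
                 for f in feats]
        assert match_conformer(moved, model) is None

    def test_exclusion_sphere_rejects_only_when_enabled(self):
        model = pinned_model()
        mol = build_active(model, "ref")
        feats = perceive_ligand_features(mol)
        heavy = np.array([xyz for (el, _q), xyz in
                          zip(mol.atoms, mol.conformer(0)) if el != "H"])
        # a sphere right on one ligand atom: clash under the pinned placement
        model.exclusion_volumes = [(heavy[0].copy(), 1.0)]
        on = match_conformer(feats, model, ScreenSettings(), heavy_coords=heavy)
        off = match_conformer(feats, model,
                              ScreenSettings(check_exclusion_volumes=False),
                              heavy_coords=heavy)
        assert on is None
        assert off is not None

    def test_score_invariant_under_rigid_transform(self, rng):
        model = pinned_model()
        mol = build_active(model, "ref")
        feats = perceive_ligand_features(mol)
        base = match_conformer(feats, model)
        rot = random_rotation(rng)
        trans = rng.normal(scale=10.0, size=3)
        moved = [f.transformed(rot, trans) for f in feats]
        transformed = match_conformer(moved, model)
        assert transformed is not None
        assert abs(base.fit_score - transformed.fit_score) < 1e-6


@pytest.fixture(scope="module")
def small_library(final_model_result):
    model = final_model_result.model
    spec = LibrarySpec(n_actives=4, decoys_per_active=10, seed=3)
    return model, *generate_screening_library(model, spec)


class TestScreenLibrary:
    def test_only_planted_actives_match(self, small_library):
        model, mols, labels = small_library
        records = screen_library(mols, model, labels=labels)
        matched = {r.molecule_id for r in records if r.matched}
        actives = {i for i, lab in labels.items() if lab == "active"}
        assert matched == actives

    def test_unmatched_records_carry_no_score(self, small_library):
        model, mols, labels = small_library
        records = screen_library(mols, model, labels=labels)
        assert all(r.fit_score is None for r in records if not r.matched)

    def test_empty_library(self, final_model_result):
        assert screen_library([], final_model_result.model) == []

    def test_deterministic_rescreen(self, small_library):
        model, mols, labels = small_library
        r1 = screen_library(mols, model, labels=labels)
        r2 = screen_library(mols, model, labels=labels)
        assert [(r.molecule_id, r.matched, r.fit_score) for r in r1] == \
            [(r.molecule_id, r.matched, r.fit_score) for r in r2]

    def test_conformerless_molecule_unmatched(self, final_model_result):
        from rdkit import Chem

        from dynopharm.io_structures import Molecule

        mol = Molecule("flat", Chem.MolFromSmiles("CCO"))
        records = screen_library([mol], final_model_result.model)
        assert records[0].matched is False


def records_from_ranking(active_positions, n):
    """Records ranked by descending score; actives at the given positions."""
    recs, labels = [], {}
    for i in range(n):
        mol_id = f"m{i}"
        recs.append(ScreenRecord(mol_id, True, fit_score=float(n - i)))
        labels[mol_id] = "active" if i in active_positions else "decoy"
    return recs, labels


class TestEnrichmentMetrics:
    def test_two_actives_in_top_four_of_463(self):
        """The printed one-decimal enrichment factor for a 463-compound
        library with 15 actives and 2 actives in the top 1% bin."""
        positions = {0, 1} | set(range(450, 463))
        recs, labels = records_from_ranking(positions, 463)
        assert sum(1 for v in labels.values() if v == "active") == 15
        metrics = enrichment_metrics(recs, labels, fractions=[0.01])
        assert round(metrics.ef[0.01], 1) == 15.4
        assert abs(metrics.ef[0.01] - (2 / 4) / (15 / 463)) < 1e-12

    def test_perfect_ranking_closed_form(self):
        recs, labels = records_from_ranking(set(range(15)), 463)
        metrics = enrichment_metrics(recs, labels, fractions=[0.01])
        assert abs(metrics.ef[0.01] - (4 / 4) / (15 / 463)) < 1e-12
        assert metrics.auc == 1.0

    def test_random_scores_auc_half(self):
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            scores = rng.normal(size=2000)
            labels = {}
            recs = []
            for i, s in enumerate(scores):
                mol_id = f"m{i}"
                labels[mol_id] = "active" if i < 200 else "decoy"
                recs.append(ScreenRecord(mol_id, True, fit_score=float(s)))
            aucs.append(enrichment_metrics(recs, labels).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_auc_equals_mann_whitney_statistic(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_a, n_d = int(rng.integers(5, 30)), int(rng.integers(5, 30))
            scores = rng.normal(size=n_a + n_d)
            labels, recs = {}, []
            for i, s in enumerate(scores):
                mol_id = f"m{i}"
                labels[mol_id] = "active" if i < n_a else "decoy"
                recs.append(ScreenRecord(mol_id, True, fit_score=float(s)))
            auc = enrichment_metrics(recs, labels).auc
            u = mannwhitneyu(scores[:n_a], scores[n_a:],
                             alternative="two-sided").statistic
            assert abs(auc - u / (n_a * n_d)) < 1e-9

    def test_unmatched_rank_after_matched(self):
        recs = [ScreenRecord("a", False), ScreenRecord("b", True, fit_score=1.0)]
        labels = {"a": "decoy", "b": "active"}
        metrics = enrichment_metrics(recs, labels)
        assert metrics.auc == 1.0
        pts = roc_points(recs, labels)
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]

    def test_degenerate_labels_rejected(self):
        recs, labels = records_from_ranking(set(range(5)), 5)
        with pytest.raises(DegenerateLabelsError):
            enrichment_metrics(recs, labels)


class TestExclusionMonotonicity:
    def test_disabling_exclusion_volumes_never_decreases_retrieval(
            self, final_model_result, clean_complex):
        from dynopharm.pharmacophore_build import generate_exclusion_volumes

        traj, _ = clean_complex
        model = final_model_result.model
        model = PharmacophoreModel(
            features=model.features, flags=list(model.flags),
            either_groups=list(model.either_groups),
            exclusion_volumes=generate_exclusion_volumes(traj, model=model))
        mols, labels = generate_screening_library(
            model, LibrarySpec(n_actives=3, decoys_per_active=8,
                               n_feature_matching_decoys=2, seed=5))
        with_ev = screen_library(mols, model, ScreenSettings(), labels=labels)
        without_ev = screen_library(
            mols, model, ScreenSettings(check_exclusion_volumes=False),
            labels=labels)
        n_with = sum(r.matched for r in with_ev)
        n_without = sum(r.matched for r in without_ev)
        assert n_without >= n_with
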