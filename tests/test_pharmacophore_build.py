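"""Model merging, alignment, flags, final model and exclusion volumes."""

import itertools

import numpy as np
import pytest

from dynopharm.errors import InsufficientModelsError, NoModelsError
from dynopharm.feature_perception import ChemFeature, FeatureType
from dynopharm.geometry import apply_transform, kabsch, random_rotation
from dynopharm.pharmacophore_build import (
    ESSENTIAL,
    OPTIONAL,
    FlagsSpec,
    PharmacophoreModel,
    align_models,
    apply_flags,
    build_final_model,
    devectorize,
    generate_exclusion_volumes,
    merge_models,
    signature_of,
)


def feature(ftype, center, radius=1.5, direction=None):
    return ChemFeature(ftype, center, radius, direction=direction)


def single_linkage_oracle(centers, tol):
    """Brute-force union-find single-linkage clustering."""
    n = len(centers)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if np.linalg.norm(centers[i] - centers[j]) <= tol:
            parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


class TestMerge:
    def test_merging_model_with_itself_keeps_feature_count(self, final_model_result):
        model = final_model_result.model
        merged = merge_models([model, model], tol=1.5)
        assert len(merged.features) == len(model.features)

    def test_two_close_hydrophobics_interpolate_to_midpoint(self):
        m1 = PharmacophoreModel(features=[feature(FeatureType.H, (0, 0, 0))])
        m2 = PharmacophoreModel(features=[feature(FeatureType.H, (0.5, 0, 0))])
        merged = merge_models([m1, m2], tol=1.5)
        assert len(merged.features) == 1
        np.testing.assert_allclose(merged.features[0].center, (0.25, 0, 0))

    def test_distinct_types_never_merge(self):
        m = PharmacophoreModel(features=[feature(FeatureType.H, (0, 0, 0)),
                                         feature(FeatureType.PI, (0.1, 0, 0))])
        assert len(merge_models([m], tol=1.5).features) == 2

    def test_matches_brute_force_single_linkage(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 20))
            centers = rng.normal(size=(n, 3)) * 2.0
            model = PharmacophoreModel(
                features=[feature(FeatureType.H, c) for c in centers])
            merged = merge_models([model], tol=1.5)
            assert len(merged.features) == single_linkage_oracle(centers, 1.5)

    def test_order_invariant(self, ligand_models):
        models = list(ligand_models.values())
        a = merge_models(models, tol=1.5)
        b = merge_models(models[::-1], tol=1.5)
        sa = sorted((f.type.value, tuple(np.round(f.center, 6))) for f in a.features)
        sb = sorted((f.type.value, tuple(np.round(f.center, 6))) for f in b.features)
        assert sa == sb

    def test_output_count_bounded_by_input_total(self, ligand_models):
        models = list(ligand_models.values())
        merged = merge_models(models, tol=1.5)
        assert len(merged.features) <= sum(len(m.features) for m in models)

    def test_empty_input_rejected(self):
        with pytest.raises(NoModelsError):
            merge_models([])


class TestDevectorize:
    def test_vector_donors_become_spheres(self):
        model = PharmacophoreModel(features=[
            feature(FeatureType.HBD, (0, 0, 0), direction=(0, 0, 1)),
            feature(FeatureType.HBD, (2, 0, 0), direction=(0, 1, 0)),
            feature(FeatureType.HBD, (0, 2, 0), direction=(1, 0, 0))])
        out = devectorize(model)
        assert len(out.features) == 3
        assert all(f.direction is None for f in out.features)
        for f1, f2 in zip(model.features, out.features):
            np.testing.assert_allclose(f1.center, f2.center)

    def test_sphere_model_unchanged(self):
        model = PharmacophoreModel(features=[feature(FeatureType.H, (1, 2, 3))])
        out = devectorize(model)
        assert out.features[0].direction is None
        np.testing.assert_allclose(out.features[0].center, (1, 2, 3))


def make_model(spec):
    """spec: list of (type, center)."""
    return PharmacophoreModel(features=[feature(t, c) for t, c in spec])


BASE_SPEC = [
    (FeatureType.PI, (0.0, 2.0, 0.0)),
    (FeatureType.H, (2.5, 0.0, -4.0)),
    (FeatureType.AR, (1.5, 0.0, 0.0)),
    (FeatureType.HBD, (3.3, 0.0, 6.0)),
]


class TestAlign:
    def test_exact_recovery_of_transformed_copy(self, rng):
        model = make_model(BASE_SPEC)
        rot = random_rotation(rng)
        trans = rng.normal(scale=6.0, size=3)
        moved = model.transformed(rot, trans)
        result = align_models(model, moved)
        assert result.success
        assert result.n_pairs == len(model.features)
        assert result.rmsd < 1e-6
        assert np.isclose(np.linalg.det(result.rotation), 1.0)
        # success is symmetric for exact copies
        assert align_models(moved, model).success

    def test_different_layout_fails(self):
        reference = make_model(BASE_SPEC)
        # two features only: a different binding mode cannot reach min_pairs
        other = make_model([(FeatureType.PI, (0.0, -2.0, 0.0)),
                            (FeatureType.HBD, (3.3, 0.0, 6.0))])
        result = align_models(reference, other, min_pairs=3)
        assert not result.success
        assert "failed" in result.reason()

    def test_matches_exhaustive_correspondence_oracle(self, rng):
        """Pair count and RMSD equal brute-force enumeration on small models."""
        for trial in range(5):
            spec = [(FeatureType.PI, rng.normal(size=3) * 3),
                    (FeatureType.H, rng.normal(size=3) * 3),
                    (FeatureType.H, rng.normal(size=3) * 3 + 5),
                    (FeatureType.HBD, rng.normal(size=3) * 3)]
            reference = make_model(spec)
            rot = random_rotation(rng)
            trans = rng.normal(scale=4.0, size=3)
            other = reference.transformed(rot, trans)
            result = align_models(reference, other, min_pairs=3, tol=1.5)

            # oracle: enumerate every type-consistent injective mapping of
            # >= 3 features, superpose, count pairs within tol
            best = (0, np.inf)
            n = len(other.features)
            for size in range(3, n + 1):
                for o_sub in itertools.combinations(range(n), size):
                    ref_pool = [[i for i, f in enumerate(reference.features)
                                 if f.type is other.features[j].type] for j in o_sub]
                    for r_sub in itertools.product(*ref_pool):
                        if len(set(r_sub)) != size:
                            continue
                        o_pts = np.array([other.features[j].center for j in o_sub])
                        r_pts = np.array([reference.features[i].center for i in r_sub])
                        try:
                            rr, tt = kabsch(o_pts, r_pts, allow_degenerate=True)
                        except Exception:
                            continue
                        moved = apply_transform(o_pts, rr, tt)
                        d = np.linalg.norm(moved - r_pts, axis=1)
                        if np.all(d <= 1.5):
                            rms = float(np.sqrt(np.mean(d ** 2)))
                            if (size, -rms) > (best[0], -best[1]):
                                best = (size, rms)
            assert result.n_pairs == best[0]
            assert abs(result.rmsd - best[1]) < 1e-6


class TestFlagsAndFinalModel:
    def test_default_flags_two_essential_one_either_group(self):
        model = make_model(BASE_SPEC + [(FeatureType.H, (0.0, 0.0, 3.0)),
                                        (FeatureType.H, (-2.0, 1.0, 0.0))])
        flagged = apply_flags(model, FlagsSpec())
        assert flagged.flags.count(ESSENTIAL) == 2
        assert len(flagged.either_groups) == 1
        essential_types = {flagged.features[i].type
                           for i in flagged.essential_indices}
        assert essential_types == {FeatureType.PI, FeatureType.H}
        # either-group members are flagged optional individually
        for g in flagged.either_groups:
            for i in g:
                assert flagged.flags[i] == OPTIONAL

    def test_four_alignable_models_build_without_exclusions(self, ligand_models):
        models = [m for n, m in ligand_models.items() if n != "quinidine-like"]
        result = build_final_model(models)
        assert result.excluded == []
        assert all(f.direction is None for f in result.model.features)

    def test_unalignable_model_excluded_with_reason(self, final_model_result):
        assert len(final_model_result.excluded) == 1
        name, reason = final_model_result.excluded[0]
        assert name == "quinidine-like"
        assert "alignment failed" in reason

    def test_fewer_than_two_models_rejected(self, ligand_models):
        with pytest.raises(InsufficientModelsError):
            build_final_model([ligand_models["astemizole-like"]])


class TestExclusionVolumes:
    def test_zero_margin_empty(self, clean_complex):
        traj, _ = clean_complex
        assert generate_exclusion_volumes(traj, ligand_margin=0.0) == []

    def test_spheres_keep_clearance_from_features(self, clean_complex,
                                                  final_model_result):
        traj, _ = clean_complex
        model = final_model_result.model
        volumes = generate_exclusion_volumes(traj, model=model,
                                             feature_clearance=2.0)
        assert volumes
        centers = np.array([f.center for f in model.features])
        for pos, _radius in volumes:
            assert np.linalg.norm(centers - pos, axis=1).min() > 2.0

    def test_matches_brute_force_lining_atom_count(self, clean_complex):
        traj, _ = clean_complex
        margin = 8.0
        volumes = generate_exclusion_volumes(traj, ligand_margin=margin)
        mean = traj.coords.mean(axis=0)
        lig = mean[traj.ligand_indices]
        expected = 0
        for i in traj.protein_indices:
            if traj.atom_table[i].element.upper() == "H":
                continue
            if np.linalg.norm(lig - mean[i], axis=1).min() <= margin:
                expected += 1
        assert len(volumes) == expected


def test_signature_is_order_independent():
    f1 = ChemFeature(FeatureType.H, (0, 0, 0), 1.5, partner=("D", 465, "ALA"))
    f2 = ChemFeature(FeatureType.HBD, (1, 0, 0), 1.5, partner=("B", 436, "SER"))
    assert signature_of([f1, f2]) == signature_of([f2, f1])
    assert signature_of([f1, f2]) == (("H", "D", 465), ("HBD", "B", 436))
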