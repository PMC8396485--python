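"""Merging, aligning and finalizing dynamic pharmacophore models.

The model-building workflow mirrors common practice for MD-derived
("dynamic") pharmacophores of a symmetric channel pore:

1. per-ligand models are merged by interpolating overlapping same-type
   features (single-linkage clustering of feature centers);
2. merged models from different ligands are aligned by their feature
   geometry; a model whose feature layout cannot be superposed onto the
   others (different binding mode) is excluded, with the failure reported;
3. vector features are converted to plain spheres ("devectorized");
4. essential/optional flags are applied, including an either/or pair of
   hydrophobic features of which exactly one must match;
5. exclusion volumes are generated from the time-averaged positions of
   pocket-lining protein heavy atoms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientModelsError, NoModelsError
from .feature_perception import ChemFeature, FeatureType
from .geometry import apply_transform, kabsch

ESSENTIAL = "essential"
OPTIONAL = "optional"


def signature_of(features: Sequence[ChemFeature]) -> tuple:
    """Canonical, order-independent signature of an interaction set.

    Each feature contributes ``(type, chain, resid)`` from its protein
    partner; the tuple is sorted so that signature equality means equality
    of the interaction sets.
    """
    items = []
    for f in features:
        chain, resid = ("", -1) if f.partner is None else (f.partner[0], f.partner[1])
        items.append((f.type.value, chain, resid))
    return tuple(sorted(set(items)))


@dataclass
class PharmacophoreModel:
    """Features plus exclusion volumes, flags and either/or groups."""

    features: list[ChemFeature] = field(default_factory=list)
    exclusion_volumes: list[tuple] = field(default_factory=list)  # (center, radius)
    flags: list[str] = field(default_factory=list)
    either_groups: list[tuple] = field(default_factory=list)  # pairs of feature indices
    name: str = ""

    def __post_init__(self):
        if not self.flags:
            self.flags = [OPTIONAL] * len(self.features)
        if len(self.flags) != len(self.features):
            raise ValueError("flags must match features one-to-one")

    @property
    def signature(self) -> tuple:
        return signature_of(self.features)

    @property
    def essential_indices(self) -> list[int]:
        return [i for i, f in enumerate(self.flags) if f == ESSENTIAL]

    def features_of_type(self, ftype: FeatureType) -> list[int]:
        return [i for i, f in enumerate(self.features) if f.type is ftype]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PharmacophoreModel":
        return replace(
            self,
            features=[f.transformed(rotation, translation) for f in self.features],
            exclusion_volumes=[(rotation @ c + translation, r)
                               for c, r in self.exclusion_volumes],
        )


def frame_pharmacophore(records, lig_features=None) -> PharmacophoreModel:
    """Build the per-frame model from that frame's interaction records.

    One feature per record, placed at the ligand-side feature center and
    typed by the interaction; the model's signature identifies the
    interaction set for uniqueness counting.
    """
    features = [
        replace(r.ligand_feature, type=r.type, partner=r.residue) for r in records
    ]
    return PharmacophoreModel(features=features)


# ---------------------------------------------------------------------------
# merging


def _single_linkage_clusters(centers: np.ndarray, tol: float) -> list[list[int]]:
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    n = len(centers)
    if n == 1:
        return [[0]]
    labels = fcluster(linkage(pdist(centers), method="single"), t=tol,
                      criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(i)
    return sorted(clusters.values(), key=lambda c: min(c))


def merge_models(models: Sequence[PharmacophoreModel], tol: float = 1.5) -> PharmacophoreModel:
    """Interpolate overlapping same-type features across models.

    Single-linkage clusters of same-type features whose centers are within
    ``tol`` Å are replaced by one feature at the cluster centroid with radius
    ``max(member radii, cluster spread)``. Features of distinct type never
    merge. Deterministic and invariant to input-model order.
    """
    if not models:
        raise NoModelsError("merge_models needs at least one model")
    pooled = [f for m in models for f in m.features]
    merged: list[ChemFeature] = []
    for ftype in FeatureType:
        members = [f for f in pooled if f.type is ftype]
        # sort for order-invariance of the clustering input
        members.sort(key=lambda f: tuple(np.round(f.center, 6)))
        if not members:
            continue
        centers = np.array([f.center for f in members])
        for cluster in _single_linkage_clusters(centers, tol):
            feats = [members[i] for i in cluster]
            center = np.mean([f.center for f in feats], axis=0)
            spread = max(float(np.linalg.norm(f.center - center)) for f in feats)
            radius = max(max(f.radius for f in feats), spread)
            direction = None
            if all(f.direction is not None for f in feats):
                ref = feats[0].direction
                acc = np.zeros(3)
                for f in feats:
                    d = f.direction if np.dot(f.direction, ref) >= 0 else -f.direction
                    acc += d
                nrm = np.linalg.norm(acc)
                direction = acc / nrm if nrm > 0 else None
            partners = {f.partner for f in feats}
            partner = feats[0].partner if len(partners) == 1 else None
            merged.append(ChemFeature(ftype, center, radius, direction=direction,
                                      partner=partner))
    exclusion = [ev for m in models for ev in m.exclusion_volumes]
    return PharmacophoreModel(features=merged, exclusion_volumes=exclusion)


def devectorize(model: PharmacophoreModel) -> PharmacophoreModel:
    """Convert all vector features to plain sphere features (drop directions)."""
    return replace(model, features=[replace(f, direction=None) for f in model.features])


# ---------------------------------------------------------------------------
# model alignment


@dataclass
class AlignmentResult:
    success: bool
    rotation: Optional[np.ndarray]
    translation: Optional[np.ndarray]
    pairs: list[tuple]  # (reference feature index, other feature index)
    rmsd: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def reason(self) -> str:
        if self.success:
            return "aligned"
        return f"alignment failed: {self.n_pairs} paired feature(s), rmsd {self.rmsd:.2f} Å"


def _mutual_nearest_pairs(ref_model, other_model, rot, trans, tol):
    """Greedy mutually-nearest same-type pairing within ``tol`` after transform."""
    moved = [apply_transform(f.center[None, :], rot, trans)[0]
             for f in other_model.features]
    candidates = []
    for i, rf in enumerate(ref_model.features):
        for j, of in enumerate(other_model.features):
            if rf.type is not of.type:
                continue
            d = float(np.linalg.norm(rf.center - moved[j]))
            if d <= tol:
                candidates.append((d, i, j))
    candidates.sort()
    used_i, used_j, pairs = set(), set(), []
    for d, i, j in candidates:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append((i, j))
    return pairs


def align_models(reference: PharmacophoreModel, other: PharmacophoreModel,
                 min_pairs: int = 3, tol: float = 1.5) -> AlignmentResult:
    """Rigidly align ``other`` onto ``reference`` by feature correspondence.

    Seed correspondences are type-compatible feature triplets (required to
    include the positive-ionizable feature when both models have one),
    superposed by a Kabsch fit and greedily extended with mutually-nearest
    same-type pairs within ``tol``. The best result by (pair count, lowest
    RMSD) is returned; success requires at least ``min_pairs`` pairs and a
    paired-feature RMSD of at most ``tol``. Failure is a result, not an error.
    """
    best: Optional[AlignmentResult] = None
    ref_pi = reference.features_of_type(FeatureType.PI)
    oth_pi = other.features_of_type(FeatureType.PI)
    require_pi = bool(ref_pi) and bool(oth_pi)

    def candidate_ref_triples(o_triple):
        types = [other.features[j].type for j in o_triple]
        pools = [[i for i, f in enumerate(reference.features) if f.type is t]
                 for t in types]
        for combo in itertools.product(*pools):
            if len(set(combo)) != 3:
                continue
            yield combo

    n_other = len(other.features)
    for o_triple in itertools.combinations(range(n_other), 3):
        if require_pi and not any(j in oth_pi for j in o_triple):
            continue
        o_pts = np.array([other.features[j].center for j in o_triple])
        o_d = [np.linalg.norm(o_pts[a] - o_pts[b]) for a, b in ((0, 1), (0, 2), (1, 2))]
        for r_triple in candidate_ref_triples(o_triple):
            if require_pi and not any(i in ref_pi for i in r_triple):
                continue
            r_pts = np.array([reference.features[i].center for i in r_triple])
            r_d = [np.linalg.norm(r_pts[a] - r_pts[b])
                   for a, b in ((0, 1), (0, 2), (1, 2))]
            if any(abs(a - b) > 2 * tol for a, b in zip(o_d, r_d)):
                continue
            rot, trans = kabsch(o_pts, r_pts, allow_degenerate=True)
            pairs = _mutual_nearest_pairs(reference, other, rot, trans, tol)
            if len(pairs) < 3:
                continue
            # refit on all paired centers
            o_all = np.array([other.features[j].center for _, j in pairs])
            r_all = np.array([reference.features[i].center for i, _ in pairs])
            rot, trans = kabsch(o_all, r_all, allow_degenerate=True)
            pairs = _mutual_nearest_pairs(reference, other, rot, trans, tol)
            if not pairs:
                continue
            o_all = np.array([other.features[j].center for _, j in pairs])
            r_all = np.array([reference.features[i].center for i, _ in pairs])
            moved = apply_transform(o_all, rot, trans)
            rms = float(np.sqrt(np.mean(np.sum((moved - r_all) ** 2, axis=1))))
            cand = AlignmentResult(
                success=(len(pairs) >= min_pairs and rms <= tol),
                rotation=rot, translation=trans, pairs=pairs, rmsd=rms)
            if best is None or (cand.n_pairs, -cand.rmsd) > (best.n_pairs, -best.rmsd):
                best = cand
    if best is None:
        return AlignmentResult(False, None, None, [], float("inf"))
    return best


# ---------------------------------------------------------------------------
# flags and the final model


@dataclass
class FlagsSpec:
    """Declarative essential/optional assignment for the final model.

    Defaults encode the usual pore-blocker layout: the positive-ionizable
    feature and the hydrophobic feature closest to it are essential; the
    next two hydrophobic features form an either/or pair (exactly one must
    match, covering ligands that do or do not reach a side pocket); all
    remaining features are optional.
    """

    essential_types: tuple = (FeatureType.PI,)
    n_essential_hydrophobic: int = 1
    hydrophobic_either_pair: bool = True


def apply_flags(model: PharmacophoreModel, spec: Optional[FlagsSpec] = None) -> PharmacophoreModel:
    spec = spec or FlagsSpec()
    flags = [OPTIONAL] * len(model.features)
    either: list[tuple] = []
    for i, f in enumerate(model.features):
        if f.type in spec.essential_types:
            flags[i] = ESSENTIAL
    pi_idx = model.features_of_type(FeatureType.PI)
    if pi_idx:
        anchor = np.mean([model.features[i].center for i in pi_idx], axis=0)
    elif model.features:
        anchor = np.mean([f.center for f in model.features], axis=0)
    else:
        anchor = np.zeros(3)
    h_idx = sorted(model.features_of_type(FeatureType.H),
                   key=lambda i: float(np.linalg.norm(model.features[i].center - anchor)))
    for i in h_idx[: spec.n_essential_hydrophobic]:
        flags[i] = ESSENTIAL
    rest = h_idx[spec.n_essential_hydrophobic:]
    if spec.hydrophobic_either_pair and len(rest) >= 2:
        either.append((rest[0], rest[1]))
    return replace(model, flags=flags, either_groups=either)


@dataclass
class FinalModelResult:
    model: PharmacophoreModel
    excluded: list[tuple]  # (model name or index, reason)
    alignments: list[AlignmentResult]


def build_final_model(merged_models: Sequence[PharmacophoreModel],
                      flags_spec: Optional[FlagsSpec] = None,
                      min_pairs: int = 3, align_tol: float = 1.5,
                      merge_tol: float = 1.5) -> FinalModelResult:
    """Align per-ligand merged models, merge, devectorize and flag.

    All models are aligned onto the first; un-alignable models are excluded
    and reported with the failure reason. Raises
    :class:`InsufficientModelsError` when fewer than two models align.
    """
    if len(merged_models) < 2:
        raise InsufficientModelsError("need at least two merged models")
    reference = merged_models[0]
    aligned = [reference]
    excluded: list[tuple] = []
    alignments: list[AlignmentResult] = []
    for k, model in enumerate(merged_models[1:], start=1):
        result = align_models(reference, model, min_pairs=min_pairs, tol=align_tol)
        alignments.append(result)
        if result.success:
            aligned.append(model.transformed(result.rotation, result.translation))
        else:
            excluded.append((model.name or f"model-{k}", result.reason()))
    if len(aligned) < 2:
        raise InsufficientModelsError(
            "fewer than two alignable models; excluded: "
            + "; ".join(f"{n} ({r})" for n, r in excluded))
    final = devectorize(merge_models(aligned, tol=merge_tol))
    final = apply_flags(final, flags_spec)
    return FinalModelResult(model=final, excluded=excluded, alignments=alignments)


# ---------------------------------------------------------------------------
# exclusion volumes


def generate_exclusion_volumes(traj, window=None, ligand_margin: float = 8.0,
                               radius: float = 1.2,
                               model: Optional[PharmacophoreModel] = None,
                               feature_clearance: float = 2.0) -> list[tuple]:
    """Exclusion spheres from time-averaged pocket-lining heavy atoms.

    One sphere per protein heavy atom whose mean position over the frame
    window lies within ``ligand_margin`` Å of any ligand atom's mean
    position; atoms within ``feature_clearance`` Å of a model feature center
    are skipped so spheres never sit on a feature.
    """
    from .interaction_analysis import resolve_window

    lo, hi = resolve_window(traj.n_frames, window)
    mean_coords = traj.coords[lo:hi].mean(axis=0)
    lig_idx = traj.ligand_indices
    prot_idx = [i for i in traj.protein_indices
                if traj.atom_table[i].element.upper() != "H"]
    if len(lig_idx) == 0 or not prot_idx:
        return []
    lig_mean = mean_coords[lig_idx]
    feature_centers = (np.array([f.center for f in model.features])
                       if model is not None and model.features else None)
    volumes = []
    for i in prot_idx:
        pos = mean_coords[i]
        if np.linalg.norm(lig_mean - pos, axis=1).min() > ligand_margin:
            continue
        if feature_centers is not None and \
                np.linalg.norm(feature_centers - pos, axis=1).min() <= feature_clearance:
            continue
        volumes.append((pos.copy(), radius))
    return volumes
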