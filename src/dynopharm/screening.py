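"""Pharmacophore virtual screening and retrieval statistics.

Matching follows retrieval-style semantics: a library conformer matches a
model when a rigid placement exists under which every essential feature
(and exactly one member of each either/or pair) is satisfied by a same-type
conformer feature inside the model feature's tolerance sphere, with zero
omitted query features by default, and no conformer heavy atom inside an
exclusion volume. Matched molecules are ranked by a pharmacophore-fit score

    S = w_match * M - w_rmsd * RMSD_feat        (defaults 10 and 3)

with M the number of matched feature pairs and RMSD_feat the RMS of the
paired center distances after placement. The validated contract is the
relative ranking, not the absolute score.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import DegenerateLabelsError
from .feature_perception import ChemFeature, FeatureType, perceive_ligand_features
from .geometry import apply_transform, kabsch
from .pharmacophore_build import ESSENTIAL, PharmacophoreModel

log = logging.getLogger(__name__)


@dataclass
class ScreenSettings:
    """Screening behaviour: match-all-essential, zero omitted features."""

    max_omitted_features: int = 0
    check_exclusion_volumes: bool = True
    stop_after_first_match: bool = True
    w_match: float = 10.0
    w_rmsd: float = 3.0

    def __post_init__(self):
        if self.max_omitted_features < 0:
            raise ValueError("max_omitted_features must be >= 0")


@dataclass
class MatchResult:
    rotation: np.ndarray
    translation: np.ndarray
    pairs: list[tuple]  # (model feature index, conformer feature index)
    fit_score: float
    rmsd_feat: float


@dataclass
class ScreenRecord:
    molecule_id: str
    matched: bool
    fit_score: Optional[float] = None
    conformer: Optional[int] = None
    pairs: list = field(default_factory=list)
    label: Optional[str] = None


def _required_sets(model: PharmacophoreModel, settings: ScreenSettings):
    """Yield (required indices, forbidden indices) per either-group choice.

    ``forbidden`` holds the unchosen member of each either/or pair so that
    exactly one member of the pair ends up in the matched set.
    """
    essential = [i for i in model.essential_indices
                 if not any(i in g for g in model.either_groups)]
    if not essential and not model.either_groups:
        # an unflagged model means "match all query features"
        essential = list(range(len(model.features)))
    if not model.either_groups:
        yield list(essential), set()
        return
    for choice in itertools.product(*[list(g) for g in model.either_groups]):
        forbidden = {m for g, c in zip(model.either_groups, choice)
                     for m in g if m != c}
        yield essential + list(choice), forbidden


def _assign_required(model, conf_features, rot, trans, required):
    """Optimal per-type assignment of required model features to conformer
    features within their radii; returns pairs or None if infeasible."""
    moved = np.array([apply_transform(f.center[None, :], rot, trans)[0]
                      for f in conf_features])
    pairs = []
    used = set()
    by_type: dict[FeatureType, list[int]] = {}
    for i in required:
        by_type.setdefault(model.features[i].type, []).append(i)
    for ftype, midx in sorted(by_type.items(), key=lambda kv: kv[0].value):
        cidx = [j for j, f in enumerate(conf_features)
                if f.type is ftype and j not in used]
        if len(cidx) < len(midx):
            return None
        cost = np.full((len(midx), len(cidx)), 1e6)
        for a, i in enumerate(midx):
            mf = model.features[i]
            for b, j in enumerate(cidx):
                d = float(np.linalg.norm(mf.center - moved[j]))
                if d <= mf.radius:
                    cost[a, b] = d
        rows, cols = linear_sum_assignment(cost)
        if np.any(cost[rows, cols] >= 1e6):
            return None
        for a, b in zip(rows, cols):
            pairs.append((midx[a], cidx[b]))
            used.add(cidx[b])
    return pairs


def _extend_optional(model, conf_features, rot, trans, pairs, forbidden):
    moved = np.array([apply_transform(f.center[None, :], rot, trans)[0]
                      for f in conf_features])
    used_m = {i for i, _ in pairs}
    used_c = {j for _, j in pairs}
    candidates = []
    for i, mf in enumerate(model.features):
        if i in used_m or i in forbidden:
            continue
        for j, cf in enumerate(conf_features):
            if j in used_c or cf.type is not mf.type:
                continue
            d = float(np.linalg.norm(mf.center - moved[j]))
            if d <= mf.radius:
                candidates.append((d, i, j))
    candidates.sort()
    for d, i, j in candidates:
        if i in used_m or j in used_c:
            continue
        pairs.append((i, j))
        used_m.add(i)
        used_c.add(j)
    return pairs


def match_conformer(features: Sequence[ChemFeature], model: PharmacophoreModel,
                    settings: Optional[ScreenSettings] = None,
                    heavy_coords: Optional[np.ndarray] = None,
                    ) -> Optional[MatchResult]:
    """Find a rigid placement of a conformer that satisfies the model.

    ``features`` are the conformer's perceived features; ``heavy_coords``
    (n, 3) are its heavy-atom coordinates, used for the exclusion-volume
    check when enabled. Returns the best-scoring match, or ``None`` — no
    match is a valid outcome, not an error.
    """
    settings = settings or ScreenSettings()
    best: Optional[MatchResult] = None
    n_feat = len(model.features)
    if n_feat == 0:
        return None

    for required, forbidden in _required_sets(model, settings):
        # seed sets: triplets from the required features, padded with other
        # model features when fewer than three are required
        if len(required) >= 3:
            seed_sets = list(itertools.combinations(sorted(required), 3))
        else:
            others = [i for i in range(n_feat)
                      if i not in required and i not in forbidden]
            seed_sets = [tuple(sorted(set(required) | set(extra)))
                         for extra in itertools.combinations(others, 3 - len(required))]
            # fallback: fit on the required features alone (degenerate
            # 1-2-point superposition), for conformers lacking optional types
            seed_sets.append(tuple(sorted(required)))
        for seed in seed_sets:
            m_pts = np.array([model.features[i].center for i in seed])
            pools = []
            for i in seed:
                pools.append([j for j, f in enumerate(features)
                              if f.type is model.features[i].type])
            for combo in itertools.product(*pools):
                if len(set(combo)) != len(combo):
                    continue
                c_pts = np.array([features[j].center for j in combo])
                ok = True
                for (a, b) in itertools.combinations(range(len(seed)), 2):
                    dm = np.linalg.norm(m_pts[a] - m_pts[b])
                    dc = np.linalg.norm(c_pts[a] - c_pts[b])
                    tol_ab = model.features[seed[a]].radius + model.features[seed[b]].radius
                    if abs(dm - dc) > tol_ab:
                        ok = False
                        break
                if not ok:
                    continue
                rot, trans = kabsch(c_pts, m_pts, allow_degenerate=True)
                pairs = _assign_required(model, features, rot, trans, required)
                if pairs is None:
                    continue
                # refit on the required pairs, then re-verify and extend
                c_all = np.array([features[j].center for _, j in pairs])
                m_all = np.array([model.features[i].center for i, _ in pairs])
                if len(pairs) >= 3:
                    rot, trans = kabsch(c_all, m_all, allow_degenerate=True)
                    pairs = _assign_required(model, features, rot, trans, required)
                    if pairs is None:
                        continue
                pairs = _extend_optional(model, features, rot, trans, pairs, forbidden)
                if settings.check_exclusion_volumes and model.exclusion_volumes \
                        and heavy_coords is not None and len(heavy_coords):
                    moved_atoms = apply_transform(heavy_coords, rot, trans)
                    clash = False
                    for center, radius in model.exclusion_volumes:
                        if np.linalg.norm(moved_atoms - center, axis=1).min() < radius:
                            clash = True
                            break
                    if clash:
                        continue
                moved = np.array([apply_transform(features[j].center[None, :],
                                                  rot, trans)[0] for _, j in pairs])
                targets = np.array([model.features[i].center for i, _ in pairs])
                rmsd_feat = float(np.sqrt(np.mean(np.sum((moved - targets) ** 2, axis=1))))
                score = settings.w_match * len(pairs) - settings.w_rmsd * rmsd_feat
                if best is None or score > best.fit_score:
                    best = MatchResult(rot, trans, pairs, score, rmsd_feat)
    return best


def screen_library(library, model: PharmacophoreModel,
                   settings: Optional[ScreenSettings] = None,
                   labels: Optional[dict] = None) -> list[ScreenRecord]:
    """Screen a conformer library against a pharmacophore model.

    Conformers are tried in order; with ``stop_after_first_match`` the first
    matching conformer is recorded. Molecules without conformers are
    unmatched (warned). Deterministic given input order.
    """
    settings = settings or ScreenSettings()
    records = []
    for mol in library:
        label = labels.get(mol.id) if labels else None
        if mol.n_conformers == 0:
            log.warning("molecule %s has no conformers; recorded as unmatched", mol.id)
            records.append(ScreenRecord(mol.id, False, label=label))
            continue
        best: Optional[MatchResult] = None
        best_conf = None
        heavy = [i for i, (el, _q) in enumerate(mol.atoms) if el != "H"]
        for c in range(mol.n_conformers):
            features = perceive_ligand_features(mol, c)
            coords = mol.conformer(c)[heavy]
            result = match_conformer(features, model, settings, heavy_coords=coords)
            if result is not None:
                if best is None or result.fit_score > best.fit_score:
                    best, best_conf = result, c
                if settings.stop_after_first_match:
                    break
        if best is None:
            records.append(ScreenRecord(mol.id, False, label=label))
        else:
            records.append(ScreenRecord(mol.id, True, best.fit_score, best_conf,
                                        list(best.pairs), label=label))
    return records


# ---------------------------------------------------------------------------
# retrieval metrics


@dataclass
class EnrichmentMetrics:
    auc: float
    ef: dict  # fraction -> enrichment factor
    tp: int   # actives retrieved at full retrieval
    fp: int   # decoys retrieved at full retrieval
    n_actives: int
    n: int

    @property
    def n_decoys(self) -> int:
        return self.n - self.n_actives


def ranked_records(records: Sequence[ScreenRecord]) -> list[ScreenRecord]:
    """Matched first by descending fit score (stable), unmatched after."""
    matched = [r for r in records if r.matched]
    unmatched = [r for r in records if not r.matched]
    matched.sort(key=lambda r: -r.fit_score)
    return matched + unmatched


def enrichment_metrics(records: Sequence[ScreenRecord],
                       labels: Optional[dict] = None,
                       fractions: Sequence[float] = (0.01,)) -> EnrichmentMetrics:
    """ROC AUC and enrichment factors from labelled screen records.

    EF_f = (a_f / n_f) / (A / N) with n_f = max(1, floor(f*N)) and a_f the
    actives among the top n_f ranked compounds. The AUC is the area under
    the ROC curve traced by walking the full ranked list (unmatched
    molecules rank last, in stable input order).
    """

    def label_of(r: ScreenRecord) -> str:
        if labels is not None and r.molecule_id in labels:
            return labels[r.molecule_id]
        if r.label is None:
            raise DegenerateLabelsError(f"record {r.molecule_id} is unlabelled")
        return r.label

    is_active = [label_of(r) == "active" for r in ranked_records(records)]
    n = len(is_active)
    a = sum(is_active)
    if a == 0 or a == n:
        raise DegenerateLabelsError("need both actives and decoys")
    ef = {}
    for f in fractions:
        n_f = max(1, int(np.floor(f * n)))
        a_f = sum(is_active[:n_f])
        ef[f] = (a_f / n_f) / (a / n)
    tp_run = 0
    area = 0
    for active in is_active:
        if active:
            tp_run += 1
        else:
            area += tp_run
    auc = area / (a * (n - a))
    ranked = ranked_records(records)
    tp = sum(1 for r, act in zip(ranked, is_active) if r.matched and act)
    fp = sum(1 for r, act in zip(ranked, is_active) if r.matched and not act)
    return EnrichmentMetrics(auc=float(auc), ef=ef, tp=tp, fp=fp, n_actives=a, n=n)


def roc_points(records: Sequence[ScreenRecord], labels: Optional[dict] = None) -> np.ndarray:
    """(FPR, TPR) points along the ranked list, for plotting/export."""

    def label_of(r):
        if labels is not None and r.molecule_id in labels:
            return labels[r.molecule_id]
        return r.label

    ranked = ranked_records(records)
    is_active = np.array([label_of(r) == "active" for r in ranked])
    a = is_active.sum()
    d = len(is_active) - a
    tpr = np.concatenate([[0.0], np.cumsum(is_active) / max(a, 1)])
    fpr = np.concatenate([[0.0], np.cumsum(~is_active) / max(d, 1)])
    return np.column_stack([fpr, tpr])
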