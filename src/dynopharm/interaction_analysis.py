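"""Frame-wise ligand–protein interaction detection and occurrence statistics.

Each trajectory frame is reduced to a set of interaction records
(hydrophobic, aromatic, H-bond donor/acceptor, cation-pi — reported under
the positive-ionizable class — and halogen bond), each tied to a protein
residue. Per-frame records feed three aggregations:

* the occurrence table: percent of analyzed frames in which each
  (residue, interaction type) occurs;
* the per-frame pharmacophore model and its canonical signature;
* the unique-model histogram from which the most frequent models are
  selected and given representative (per-feature centroid) geometry.

All geometric thresholds live in :class:`GeometricRules` and default to
standard interaction-geometry survey values.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyWindowError
from .feature_perception import (
    ChemFeature,
    FeatureType,
    GroupKind,
    ResidueGroupTopology,
    centroid,
    perceive_ligand_features,
    plane_normal,
    residue_group_topologies,
)
from .pharmacophore_build import PharmacophoreModel, frame_pharmacophore, signature_of

log = logging.getLogger(__name__)


@dataclass
class GeometricRules:
    """Distance/angle thresholds for interaction detection (Å, degrees)."""

    hbond_dist_max: float = 3.5
    hbond_angle_min: float = 130.0
    hydrophobic_dist_max: float = 4.5
    aromatic_centroid_max: float = 5.5
    parallel_angle_max: float = 30.0
    tshape_angle_min: float = 60.0
    cation_pi_max: float = 6.0
    halogen_dist_max: float = 3.8
    halogen_angle_min: float = 140.0
    ionic_dist_max: float = 5.5

    def __post_init__(self):
        for name in ("hbond_angle_min", "parallel_angle_max",
                     "tshape_angle_min", "halogen_angle_min"):
            v = getattr(self, name)
            if not 0 <= v <= 180:
                raise ValueError(f"{name} must be within [0, 180]")
        for name in ("hbond_dist_max", "hydrophobic_dist_max",
                     "aromatic_centroid_max", "cation_pi_max",
                     "halogen_dist_max", "ionic_dist_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class InteractionRecord:
    frame_index: int
    type: FeatureType
    ligand_feature: ChemFeature
    residue: tuple  # (chain, resid, resname)


def resolve_window(n_frames: int, window) -> tuple[int, int]:
    """Normalize a frame window to a half-open index range ``(lo, hi)``."""
    if window is None:
        lo, hi = 0, n_frames
    else:
        lo, hi = int(window[0]), int(window[1])
    if lo < 0 or hi > n_frames or hi <= lo:
        raise EmptyWindowError(f"window {window!r} is empty for {n_frames} frames")
    return lo, hi


def last_fraction_window(n_frames: int, frac: float) -> tuple[int, int]:
    """The trailing ``frac`` of the trajectory (e.g. the last 20% of frames,
    corresponding to the last 20 ns of a 100 ns run)."""
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    lo = n_frames - max(1, int(round(frac * n_frames)))
    return max(lo, 0), n_frames


# ---------------------------------------------------------------------------
# ligand feature template: perceive once, re-realize geometry per frame


@dataclass
class _LigandFeatureSlot:
    type: FeatureType
    atom_indices: tuple   # trajectory atom indices defining the center
    h_index: Optional[int] = None      # donor hydrogen (HBD)
    carbon_index: Optional[int] = None  # C of a C-X halogen-bond donor
    radius: float = 1.5


class LigandFeatureTemplate:
    """Frame-independent ligand feature topology.

    Features are perceived once on the ligand's bonded template molecule;
    per-frame geometry (centroids, ring normals, donor H directions) is then
    recomputed directly from the frame coordinate array.
    """

    def __init__(self, slots: list[_LigandFeatureSlot]):
        self.slots = slots

    @classmethod
    def from_molecule(cls, mol, ligand_indices: Sequence[int],
                      conformer: int = 0) -> "LigandFeatureTemplate":
        lig_idx = np.asarray(ligand_indices, int)
        feats = perceive_ligand_features(mol, conformer)
        slots = []
        for f in feats:
            src = tuple(int(lig_idx[i]) for i in f.source_atoms)
            h_index = carbon_index = None
            if f.type is FeatureType.HBD and len(f.source_atoms) > 1:
                h_index = src[1]
                src = (src[0],)
            elif f.type is FeatureType.XBD:
                carbon_index = src[0]
                src = (src[1],)
            slots.append(_LigandFeatureSlot(f.type, src, h_index, carbon_index,
                                            radius=f.radius))
        return cls(slots)

    def realize(self, coords: np.ndarray) -> list[ChemFeature]:
        out = []
        for s in self.slots:
            pts = coords[list(s.atom_indices)]
            center = pts.mean(axis=0)
            direction = None
            source = s.atom_indices
            if s.type is FeatureType.AR:
                direction = plane_normal(pts)
            elif s.type is FeatureType.HBD and s.h_index is not None:
                direction = coords[s.h_index] - center
                source = s.atom_indices + (s.h_index,)
            elif s.type is FeatureType.XBD and s.carbon_index is not None:
                direction = center - coords[s.carbon_index]
                source = (s.carbon_index,) + s.atom_indices
            out.append(ChemFeature(s.type, center, s.radius, direction=direction,
                                   source_atoms=source))
        return out


def _infer_ligand_template(traj) -> "object":
    """Fallback bonded template from ligand geometry (covalent-radius bonds).

    Used only when the trajectory carries no explicit ligand molecule;
    aromaticity is assigned geometrically to planar 5/6-rings of C/N.
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    from .feature_perception import ring_planarity_rms
    from .io_structures import Molecule

    covalent = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
                "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39, "P": 1.07}
    lig_idx = traj.ligand_indices
    atoms = [traj.atom_table[i] for i in lig_idx]
    coords = traj.coords[0][lig_idx]
    rw = Chem.RWMol()
    for a in atoms:
        rw.AddAtom(Chem.Atom(a.element))
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            d = np.linalg.norm(coords[i] - coords[j])
            cutoff = covalent.get(atoms[i].element, 0.8) + \
                covalent.get(atoms[j].element, 0.8) + 0.45
            if d > cutoff:
                continue
            pair = {atoms[i].element, atoms[j].element}
            # short C-O contacts are carbonyls; PDB carries no bond orders
            order = Chem.BondType.DOUBLE if pair == {"C", "O"} and d <= 1.30 \
                else Chem.BondType.SINGLE
            rw.AddBond(i, j, order)
    for atom in rw.GetAtoms():
        if atom.GetSymbol() == "N" and atom.GetDegree() == 4:
            atom.SetFormalCharge(1)  # quaternary / protonated nitrogen
        atom.SetNoImplicit(True)
    conf = Chem.Conformer(len(atoms))
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    rw.AddConformer(conf)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_SYMMRINGS
                     | Chem.SanitizeFlags.SANITIZE_SETHYBRIDIZATION)
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) in (5, 6) and \
                all(mol.GetAtomWithIdx(i).GetSymbol() in ("C", "N") for i in ring) and \
                ring_planarity_rms(coords[list(ring)]) <= 0.2:
            for i in ring:
                mol.GetAtomWithIdx(i).SetIsAromatic(True)
            for i in range(len(ring)):
                b = mol.GetBondBetweenAtoms(ring[i], ring[(i + 1) % len(ring)])
                b.SetIsAromatic(True)
    return Molecule("LIG", mol)


# ---------------------------------------------------------------------------
# per-frame detection


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u = a - vertex
    v = b - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    cosang = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    return float(np.degrees(np.arccos(cosang)))


def detect_frame_interactions(frame, lig_features: Sequence[ChemFeature],
                              protein_groups, rules: Optional[GeometricRules] = None,
                              ) -> list[InteractionRecord]:
    """Detect all ligand–protein interactions of one frame.

    ``lig_features`` and ``protein_groups`` must come from the same frame.
    An empty result is valid.
    """
    rules = rules or GeometricRules()
    coords = frame.coords if hasattr(frame, "coords") else None
    frame_index = frame.index if hasattr(frame, "index") else 0
    records: list[InteractionRecord] = []

    def group_atom_coords(g):
        if coords is not None:
            return coords[list(g.atom_indices)]
        return np.atleast_2d(g.center)

    for lf in lig_features:
        for g in protein_groups:
            if lf.type is FeatureType.HBD and g.kind is GroupKind.ACCEPTOR:
                for apos in group_atom_coords(g):
                    d = np.linalg.norm(lf.center - apos)
                    if d > rules.hbond_dist_max:
                        continue
                    if lf.direction is not None:
                        # true H position when the frame carries it, else an
                        # idealized 1.0 Å N/O-H bond along the direction
                        if coords is not None and len(lf.source_atoms) > 1:
                            hpos = coords[lf.source_atoms[-1]]
                        else:
                            hpos = lf.center + lf.direction * 1.0
                        if _angle_deg(lf.center, hpos, apos) < rules.hbond_angle_min:
                            continue
                    records.append(InteractionRecord(frame_index, FeatureType.HBD, lf, g.residue))
                    break
            elif lf.type is FeatureType.HBA and g.kind is GroupKind.DONOR:
                for dpos in group_atom_coords(g):
                    d = np.linalg.norm(lf.center - dpos)
                    if d <= rules.hbond_dist_max:
                        records.append(
                            InteractionRecord(frame_index, FeatureType.HBA, lf, g.residue))
                        break
            elif lf.type is FeatureType.H and g.kind is GroupKind.HYDROPHOBIC:
                dmin = np.linalg.norm(group_atom_coords(g) - lf.center, axis=1).min()
                if dmin <= rules.hydrophobic_dist_max:
                    records.append(InteractionRecord(frame_index, FeatureType.H, lf, g.residue))
            elif lf.type is FeatureType.AR and g.kind is GroupKind.AROMATIC:
                d = np.linalg.norm(lf.center - g.center)
                if d > rules.aromatic_centroid_max:
                    continue
                ang = _interplanar_angle(lf.direction, g.normal) \
                    if lf.direction is not None and g.normal is not None else 0.0
                if ang <= rules.parallel_angle_max or ang >= rules.tshape_angle_min:
                    records.append(InteractionRecord(frame_index, FeatureType.AR, lf, g.residue))
            elif lf.type is FeatureType.PI and g.kind is GroupKind.AROMATIC:
                if np.linalg.norm(lf.center - g.center) <= rules.cation_pi_max:
                    records.append(InteractionRecord(frame_index, FeatureType.PI, lf, g.residue))
            elif lf.type is FeatureType.PI and g.kind is GroupKind.NEGATIVE:
                if np.linalg.norm(lf.center - g.center) <= rules.ionic_dist_max:
                    records.append(InteractionRecord(frame_index, FeatureType.PI, lf, g.residue))
            elif lf.type is FeatureType.XBD and g.kind is GroupKind.ACCEPTOR:
                cpos = None
                if coords is not None and len(lf.source_atoms) > 1:
                    cpos = coords[lf.source_atoms[0]]
                elif lf.direction is not None:
                    cpos = lf.center - lf.direction * 1.8
                for apos in group_atom_coords(g):
                    if np.linalg.norm(lf.center - apos) > rules.halogen_dist_max:
                        continue
                    if cpos is not None and \
                            _angle_deg(cpos, lf.center, apos) < rules.halogen_angle_min:
                        continue
                    records.append(InteractionRecord(frame_index, FeatureType.XBD, lf, g.residue))
                    break
    return records


class InteractionDetector:
    """Precomputed per-trajectory detector for the frame loop.

    Ligand feature topology and protein group topologies are derived once;
    per frame only geometry is recomputed.
    """

    def __init__(self, traj, rules: Optional[GeometricRules] = None,
                 near: float = 8.0):
        self.traj = traj
        self.rules = rules or GeometricRules()
        self.near = near
        template = traj.ligand_template or _infer_ligand_template(traj)
        self.ligand_features = LigandFeatureTemplate.from_molecule(
            template, traj.ligand_indices)
        self.group_topologies = residue_group_topologies(
            traj.atom_table, traj.protein_indices)
        self._lig_idx = traj.ligand_indices

    def detect(self, frame_index: int) -> list[InteractionRecord]:
        from .feature_perception import realize_group

        coords = self.traj.coords[frame_index]
        lig_features = self.ligand_features.realize(coords)
        lig_coords = coords[self._lig_idx]
        groups = []
        for topo in self.group_topologies:
            g = realize_group(topo, coords)
            if np.linalg.norm(lig_coords - g.center, axis=1).min() <= self.near:
                groups.append(g)
        frame = self.traj.frame(frame_index)
        return detect_frame_interactions(frame, lig_features, groups, self.rules)

    def interaction_set(self, frame_index: int) -> frozenset:
        return frozenset((r.type.value, r.residue[0], r.residue[1])
                         for r in self.detect(frame_index))


# ---------------------------------------------------------------------------
# aggregations


@dataclass
class OccurrenceTable:
    """Percent of analyzed frames with each (residue, interaction type)."""

    table: pd.DataFrame  # columns: chain, resid, resname, interaction, percent
    n_frames: int

    def percent(self, chain: str, resid: int, interaction: FeatureType) -> float:
        t = self.table
        sel = t[(t.chain == chain) & (t.resid == resid)
                & (t.interaction == interaction.value)]
        return float(sel.percent.iloc[0]) if len(sel) else 0.0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class ModelEnsemble:
    """Per-frame pharmacophore models over a window, with their histogram."""

    frame_indices: list[int]
    frame_records: list[list[InteractionRecord]]
    signatures: list[tuple]

    @property
    def histogram(self) -> Counter:
        return Counter(self.signatures)


def build_model_ensemble(traj, rules: Optional[GeometricRules] = None,
                         window=None, near: float = 8.0) -> ModelEnsemble:
    lo, hi = resolve_window(traj.n_frames, window)
    detector = InteractionDetector(traj, rules, near=near)
    frame_indices, frame_records, signatures = [], [], []
    for i in range(lo, hi):
        records = detector.detect(i)
        features = [replace(r.ligand_feature, type=r.type, partner=r.residue)
                    for r in records]
        frame_indices.append(i)
        frame_records.append(records)
        signatures.append(signature_of(features))
    return ModelEnsemble(frame_indices, frame_records, signatures)


def occurrence_table(traj, rules: Optional[GeometricRules] = None,
                     window=None) -> OccurrenceTable:
    """Occurrence percentages of every (residue, interaction type) pair.

    percent = 100 * (# window frames containing at least one record of that
    pair) / (# window frames); rows sorted by chain, then residue id.
    """
    ensemble = build_model_ensemble(traj, rules, window)
    n = len(ensemble.frame_indices)
    counts: Counter = Counter()
    resnames: dict[tuple, str] = {}
    for records in ensemble.frame_records:
        present = {(r.residue[0], r.residue[1], r.type.value) for r in records}
        for r in records:
            resnames[(r.residue[0], r.residue[1])] = r.residue[2]
        counts.update(present)
    rows = [
        {"chain": chain, "resid": resid, "resname": resnames[(chain, resid)],
         "interaction": itype, "percent": 100.0 * c / n}
        for (chain, resid, itype), c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["chain", "resid", "resname",
                                     "interaction", "percent"])
    df = df.sort_values(["chain", "resid", "interaction"]).reset_index(drop=True)
    return OccurrenceTable(df, n)


def model_histogram(traj, rules: Optional[GeometricRules] = None,
                    window=None) -> Counter:
    """Count how often each unique per-frame model signature appears."""
    return build_model_ensemble(traj, rules, window).histogram


def select_frequent_models(ensemble: ModelEnsemble, k: int) -> list[PharmacophoreModel]:
    """The ``k`` most frequent unique models, with representative geometry.

    Ties are broken deterministically: higher frame count, then more
    features, then lexicographically smaller signature. Each selected
    model's feature centers are per-feature centroids over the frames that
    carry its signature. If fewer than ``k`` unique signatures exist, all
    are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hist = ensemble.histogram
    ranked = sorted(hist.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} unique models available; requested {k}")
    selected = ranked[:k]
    models = []
    for sig, _count in selected:
        # collect per-record-key centers across this signature's frames
        acc: dict[tuple, list[np.ndarray]] = {}
        partners: dict[tuple, tuple] = {}
        for records, s in zip(ensemble.frame_records, ensemble.signatures):
            if s != sig:
                continue
            per_frame: dict[tuple, list[np.ndarray]] = {}
            for r in records:
                key = (r.type.value, r.residue[0], r.residue[1])
                per_frame.setdefault(key, []).append(r.ligand_feature.center)
                partners[key] = r.residue
            for key, centers in per_frame.items():
                acc.setdefault(key, []).append(np.mean(centers, axis=0))
        features = []
        for key in sorted(acc):
            centers = acc[key]
            ftype = FeatureType(key[0])
            radius = 1.1 if ftype is FeatureType.AR else 1.5
            features.append(ChemFeature(ftype, np.mean(centers, axis=0), radius,
                                        partner=partners[key]))
        models.append(PharmacophoreModel(features=features, name=str(sig)))
    return models
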