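"""Pharmacophore feature perception for ligands and protein residues.

Feature types follow the common six-class scheme used in structure-based
pharmacophore tools: hydrophobic (H), aromatic ring (AR), positive ionizable
(PI), hydrogen-bond donor (HBD), hydrogen-bond acceptor (HBA) and halogen-bond
donor (XBD).

The perception rules are deliberately simple, geometric and open:

* every aromatic ring contributes one AR feature at its centroid, carrying the
  ring-plane normal as direction;
* PI is assigned to nitrogen atoms with formal charge +1, or — as a fallback
  for un-protonated input — to neutral sp3 amines bearing at least one
  hydrogen and no adjacent carbonyl carbon;
* N–H and O–H groups are HBD; nitrogen/oxygen atoms with an available lone
  pair are HBA (ether, hydroxyl, carbonyl oxygens; amine and aromatic
  nitrogens without hydrogens; amide nitrogens are excluded);
* hydrophobic features are placed at the centroid of each connected fragment
  of at least two carbon/halogen heavy atoms none of which is bonded to
  N, O or S;
* C–Cl, C–Br and C–I groups are halogen-bond donors (XBD) located on the
  halogen, directed along the C→X axis; fluorine is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .errors import NoGeometryError

if TYPE_CHECKING:  # avoid a runtime import cycle with io_structures
    from .io_structures import Frame, Molecule

HALOGEN_XBD = {"Cl", "Br", "I"}
POLAR_ELEMENTS = {"N", "O", "S"}


class FeatureType(str, Enum):
    """Closed set of pharmacophore feature / interaction classes."""

    H = "H"      # hydrophobic
    AR = "AR"    # aromatic ring
    PI = "PI"    # positive ionizable (also labels cation-pi and ionic contacts)
    HBD = "HBD"  # hydrogen-bond donor
    HBA = "HBA"  # hydrogen-bond acceptor
    XBD = "XBD"  # halogen-bond donor


#: display colours matching the usual occurrence-table legend
FEATURE_COLORS = {
    FeatureType.AR: "blue",
    FeatureType.H: "yellow",
    FeatureType.HBA: "red",
    FeatureType.HBD: "green",
    FeatureType.PI: "cyan",
    FeatureType.XBD: "pink",
}

DEFAULT_FEATURE_RADIUS = 1.5  # Å, sphere tolerance for point features
DEFAULT_AR_RADIUS = 1.1      # Å, ring-plane tolerance for aromatic features


@dataclass(frozen=True)
class ChemFeature:
    """A typed pharmacophore feature with geometry and provenance."""

    type: FeatureType
    center: np.ndarray
    radius: float = DEFAULT_FEATURE_RADIUS
    direction: Optional[np.ndarray] = None
    source_atoms: tuple = ()
    partner: Optional[tuple] = None  # (chain, resid, resname) on the protein side

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            n = np.linalg.norm(d)
            if n > 0:
                d = d / n
            object.__setattr__(self, "direction", d)
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")

    def moved(self, center: np.ndarray, direction=None) -> "ChemFeature":
        return replace(self, center=np.asarray(center, float), direction=direction)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChemFeature":
        center = rotation @ self.center + translation
        direction = None if self.direction is None else rotation @ self.direction
        return replace(self, center=center, direction=direction)


class GroupKind(str, Enum):
    """Interaction-capable roles a protein residue can expose."""

    DONOR = "donor"
    ACCEPTOR = "acceptor"
    AROMATIC = "aromatic"
    HYDROPHOBIC = "hydrophobic"
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass
class ProteinGroup:
    """One interaction-capable group of a protein residue in one frame."""

    kind: GroupKind
    residue: tuple  # (chain, resid, resname)
    atom_indices: tuple
    center: np.ndarray
    normal: Optional[np.ndarray] = None  # aromatic rings only
    aux_indices: tuple = ()  # e.g. donor hydrogens, if present


# ---------------------------------------------------------------------------
# geometry helpers


def centroid(coords: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float).mean(axis=0)


def plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through ``coords`` (SVD)."""
    x = np.asarray(coords, float)
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    n = vt[-1]
    return n / np.linalg.norm(n)


def ring_planarity_rms(coords: np.ndarray) -> float:
    x = np.asarray(coords, float)
    c = x - x.mean(axis=0)
    n = plane_normal(x)
    return float(np.sqrt(np.mean((c @ n) ** 2)))


# ---------------------------------------------------------------------------
# ligand feature perception (RDKit-based)


def _is_pi_nitrogen(atom) -> bool:
    if atom.GetSymbol() != "N":
        return False
    if atom.GetFormalCharge() > 0:
        return True
    if atom.GetFormalCharge() != 0:
        return False
    # fallback heuristic for un-protonated input: neutral sp3 amine with >=1 H
    # and no adjacent carbonyl carbon (amides are not basic)
    from rdkit import Chem

    if atom.GetHybridization() != Chem.HybridizationType.SP3:
        return False
    n_h = atom.GetTotalNumHs() + sum(
        1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "H")
    if n_h < 1:
        return False
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() == "C":
            for nb2 in nb.GetNeighbors():
                bond = nb.GetOwningMol().GetBondBetweenAtoms(nb.GetIdx(), nb2.GetIdx())
                if nb2.GetSymbol() == "O" and bond.GetBondTypeAsDouble() == 2.0:
                    return False
    return True


def _is_acceptor(atom) -> bool:
    sym = atom.GetSymbol()
    if sym == "O":
        return atom.GetFormalCharge() <= 0
    if sym == "N":
        if atom.GetFormalCharge() > 0:
            return False
        # amide nitrogens are not acceptors
        for nb in atom.GetNeighbors():
            if nb.GetSymbol() == "C":
                for nb2 in nb.GetNeighbors():
                    bond = nb.GetOwningMol().GetBondBetweenAtoms(nb.GetIdx(), nb2.GetIdx())
                    if nb2.GetSymbol() == "O" and bond.GetBondTypeAsDouble() == 2.0:
                        return False
        # aromatic N-H (pyrrole-type) has no available lone pair
        if atom.GetIsAromatic() and atom.GetTotalNumHs() > 0:
            return False
        return True
    return False


def _hydrophobic_fragments(rdmol) -> list[list[int]]:
    """Connected fragments of apolar heavy atoms (C / halogen, not bonded to N/O/S)."""
    apolar = set()
    for atom in rdmol.GetAtoms():
        sym = atom.GetSymbol()
        if sym != "C" and sym not in HALOGEN_XBD:
            continue
        if any(nb.GetSymbol() in POLAR_ELEMENTS for nb in atom.GetNeighbors()):
            continue
        apolar.add(atom.GetIdx())
    # connected components within the apolar set
    seen: set[int] = set()
    fragments = []
    for start in sorted(apolar):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for nb in rdmol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in apolar and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(comp) >= 2:
            fragments.append(sorted(comp))
    return fragments


def perceive_ligand_features(
    mol: "Molecule",
    conformer: int = 0,
    *,
    radius: float = DEFAULT_FEATURE_RADIUS,
    ar_radius: float = DEFAULT_AR_RADIUS,
) -> list[ChemFeature]:
    """Perceive pharmacophore features of one conformer of a small molecule.

    Raises
    ------
    NoGeometryError
        if the molecule has no conformer with the requested index.
    """
    rdmol = mol.rdmol
    if conformer >= rdmol.GetNumConformers():
        raise NoGeometryError(f"molecule {mol.id!r} has no conformer {conformer}")
    xyz = mol.conformer(conformer)
    features: list[ChemFeature] = []

    # aromatic rings -> AR
    ring_info = rdmol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(rdmol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            coords = xyz[list(ring)]
            features.append(
                ChemFeature(FeatureType.AR, centroid(coords), ar_radius,
                            direction=plane_normal(coords), source_atoms=tuple(sorted(ring)))
            )

    # hydrophobic fragments -> H
    for frag in _hydrophobic_fragments(rdmol):
        features.append(
            ChemFeature(FeatureType.H, centroid(xyz[frag]), radius,
                        source_atoms=tuple(frag))
        )

    for atom in rdmol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        if _is_pi_nitrogen(atom):
            features.append(ChemFeature(FeatureType.PI, xyz[i], radius, source_atoms=(i,)))
        if sym in ("N", "O"):
            # donors: N-H / O-H, using an explicit H direction when present
            h_idx = [nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetSymbol() == "H"]
            n_h = len(h_idx) + atom.GetNumImplicitHs()
            if n_h > 0 and atom.GetFormalCharge() >= 0:
                direction = xyz[h_idx[0]] - xyz[i] if h_idx else None
                features.append(
                    ChemFeature(FeatureType.HBD, xyz[i], radius, direction=direction,
                                source_atoms=(i,) + tuple(h_idx))
                )
            if _is_acceptor(atom):
                features.append(ChemFeature(FeatureType.HBA, xyz[i], radius, source_atoms=(i,)))
        if sym in HALOGEN_XBD:
            carbons = [nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetSymbol() == "C"]
            if carbons:
                direction = xyz[i] - xyz[carbons[0]]
                features.append(
                    ChemFeature(FeatureType.XBD, xyz[i], radius, direction=direction,
                                source_atoms=(carbons[0], i))
                )
    return features


# ---------------------------------------------------------------------------
# protein group perception (template-based, standard residue names)

RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "ASN": ("ND2",), "GLN": ("NE2",),
    "TRP": ("NE1",), "HIS": ("ND1", "NE2"), "CYS": ("SG",),
}

SIDECHAIN_ACCEPTORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",), "GLN": ("OE1",), "HIS": ("ND1", "NE2"), "MET": ("SD",),
}

# apolar side-chain carbons that can carry hydrophobic contacts
HYDROPHOBIC_ATOMS = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "CE"),
    "PRO": ("CB", "CG", "CD"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "LYS": ("CB", "CG", "CD"),
    "ARG": ("CB", "CG"),
    "THR": ("CG2",),
    "GLU": ("CB", "CG"),
    "GLN": ("CB", "CG"),
    "ASP": ("CB",),
    "ASN": ("CB",),
    "HIS": ("CB",),
    "SER": ("CB",),
    "CYS": ("CB",),
}

POSITIVE_ATOMS = {"LYS": ("NZ",), "ARG": ("CZ",), "HIP": ("CE1",)}
NEGATIVE_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

STANDARD_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

RING_PLANARITY_RMS_MAX = 0.1  # Å


@dataclass
class ResidueGroupTopology:
    """Frame-independent description of one protein group (atom indices only)."""

    kind: GroupKind
    residue: tuple
    atom_indices: tuple
    aux_indices: tuple = ()


def residue_group_topologies(atoms: Sequence, protein_indices: Sequence[int],
                             warn=None) -> list[ResidueGroupTopology]:
    """Derive interaction-capable groups from atom metadata once.

    ``atoms`` is a sequence with ``name``/``resname``/``resid``/``chain``
    attributes (the trajectory atom table). Nonstandard residues are skipped
    with a warning callback.
    """
    import logging

    log = logging.getLogger(__name__)
    by_res: dict[tuple, dict[str, int]] = {}
    resnames: dict[tuple, str] = {}
    for i in protein_indices:
        a = atoms[i]
        key = (a.chain, a.resid)
        by_res.setdefault(key, {})[a.name] = i
        resnames[key] = a.resname

    groups: list[ResidueGroupTopology] = []
    for key in sorted(by_res):
        names = by_res[key]
        resname = resnames[key]
        residue = (key[0], key[1], resname)
        if resname not in STANDARD_RESNAMES:
            msg = f"skipping nonstandard residue {resname} {key[0]}{key[1]}"
            (warn or log.warning)(msg)
            continue

        def have(wanted):
            return all(n in names for n in wanted)

        def idx(wanted):
            return tuple(names[n] for n in wanted)

        ring = RING_ATOMS.get(resname)
        if ring and have(ring):
            groups.append(ResidueGroupTopology(GroupKind.AROMATIC, residue, idx(ring)))
        for n in SIDECHAIN_DONORS.get(resname, ()):
            if n in names:
                h = tuple(names[hn] for hn in names
                          if hn.startswith("H") and hn.endswith(n[1:]) and n[1:] != "")
                groups.append(ResidueGroupTopology(GroupKind.DONOR, residue, (names[n],), h))
        for n in SIDECHAIN_ACCEPTORS.get(resname, ()):
            if n in names:
                groups.append(ResidueGroupTopology(GroupKind.ACCEPTOR, residue, (names[n],)))
        # backbone donor / acceptor
        if "N" in names and resname != "PRO":
            groups.append(ResidueGroupTopology(GroupKind.DONOR, residue, (names["N"],)))
        if "O" in names:
            groups.append(ResidueGroupTopology(GroupKind.ACCEPTOR, residue, (names["O"],)))
        hydro = tuple(names[n] for n in HYDROPHOBIC_ATOMS.get(resname, ()) if n in names)
        if hydro:
            groups.append(ResidueGroupTopology(GroupKind.HYDROPHOBIC, residue, hydro))
        for table, kind in ((POSITIVE_ATOMS, GroupKind.POSITIVE),
                            (NEGATIVE_ATOMS, GroupKind.NEGATIVE)):
            wanted = table.get(resname, ())
            if wanted and have(wanted):
                groups.append(ResidueGroupTopology(kind, residue, idx(wanted)))
    return groups


def realize_group(topo: ResidueGroupTopology, coords: np.ndarray) -> ProteinGroup:
    """Attach geometry from one frame's coordinate array to a group topology."""
    pts = coords[list(topo.atom_indices)]
    if topo.kind is GroupKind.AROMATIC:
        return ProteinGroup(topo.kind, topo.residue, topo.atom_indices,
                            centroid(pts), normal=plane_normal(pts),
                            aux_indices=topo.aux_indices)
    return ProteinGroup(topo.kind, topo.residue, topo.atom_indices,
                        centroid(pts), aux_indices=topo.aux_indices)


def perceive_protein_groups(frame: "Frame", near: float | None = 8.0) -> list[ProteinGroup]:
    """Perceive interaction-capable protein groups of one trajectory frame.

    ``near`` keeps only groups whose center lies within the cutoff of any
    ligand atom (default 8 Å); pass ``None`` to keep everything.
    """
    traj = frame.trajectory
    coords = frame.coords
    topos = residue_group_topologies(traj.atom_table, traj.protein_indices)
    groups = [realize_group(t, coords) for t in topos]
    if near is not None and len(traj.ligand_indices):
        lig = coords[traj.ligand_indices]
        kept = []
        for g in groups:
            d = np.linalg.norm(lig - g.center, axis=1).min()
            if d <= near:
                kept.append(g)
        groups = kept
    return groups
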