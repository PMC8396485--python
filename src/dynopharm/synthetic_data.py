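"""Synthetic complexes and screening libraries with known ground truth.

This module generates every input the pipeline needs, emulating the study
system — a four-fold symmetric channel-pore binding site lined with serine,
tyrosine, alanine and phenylalanine side chains, a pore-blocker-like ligand
carrying a positively charged amine, aromatic ring, hydrophobic tail,
H-bond-donating amide and a chlorine — without any external download:

* :func:`generate_complex_trajectory` draws, per frame, which of the
  scheduled ligand–protein interactions are realized (independent Bernoulli
  occupancies), places the corresponding ligand fragments in poses that
  satisfy exactly those interactions under the detector's geometric rules,
  adds isotropic Gaussian coordinate jitter, and returns the trajectory
  together with the exact per-frame interaction sets;
* :func:`generate_screening_library` builds feature-satisfying actives and
  property-matched decoys whose bond graph is rearranged so that no
  generated conformer can satisfy the model's essential features (the
  DUD-E-style "similar 1D properties, dissimilar 2D topology" contract).

The generator verifies its own output with an internal interaction check
implemented independently of :mod:`dynopharm.interaction_analysis` (the two
share only the :class:`GeometricRules` thresholds); frames where jitter
flips any interaction are resampled.

Synthetic conformers are geometric scaffolds placed to realize feature
arrangements; they are not energy-minimized structures.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DecoyGenerationError, InfeasibleScheduleError
from .feature_perception import HYDROPHOBIC_ATOMS, RING_ATOMS
from .interaction_analysis import GeometricRules
from .io_structures import Atom, Molecule, Trajectory
from .pharmacophore_build import ESSENTIAL, PharmacophoreModel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pocket template


@dataclass
class PocketSpec:
    """A C_n-symmetric pore-like pocket (default four-fold).

    Each chain carries, top to bottom along the pore axis (z): a serine
    hydroxyl (resid 436), a tyrosine ring (464), an alanine hydrophobic
    site (465) and a phenylalanine ring (468). Chain A's template is
    rotated about z to place chains B, C, D ... at equal azimuths.
    """

    n_chains: int = 4
    ligand_resname: str = "LIG"

    @property
    def chain_ids(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_chains)]

    def chain_angle(self, chain: str) -> float:
        return 2.0 * math.pi * (ord(chain) - ord("A")) / self.n_chains


# chain-A template: residue -> [(atom name, element, xyz)]
_CHAIN_A_RESIDUES = [
    (436, "SER", [
        ("N", "N", (9.3, 0.2, 7.1)), ("CA", "C", (8.6, -0.2, 6.0)),
        ("C", "C", (9.2, -0.1, 4.7)), ("O", "O", (9.9, 0.6, 4.0)),
        ("CB", "C", (7.4, 0.6, 6.2)), ("OG", "O", (6.3, 0.0, 6.0)),
    ]),
    (464, "TYR", [
        ("N", "N", (9.5, -0.4, 3.5)), ("CA", "C", (8.8, 0.4, 2.7)),
        ("C", "C", (9.0, 0.2, 1.3)), ("O", "O", (9.6, 1.0, 0.8)),
        ("CB", "C", (7.6, 0.0, 2.2)),
        ("CG", "C", (6.5, 0.0, 1.39)),
        ("CD1", "C", (6.5, 1.20, 0.695)), ("CD2", "C", (6.5, -1.20, 0.695)),
        ("CE1", "C", (6.5, 1.20, -0.695)), ("CE2", "C", (6.5, -1.20, -0.695)),
        ("CZ", "C", (6.5, 0.0, -1.39)), ("OH", "O", (6.5, 0.0, -2.77)),
    ]),
    (465, "ALA", [
        ("N", "N", (8.0, -0.6, -5.1)), ("CA", "C", (7.4, 0.2, -4.2)),
        ("C", "C", (8.1, 0.3, -3.0)), ("O", "O", (8.7, 1.2, -2.6)),
        ("CB", "C", (6.0, 0.0, -4.0)),
    ]),
    (468, "PHE", [
        ("N", "N", (8.6, -0.5, -10.9)), ("CA", "C", (7.9, 0.3, -10.1)),
        ("C", "C", (8.4, 0.5, -8.7)), ("O", "O", (9.1, 1.3, -8.3)),
        ("CB", "C", (7.4, 0.0, -7.6)),
        ("CG", "C", (6.5, 0.0, -8.11)),
        ("CD1", "C", (6.5, 1.20, -8.805)), ("CD2", "C", (6.5, -1.20, -8.805)),
        ("CE1", "C", (6.5, 1.20, -10.195)), ("CE2", "C", (6.5, -1.20, -10.195)),
        ("CZ", "C", (6.5, 0.0, -10.89)),
    ]),
]


def _rot_z(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_pocket_atoms(pocket: PocketSpec) -> tuple[list[Atom], np.ndarray]:
    """Protein atom table and template coordinates of the symmetric pocket."""
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1
    for chain in pocket.chain_ids:
        rot = _rot_z(pocket.chain_angle(chain))
        for resid, resname, entries in _CHAIN_A_RESIDUES:
            for name, element, xyz in entries:
                atoms.append(Atom(serial, name, element, resname, resid, chain,
                                  rot @ np.asarray(xyz, float)))
                coords.append(rot @ np.asarray(xyz, float))
                serial += 1
    return atoms, np.array(coords)


# ---------------------------------------------------------------------------
# ligand template: five independent feature-bearing fragments

# fragment name -> [(atom name, element, base "on" xyz)]; the "on" pose of
# each fragment targets chain A and is rotated to the scheduled chain.
_LIGAND_FRAGMENTS = {
    # trans-amide: N-H donates to the serine hydroxyl; carbonyl O points away
    "amide": [("C1", "C", (1.95, 0.0, 6.0)), ("O1", "O", (0.75, 0.0, 6.0)),
              ("N1", "N", (3.3, 0.0, 6.0)), ("H1", "H", (4.3, 0.0, 6.0)),
              ("C2", "C", (3.7, 1.4, 6.4))],
    # quaternary ammonium: cation-pi partner of the tyrosine ring
    "ammonium": [("N2", "N", (2.0, 0.0, 0.0)), ("C3", "C", (2.9, 0.9, 0.9)),
                 ("C4", "C", (1.1, -0.9, 0.9)), ("C5", "C", (2.9, -0.9, -0.9)),
                 ("C6", "C", (1.1, 0.9, -0.9))],
    # benzene: parallel pi-stacking with the tyrosine ring at 5.0 Å
    "benzene": [("C7", "C", (1.5, 0.0, 1.39)), ("C8", "C", (1.5, 1.20, 0.695)),
                ("C9", "C", (1.5, 1.20, -0.695)), ("C10", "C", (1.5, 0.0, -1.39)),
                ("C11", "C", (1.5, -1.20, -0.695)), ("C12", "C", (1.5, -1.20, 0.695))],
    # ethyl: hydrophobic contact with the alanine CB
    "ethyl": [("C13", "C", (2.5, 0.75, -4.0)), ("C14", "C", (2.5, -0.75, -4.0))],
    # chloromethyl: halogen bond donated to the serine hydroxyl oxygen
    "chloro": [("C15", "C", (1.3, 0.0, 6.0)), ("CL1", "Cl", (3.1, 0.0, 6.0))],
}

_FRAGMENT_ORDER = ("amide", "ammonium", "benzene", "ethyl", "chloro")

# parked ("off") positions, far above the pocket and outside every cutoff
_PARKED_OFFSET = {
    "amide": (-12.0, 0.0, 25.0),
    "ammonium": (0.0, 12.0, 25.0),
    "benzene": (12.0, 0.0, 25.0),
    "ethyl": (0.0, -12.0, 25.0),
    "chloro": (8.0, 8.0, 25.0),
}

# supported interaction keys: (interaction type, target resid) per fragment;
# the chain is free (the on-pose is rotated to the scheduled chain)
_FRAGMENT_INTERACTION = {
    "amide": ("HBD", 436),
    "ammonium": ("PI", 464),
    "benzene": ("AR", 464),
    "ethyl": ("H", 465),
    "chloro": ("XBD", 436),
}


def build_ligand_template(pocket: PocketSpec) -> Molecule:
    """The ligand as a bonded RDKit molecule (fragments are disconnected)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    index = {}
    coords = []
    for frag in _FRAGMENT_ORDER:
        for name, element, xyz in _LIGAND_FRAGMENTS[frag]:
            a = Chem.Atom(element)
            if name == "N2":
                a.SetFormalCharge(1)
            a.SetNoImplicit(True)
            index[name] = rw.AddAtom(a)
            coords.append(xyz)
    bonds = [("C1", "O1", Chem.BondType.DOUBLE), ("C1", "N1", Chem.BondType.SINGLE),
             ("N1", "H1", Chem.BondType.SINGLE), ("N1", "C2", Chem.BondType.SINGLE),
             ("N2", "C3", Chem.BondType.SINGLE), ("N2", "C4", Chem.BondType.SINGLE),
             ("N2", "C5", Chem.BondType.SINGLE), ("N2", "C6", Chem.BondType.SINGLE),
             ("C13", "C14", Chem.BondType.SINGLE), ("C15", "CL1", Chem.BondType.SINGLE)]
    ring = ["C7", "C8", "C9", "C10", "C11", "C12"]
    for i in range(6):
        bonds.append((ring[i], ring[(i + 1) % 6], Chem.BondType.AROMATIC))
    for a, b, order in bonds:
        rw.AddBond(index[a], index[b], order)
    for name in ring:
        rw.GetAtomWithIdx(index[name]).SetIsAromatic(True)
    conf = Chem.Conformer(rw.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    rw.AddConformer(conf)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL
                     ^ Chem.SanitizeFlags.SANITIZE_ADJUSTHS)
    return Molecule("LIG", mol)


# ---------------------------------------------------------------------------
# occupancy schedules and trajectory generation


@dataclass
class OccupancySchedule:
    """Target per-frame probabilities of scheduled interactions.

    Keys are ``(interaction type, chain, resid)`` — e.g.
    ``("HBD", "A", 436)`` for the amide→serine hydrogen bond. Defaults
    emulate the shape of a pore-blocker occurrence table: a near-permanent
    H-bond (0.95), persistent hydrophobic contact (0.90), intermittent
    cation-pi (0.50), brief aromatic stacking (0.25) and occasional halogen
    bonding (0.15) over 500 analyzed frames.
    """

    probabilities: dict = field(default_factory=lambda: {
        ("HBD", "A", 436): 0.95,
        ("H", "A", 465): 0.90,
        ("PI", "B", 464): 0.50,
        ("AR", "A", 464): 0.25,
        ("XBD", "C", 436): 0.15,
    })
    n_frames: int = 500
    sigma: float = 0.15  # Å, isotropic per-atom jitter
    seed: int = 0

    def __post_init__(self):
        for key, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {key} outside [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _fragment_for_key(key: tuple) -> str:
    for frag, (itype, resid) in _FRAGMENT_INTERACTION.items():
        if key[0] == itype and key[2] == resid:
            return frag
    raise InfeasibleScheduleError(f"no ligand pose realizes interaction {key}")


class _PocketChecker:
    """The generator's own interaction check (independent of the detector).

    Enumerates candidate ligand-probe/protein-site pairs directly from the
    pocket construction and evaluates the geometric rules with its own
    formulas. Used for schedule feasibility and post-jitter verification.
    """

    def __init__(self, pocket: PocketSpec, protein_atoms: list[Atom],
                 lig_names: list[str], rules: GeometricRules):
        self.rules = rules
        self.lig_pos = {n: i for i, n in enumerate(lig_names)}
        self.sites = []  # (kind, residue, [protein atom indices])
        by_res: dict[tuple, dict[str, int]] = {}
        for i, a in enumerate(protein_atoms):
            by_res.setdefault((a.chain, a.resid, a.resname), {})[a.name] = i
        for (chain, resid, resname), names in by_res.items():
            residue = (chain, resid, resname)
            ring = RING_ATOMS.get(resname)
            if ring and all(n in names for n in ring):
                self.sites.append(("ring", residue, [names[n] for n in ring]))
            acceptors = [names[n] for n in ("OG", "OH", "O") if n in names]
            if acceptors:
                self.sites.append(("acceptor", residue, acceptors))
            donors = [names[n] for n in ("OG", "OH", "N") if n in names]
            if donors:
                self.sites.append(("donor", residue, donors))
            hydro = [names[n] for n in HYDROPHOBIC_ATOMS.get(resname, ()) if n in names]
            if hydro:
                self.sites.append(("hydrophobic", residue, hydro))

    def interactions(self, prot_coords: np.ndarray, lig_coords: np.ndarray) -> frozenset:
        r = self.rules
        lp = lambda name: lig_coords[self.lig_pos[name]]
        found = set()
        ring_names = ["C7", "C8", "C9", "C10", "C11", "C12"]
        lig_ring = np.array([lp(n) for n in ring_names])
        lig_ring_c = lig_ring.mean(axis=0)
        u, s, vt = np.linalg.svd(lig_ring - lig_ring_c)
        lig_ring_n = vt[-1]
        hydro_probes = {
            "benzene": lig_ring_c,
            "ethyl": 0.5 * (lp("C13") + lp("C14")),
            "chloro": 0.5 * (lp("C15") + lp("CL1")),
        }
        for kind, residue, idx in self.sites:
            pts = prot_coords[idx]
            key = (residue[0], residue[1])
            if kind == "acceptor":
                for apos in pts:
                    d = np.linalg.norm(lp("N1") - apos)
                    if d <= r.hbond_dist_max:
                        h, n = lp("H1"), lp("N1")
                        cosang = np.dot(n - h, apos - h) / (
                            np.linalg.norm(n - h) * np.linalg.norm(apos - h))
                        if math.degrees(math.acos(np.clip(cosang, -1, 1))) >= r.hbond_angle_min:
                            found.add(("HBD",) + key)
                    dx = np.linalg.norm(lp("CL1") - apos)
                    if dx <= r.halogen_dist_max:
                        c, x = lp("C15"), lp("CL1")
                        cosang = np.dot(c - x, apos - x) / (
                            np.linalg.norm(c - x) * np.linalg.norm(apos - x))
                        if math.degrees(math.acos(np.clip(cosang, -1, 1))) >= r.halogen_angle_min:
                            found.add(("XBD",) + key)
            elif kind == "donor":
                for dpos in pts:
                    if np.linalg.norm(lp("O1") - dpos) <= r.hbond_dist_max:
                        found.add(("HBA",) + key)
                        break
            elif kind == "hydrophobic":
                for probe in hydro_probes.values():
                    if np.linalg.norm(pts - probe, axis=1).min() <= r.hydrophobic_dist_max:
                        found.add(("H",) + key)
                        break
            elif kind == "ring":
                cen = pts.mean(axis=0)
                _, _, vt2 = np.linalg.svd(pts - cen)
                normal = vt2[-1]
                if np.linalg.norm(lig_ring_c - cen) <= r.aromatic_centroid_max:
                    cosang = abs(float(np.dot(lig_ring_n, normal)))
                    ang = math.degrees(math.acos(np.clip(cosang, 0, 1)))
                    if ang <= r.parallel_angle_max or ang >= r.tshape_angle_min:
                        found.add(("AR",) + key)
                if np.linalg.norm(lp("N2") - cen) <= r.cation_pi_max:
                    found.add(("PI",) + key)
        return frozenset(found)


def _ligand_coords_for_state(pocket: PocketSpec, on_keys: Sequence[tuple]) -> np.ndarray:
    """Assemble ligand coordinates realizing exactly the given interactions."""
    frag_target: dict[str, Optional[str]] = {f: None for f in _FRAGMENT_ORDER}
    for key in on_keys:
        frag = _fragment_for_key(key)
        if frag_target[frag] is not None:
            raise InfeasibleScheduleError(
                f"fragment {frag!r} cannot realize two interactions at once")
        frag_target[frag] = key[1]  # target chain
    coords = []
    for frag in _FRAGMENT_ORDER:
        base = np.array([xyz for _n, _e, xyz in _LIGAND_FRAGMENTS[frag]], float)
        chain = frag_target[frag]
        if chain is None:
            coords.append(base - base.mean(axis=0) + np.asarray(_PARKED_OFFSET[frag]))
        else:
            coords.append(base @ _rot_z(pocket.chain_angle(chain)).T)
    return np.vstack(coords)


def generate_complex_trajectory(
    schedule: Optional[OccupancySchedule] = None,
    pocket: Optional[PocketSpec] = None,
    rules: Optional[GeometricRules] = None,
    rigid_transform: Optional[tuple] = None,
    max_resample: int = 100,
) -> tuple[Trajectory, list[frozenset]]:
    """Generate a pocket–ligand trajectory with planted interaction occupancies.

    Returns the trajectory and the ground-truth interaction set
    ``{(type, chain, resid), ...}`` of every frame. Frames whose jitter
    flips any interaction (relative to the planted state, as judged by the
    generator's internal check) are resampled up to ``max_resample`` times.
    ``rigid_transform`` — an optional ``(rotation, translation)`` — moves
    the whole complex, emulating an arbitrary lab frame.
    """
    schedule = schedule or OccupancySchedule()
    pocket = pocket or PocketSpec()
    rules = rules or GeometricRules()
    keys = sorted(schedule.probabilities)
    for key in keys:
        frag = _fragment_for_key(key)
        if key[1] not in pocket.chain_ids:
            raise InfeasibleScheduleError(f"unknown chain in {key}")
    protein_atoms, protein_coords = build_pocket_atoms(pocket)
    template = build_ligand_template(pocket)
    lig_atom_names = [n for frag in _FRAGMENT_ORDER
                      for n, _e, _x in _LIGAND_FRAGMENTS[frag]]
    checker = _PocketChecker(pocket, protein_atoms, lig_atom_names, rules)

    # exhaustive feasibility check: every on/off combination must produce
    # exactly its planted interaction set (in the jitter-free geometry)
    for state in itertools.product((False, True), repeat=len(keys)):
        on = [k for k, s in zip(keys, state) if s]
        try:
            lig = _ligand_coords_for_state(pocket, on)
        except InfeasibleScheduleError:
            raise
        got = checker.interactions(protein_coords, lig)
        if got != frozenset(on):
            raise InfeasibleScheduleError(
                f"state {on} produces {sorted(got)} under the geometric rules")

    rng = np.random.default_rng(schedule.seed)
    n_prot = len(protein_atoms)
    n_lig = len(lig_atom_names)
    frames = np.empty((schedule.n_frames, n_prot + n_lig, 3))
    truth: list[frozenset] = []
    for f in range(schedule.n_frames):
        on = [k for k in keys if rng.random() < schedule.probabilities[k]]
        planted = frozenset(on)
        lig = _ligand_coords_for_state(pocket, on)
        for attempt in range(max_resample):
            jitter = rng.normal(scale=schedule.sigma,
                                size=(n_prot + n_lig, 3)) if schedule.sigma > 0 else 0.0
            prot_j = protein_coords + (jitter[:n_prot] if schedule.sigma > 0 else 0.0)
            lig_j = lig + (jitter[n_prot:] if schedule.sigma > 0 else 0.0)
            if checker.interactions(prot_j, lig_j) == planted:
                break
        else:
            raise InfeasibleScheduleError(
                f"jitter sigma={schedule.sigma} keeps flipping interactions "
                f"in frame {f}; schedule infeasible")
        frames[f, :n_prot] = prot_j
        frames[f, n_prot:] = lig_j
        truth.append(planted)

    lig_atoms = []
    serial = n_prot + 1
    elements = [e for frag in _FRAGMENT_ORDER for _n, e, _x in _LIGAND_FRAGMENTS[frag]]
    for name, element in zip(lig_atom_names, elements):
        lig_atoms.append(Atom(serial, name, element, pocket.ligand_resname, 1, "L",
                              frames[0, serial - 1]))
        serial += 1
    atom_table = protein_atoms + lig_atoms
    if rigid_transform is not None:
        rot, trans = rigid_transform
        frames = frames @ np.asarray(rot, float).T + np.asarray(trans, float)
    traj = Trajectory(atom_table, frames, pocket.ligand_resname,
                      ligand_template=template)
    return traj, truth


def default_ligand_schedules(n_frames: int = 150, sigma: float = 0.1,
                             seed: int = 0) -> dict[str, OccupancySchedule]:
    """Five per-ligand schedules emulating distinct pore-blocker behaviours.

    Four share a common interaction core (alignable merged models); the
    fifth realizes only two interactions — a different binding mode whose
    merged model cannot be aligned with the others and is excluded from the
    final model, mirroring the known outlier behaviour.
    """
    core = {("PI", "B", 464): 0.9, ("H", "A", 465): 0.9}

    def sched(extra, s):
        return OccupancySchedule(probabilities={**core, **extra},
                                 n_frames=n_frames, sigma=sigma, seed=seed + s)

    return {
        "astemizole-like": sched({("HBD", "A", 436): 0.85, ("AR", "A", 464): 0.8}, 1),
        "clofilium-like": sched({("AR", "A", 464): 0.8, ("XBD", "C", 436): 0.8}, 2),
        "imipramine-like": sched({("HBD", "A", 436): 0.95}, 3),
        "mk499-like": sched({("HBD", "A", 436): 0.8, ("AR", "A", 464): 0.75}, 4),
        "quinidine-like": OccupancySchedule(
            probabilities={("PI", "B", 464): 0.9, ("HBD", "A", 436): 0.9},
            n_frames=n_frames, sigma=sigma, seed=seed + 5),
    }


# ---------------------------------------------------------------------------
# screening library generation


@dataclass
class LibrarySpec:
    """Library composition and decoy property-matching tolerances."""

    n_actives: int = 15
    decoys_per_active: int = 50
    total_decoys: Optional[int] = None  # overrides decoys_per_active when set
    heavy_atom_tol: int = 2
    ring_tol: int = 0
    hbond_tol: int = 1  # HBD and HBA each
    n_feature_matching_decoys: int = 0  # decoys that match features but clash
    position_jitter: float = 0.25  # Å, fragment placement jitter for actives
    seed: int = 0


def property_vector(mol: Molecule) -> dict:
    """1D physicochemical profile used for decoy property matching."""
    rdmol = mol.rdmol
    heavy = sum(1 for a in rdmol.GetAtoms() if a.GetSymbol() != "H")
    rings = rdmol.GetRingInfo().NumRings()
    hbd = hba = 0
    from .feature_perception import _is_acceptor

    for a in rdmol.GetAtoms():
        if a.GetSymbol() in ("N", "O"):
            n_h = a.GetTotalNumHs() + sum(
                1 for nb in a.GetNeighbors() if nb.GetSymbol() == "H")
            if n_h > 0 and a.GetFormalCharge() >= 0:
                hbd += 1
            if _is_acceptor(a):
                hba += 1
    charge = sum(a.GetFormalCharge() for a in rdmol.GetAtoms())
    return {"heavy": heavy, "rings": rings, "hbd": hbd, "hba": hba, "charge": charge}


class _MolBuilder:
    """Incremental RWMol + coordinates assembly."""

    def __init__(self):
        from rdkit import Chem

        self.rw = Chem.RWMol()
        self.coords: list = []

    def add(self, element: str, xyz, charge: int = 0, bond_to: Optional[int] = None,
            order=None) -> int:
        from rdkit import Chem

        a = Chem.Atom(element)
        if charge:
            a.SetFormalCharge(charge)
        a.SetNoImplicit(False)
        idx = self.rw.AddAtom(a)
        self.coords.append(np.asarray(xyz, float))
        if bond_to is not None:
            self.rw.AddBond(idx, bond_to, order or Chem.BondType.SINGLE)
        return idx

    def bond(self, i: int, j: int, order=None):
        from rdkit import Chem

        self.rw.AddBond(i, j, order or Chem.BondType.SINGLE)

    def finish(self, mol_id: str) -> Molecule:
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        conf = Chem.Conformer(self.rw.GetNumAtoms())
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
        self.rw.AddConformer(conf)
        mol = self.rw.GetMol()
        Chem.SanitizeMol(mol)
        return Molecule(mol_id, mol)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _active_targets(model: PharmacophoreModel, choice: int) -> list[tuple]:
    """(feature type, center) for every essential feature + either choice."""
    targets = []
    either_members = {m for g in model.either_groups for m in g}
    for i in model.essential_indices:
        if i not in either_members:
            targets.append((model.features[i].type, model.features[i].center))
    for g in model.either_groups:
        pick = g[choice % len(g)]
        targets.append((model.features[pick].type, model.features[pick].center))
    return targets


def build_active(model: PharmacophoreModel, mol_id: str,
                 rng: Optional[np.random.Generator] = None, choice: int = 0,
                 jitter: float = 0.0, all_features: bool = False,
                 clash_point: Optional[np.ndarray] = None) -> Molecule:
    """A molecule whose conformer satisfies the model's essential features.

    Feature-bearing fragments are placed at the feature centers (optionally
    with a small placement jitter, capped well inside the feature radii) and
    connected through ether-oxygen linkers so that hydrophobic fragments
    stay topologically separate. With ``all_features`` every model feature
    gets a fragment; with ``clash_point`` an extra linker-borne carbon is
    placed there (used to build bulky molecules that violate exclusion
    volumes).
    """
    from rdkit import Chem

    rng = rng or np.random.default_rng(0)
    if all_features:
        targets = [(f.type, f.center) for f in model.features]
    else:
        targets = _active_targets(model, choice)
    if not targets:
        raise ValueError("model has no essential features to satisfy")
    b = _MolBuilder()
    anchors: list[tuple] = []  # (incoming anchor, outgoing anchor) per fragment
    from .feature_perception import FeatureType as FT

    for ftype, center in targets:
        center = np.asarray(center, float)
        if jitter > 0:
            offset = rng.normal(scale=jitter, size=3)
            nrm = np.linalg.norm(offset)
            cap = min(jitter * 2.0, 0.45)
            if nrm > cap:
                offset *= cap / nrm
            center = center + offset
        axis = _unit(rng.normal(size=3))
        perp = _unit(np.cross(axis, rng.normal(size=3)))
        if ftype is FT.PI:
            n = b.add("N", center, charge=1)
            arms = [(0.9, 0.9, 0.9), (-0.9, -0.9, 0.9), (0.9, -0.9, -0.9),
                    (-0.9, 0.9, -0.9)]
            carbons = [b.add("C", center + np.asarray(v), bond_to=n) for v in arms]
            anchors.append((carbons[0], carbons[1]))
        elif ftype is FT.H:
            # O-linked propyl arm: the two terminal carbons form the
            # hydrophobic pair centered on the feature
            cb = b.add("C", center + 0.75 * axis)
            cc = b.add("C", center - 0.75 * axis, bond_to=cb)
            ca = b.add("C", center + 2.1 * axis, bond_to=cb)
            anchors.append((ca, ca))
        elif ftype is FT.AR:
            ring_idx = []
            for k in range(6):
                ang = k * math.pi / 3
                pos = center + 1.39 * (math.cos(ang) * axis + math.sin(ang) * perp)
                ring_idx.append(b.add("C", pos))
            for k in range(6):
                b.bond(ring_idx[k], ring_idx[(k + 1) % 6], Chem.BondType.AROMATIC)
            for k in ring_idx:
                b.rw.GetAtomWithIdx(k).SetIsAromatic(True)
            anchors.append((ring_idx[0], ring_idx[3]))
        elif ftype is FT.HBD:
            n = b.add("N", center)
            b.add("H", center + 1.0 * axis, bond_to=n)
            c = b.add("C", center - 1.35 * axis, bond_to=n)
            b.add("O", center - 1.35 * axis + 1.2 * perp, bond_to=c,
                  order=Chem.BondType.DOUBLE)
            cm = b.add("C", center + 1.2 * perp, bond_to=n)
            anchors.append((c, cm))
        elif ftype is FT.HBA:
            o = b.add("O", center)
            c1 = b.add("C", center + 1.4 * axis, bond_to=o)
            c2 = b.add("C", center - 1.4 * axis, bond_to=o)
            anchors.append((c1, c2))
        elif ftype is FT.XBD:
            x = b.add("Cl", center)
            c = b.add("C", center - 1.8 * axis)
            b.bond(c, x)
            anchors.append((c, c))
        else:  # pragma: no cover - closed enum
            raise ValueError(f"unsupported feature type {ftype}")
    # ether linkers between consecutive fragments (out-anchor to in-anchor)
    for (_, a1), (a2, _) in zip(anchors, anchors[1:]):
        mid = 0.5 * (b.coords[a1] + b.coords[a2])
        o = b.add("O", mid, bond_to=a1)
        b.bond(o, a2)
    if clash_point is not None:
        last_out = anchors[-1][1]
        o = b.add("O", 0.5 * (b.coords[last_out] + np.asarray(clash_point, float)),
                  bond_to=last_out)
        b.add("C", clash_point, bond_to=o)
    return b.finish(mol_id)


_DECOY_ARMS = {
    # arm label -> (atoms appended per arm, HBA contribution, builder spec)
    "OC": (2, 1, ("O", "C")),
    "SC": (2, 0, ("S", "C")),
    "OCSC": (4, 1, ("O", "C", "S", "C")),
    "OCOC": (4, 2, ("O", "C", "O", "C")),
}


def build_decoy(parent_props: dict, mol_id: str, variant: int,
                rng: np.random.Generator, spec: LibrarySpec) -> Molecule:
    """A property-matched decoy that cannot satisfy hydrophobic features.

    Keeps the parent's formal charge, ring count and (within tolerance)
    heavy-atom/HBD/HBA counts, but every carbon outside the charged core is
    bonded to an oxygen or sulfur — so no conformer of the decoy has a
    hydrophobic feature, and any model with an essential hydrophobic
    feature can never be matched. The bond graph necessarily differs from
    the parent's (dissimilar 2D topology).
    """
    if parent_props["rings"] != 0:
        raise DecoyGenerationError(
            "topology-breaking decoys require ring-free parents")
    target_heavy = parent_props["heavy"]
    target_hba = parent_props["hba"]
    target_hbd = parent_props["hbd"]
    base_heavy = 5  # charged N + four core carbons
    amide_heavy = 3 * target_hbd  # each HBD arm: N, C, O (amide)
    amide_hba = target_hbd
    need_heavy = target_heavy - base_heavy - amide_heavy
    need_hba = target_hba - amide_hba
    arm_names = sorted(_DECOY_ARMS)
    best = None
    for count in range(0, 5):
        for combo in itertools.combinations_with_replacement(arm_names, count):
            heavy = sum(_DECOY_ARMS[a][0] for a in combo)
            hba = sum(_DECOY_ARMS[a][1] for a in combo)
            if abs(heavy - need_heavy) <= spec.heavy_atom_tol and \
                    abs(hba - need_hba) <= spec.hbond_tol:
                key = (abs(heavy - need_heavy) + abs(hba - need_hba), combo)
                if best is None or key < best:
                    best = key
    if best is None:
        raise DecoyGenerationError(
            f"no arm combination matches properties {parent_props}")
    # rotate through near-optimal combos so decoys are not all identical
    feasible = []
    for count in range(0, 5):
        for combo in itertools.combinations_with_replacement(arm_names, count):
            heavy = sum(_DECOY_ARMS[a][0] for a in combo)
            hba = sum(_DECOY_ARMS[a][1] for a in combo)
            if abs(heavy - need_heavy) <= spec.heavy_atom_tol and \
                    abs(hba - need_hba) <= spec.hbond_tol:
                feasible.append(combo)
    combo = feasible[variant % len(feasible)]

    from rdkit import Chem

    b = _MolBuilder()
    n = b.add("N", (0.0, 0.0, 0.0), charge=1)
    core = [b.add("C", 1.5 * _unit(rng.normal(size=3)), bond_to=n) for _ in range(4)]
    slot = 0
    for _ in range(target_hbd):
        c0 = core[slot % 4]
        slot += 1
        base = b.coords[c0]
        d = _unit(rng.normal(size=3))
        nn = b.add("N", base + 1.5 * d, bond_to=c0)
        b.add("H", base + 1.5 * d + d, bond_to=nn)
        cc = b.add("C", base + 2.9 * d, bond_to=nn)
        b.add("O", base + 2.9 * d + 1.2 * _unit(rng.normal(size=3)), bond_to=cc,
              order=Chem.BondType.DOUBLE)
    for arm in combo:
        c0 = core[slot % 4]
        slot += 1
        prev = c0
        pos = b.coords[c0].copy()
        d = _unit(rng.normal(size=3))
        for element in _DECOY_ARMS[arm][2]:
            pos = pos + 1.5 * d
            prev = b.add(element, pos, bond_to=prev)
    return b.finish(mol_id)


def generate_screening_library(model: PharmacophoreModel, spec: Optional[LibrarySpec] = None,
                               ) -> tuple[list[Molecule], dict]:
    """Actives plus property-matched, feature-broken decoys, with labels.

    Returns ``(molecules, labels)`` where labels maps molecule id to
    ``"active"`` or ``"decoy"``. Actives satisfy all essential features of
    the model (alternating either-group choices); each active's decoys
    match its 1D property profile within the ``LibrarySpec`` tolerances but have a
    rearranged bond graph that cannot realize a hydrophobic feature.
    ``n_feature_matching_decoys`` adds decoy-labelled molecules that do
    satisfy the features but collide with the model's exclusion volumes —
    these are retrieved only when exclusion-volume checking is disabled.
    """
    spec = spec or LibrarySpec()
    essentials = len([i for i in model.essential_indices
                      if not any(i in g for g in model.either_groups)]) \
        + len(model.either_groups)
    if essentials < 2:
        raise ValueError("model must have at least two essential features")
    from .feature_perception import FeatureType as FT

    has_essential_h = any(model.features[i].type is FT.H
                          for i in model.essential_indices) or any(
        model.features[m].type is FT.H for g in model.either_groups for m in g)
    if not has_essential_h:
        raise DecoyGenerationError(
            "decoy topology breaking requires an essential hydrophobic feature")
    rng = np.random.default_rng(spec.seed)
    mols: list[Molecule] = []
    labels: dict[str, str] = {}
    actives = []
    for i in range(spec.n_actives):
        mol = build_active(model, f"active-{i + 1}", rng, choice=i,
                           jitter=spec.position_jitter)
        actives.append(mol)
        mols.append(mol)
        labels[mol.id] = "active"
    if spec.total_decoys is not None:
        per_active = [spec.total_decoys // spec.n_actives] * spec.n_actives
        for i in range(spec.total_decoys % spec.n_actives):
            per_active[i] += 1
    else:
        per_active = [spec.decoys_per_active] * spec.n_actives
    for i, (active, k) in enumerate(zip(actives, per_active)):
        props = property_vector(active)
        parent_smiles = _canonical_graph(active)
        for j in range(k):
            decoy = build_decoy(props, f"decoy-{i + 1}-{j + 1}", j, rng, spec)
            if _canonical_graph(decoy) == parent_smiles:  # pragma: no cover
                raise DecoyGenerationError("decoy graph identical to parent")
            mols.append(decoy)
            labels[decoy.id] = "decoy"
    if spec.n_feature_matching_decoys:
        for k in range(spec.n_feature_matching_decoys):
            clash = _clash_point(model, choice=k)
            if clash is None:
                log.warning("no reachable exclusion volume; skipping bulky decoys")
                break
            mol = build_active(model, f"bulky-{k + 1}", rng, choice=k,
                               jitter=0.0, clash_point=clash)
            mols.append(mol)
            labels[mol.id] = "decoy"
    return mols, labels


def _clash_point(model: PharmacophoreModel, choice: int = 0) -> Optional[np.ndarray]:
    """A point that any essential-feature-exact placement maps into an
    exclusion sphere.

    With three or more (non-collinear) essential targets the placement of a
    jitter-free active is fully determined, so any sphere center works.
    With two targets the placement retains a free rotation about the axis
    through the two feature centers, so the point must lie on that axis:
    the extended line is scanned for a position inside a sphere.
    """
    if not model.exclusion_volumes:
        return None
    centers = np.array([c for c, _r in model.exclusion_volumes])
    radii = np.array([r for _c, r in model.exclusion_volumes])
    targets = np.array([c for _t, c in _active_targets(model, choice)])
    if len(targets) >= 3:
        spread = np.linalg.svd(targets - targets.mean(axis=0), compute_uv=False)
        if spread[1] > 1e-6:
            return centers[0]
    c1, c2 = targets[0], targets[1]
    axis = _unit(c2 - c1)
    best = None
    for s in np.arange(-20.0, 20.0, 0.2):
        p = c1 + s * axis
        d = np.linalg.norm(centers - p, axis=1) - radii
        i = int(np.argmin(d))
        if best is None or d[i] < best[0]:
            best = (float(d[i]), p)
    if best is not None and best[0] < -0.1:  # safely inside a sphere
        return best[1]
    return None


def _canonical_graph(mol: Molecule) -> str:
    from rdkit import Chem

    return Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(mol.rdmol)))
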