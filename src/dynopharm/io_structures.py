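"""Readers/writers for trajectories, small-molecule libraries and models.

Trajectories travel as multi-model PDB files (the lowest common denominator
for protein–ligand complex snapshots); libraries as one-SMILES-per-line text
or SDF V2000 with explicit 3D conformers; pharmacophore models as a small,
versioned JSON schema (see :func:`write_pharmacophore`).

Coordinates are Å everywhere. Atom identity is (chain, resid, atom name);
atom ordering is required to be identical across all frames of a trajectory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import (
    BadModelFileError,
    FrameMismatchError,
    LigandNotFoundError,
    TooFewFramesError,
)
from .feature_perception import ChemFeature, FeatureType, STANDARD_RESNAMES

log = logging.getLogger(__name__)


@dataclass
class Atom:
    """One atom's metadata plus its frame-0 coordinates (Å)."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    xyz: np.ndarray

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom coordinates must be finite")


@dataclass
class Frame:
    """A lightweight per-frame view into a trajectory."""

    index: int
    time_ps: float
    trajectory: "Trajectory"

    @property
    def coords(self) -> np.ndarray:
        return self.trajectory.coords[self.index]

    @property
    def atoms(self) -> list[Atom]:
        xyz = self.coords
        return [
            Atom(a.serial, a.name, a.element, a.resname, a.resid, a.chain, xyz[i])
            for i, a in enumerate(self.trajectory.atom_table)
        ]


@dataclass
class Trajectory:
    """Ordered frames of one protein–ligand complex.

    ``atom_table`` holds per-atom metadata shared by all frames; ``coords``
    is the (frames, atoms, 3) coordinate array in Å. The ligand is selected
    by residue name, the protein as all standard amino-acid residues.
    """

    atom_table: list[Atom]
    coords: np.ndarray
    ligand_resname: Optional[str] = None
    times_ps: Optional[np.ndarray] = None
    ligand_template: Optional["Molecule"] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ValueError("coords must be (frames >= 1, atoms, 3)")
        if self.coords.shape[1] != len(self.atom_table):
            raise FrameMismatchError("coordinate array does not match atom table")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def ligand_indices(self) -> np.ndarray:
        if self.ligand_resname is None:
            return np.array([], dtype=int)
        return np.array(
            [i for i, a in enumerate(self.atom_table) if a.resname == self.ligand_resname],
            dtype=int,
        )

    @property
    def protein_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atom_table) if a.resname in STANDARD_RESNAMES],
            dtype=int,
        )

    def frame(self, index: int) -> Frame:
        t = float(self.times_ps[index]) if self.times_ps is not None else float(index)
        return Frame(index, t, self)

    @property
    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def with_coords(self, coords: np.ndarray, times_ps=None) -> "Trajectory":
        return Trajectory(self.atom_table, coords, self.ligand_resname,
                          self.times_ps if times_ps is None else times_ps,
                          self.ligand_template)


# ---------------------------------------------------------------------------
# multi-model PDB I/O (biotite-backed)


def read_trajectory(path, ligand_resname: str,
                    ligand_template: Optional["Molecule"] = None) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Raises
    ------
    LigandNotFoundError
        if any model lacks the ligand residue.
    FrameMismatchError
        if models disagree in atom count or atom identity.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    arrays = [pdb.get_structure(model=m + 1) for m in range(n_models)]
    for m, arr in enumerate(arrays):
        if ligand_resname not in set(arr.res_name):
            raise LigandNotFoundError(
                f"ligand residue {ligand_resname!r} missing from model {m + 1}")
    ref = arrays[0]
    ref_id = list(zip(ref.chain_id, ref.res_id, ref.atom_name))
    for m, arr in enumerate(arrays[1:], start=2):
        if arr.array_length() != ref.array_length() or \
                list(zip(arr.chain_id, arr.res_id, arr.atom_name)) != ref_id:
            raise FrameMismatchError(f"model {m} atom ordering differs from model 1")

    atom_table = [
        Atom(i + 1, ref.atom_name[i], (ref.element[i] or "X").capitalize(),
             ref.res_name[i], int(ref.res_id[i]), str(ref.chain_id[i]), ref.coord[i])
        for i in range(ref.array_length())
    ]
    coords = np.stack([arr.coord for arr in arrays]).astype(float)
    traj = Trajectory(atom_table, coords, ligand_resname, ligand_template=ligand_template)
    if len(traj.ligand_indices) == 0:
        raise LigandNotFoundError(f"ligand residue {ligand_resname!r} not found")
    return traj


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a standard multi-model PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_frames, n_atoms = traj.n_frames, traj.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord[:] = traj.coords
    stack.chain_id = np.array([a.chain for a in traj.atom_table])
    stack.res_id = np.array([a.resid for a in traj.atom_table])
    stack.res_name = np.array([a.resname for a in traj.atom_table])
    stack.atom_name = np.array([a.name for a in traj.atom_table])
    stack.element = np.array([a.element.upper() for a in traj.atom_table])
    stack.hetero = np.array(
        [a.resname not in STANDARD_RESNAMES for a in traj.atom_table])
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))


def downsample(traj: Trajectory, n: int) -> Trajectory:
    """Keep ``n`` evenly distributed frames (first and last always retained).

    Selected indices are ``floor(i * (F - 1) / (n - 1))`` for ``i = 0..n-1``.
    """
    f = traj.n_frames
    if n > f:
        raise TooFewFramesError(f"requested {n} frames from a {f}-frame trajectory")
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = downsample_indices(f, n)
    times = traj.times_ps[idx] if traj.times_ps is not None else None
    return traj.with_coords(traj.coords[idx].copy(), times_ps=times)


def downsample_indices(n_frames: int, n: int) -> np.ndarray:
    if n == 1:
        return np.array([0], dtype=int)
    i = np.arange(n)
    return (i * (n_frames - 1)) // (n - 1)


# ---------------------------------------------------------------------------
# small molecules


@dataclass
class Molecule:
    """A small molecule: an RDKit mol plus a stable id.

    Conformer coordinate sets (Å) are stored on the RDKit mol. The ``atoms``
    and ``bonds`` views expose the minimal topology the rest of the package
    relies on.
    """

    id: str
    rdmol: "object"

    @property
    def atoms(self) -> list[tuple]:
        return [(a.GetSymbol(), a.GetFormalCharge()) for a in self.rdmol.GetAtoms()]

    @property
    def bonds(self) -> list[tuple]:
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble(),
             b.GetIsAromatic())
            for b in self.rdmol.GetBonds()
        ]

    @property
    def n_conformers(self) -> int:
        return self.rdmol.GetNumConformers()

    def conformer(self, index: int = 0) -> np.ndarray:
        conf = self.rdmol.GetConformer(index)
        return np.array(conf.GetPositions(), dtype=float)

    @classmethod
    def from_smiles(cls, smiles: str, mol_id: str) -> "Molecule":
        from rdkit import Chem

        rdmol = Chem.MolFromSmiles(smiles)
        if rdmol is None:
            raise ValueError(f"unparsable SMILES: {smiles!r}")
        return cls(mol_id, rdmol)


def read_library(path) -> list[Molecule]:
    """Read a screening library from SMILES (one per line) or SDF.

    Unparsable records are skipped, not fatal; the skip count is logged.
    SDF records sharing a title are grouped as conformers of one molecule.
    """
    path = Path(path)
    if path.suffix.lower() in (".sdf", ".mol"):
        return _read_sdf(path)
    return _read_smiles(path)


def _read_smiles(path: Path) -> list[Molecule]:
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    mols, skipped = [], 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"mol{ln}"
        rdmol = Chem.MolFromSmiles(smiles)
        if rdmol is None:
            skipped += 1
            continue
        mols.append(Molecule(mol_id, rdmol))
    if skipped:
        log.warning("read_library: skipped %d unparsable SMILES record(s)", skipped)
    return mols


def _read_sdf(path: Path) -> list[Molecule]:
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    grouped: dict[str, Molecule] = {}
    order: list[str] = []
    skipped = 0
    for n, rdmol in enumerate(supplier):
        if rdmol is None:
            skipped += 1
            continue
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        name = name.strip() or f"mol{n + 1}"
        if name not in grouped:
            grouped[name] = Molecule(name, rdmol)
            order.append(name)
        else:
            conf = rdmol.GetConformer()
            grouped[name].rdmol.AddConformer(conf, assignId=True)
    if skipped:
        log.warning("read_library: skipped %d unparsable SDF record(s)", skipped)
    return [grouped[n] for n in order]


def write_library_sdf(mols: Sequence[Molecule], path) -> None:
    """Write molecules (every conformer as its own record) as SDF V2000."""
    from rdkit import Chem

    with Chem.SDWriter(str(path)) as w:
        for mol in mols:
            m = Chem.Mol(mol.rdmol)
            m.SetProp("_Name", mol.id)
            if m.GetNumConformers() == 0:
                w.write(m)
            else:
                for conf in m.GetConformers():
                    w.write(m, confId=conf.GetId())


# ---------------------------------------------------------------------------
# pharmacophore model JSON

PHARMACOPHORE_FORMAT = "dynopharm-pharmacophore"
PHARMACOPHORE_VERSION = 1


def write_pharmacophore(model, path) -> None:
    """Serialize a pharmacophore model to versioned JSON (lossless)."""
    payload = {
        "format": PHARMACOPHORE_FORMAT,
        "version": PHARMACOPHORE_VERSION,
        "features": [
            {
                "type": f.type.value,
                "center": list(map(float, f.center)),
                "radius": float(f.radius),
                "direction": None if f.direction is None else list(map(float, f.direction)),
                "source_atoms": list(f.source_atoms),
                "partner": None if f.partner is None else list(f.partner),
                "flag": model.flags[i],
            }
            for i, f in enumerate(model.features)
        ],
        "either_groups": [list(g) for g in model.either_groups],
        "exclusion_volumes": [
            {"center": list(map(float, c)), "radius": float(r)}
            for c, r in model.exclusion_volumes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_pharmacophore(path):
    """Read a pharmacophore model written by :func:`write_pharmacophore`.

    Raises :class:`BadModelFileError` on any schema violation.
    """
    from .pharmacophore_build import PharmacophoreModel

    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise BadModelFileError(f"cannot parse model file: {exc}") from exc
    if not isinstance(payload, dict) or "features" not in payload:
        raise BadModelFileError("missing 'features' key")
    if payload.get("format") not in (None, PHARMACOPHORE_FORMAT):
        raise BadModelFileError(f"unknown format {payload.get('format')!r}")
    try:
        features, flags = [], []
        for f in payload["features"]:
            features.append(
                ChemFeature(
                    FeatureType(f["type"]),
                    np.asarray(f["center"], float),
                    float(f["radius"]),
                    direction=None if f.get("direction") is None
                    else np.asarray(f["direction"], float),
                    source_atoms=tuple(f.get("source_atoms", ())),
                    partner=None if f.get("partner") is None else tuple(f["partner"]),
                )
            )
            flags.append(f.get("flag", "optional"))
        exclusion = [
            (np.asarray(v["center"], float), float(v["radius"]))
            for v in payload.get("exclusion_volumes", [])
        ]
        either = [tuple(g) for g in payload.get("either_groups", [])]
    except (KeyError, TypeError, ValueError) as exc:
        raise BadModelFileError(f"malformed model file: {exc}") from exc
    return PharmacophoreModel(features=features, exclusion_volumes=exclusion,
                              flags=flags, either_groups=either)
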