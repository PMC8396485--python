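"""Trajectory-level descriptors: RMSF, pairwise ligand RMSD, ring distances.

The analysis order follows standard practice: the whole complex is first
superposed onto the first frame (least-squares rigid fit on a protein
selection), then descriptors are computed in that common frame without any
per-pair re-superposition — so the pairwise ligand RMSD matrix is a scaled
Euclidean metric (symmetric, zero diagonal, triangle inequality) and
preserves binding-mode drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoRingError
from .feature_perception import RING_ATOMS, centroid
from .geometry import apply_transform, kabsch
from .io_structures import Trajectory, downsample_indices

log = logging.getLogger(__name__)


def align_to_first_frame(traj: Trajectory, selection=None) -> Trajectory:
    """Superpose every frame onto frame 0 by a Kabsch fit on ``selection``.

    ``selection`` is an index array (default: all protein atoms); the whole
    frame — ligand included — moves with the fitted transform. Raises
    :class:`DegenerateFitError` for selections that do not determine a
    rotation (fewer than 3 atoms, collinear).
    """
    idx = np.asarray(selection if selection is not None else traj.protein_indices,
                     dtype=int)
    ref = traj.coords[0][idx]
    out = np.empty_like(traj.coords)
    out[0] = traj.coords[0]
    for f in range(1, traj.n_frames):
        rot, trans = kabsch(traj.coords[f][idx], ref)
        out[f] = apply_transform(traj.coords[f], rot, trans)
    return traj.with_coords(out)


def rmsf_per_residue(traj: Trajectory) -> pd.DataFrame:
    """Per-residue RMSF of the Cα atom over an aligned trajectory.

    RMSF_i = sqrt(mean_t |x_i(t) - mean_t x_i|^2). Residues without a Cα
    atom are omitted with a warning. Returns a DataFrame with columns
    (chain, resid, resname, rmsf).
    """
    ca = {}
    residues = {}
    for i in traj.protein_indices:
        a = traj.atom_table[i]
        residues.setdefault((a.chain, a.resid), a.resname)
        if a.name == "CA":
            ca[(a.chain, a.resid)] = i
    missing = [k for k in residues if k not in ca]
    if missing:
        log.warning("rmsf_per_residue: %d residue(s) lack a CA atom; omitted",
                    len(missing))
    rows = []
    for (chain, resid), i in sorted(ca.items()):
        x = traj.coords[:, i, :]
        mean = x.mean(axis=0)
        rmsf = float(np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=1))))
        rows.append({"chain": chain, "resid": resid,
                     "resname": residues[(chain, resid)], "rmsf": rmsf})
    return pd.DataFrame(rows, columns=["chain", "resid", "resname", "rmsf"])


def pairwise_ligand_rmsd(traj: Trajectory, n_samples: int | None = None) -> np.ndarray:
    """Pairwise RMSD matrix over ligand coordinates of sampled frames.

    Frames are sampled evenly (first/last kept); RMSD is computed in the
    common aligned frame with no per-pair re-superposition.
    """
    lig = traj.ligand_indices
    if len(lig) == 0:
        raise ValueError("trajectory has no ligand selection")
    n_samples = n_samples or traj.n_frames
    idx = downsample_indices(traj.n_frames, n_samples)
    x = traj.coords[np.ix_(idx, lig)]  # (n, m, 3)
    n, m, _ = x.shape
    flat = x.reshape(n, -1)
    sq = np.einsum("ij,ij->i", flat, flat)
    gram = flat @ flat.T
    d2 = (sq[:, None] + sq[None, :] - 2.0 * gram) / m
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


@dataclass
class RingDistanceSeries:
    """Per-frame distances between aromatic ring centroids of residue pairs."""

    table: pd.DataFrame  # columns: frame, pair, distance

    def series(self, pair_label: str) -> np.ndarray:
        t = self.table
        return t[t.pair == pair_label].distance.to_numpy()


def _ring_indices(traj: Trajectory, chain: str, resid: int) -> list[int]:
    names = {}
    resname = None
    for i in traj.protein_indices:
        a = traj.atom_table[i]
        if a.chain == chain and a.resid == resid:
            names[a.name] = i
            resname = a.resname
    if resname is None or resname not in RING_ATOMS:
        raise NoRingError(f"residue {chain}{resid} has no recognized aromatic ring")
    wanted = RING_ATOMS[resname]
    if not all(n in names for n in wanted):
        raise NoRingError(f"residue {chain}{resid} ({resname}) is missing ring atoms")
    return [names[n] for n in wanted]


def ring_distance_series(traj: Trajectory, residue_pairs) -> RingDistanceSeries:
    """Distance between ring centroids of each residue pair, per frame.

    ``residue_pairs`` is a list of ((chain, resid), (chain, resid)); a pair
    of identical residues is rejected. Used e.g. to follow the aromatic
    pi-pi network between the S5 phenylalanine and the S6 phenylalanine of
    each subunit, whose centroid distance jumps from ~4 to ~8 Å when the
    lower ring rotates into the central cavity.
    """
    rows = []
    for (c1, r1), (c2, r2) in residue_pairs:
        if (c1, r1) == (c2, r2):
            raise ValueError("a residue cannot be paired with itself")
        idx1 = _ring_indices(traj, c1, r1)
        idx2 = _ring_indices(traj, c2, r2)
        label = f"{c1}{r1}-{c2}{r2}"
        cen1 = traj.coords[:, idx1, :].mean(axis=1)
        cen2 = traj.coords[:, idx2, :].mean(axis=1)
        dist = np.linalg.norm(cen1 - cen2, axis=1)
        for f, d in enumerate(dist):
            rows.append({"frame": f, "pair": label, "distance": float(d)})
    return RingDistanceSeries(pd.DataFrame(rows, columns=["frame", "pair", "distance"]))
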