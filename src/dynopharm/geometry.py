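"""Rigid-body superposition utilities (Kabsch least-squares fit)."""

from __future__ import annotations

import numpy as np

from .errors import DegenerateFitError


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           allow_degenerate: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns ``(R, t)`` with ``R @ x + t`` mapping mobile points onto the
    reference. ``R`` is a proper rotation (det = +1).

    Raises
    ------
    DegenerateFitError
        for fewer than 3 points or a (near-)collinear point set, where the
        rotation about the common axis is undetermined.
    """
    p = np.asarray(mobile, float)
    q = np.asarray(reference, float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if p.shape[0] < 3 and not allow_degenerate:
        raise DegenerateFitError("need at least 3 points for a rigid fit")
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, s, vt = np.linalg.svd(h)
    if not allow_degenerate:
        scale = max(np.linalg.norm(p - pc), 1.0)
        if s[1] < 1e-8 * scale:
            raise DegenerateFitError("collinear point set: rotation undetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = qc - rot @ pc
    return rot, trans


def apply_transform(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ rot.T + trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after optimal rigid superposition."""
    rot, trans = kabsch(mobile, reference)
    return rmsd(apply_transform(mobile, rot, trans), reference)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
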