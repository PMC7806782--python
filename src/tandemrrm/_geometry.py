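"""Rigid-body superposition primitives (Kabsch algorithm).

The batched variant runs one 3x3 SVD per trajectory frame, which is what the
trajectory analyses need; the single-pair variant is the same math on one
coordinate set.  Rotations are always proper (reflections corrected).
"""
from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError

__all__ = ["kabsch_rotation", "kabsch_rmsd", "superpose_batch"]


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R minimising ||R @ mobile_i - target_i||.

    Both inputs must already be centred (n, 3).
    """
    h = mobile.T @ target  # (3, 3) covariance
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray):
    """Superpose b onto a; return (rmsd, rotation, translation).

    ``rotation @ x + translation`` maps original b coordinates onto a's frame.
    Requires >= 3 paired points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    n = a.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 paired points, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - ca, b - cb
    rot = kabsch_rotation(bc, ac)
    resid = ac - bc @ rot.T
    rmsd = float(np.sqrt((resid**2).sum() / n))
    trans = ca - rot @ cb
    return rmsd, rot, trans


def superpose_batch(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """RMSD of each frame (F, n, 3) against ``reference`` (n, 3) after
    optimal superposition, vectorised over frames."""
    x = np.asarray(frames, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if x.ndim != 3 or x.shape[1:] != ref.shape:
        raise ValueError("frames (F, n, 3) must match reference (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 atoms, got {n}")
    refc = ref - ref.mean(axis=0)
    xc = x - x.mean(axis=1, keepdims=True)
    h = np.einsum("fni,nj->fij", xc, refc)  # per-frame covariance
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", u, vt)))
    vt[:, -1, :] *= d[:, None]
    rot = np.einsum("fij,fjk->fki", u, vt)  # maps frame coords onto reference
    fitted = np.einsum("fij,fnj->fni", rot, xc)
    resid = fitted - refc[None]
    return np.sqrt((resid**2).sum(axis=(1, 2)) / n)


def fit_frames_to_reference(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Return the frames (F, n, 3) rotated/translated onto ``reference``."""
    x = np.asarray(frames, dtype=float)
    ref = np.asarray(reference, dtype=float)
    refc = ref - ref.mean(axis=0)
    xc = x - x.mean(axis=1, keepdims=True)
    h = np.einsum("fni,nj->fij", xc, refc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", u, vt)))
    vt[:, -1, :] *= d[:, None]
    rot = np.einsum("fij,fjk->fki", u, vt)
    return np.einsum("fij,fnj->fni", rot, xc) + ref.mean(axis=0)
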