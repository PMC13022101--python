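"""Least-squares rigid-body fitting (Kabsch) and RMSD series.

All fits minimize the (optionally weighted) RMSD between paired point
sets; the reflection branch of the SVD solution is corrected so the
returned rotation is always proper (det = +1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .structure_io import AtomSelection, TrajectorySystem

__all__ = ["RigidTransform", "RmsdSeries", "kabsch_fit", "align_trajectory", "rmsd_series"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> x @ rotation.T + translation`` (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_after: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RmsdSeries:
    """Per-frame minimized RMSD (Å) versus a fixed reference frame."""

    frame_indices: np.ndarray
    values: np.ndarray
    reference_frame: int


def _normalized_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise DegenerateInputError(f"weights must have shape ({n},), got {w.shape}")
    if np.any(w < 0) or w.sum() <= 0:
        raise DegenerateInputError("weights must be non-negative with positive sum")
    return w / w.sum()


def kabsch_fit(
    mobile_coords: np.ndarray,
    ref_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Optimal rigid superposition of ``mobile_coords`` onto ``ref_coords``.

    Returns the transform minimizing the weighted RMSD. Requires >= 3
    non-collinear points.
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(ref_coords, dtype=float)
    if mobile.shape != ref.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DegenerateInputError(
            f"point sets must share shape (n, 3); got {mobile.shape} vs {ref.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need >= 3 points for a rigid fit, got {n}")
    w = _normalized_weights(weights, n)

    mob_center = w @ mobile
    ref_center = w @ ref
    mob_c = mobile - mob_center
    ref_c = ref - ref_center

    cov = mob_c.T @ (ref_c * w[:, None])
    if np.linalg.matrix_rank(cov, tol=1e-12) < 2:
        raise DegenerateInputError("degenerate (collinear or coincident) geometry")
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T

    fitted = mob_c @ rotation.T + ref_center
    rmsd = float(np.sqrt(np.sum(w[:, None] * (fitted - ref) ** 2, axis=(0, 1)).sum()))
    translation = ref_center - rotation @ mob_center
    return RigidTransform(rotation=rotation, translation=translation, rmsd_after=rmsd)


def _batched_fit(
    mobile_stack: np.ndarray,
    ref: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Kabsch of many frames onto one reference.

    Returns (rotations (F,3,3), translations (F,3), rmsd (F,))."""
    stack = np.asarray(mobile_stack, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n = ref.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need >= 3 points for a rigid fit, got {n}")
    w = _normalized_weights(weights, n)

    mob_centers = np.einsum("j,fjk->fk", w, stack)
    ref_center = w @ ref
    mob_c = stack - mob_centers[:, None, :]
    ref_c = ref - ref_center

    cov = np.einsum("fji,jk->fik", mob_c * w[None, :, None], ref_c)
    u, s, vt = np.linalg.svd(cov)
    det = np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(vt, (0, 2, 1)),
                                  np.transpose(u, (0, 2, 1))))
    flip = np.ones_like(s)
    flip[:, 2] = np.sign(det)
    rot = np.einsum(
        "fij,fj,fkj->fik", np.transpose(vt, (0, 2, 1)), flip, u
    )
    fitted = np.einsum("fij,fnj->fni", rot, mob_c) + ref_center
    sq = np.sum((fitted - ref) ** 2, axis=2)
    rmsd = np.sqrt(np.einsum("fn,n->f", sq, w))
    trans = ref_center - np.einsum("fij,fj->fi", rot, mob_centers)
    return rot, trans, rmsd


def align_trajectory(
    system: TrajectorySystem,
    selection: AtomSelection,
    reference_frame: int = 0,
    weights: np.ndarray | None = None,
) -> TrajectorySystem:
    """Superpose every frame onto ``reference_frame`` using the fit selection.

    The fit is computed on the selection atoms; the resulting transform is
    applied to *all* atoms of the frame. Returns a new system.
    """
    if selection.n_atoms == 0:
        raise DegenerateInputError("alignment requires a non-empty selection")
    if not 0 <= reference_frame < system.n_frames:
        raise DegenerateInputError(
            f"reference_frame {reference_frame} out of range [0, {system.n_frames})"
        )
    idx = selection.indices
    ref = system.coords[reference_frame, idx]
    rot, trans, _ = _batched_fit(system.coords[:, idx, :], ref, weights)
    aligned = np.einsum("fij,fnj->fni", rot, system.coords) + trans[:, None, :]
    return TrajectorySystem(
        names=system.names,
        resids=system.resids,
        resnames=system.resnames,
        chain_ids=system.chain_ids,
        elements=system.elements,
        coords=aligned,
        dt_ps=system.dt_ps,
        source_paths=system.source_paths,
    )


def rmsd_series(
    system: TrajectorySystem,
    selection: AtomSelection,
    reference_frame: int = 0,
    weights: np.ndarray | None = None,
) -> RmsdSeries:
    """Per-frame minimized RMSD versus ``reference_frame`` on the selection."""
    if selection.n_atoms == 0:
        raise DegenerateInputError("rmsd_series requires a non-empty selection")
    if not 0 <= reference_frame < system.n_frames:
        raise DegenerateInputError(
            f"reference_frame {reference_frame} out of range [0, {system.n_frames})"
        )
    idx = selection.indices
    ref = system.coords[reference_frame, idx]
    _, _, rmsd = _batched_fit(system.coords[:, idx, :], ref, weights)
    rmsd[reference_frame] = 0.0
    return RmsdSeries(
        frame_indices=np.arange(system.n_frames),
        values=rmsd,
        reference_frame=reference_frame,
    )
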