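"""Scale-preserving Procrustes alignment of corresponded body shapes.

Superimposition uses translation and proper rotation only — no scaling and
no reflection — so that size differences between bodies, which carry real
information about composition, survive alignment.  The consensus procedure
centres every shape, averages them, and fits each shape to the average;
optionally the average/fit cycle is iterated to convergence (generalized
Procrustes analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import RETAINED_REGIONS, BodyMesh, check_correspondence


class DegenerateShapeError(ValueError):
    """Reference shape has no spatial extent."""


@dataclass
class AlignmentResult:
    """Rigid transform taking a shape onto a reference.

    ``aligned.vertices = shape.vertices @ rotation.T + translation``.
    """

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,)
    aligned: BodyMesh
    residual: float  # RMS point distance to the reference, cm


def _rigid_fit(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation mapping src onto dst (Kabsch).

    The rotation is constrained to be proper (det = +1): if the unconstrained
    orthogonal solution is a reflection, the smallest singular direction is
    flipped.  Bodies must never be mirrored.
    """
    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    h = (src - c_src).T @ (dst - c_dst)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = c_dst - rot @ c_src
    return rot, trans


def align_to_reference(
    shape: BodyMesh,
    reference: BodyMesh,
    regions: tuple[str, ...] = RETAINED_REGIONS,
) -> AlignmentResult:
    """Rigidly align ``shape`` to ``reference`` (corresponded vertices).

    Minimises the sum of squared point distances over translation and proper
    rotation.  The transform is estimated from the vertices in ``regions``
    (by default the retained torso + limbs; head/hands/feet are excluded
    before superimposition) and applied to the whole mesh.  Centroid size is
    preserved exactly (rigid transform), so a uniformly larger body stays
    larger after alignment.
    """
    if shape.n_vertices != reference.n_vertices:
        raise ValueError(
            f"{shape.identity_id}: {shape.n_vertices} vertices vs reference "
            f"{reference.n_vertices}"
        )
    mask = shape.region_mask(regions)
    if not mask.any():
        mask = np.ones(shape.n_vertices, bool)
    ref_pts = reference.vertices[mask]
    spread = ref_pts - ref_pts.mean(axis=0)
    if float(np.abs(spread).max(initial=0.0)) < 1e-12:
        raise DegenerateShapeError("reference has all points identical")
    rot, trans = _rigid_fit(shape.vertices[mask], ref_pts)
    aligned = shape.copy()
    aligned.vertices = shape.vertices @ rot.T + trans
    residual = float(
        np.sqrt(
            np.mean(np.sum((aligned.vertices[mask] - ref_pts) ** 2, axis=1))
        )
    )
    return AlignmentResult(rotation=rot, translation=trans, aligned=aligned, residual=residual)


def build_consensus(
    cohort: Sequence[BodyMesh],
    iterations: int = 1,
    tol: float = 1e-6,
    max_iterations: int = 100,
) -> tuple[BodyMesh, list[BodyMesh], list[AlignmentResult]]:
    """Consensus mean shape and cohort aligned to it.

    ``iterations=1`` performs the single-pass procedure: centre each shape
    on its centroid, average coordinate-wise, then fit every shape to that
    average.  With ``iterations > 1`` the average/fit cycle repeats until
    the mean shape moves less than ``tol`` cm at every point, or the
    iteration cap is reached.

    Returns ``(mean, aligned_cohort, results)`` in cohort order.
    """
    if len(cohort) < 2:
        raise ValueError("consensus needs at least 2 shapes")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    check_correspondence(cohort)

    mask0 = cohort[0].region_mask(RETAINED_REGIONS)
    if not mask0.any():
        mask0 = np.ones(cohort[0].n_vertices, bool)
    centred = [m.vertices - m.vertices[mask0].mean(axis=0) for m in cohort]
    mean_pts = np.mean(centred, axis=0)
    mean = cohort[0].copy(identity_id="consensus_mean")
    mean.vertices = mean_pts

    results: list[AlignmentResult] = []
    for it in range(min(iterations, max_iterations)):
        results = [align_to_reference(m, mean) for m in cohort]
        if it + 1 >= iterations:
            break
        new_mean_pts = np.mean([r.aligned.vertices for r in results], axis=0)
        movement = float(np.abs(new_mean_pts - mean.vertices).max())
        if movement < tol:
            break  # keep mean consistent with the alignments just computed
        mean.vertices = new_mean_pts
    aligned = [r.aligned for r in results]
    return mean, aligned, results
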