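"""Procrustes superimposition of landmark constellations.

Shape analysis of swallow kinematics starts by removing similarity nuisance
— translation, scale (magnification), rotation (patient position) — so only
shape variation remains. This module implements full Procrustes
superimposition in 2-D: pairwise alignment in closed form and iterative
generalized Procrustes analysis (GPA) producing a consensus configuration.

Conventions:

* Scale is removed to unit centroid size (full Procrustes) because
  fluoroscopic magnification differs between videos.
* Rotations are proper (det +1) — lateral-view anatomy is never mirrored.
  The 2-D optimal rotation is solved in closed form from the
  cross-covariance; the closed form can only produce proper rotations.
* The converged solution is canonically oriented: the consensus's principal
  axis is rotated to +y (the roughly vertical vertebral column), removing
  the global-rotation gauge freedom so outputs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateShapeError, ShapeMismatchError

#: a Shape is a (k, 2) float array of landmark coordinates
Shape = np.ndarray

_DEGENERATE_TOL = 1e-12


def _as_shape(shape) -> np.ndarray:
    arr = np.asarray(shape, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ShapeMismatchError(f"shape must be (k, 2), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("shape coordinates must be finite")
    return arr


def centroid(shape: Shape) -> np.ndarray:
    """Mean landmark position of a configuration."""
    return _as_shape(shape).mean(axis=0)


def centroid_size(shape: Shape) -> float:
    """Root-sum-of-squares of landmark distances from the centroid.

    The morphometric scale measure removed by superimposition. Raises
    :class:`DegenerateShapeError` if all points coincide.
    """
    arr = _as_shape(shape)
    size = float(np.sqrt(((arr - arr.mean(axis=0)) ** 2).sum()))
    if size < _DEGENERATE_TOL:
        raise DegenerateShapeError("all landmarks coincide; size undefined")
    return size


def _normalize(shape: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Center and scale to unit centroid size; return (unit, centroid, size)."""
    c = shape.mean(axis=0)
    centered = shape - c
    size = float(np.sqrt((centered**2).sum()))
    if size < _DEGENERATE_TOL:
        raise DegenerateShapeError("all landmarks coincide; size undefined")
    return centered / size, c, size


def rotation_matrix(angle: float) -> np.ndarray:
    """2-D proper rotation matrix for ``angle`` radians (counterclockwise)."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def optimal_rotation_angle(reference: np.ndarray, target: np.ndarray) -> float:
    """Angle rotating ``target`` onto ``reference`` with least squared error.

    Closed form for 2-D: atan2 of the summed cross and dot products of
    corresponding landmark vectors. Always a proper rotation.
    """
    dot = float((target * reference).sum())
    cross = float(
        (target[:, 0] * reference[:, 1] - target[:, 1] * reference[:, 0]).sum()
    )
    return float(np.arctan2(cross, dot))


@dataclass(frozen=True)
class SimilarityTransform:
    """Proper similarity map ``p -> scale * R(rotation) p + translation``."""

    rotation: float
    scale: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )

    def apply(self, shape: Shape) -> np.ndarray:
        arr = _as_shape(shape)
        return self.scale * arr @ rotation_matrix(self.rotation).T + (
            self.translation
        )

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(rotation=0.0, scale=1.0, translation=np.zeros(2))


def procrustes_distance(shape_a: Shape, shape_b: Shape) -> float:
    """Full Procrustes distance between two configurations.

    Root-sum-of-squares between the unit-size, centered, optimally rotated
    configurations — a pseudo-metric that is zero iff the shapes are
    similarity-equivalent.
    """
    a, _, _ = _normalize(_as_shape(shape_a))
    b, _, _ = _normalize(_as_shape(shape_b))
    if a.shape != b.shape:
        raise ShapeMismatchError(
            f"landmark counts differ: {a.shape[0]} vs {b.shape[0]}"
        )
    angle = optimal_rotation_angle(a, b)
    return float(np.sqrt(((a - b @ rotation_matrix(angle).T) ** 2).sum()))


def align_pair(
    reference: Shape, target: Shape
) -> tuple[np.ndarray, SimilarityTransform, float]:
    """Optimally superimpose ``target`` on ``reference``.

    Returns the aligned target (mapped into the reference's original frame:
    same centroid and centroid size as the reference), the similarity
    transform realizing that map, and the full Procrustes distance.
    """
    ref = _as_shape(reference)
    tgt = _as_shape(target)
    if ref.shape != tgt.shape:
        raise ShapeMismatchError(
            f"landmark counts differ: {ref.shape[0]} vs {tgt.shape[0]}"
        )
    ref_u, ref_c, ref_s = _normalize(ref)
    tgt_u, tgt_c, tgt_s = _normalize(tgt)
    angle = optimal_rotation_angle(ref_u, tgt_u)
    rot = rotation_matrix(angle)
    distance = float(np.sqrt(((ref_u - tgt_u @ rot.T) ** 2).sum()))
    scale = ref_s / tgt_s
    translation = ref_c - scale * (rot @ tgt_c)
    transform = SimilarityTransform(
        rotation=angle, scale=scale, translation=translation
    )
    return transform.apply(tgt), transform, distance


@dataclass(frozen=True)
class AlignedSet:
    """Result of generalized Procrustes analysis.

    ``shapes`` are the superimposed configurations (centroid at the origin,
    unit centroid size); ``consensus`` is the renormalized arithmetic mean;
    ``transforms[i]`` maps input shape i onto ``shapes[i]``.
    """

    shapes: np.ndarray = field(repr=False)  # (n, k, 2)
    consensus: np.ndarray = field(repr=False)  # (k, 2)
    centroid_sizes: np.ndarray = field(repr=False)  # (n,)
    transforms: tuple[SimilarityTransform, ...] = field(repr=False)
    n_iterations: int = 0
    mean_change: float = 0.0
    converged: bool = True
    tangent_projected: bool = False

    @property
    def n_shapes(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.shapes.shape[1]

    def flattened(self) -> np.ndarray:
        """Aligned coordinates as ``(n, 2k)`` rows (x1, y1, ..., xk, yk)."""
        return self.shapes.reshape(self.n_shapes, -1)


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation aligning the consensus's principal axis to +y.

    The principal axis is the leading eigenvector of the 2x2 landmark
    scatter; its sign is fixed so the rotation is deterministic.
    """
    cov = consensus.T @ consensus
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]  # leading eigenvector
    if axis[1] < 0 or (axis[1] == 0 and axis[0] < 0):
        axis = -axis
    # rotate axis onto (0, 1)
    angle = np.arctan2(axis[1], axis[0])
    return rotation_matrix(np.pi / 2 - angle)


def gpa(
    shapes: Sequence[Shape],
    tol: float = 1e-10,
    max_iter: int = 100,
    tangent_projection: bool = False,
) -> AlignedSet:
    """Generalized Procrustes analysis of two or more configurations.

    All shapes are centered and scaled to unit centroid size, then
    iteratively rotated to the running consensus (initialized from the first
    shape) until the consensus changes by less than ``tol``
    (root-sum-of-squares) or ``max_iter`` is reached; non-convergence is
    recorded on the result, not raised. The converged solution is rotated to
    the canonical orientation (consensus principal axis to +y).

    With ``tangent_projection=True``, aligned shapes are additionally
    projected orthogonally onto the tangent space at the consensus; at
    swallowing-scale shape variation the effect is negligible, but the flag
    makes the modeling choice explicit.
    """
    arrs = [_as_shape(s) for s in shapes]
    if len(arrs) < 2:
        raise ValueError("gpa needs at least 2 shapes")
    k = arrs[0].shape[0]
    for arr in arrs:
        if arr.shape[0] != k:
            raise ShapeMismatchError("all shapes must share a landmark count")
    units, cents, sizes = [], [], []
    for arr in arrs:
        u, c, s = _normalize(arr)
        units.append(u)
        cents.append(c)
        sizes.append(s)
    units = np.stack(units)  # (n, k, 2)

    consensus = units[0].copy()
    n_iter = 0
    change = np.inf
    angles = np.zeros(len(arrs))
    for n_iter in range(1, max_iter + 1):
        for i in range(units.shape[0]):
            angles[i] = optimal_rotation_angle(consensus, units[i])
            units[i] = units[i] @ rotation_matrix(angles[i]).T
        new_consensus = units.mean(axis=0)
        new_consensus, _, _ = _normalize(new_consensus)
        change = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if change < tol:
            break
    converged = change < tol

    canon = _canonical_rotation(consensus)
    consensus = consensus @ canon.T
    units = units @ canon.T
    canon_angle = float(np.arctan2(canon[1, 0], canon[0, 0]))

    # total rotation applied to each input: accumulated per-iteration angles
    # are not tracked individually; recover each shape's net rotation directly
    transforms = []
    for i, arr in enumerate(arrs):
        u, c, s = _normalize(arr)
        net = optimal_rotation_angle(units[i], u)
        transforms.append(
            SimilarityTransform(
                rotation=net,
                scale=1.0 / sizes[i],
                translation=-(rotation_matrix(net) @ cents[i]) / sizes[i],
            )
        )

    if tangent_projection:
        c_flat = consensus.reshape(-1)
        flat = units.reshape(units.shape[0], -1)
        # orthogonal projection onto the tangent plane at the consensus
        flat = c_flat + (flat - flat @ np.outer(c_flat, c_flat))
        units = flat.reshape(units.shape)

    return AlignedSet(
        shapes=units,
        consensus=consensus,
        centroid_sizes=np.array(sizes),
        transforms=tuple(transforms),
        n_iterations=n_iter,
        mean_change=change,
        converged=converged,
        tangent_projected=tangent_projection,
    )


def aligned_to_frame(aligned: AlignedSet) -> "pd.DataFrame":  # noqa: F821
    """Aligned coordinates and transforms as a tidy table (CSV-ready)."""
    import pandas as pd

    rows = []
    for i in range(aligned.n_shapes):
        t = aligned.transforms[i]
        for j in range(aligned.n_landmarks):
            rows.append(
                {
                    "shape_index": i,
                    "landmark_id": j + 1,
                    "x": aligned.shapes[i, j, 0],
                    "y": aligned.shapes[i, j, 1],
                    "centroid_size": aligned.centroid_sizes[i],
                    "rotation": t.rotation,
                    "scale": t.scale,
                    "tx": t.translation[0],
                    "ty": t.translation[1],
                }
            )
    return pd.DataFrame(rows)
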