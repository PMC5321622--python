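"""Ordination and two-group discriminant analysis in shape space.

After superimposition, each frame's 12-landmark configuration is a point in
a 24-dimensional flattened shape space (with at most 2k - 4 = 20 degrees of
freedom once translation, scale and rotation are removed). This module
provides principal component analysis of that space and a two-group
discriminant function analysis (DFA) whose axis, re-expressed per landmark,
is the displacement-vector field ("eigenvectors") used to visualize which
components of swallowing mechanics separate the groups — e.g. oral
transport vs pharyngeal phase.

The pooled within-group covariance is singular in the full 24-dim space, so
the discriminant is computed inside the PCA subspace retaining at most
``min(n1 + n2 - 2, 20)`` components with eigenvalue above ``1e-12`` of the
largest, then back-projected. Significance is assessed by permutation: the
group labels are shuffled and the discriminant fully re-estimated per
shuffle, guarding against selection bias; the statistic is the absolute
difference of group mean discriminant scores and the p-value uses add-one
smoothing, ``p = (b + 1) / (n_permutations + 1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .exceptions import ClassSizeError, GroupError, LabelError, SampleSizeError
from .landmark_model import N_LANDMARKS, LandmarkRegistry
from .procrustes import AlignedSet

_EIGTOL = 1e-12
_MIN_CLASS = 3


@dataclass(frozen=True)
class ShapePCA:
    """Eigendecomposition of aligned-shape covariance about the consensus."""

    eigenvalues: np.ndarray = field(repr=False)  # descending
    components: np.ndarray = field(repr=False)  # (m, 2k), orthonormal rows
    scores: np.ndarray = field(repr=False)  # (n, m)
    variance_ratio: np.ndarray = field(repr=False)
    mean: np.ndarray = field(repr=False)  # flattened consensus (2k,)


def shape_pca(aligned: AlignedSet) -> ShapePCA:
    """Principal components of the flattened aligned coordinates.

    Deviations are taken about the consensus shape. All components spanning
    the sample are retained, so reconstruction from the full score matrix is
    exact to numerical precision.
    """
    n = aligned.n_shapes
    if n < 3:
        raise SampleSizeError(f"shape PCA needs at least 3 shapes, got {n}")
    mu = aligned.consensus.reshape(-1)
    x0 = aligned.flattened() - mu
    # thin SVD spans the deviation rows exactly
    _, svals, vt = np.linalg.svd(x0, full_matrices=False)
    eigenvalues = svals**2 / (n - 1)
    total = eigenvalues.sum()
    ratio = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return ShapePCA(
        eigenvalues=eigenvalues,
        components=vt,
        scores=x0 @ vt.T,
        variance_ratio=ratio,
        mean=mu,
    )


@dataclass(frozen=True)
class DFAResult:
    """Two-group discriminant function in shape space.

    ``axis`` is the unit discriminant direction (the whitened Fisher
    coefficient vector) in the flattened space; scores and the permutation
    test use it. ``displacement_vectors`` is the shape change the analysis
    separates — the between-group mean difference of aligned coordinates,
    reshaped to per-landmark (dx, dy) pairs. The two are kept distinct on
    purpose: a coefficient vector weighted by the inverse within-group
    covariance is not itself a shape deformation, and visualizing it as one
    misreads the anatomy; the group mean difference is what the arrows in a
    shape-change plot depict.
    """

    axis: np.ndarray = field(repr=False)  # (2k,), unit norm
    displacement_vectors: np.ndarray = field(repr=False)  # (k, 2)
    scores: np.ndarray = field(repr=False)  # (n,)
    labels: np.ndarray = field(repr=False)
    group_order: tuple[str, str]
    separation: float
    p_value: float
    n_permutations: int
    seed: int

    @property
    def group_sizes(self) -> tuple[int, int]:
        return (
            int(np.sum(self.labels == self.group_order[0])),
            int(np.sum(self.labels == self.group_order[1])),
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-landmark displacement table (landmark_id, dx, dy, magnitude)."""
        mag = np.linalg.norm(self.displacement_vectors, axis=1)
        return pd.DataFrame(
            {
                "landmark_id": np.arange(1, len(mag) + 1),
                "dx": self.displacement_vectors[:, 0],
                "dy": self.displacement_vectors[:, 1],
                "magnitude": mag,
            }
        )

    def summary(self) -> dict:
        n1, n2 = self.group_sizes
        return {
            "groups": list(self.group_order),
            "group_sizes": [n1, n2],
            "separation": self.separation,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }

    def write_summary(self, sink: TextIO) -> None:
        json.dump(self.summary(), sink, indent=2)
        sink.write("\n")


def _fit_direction(
    z: np.ndarray, mask2: np.ndarray, gram: np.ndarray
) -> tuple[np.ndarray, float]:
    """Fisher direction and |mean score difference| in the reduced space.

    ``z`` is (n, m) reduced data, ``mask2`` the boolean group-2 indicator and
    ``gram`` the precomputed ``z.T @ z``. The pooled within-group scatter is
    obtained from the Gram matrix and group means, so permutation re-fits
    cost O(n m + m^3).
    """
    n = z.shape[0]
    n2 = int(mask2.sum())
    n1 = n - n2
    m1 = z[~mask2].mean(axis=0)
    m2 = z[mask2].mean(axis=0)
    sw = (gram - n1 * np.outer(m1, m1) - n2 * np.outer(m2, m2)) / (n - 2)
    diff = m2 - m1
    try:
        w = np.linalg.solve(sw, diff)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(sw, diff, rcond=None)[0]
    norm = np.linalg.norm(w)
    if norm < 1e-300:
        return np.zeros_like(w), 0.0
    w /= norm
    return w, float(abs(w @ diff))


def discriminant_analysis(
    aligned: AlignedSet,
    labels: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
    group_order: tuple[str, str] | None = None,
) -> DFAResult:
    """Two-group DFA of aligned shapes with a permutation test.

    Each aligned configuration is one observation carrying a two-class
    label. The discriminant direction is
    ``pooled-within-covariance^{-1} (mean2 - mean1)`` computed in the
    regularizing PCA subspace and back-projected; the axis is oriented so
    group 2 (by ``group_order``, default the sorted label order — i.e.
    'pharyngeal' when the labels are swallow phases) has the larger mean
    score. Scores are projections of the consensus-centered coordinates on
    the axis.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != aligned.n_shapes:
        raise LabelError(
            f"{labels.shape[0]} labels for {aligned.n_shapes} shapes"
        )
    uniq = sorted(np.unique(labels).tolist())
    if len(uniq) != 2:
        raise LabelError(f"need exactly 2 classes, got {uniq}")
    if group_order is None:
        group_order = (uniq[0], uniq[1])
    elif sorted(group_order) != uniq:
        raise LabelError(
            f"group_order {group_order} does not match labels {uniq}"
        )
    mask2 = labels == group_order[1]
    n2 = int(mask2.sum())
    n1 = labels.shape[0] - n2
    if min(n1, n2) < _MIN_CLASS:
        raise ClassSizeError(
            f"each class needs >= {_MIN_CLASS} members, got {n1} and {n2}"
        )
    if n_permutations < 0:
        raise ValueError("n_permutations must be non-negative")

    mu = aligned.consensus.reshape(-1)
    x0 = aligned.flattened() - mu  # (n, 2k)
    n = x0.shape[0]

    # label-independent regularizing subspace
    _, svals, vt = np.linalg.svd(x0, full_matrices=False)
    eig = svals**2
    m_max = min(n1 + n2 - 2, 2 * aligned.n_landmarks - 4)
    keep = (eig > _EIGTOL * eig[0]) if eig[0] > 0 else np.zeros_like(eig, bool)
    basis = vt[keep][:m_max]  # (m, 2k)
    z = x0 @ basis.T
    gram = z.T @ z

    w, separation = _fit_direction(z, mask2, gram)
    axis = w @ basis  # back to 2k dims; unit norm since basis orthonormal

    # orient: group-2 mean score positive
    scores = x0 @ axis
    if scores[mask2].mean() < scores[~mask2].mean():
        axis = -axis
        scores = -scores

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm_mask = np.zeros(n, dtype=bool)
        perm_mask[rng.choice(n, size=n2, replace=False)] = True
        _, stat = _fit_direction(z, perm_mask, gram)
        if stat >= separation - 1e-12:
            exceed += 1
    p_value = (exceed + 1) / (n_permutations + 1)

    mean_diff = x0[mask2].mean(axis=0) - x0[~mask2].mean(axis=0)
    vectors = mean_diff.reshape(-1, 2)

    return DFAResult(
        axis=axis,
        displacement_vectors=vectors,
        scores=scores,
        labels=labels,
        group_order=group_order,
        separation=separation,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
    )


@dataclass(frozen=True)
class AnchoredVectors:
    """Displacement field re-expressed relative to a reference landmark group.

    Mirrors the manual step of transposing shape-change vectors in reference
    to the vertebral column (the head/neck extension landmarks): the mean
    displacement over the reference group is subtracted from every landmark,
    so motion is read relative to the skeletal frame.
    """

    vectors: np.ndarray = field(repr=False)  # (k, 2)
    reference_group: str

    def to_frame(self) -> pd.DataFrame:
        mag = np.linalg.norm(self.vectors, axis=1)
        return pd.DataFrame(
            {
                "landmark_id": np.arange(1, len(mag) + 1),
                "dx": self.vectors[:, 0],
                "dy": self.vectors[:, 1],
                "magnitude": mag,
            }
        )


def transpose_to_reference(
    vectors: DFAResult | AnchoredVectors | np.ndarray,
    registry: LandmarkRegistry,
    reference_group: str = "head_neck_extension",
) -> AnchoredVectors:
    """Anchor a displacement field to a functional landmark group.

    Subtracts the mean displacement of the reference group's landmarks from
    every landmark's displacement; the anchored field has zero mean over the
    reference group. Idempotent.
    """
    if isinstance(vectors, DFAResult):
        field_ = vectors.displacement_vectors
    elif isinstance(vectors, AnchoredVectors):
        field_ = vectors.vectors
    else:
        field_ = np.asarray(vectors, dtype=float)
    if field_.shape != (N_LANDMARKS, 2):
        raise ValueError(f"expected (12, 2) displacement field, got {field_.shape}")
    member_ids = registry.group_members(reference_group)
    if not member_ids:
        raise GroupError(reference_group)
    idx = np.array(member_ids) - 1
    anchored = field_ - field_[idx].mean(axis=0)
    return AnchoredVectors(vectors=anchored, reference_group=reference_group)
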