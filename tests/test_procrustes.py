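import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import casm
from casm.exceptions import DegenerateShapeError, ShapeMismatchError
from casm.procrustes import (
    _normalize,
    aligned_to_frame,
    rotation_matrix,
)


def grid_search_distance(shape_a, shape_b, step=1e-4):
    """Brute-force full Procrustes distance over a rotation-angle grid."""
    a, _, _ = _normalize(np.asarray(shape_a, float))
    b, _, _ = _normalize(np.asarray(shape_b, float))
    thetas = np.arange(0.0, 2 * np.pi, step)
    cos, sin = np.cos(thetas), np.sin(thetas)
    # ||a - R b||^2 = 2 - 2 (cos * dot + sin * cross)
    dot = float((a * b).sum())
    cross = float((b[:, 0] * a[:, 1] - b[:, 1] * a[:, 0]).sum())
    d2 = 2.0 - 2.0 * (cos * dot + sin * cross)
    return float(np.sqrt(d2.min().clip(0)))


def random_similarity(rng, shape):
    theta = rng.uniform(0, 2 * np.pi)
    scale = rng.uniform(0.5, 2.0)
    shift = rng.normal(0, 10, 2)
    return scale * shape @ rotation_matrix(theta).T + shift


class TestCentroidSize:
    def test_unit_square_is_sqrt8(self):
        square = np.array([[1, 1], [1, -1], [-1, -1], [-1, 1]], float)
        assert casm.centroid_size(square) == pytest.approx(np.sqrt(8))

    @given(c=st.floats(0.01, 100))
    def test_homogeneous_in_scale(self, c):
        shape = np.arange(24, dtype=float).reshape(12, 2)
        assert casm.centroid_size(c * shape) == pytest.approx(
            c * casm.centroid_size(shape), rel=1e-12
        )

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateShapeError):
            casm.centroid_size(np.zeros((12, 2)))


class TestAlignPair:
    def test_self_alignment_is_identity(self, random_shape):
        aligned, transform, dist = casm.align_pair(random_shape, random_shape)
        assert dist == pytest.approx(0, abs=1e-12)
        assert transform.rotation == pytest.approx(0, abs=1e-12)
        assert transform.scale == pytest.approx(1, rel=1e-12)
        assert np.allclose(aligned, random_shape, atol=1e-9)

    def test_similarity_transform_is_fully_removed(self, random_shape):
        target = (
            2.0 * random_shape @ rotation_matrix(np.deg2rad(30)).T
            + np.array([5.0, 7.0])
        )
        aligned, transform, dist = casm.align_pair(random_shape, target)
        assert dist == pytest.approx(0, abs=1e-9)
        assert abs(transform.rotation) == pytest.approx(
            np.deg2rad(30), abs=1e-9
        )
        assert transform.scale == pytest.approx(0.5, rel=1e-9)
        assert np.allclose(aligned, random_shape, atol=1e-8)

    def test_transform_maps_target_onto_aligned(self, rng, random_shape):
        target = rng.normal(0, 20, (12, 2))
        aligned, transform, _ = casm.align_pair(random_shape, target)
        assert np.allclose(transform.apply(target), aligned, atol=1e-10)

    def test_distance_matches_grid_search_oracle(self, rng):
        for _ in range(5):
            a = rng.normal(0, 10, (12, 2))
            b = rng.normal(0, 10, (12, 2))
            _, _, dist = casm.align_pair(a, b)
            assert dist == pytest.approx(
                grid_search_distance(a, b), abs=1e-6
            )

    def test_landmark_count_mismatch(self, random_shape):
        with pytest.raises(ShapeMismatchError):
            casm.align_pair(random_shape, random_shape[:10])


class TestProcrustesDistanceIsPseudoMetric:
    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=(2, 12, 2)) * 10
            assert casm.procrustes_distance(a, b) == pytest.approx(
                casm.procrustes_distance(b, a), abs=1e-9
            )

    def test_zero_iff_similarity_equivalent(self, rng, random_shape):
        twin = random_similarity(rng, random_shape)
        assert casm.procrustes_distance(random_shape, twin) < 1e-9
        other = rng.normal(0, 10, (12, 2))
        assert casm.procrustes_distance(random_shape, other) > 1e-3

    def test_triangle_inequality_on_random_triples(self, rng):
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 12, 2)) * 10
            dab = casm.procrustes_distance(a, b)
            dbc = casm.procrustes_distance(b, c)
            dac = casm.procrustes_distance(a, c)
            assert dac <= dab + dbc + 1e-6

    def test_agrees_with_scipy_disparity(self, rng):
        """Independent cross-check: scipy's procrustes disparity (which also
        optimizes scale) relates to the full distance d by
        disparity = 1 - (1 - d^2/2)^2. scipy permits reflections and our
        alignment never does, so the shapes are drawn close enough that the
        optimal orthogonal map is a proper rotation."""
        from scipy.spatial import procrustes as scipy_procrustes

        for _ in range(5):
            a = rng.normal(size=(12, 2)) * 10
            b = a + rng.normal(size=(12, 2))
            d = casm.procrustes_distance(a, b)
            _, _, disparity = scipy_procrustes(a, b)
            assert disparity == pytest.approx(
                1 - (1 - d**2 / 2) ** 2, abs=1e-10
            )


class TestGPA:
    def test_identical_copies_have_zero_residuals(self, random_shape):
        aligned = casm.gpa([random_shape.copy() for _ in range(10)])
        for i in range(10):
            assert (
                casm.procrustes_distance(aligned.shapes[i], aligned.shapes[0])
                < 1e-9
            )
        assert (
            casm.procrustes_distance(aligned.consensus, random_shape) < 1e-9
        )

    def test_similarity_transforms_of_one_shape_collapse(
        self, rng, random_shape
    ):
        shapes = [random_similarity(rng, random_shape) for _ in range(50)]
        aligned = casm.gpa(shapes)
        base = aligned.shapes[0]
        for i in range(50):
            assert np.abs(aligned.shapes[i] - base).max() < 1e-8

    def test_aligned_set_invariants(self, rng):
        shapes = rng.normal(0, 10, size=(8, 12, 2))
        aligned = casm.gpa(list(shapes))
        assert np.abs(aligned.shapes.mean(axis=1)).max() < 1e-9
        sizes = np.sqrt((aligned.shapes**2).sum(axis=(1, 2)))
        assert np.abs(sizes - 1).max() < 1e-9
        mean = aligned.shapes.mean(axis=0)
        mean_renorm, _, _ = _normalize(mean)
        assert np.abs(aligned.consensus - mean_renorm).max() < 1e-9
        assert aligned.converged

    def test_two_shapes_consensus_is_equidistant(self, rng):
        a, b = rng.normal(size=(2, 12, 2)) * 10
        aligned = casm.gpa([a, b])
        da = casm.procrustes_distance(aligned.consensus, a)
        db = casm.procrustes_distance(aligned.consensus, b)
        assert da == pytest.approx(db, abs=1e-6)
        assert da == pytest.approx(
            grid_search_distance(aligned.consensus, a), abs=1e-6
        )

    def test_input_order_only_changes_global_rotation(self, rng):
        shapes = list(rng.normal(0, 10, size=(9, 12, 2)))
        fwd = casm.gpa(shapes)
        rev = casm.gpa(shapes[::-1])
        # canonical orientation removes the rotation gauge entirely
        assert np.abs(fwd.consensus - rev.consensus).max() < 1e-8
        assert np.abs(fwd.shapes - rev.shapes[::-1]).max() < 1e-7

    def test_transforms_map_inputs_onto_aligned(self, rng):
        shapes = list(rng.normal(0, 10, size=(5, 12, 2)))
        aligned = casm.gpa(shapes)
        for i, s in enumerate(shapes):
            assert np.allclose(
                aligned.transforms[i].apply(s), aligned.shapes[i], atol=1e-9
            )

    def test_degenerate_member_rejected(self, random_shape):
        with pytest.raises(DegenerateShapeError):
            casm.gpa([random_shape, np.zeros((12, 2))])

    def test_tangent_projection_flag_is_small_perturbation(self, rng):
        shapes = list(
            casm.synthetic.DEFAULT_TEMPLATE[None]
            + rng.normal(0, 2, size=(10, 12, 2))
        )
        plain = casm.gpa(shapes)
        tangent = casm.gpa(shapes, tangent_projection=True)
        assert tangent.tangent_projected
        assert np.abs(plain.shapes - tangent.shapes).max() < 1e-3

    def test_serializes_to_tidy_frame(self, rng):
        aligned = casm.gpa(list(rng.normal(size=(3, 12, 2))))
        frame = aligned_to_frame(aligned)
        assert len(frame) == 3 * 12
        assert {"x", "y", "rotation", "scale"} <= set(frame.columns)
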