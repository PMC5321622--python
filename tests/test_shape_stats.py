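import dataclasses

import numpy as np
import pytest

import casm
from casm.exceptions import (
    ClassSizeError,
    GroupError,
    LabelError,
    SampleSizeError,
)
from casm.procrustes import rotation_matrix
from casm.synthetic import DEFAULT_TEMPLATE


def make_two_group_alignment(
    rng, displacement, n_per_group=30, noise=0.5
):
    """GPA'd sample: group 'a' around the template, group 'b' displaced."""
    shapes = []
    labels = []
    for _ in range(n_per_group):
        shapes.append(DEFAULT_TEMPLATE + rng.normal(0, noise, (12, 2)))
        labels.append("a")
    for _ in range(n_per_group):
        shapes.append(
            DEFAULT_TEMPLATE + displacement + rng.normal(0, noise, (12, 2))
        )
        labels.append("b")
    return casm.gpa(shapes), np.array(labels)


def aligned_displacement_truth(displacement):
    """The group-b minus group-a mean difference expressed in aligned space."""
    aligned = casm.gpa([DEFAULT_TEMPLATE, DEFAULT_TEMPLATE + displacement])
    return (aligned.shapes[1] - aligned.shapes[0]).reshape(-1)


def field_angle_deg(u, v):
    u, v = np.ravel(u), np.ravel(v)
    c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(abs(c), -1, 1)))


class TestShapePCA:
    def test_single_displacement_field_dominates(self, rng):
        field = np.zeros((12, 2))
        field[8] = (4.0, 5.0)  # hyoid-only displacement direction
        shapes = [
            DEFAULT_TEMPLATE + t * field for t in rng.uniform(-1, 1, 40)
        ]
        pca = casm.shape_pca(casm.gpa(shapes))
        assert pca.variance_ratio[0] > 0.99
        truth = aligned_displacement_truth(field)
        cos = abs(pca.components[0] @ truth) / np.linalg.norm(truth)
        assert cos > 0.999

    def test_identical_shapes_have_zero_eigenvalues(self):
        pca = casm.shape_pca(casm.gpa([DEFAULT_TEMPLATE.copy()] * 5))
        assert np.all(pca.eigenvalues < 1e-10)

    def test_superimposition_removes_four_degrees_of_freedom(self, rng):
        """Centering (2 d.o.f.) and rotation (1) are linear constraints and
        vanish exactly; the unit-size constraint is a sphere, so its radial
        direction carries only second-order variance and vanishes exactly
        once tangent-projected, leaving at most 2k - 4 = 20 components."""
        shapes = list(DEFAULT_TEMPLATE[None] + rng.normal(0, 3, (60, 12, 2)))
        pca = casm.shape_pca(casm.gpa(shapes))
        exact_zeros = (pca.eigenvalues < 1e-10 * pca.eigenvalues[0]).sum()
        assert exact_zeros >= 3
        assert pca.eigenvalues[20:].sum() < 5e-3 * pca.eigenvalues.sum()
        assert pca.variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        tangent = casm.shape_pca(casm.gpa(shapes, tangent_projection=True))
        nonzero = (tangent.eigenvalues > 1e-10 * tangent.eigenvalues[0]).sum()
        assert nonzero <= 20

    def test_reconstruction_is_exact(self, rng):
        shapes = list(DEFAULT_TEMPLATE[None] + rng.normal(0, 2, (10, 12, 2)))
        aligned = casm.gpa(shapes)
        pca = casm.shape_pca(aligned)
        recon = pca.mean + pca.scores @ pca.components
        assert np.abs(recon - aligned.flattened()).max() < 1e-8

    def test_too_few_shapes_rejected(self):
        aligned = casm.gpa([DEFAULT_TEMPLATE, DEFAULT_TEMPLATE * 2.0])
        with pytest.raises(SampleSizeError):
            casm.shape_pca(aligned)


class TestDiscriminantAnalysis:
    def test_recovers_constrictor_only_displacement(self, rng):
        field = np.zeros((12, 2))
        field[10] = (6.0, 1.0)  # landmark 11
        field[11] = (6.0, 1.0)  # landmark 12
        aligned, labels = make_two_group_alignment(rng, field)
        result = casm.discriminant_analysis(
            aligned, labels, n_permutations=99, seed=3
        )
        mags = np.linalg.norm(result.displacement_vectors, axis=1)
        assert set(np.argsort(mags)[-2:] + 1) == {11, 12}
        truth = aligned_displacement_truth(field)
        assert field_angle_deg(result.displacement_vectors, truth) < 15
        assert result.p_value <= 0.01

    def test_axis_is_unit_and_vectors_are_the_group_mean_difference(
        self, rng
    ):
        field = np.zeros((12, 2))
        field[8] = (3.0, 3.0)
        aligned, labels = make_two_group_alignment(rng, field, n_per_group=10)
        result = casm.discriminant_analysis(aligned, labels, 49, seed=0)
        assert np.linalg.norm(result.axis) == pytest.approx(1.0, abs=1e-9)
        x0 = aligned.flattened() - aligned.consensus.reshape(-1)
        diff = x0[labels == "b"].mean(axis=0) - x0[labels == "a"].mean(axis=0)
        assert np.allclose(
            result.displacement_vectors.reshape(-1), diff, atol=1e-12
        )
        assert 1 / 50 <= result.p_value <= 1.0

    def test_group2_mean_score_is_positive(self, rng):
        field = np.zeros((12, 2))
        field[8] = (3.0, 3.0)
        aligned, labels = make_two_group_alignment(rng, field, n_per_group=10)
        result = casm.discriminant_analysis(aligned, labels, 0, seed=0)
        assert result.group_order == ("a", "b")
        assert result.scores[labels == "b"].mean() > (
            result.scores[labels == "a"].mean()
        )

    def test_identical_groups_give_zero_separation_and_p_one(self, rng):
        shapes = list(DEFAULT_TEMPLATE[None] + rng.normal(0, 1, (8, 12, 2)))
        aligned = casm.gpa(shapes + shapes)
        labels = np.array(["a"] * 8 + ["b"] * 8)
        result = casm.discriminant_analysis(aligned, labels, 99, seed=0)
        assert result.separation == pytest.approx(0, abs=1e-9)
        assert result.p_value == 1.0

    def test_scores_invariant_to_global_rotation(self, rng):
        field = np.zeros((12, 2))
        field[9] = (-4.0, 1.0)
        aligned, labels = make_two_group_alignment(rng, field, n_per_group=10)
        rot = rotation_matrix(0.7)
        rotated = dataclasses.replace(
            aligned,
            shapes=aligned.shapes @ rot.T,
            consensus=aligned.consensus @ rot.T,
        )
        r1 = casm.discriminant_analysis(aligned, labels, 0, seed=0)
        r2 = casm.discriminant_analysis(rotated, labels, 0, seed=0)
        assert np.abs(r1.scores - r2.scores).max() < 1e-8

    def test_permutation_p_is_seed_reproducible(self, rng):
        field = np.zeros((12, 2))
        field[8] = (1.0, 1.0)
        aligned, labels = make_two_group_alignment(
            rng, field, n_per_group=8, noise=2.0
        )
        p1 = casm.discriminant_analysis(aligned, labels, 199, seed=42).p_value
        p2 = casm.discriminant_analysis(aligned, labels, 199, seed=42).p_value
        assert p1 == p2

    def test_axis_angle_improves_with_sample_size(self, rng):
        """Median angle to the true displacement shrinks as n grows."""
        field = np.zeros((12, 2))
        field[10] = (4.0, 2.0)
        truth = aligned_displacement_truth(field)
        medians = []
        for n in (10, 50, 250):
            angles = [
                field_angle_deg(
                    casm.discriminant_analysis(
                        *make_two_group_alignment(
                            rng, field, n_per_group=n, noise=2.0
                        ),
                        n_permutations=0,
                        seed=0,
                    ).displacement_vectors,
                    truth,
                )
                for _ in range(5)
            ]
            medians.append(np.median(angles))
        assert medians[2] < medians[0]

    def test_class_and_label_errors(self, rng):
        shapes = list(DEFAULT_TEMPLATE[None] + rng.normal(0, 1, (6, 12, 2)))
        aligned = casm.gpa(shapes)
        with pytest.raises(ClassSizeError):
            casm.discriminant_analysis(
                aligned, ["a", "a", "a", "a", "a", "b"], 9, seed=0
            )
        with pytest.raises(LabelError):
            casm.discriminant_analysis(
                aligned, ["a", "b", "c", "a", "b", "c"], 9, seed=0
            )


class TestTransposeToReference:
    def _result(self, rng):
        field = np.zeros((12, 2))
        field[8] = (5.0, 5.0)
        aligned, labels = make_two_group_alignment(rng, field, n_per_group=10)
        return casm.discriminant_analysis(aligned, labels, 0, seed=0)

    def test_reference_group_mean_is_zero(self, rng, registry):
        anchored = casm.transpose_to_reference(
            self._result(rng), registry, "head_neck_extension"
        )
        assert np.abs(anchored.vectors[:5].mean(axis=0)).max() < 1e-12

    def test_uniform_field_anchors_to_zero(self, registry):
        uniform = np.tile([2.0, -3.0], (12, 1))
        anchored = casm.transpose_to_reference(uniform, registry)
        assert np.abs(anchored.vectors).max() < 1e-12

    def test_idempotent(self, rng, registry):
        once = casm.transpose_to_reference(self._result(rng), registry)
        twice = casm.transpose_to_reference(once, registry)
        assert np.allclose(once.vectors, twice.vectors, atol=1e-15)

    def test_unknown_group_rejected(self, rng, registry):
        with pytest.raises(GroupError):
            casm.transpose_to_reference(
                self._result(rng), registry, "vertebral"
            )
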