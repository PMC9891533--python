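"""The between-model map, its Jacobian/sensitivities, manifolds, steering."""

import numpy as np
import pytest

from spheromap.information_geometry import fim, model_jacobian
from spheromap.model_map import (
    MapJacobian,
    MapResult,
    SensitivityMatrix,
    feature_manifold,
    fit_map,
    map_jacobian,
    orthogonality_report,
    sensitivity_matrix,
    steer,
    tangent_normal_check,
)

T = np.arange(0.0, 22.0)


class TestFitMap:
    def test_self_map_is_identity(self):
        res = fit_map("logistic", [1.21, 316.0], "logistic")
        np.testing.assert_allclose(res.target_params, [1.21, 316.0], rtol=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.residual_norm == pytest.approx(0.0, abs=1e-9)

    def test_nested_source_recovered_exactly(self):
        # Richards with beta = 1 is the logistic model: the map must
        # recover the generating (lam, Rmax) to optimiser tolerance
        res = fit_map("richards", [1.3, 280.0, 1.0], "logistic")
        np.testing.assert_allclose(res.target_params, [1.3, 280.0], rtol=1e-5)
        assert res.r_squared > 1.0 - 1e-10

    def test_surrogate_quality_ordering(self, map_to_logistic, map_to_gompertz):
        # the bounded Gompertz crowding function resembles the Greenspan
        # one far more closely than the logistic does
        assert map_to_gompertz.r_squared > map_to_logistic.r_squared
        assert abs(map_to_gompertz.target_params[0] - 1.0) < abs(
            map_to_logistic.target_params[0] - 1.0
        )

    def test_invalid_r_squared_rejected(self):
        with pytest.raises(ValueError):
            MapResult("a", np.ones(2), "b", np.ones(2), 1.5, 0.0)


class TestMapJacobian:
    def test_self_map_jacobian_is_identity(self):
        J = map_jacobian("logistic", [1.21, 316.0], "logistic")
        np.testing.assert_allclose(J.matrix, np.eye(2), atol=1e-4)

    def test_nested_identity_block(self):
        # for the Richards source at beta = 1, d(lam, Rmax)/d(lam, Rmax)
        # through the logistic map is the identity
        J = map_jacobian("richards", [1.3, 280.0, 1.0], "logistic")
        np.testing.assert_allclose(J.matrix[:, :2], np.eye(2), atol=5e-3)

    def test_step_halving_stable(self, p1, jac_greenspan_logistic):
        J2 = map_jacobian("greenspan", p1, "logistic", fd_step=2e-3,
                          anchor=jac_greenspan_logistic.anchor)
        ref = np.max(np.abs(jac_greenspan_logistic.matrix), axis=1, keepdims=True)
        np.testing.assert_allclose(
            jac_greenspan_logistic.matrix / ref, J2.matrix / ref, atol=5e-3
        )


class TestSensitivityMatrix:
    def test_self_map_sensitivity_is_identity(self):
        J = map_jacobian("logistic", [1.21, 316.0], "logistic")
        S = sensitivity_matrix(J)
        np.testing.assert_allclose(S.matrix, np.eye(2), atol=1e-4)

    def test_radial_death_to_logistic_reference_values(self):
        # frozen reference sensitivities of the (lam, Rmax) features to the
        # radial-death parameters at the Greenspan-equivalent point
        p5 = fit_map("greenspan", [0.8, 150, 1, 1], "radial_death").target_params
        np.testing.assert_allclose(p5, [1.010, 1.314, 76.93], rtol=5e-3)
        S = sensitivity_matrix(map_jacobian("radial_death", p5, "logistic"))
        expected = np.array([[0.874, 0.126, -0.0506], [0.519, -0.52, 1.01]])
        np.testing.assert_allclose(S.matrix, expected, rtol=0.02, atol=0.002)

    def test_lambda_nearly_one_to_one(self, sens_greenspan_logistic):
        S = sens_greenspan_logistic
        assert S.matrix[0, 3] == pytest.approx(0.99, abs=0.02)  # lam to lam
        assert S.matrix[1, 1] == pytest.approx(1.01, abs=0.03)  # Rmax to Rd

    def test_zero_parameter_rejected(self, jac_greenspan_logistic):
        with pytest.raises(ValueError):
            sensitivity_matrix(jac_greenspan_logistic, p_i=[0.0, 150, 1, 1])

    def test_reciprocal_convention(self, jac_greenspan_logistic):
        S1 = sensitivity_matrix(jac_greenspan_logistic)
        S2 = sensitivity_matrix(jac_greenspan_logistic, convention="source_per_target")
        anchor = jac_greenspan_logistic.anchor
        scale = np.outer(anchor.target_params, 1.0 / anchor.source_params) ** 2
        np.testing.assert_allclose(S2.matrix, S1.matrix * scale, rtol=1e-10)


@pytest.fixture(scope="module")
def lam_surface(p1):
    spec = {"Q": (0.7, 0.9), "gamma": (0.6, 1.4), "solve": ("Rd", (80.0, 300.0))}
    return feature_manifold("greenspan", p1, "logistic", "lam", spec, resolution=3)


@pytest.fixture(scope="module")
def rd_sensitivity():
    p5 = np.array([1.010, 1.314, 76.93])
    J = map_jacobian("radial_death", p5, "logistic")
    return p5, J, sensitivity_matrix(J)


class TestManifold:
    def test_anchor_gridline_passes_through_anchor(self, lam_surface, p1):
        # the gridline through (Q, gamma) = (0.8, 1.0) must solve to Rd = 150
        pts = lam_surface.points
        on_anchor = pts[(np.isclose(pts[:, 0], 0.8)) & (np.isclose(pts[:, 2], 1.0))]
        assert on_anchor.shape[0] == 1
        assert on_anchor[0, 1] == pytest.approx(150.0, rel=5e-3)

    def test_every_point_refits_to_level(self, lam_surface):
        for q in lam_surface.points:
            refit = fit_map("greenspan", q, "logistic")
            assert refit.target_params[0] == pytest.approx(lam_surface.level, rel=5e-3)

    def test_bad_slice_spec_rejected(self, p1):
        with pytest.raises(ValueError):
            feature_manifold("greenspan", p1, "logistic", "lam", {"Q": (0.7, 0.9)})


class TestTangentNormal:
    def test_orthonormal_rows_give_third_axis(self):
        J = MapJacobian(
            matrix=np.array([[1.0, 0, 0], [0, 1.0, 0]]),
            target_names=("lam", "Rmax"),
            source_names=("a", "b", "c"),
            anchor=MapResult("x", np.ones(3), "y", np.ones(2), 1.0, 0.0),
        )
        F = fim(model_jacobian("radial_death", [1.0, 1.0, 150.0], T), 20.0)
        # construct a FIM whose sloppiest direction is e3
        import dataclasses

        Fstub = dataclasses.replace(
            F, fim=np.diag([5.0, 2.0, 1e-8]), param_names=("a", "b", "c")
        )
        out = tangent_normal_check(J, Fstub, ["a", "b", "c"])
        assert out["abs_cosine"] == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, jac_greenspan_logistic):
        F = fim(model_jacobian("greenspan", [0.8, 150, 1, 1], T), 20.0)
        base = tangent_normal_check(jac_greenspan_logistic, F, ["Q", "Rd", "gamma"])
        scaled = MapJacobian(
            matrix=jac_greenspan_logistic.matrix * np.array([[3.0], [0.2]]),
            target_names=jac_greenspan_logistic.target_names,
            source_names=jac_greenspan_logistic.source_names,
            anchor=jac_greenspan_logistic.anchor,
        )
        out = tangent_normal_check(scaled, F, ["Q", "Rd", "gamma"])
        assert out["abs_cosine"] == pytest.approx(base["abs_cosine"], abs=1e-9)

    def test_sloppy_direction_lies_in_tangent_intersection(self, jac_greenspan_logistic):
        # the cross product of the feature gradients aligns with the
        # sloppiest Fisher eigenvector in the (Q, Rd, gamma) slice
        F = fim(model_jacobian("greenspan", [0.8, 150, 1, 1], T), 20.0)
        out = tangent_normal_check(jac_greenspan_logistic, F, ["Q", "Rd", "gamma"])
        assert out["abs_cosine"] >= 0.99


class TestOrthogonalityReport:
    def test_dots_bounded_and_aligned_case(self):
        J = MapJacobian(
            matrix=np.array([[2.0, 0.0], [0.0, 3.0]]),
            target_names=("lam", "Rmax"),
            source_names=("a", "b"),
            anchor=MapResult("x", np.ones(2), "y", np.ones(2), 1.0, 0.0),
        )
        F = fim(_diag_jacobian(), 1.0)
        rep = orthogonality_report(F, J)
        assert np.all(np.abs(rep.dots) <= 1.0 + 1e-12)
        # eigenvectors of a diagonal FIM are the axes: dots are 0/1
        np.testing.assert_allclose(np.abs(rep.dots), [[0.0, 1.0], [1.0, 0.0]], atol=1e-9)

    def test_greenspan_sloppy_direction_orthogonal_to_feature_rows(
        self, jac_greenspan_logistic
    ):
        F = fim(model_jacobian("greenspan", [0.8, 150, 1, 1], T), 20.0)
        rep = orthogonality_report(F, jac_greenspan_logistic)
        # ascending eigenvalue order: first row is the sloppiest direction
        assert np.all(np.abs(rep.dots[0]) < 0.05)
        assert rep.relative_eigenvalues[0] < rep.relative_eigenvalues[-1]


def _diag_jacobian():
    from spheromap.information_geometry import SensitivityJacobian

    m = np.zeros((4, 2))
    m[0, 0] = 2.0
    m[1, 1] = 1.0
    return SensitivityJacobian(m, ("a", "b"), np.arange(4.0))


class TestSteer:
    def test_zero_change_is_noop(self, rd_sensitivity):
        p5, _, S = rd_sensitivity
        np.testing.assert_allclose(steer(p5, S, "lam", 0.0), p5, rtol=1e-12)

    def test_plain_row_moves_both_features(self, rd_sensitivity):
        p5, J, S = rd_sensitivity
        p_new = steer(p5, S, "lam", 0.10)
        after = fit_map("radial_death", p_new, "logistic")
        base = J.anchor.target_params
        rel = (after.target_params - base) / base
        assert rel[0] > 0.05  # lam rises as requested
        assert abs(rel[1]) > 0.01  # and drags Rmax along

    def test_orthogonalised_row_isolates_target_feature(self, rd_sensitivity):
        p5, J, S = rd_sensitivity
        p_new = steer(p5, S, "lam", 0.10, orthogonalize=True)
        after = fit_map("radial_death", p_new, "logistic")
        base = J.anchor.target_params
        rel = (after.target_params - base) / base
        assert abs(rel[0]) > 0.03
        assert abs(rel[1]) < abs(rel[0]) / 3.0

    def test_parallel_rows_rejected(self):
        S = SensitivityMatrix(
            np.array([[1.0, 2.0], [2.0, 4.0]]), ("lam", "Rmax"), ("a", "b")
        )
        with pytest.raises(ValueError):
            steer(np.ones(2), S, "lam", 0.1, orthogonalize=True)
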