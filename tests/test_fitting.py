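"""Identification machinery: norms, scaling iteration, sweep recovery."""

import numpy as np
import pytest

from laosfit.constitutive import MaterialParameters
from laosfit.fitting import (
    DesignSystem,
    default_alpha_grid,
    default_b_grid,
    fit_parameter_scaling,
    norm_l2,
    norm_pointwise,
    norm_scaling,
    solve_linear_nonneg,
    sweep_fit,
)
from laosfit.kinematics import SampleGeometry, TestCondition
from laosfit.synthetic import SyntheticStudyConfig, default_protocol, generate_dataset


def small_protocol(**kw):
    """Three fast, mixed conditions."""
    proto = default_protocol(points_per_period=64, n_burnin=2, n_record=1)
    return [proto[1], proto[7], proto[13]]


@pytest.fixture(scope="module")
def noisefree_vexp():
    cfg = SyntheticStudyConfig(
        true_params=MaterialParameters("vexp", delta=300.0, alpha=0.2, b=1.3),
        protocol=small_protocol(),
        noise_sd=0.0,
        seed=0,
    )
    return generate_dataset(cfg)


def design_blocks(dataset, model, alpha, b):
    from laosfit.forward import ForwardOperator, SurfaceMesh

    A_blocks, b_blocks = [], []
    for tr in dataset.traces:
        op = ForwardOperator(tr.cond, SurfaceMesh.radial(tr.cond.geometry.r, 16))
        tau_e, tau_v = op.unit_torque_columns(model, alpha, b)
        cols = [tau_v] if tau_e is None else [tau_e, tau_v]
        A_blocks.append(np.stack(cols, axis=1))
        b_blocks.append(tr.tau)
    return A_blocks, b_blocks


class TestNonnegativeLsq:
    def test_identity_system(self):
        assert np.allclose(solve_linear_nonneg(np.eye(2), [2.0, 3.0]), [2.0, 3.0])

    def test_negative_optimum_clamped_to_boundary(self):
        x = solve_linear_nonneg(np.array([[1.0], [1.0]]), [-1.0, -1.0])
        assert x[0] == 0.0

    def test_exact_recovery(self, rng):
        A = rng.normal(size=(50, 2))
        x_true = np.array([1.5, 0.7])
        x = solve_linear_nonneg(A, A @ x_true)
        assert np.max(np.abs(x - x_true)) < 1e-10

    def test_empty_system_rejected(self):
        with pytest.raises(ValueError):
            solve_linear_nonneg(np.empty((0, 2)), np.empty(0))


class TestNorms:
    def test_exact_solution_is_zero_percent(self, rng):
        A = rng.normal(size=(20, 2))
        x = np.array([2.0, 1.0])
        b = A @ x
        assert norm_l2(A, x, b) < 1e-12
        assert norm_pointwise([A], x, [b], 1e-3 * np.max(np.abs(b))) < 1e-12

    def test_zero_parameters_give_exactly_100_percent(self, rng):
        A = rng.normal(size=(20, 2))
        b = rng.normal(size=20)
        zero = np.zeros(2)
        assert norm_l2(A, zero, b) == 100.0
        assert norm_pointwise([A], zero, [b], 1e-3) == 100.0
        assert norm_scaling([A], zero, np.ones(1), [b]) == 100.0

    def test_l2_pythagoras_on_interior_solution(self, rng):
        A = rng.normal(size=(40, 2))
        b = A @ np.array([1.0, 2.0]) + 0.1 * rng.normal(size=40)
        x = solve_linear_nonneg(A, b)
        assert np.all(x > 0)  # interior => orthogonal projection
        err = norm_l2(A, x, b) / 100.0
        proj = np.linalg.norm(A @ x) / np.linalg.norm(b)
        assert err**2 + proj**2 == pytest.approx(1.0, abs=1e-10)

    def test_pointwise_punishes_shape_mismatch_on_small_test(self, rng):
        """Two tests with identical shape, amplitudes 1 and 100; the model
        matches only the large one — the point-wise norm must read worse
        than the L2 norm, which the large test dominates."""
        t = np.linspace(0, 2 * np.pi, 100)
        shape = np.sin(t)
        b1, b2 = shape, 100.0 * shape
        A1 = np.cos(t)[:, None]  # wrong shape on the small test
        A2 = 100.0 * shape[:, None]  # perfect on the large test
        x = np.array([1.0])
        tol = [1e-3, 1e-1]
        l2 = norm_l2(np.vstack([A1, A2]), x, np.concatenate([b1, b2]))
        pw = norm_pointwise([A1, A2], x, [b1, b2], tol)
        assert pw > l2

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            norm_pointwise([np.ones((3, 1))], [1.0], [np.ones(3)], 0.0)


class TestParameterScaling:
    def test_single_model_generated_test(self, rng):
        A = np.abs(rng.normal(size=(30, 1))) + 0.1
        b = (A @ [250.0]).ravel()
        st = fit_parameter_scaling([A], [b])
        assert st.beta[0] == pytest.approx(1.0)
        assert st.error < 1e-10
        assert st.x_per_test[0, 0] == pytest.approx(250.0)

    def test_two_tests_with_2to1_parameters_recovered(self, rng):
        """Data generated with x1 = 2·x2 is matched exactly; the recovered
        absolute per-test parameters reproduce both sets."""
        col1 = rng.normal(size=40)
        col2 = rng.normal(size=40)
        A1, A2 = col1[:, None], col2[:, None]
        b1 = (A1 @ [400.0]).ravel()
        b2 = (A2 @ [200.0]).ravel()
        st = fit_parameter_scaling([A1, A2], [b1, b2])
        assert st.error < 1e-8
        assert st.x_per_test[0, 0] == pytest.approx(400.0, rel=1e-6)
        assert st.x_per_test[1, 0] == pytest.approx(200.0, rel=1e-6)

    def test_gauge_invariance(self, rng):
        A_blocks = [rng.normal(size=(25, 2)) for _ in range(3)]
        b_blocks = [rng.normal(size=25) for _ in range(3)]
        x = np.array([1.0, 2.0])
        beta = np.array([0.5, 1.0, 2.0])
        j1 = norm_scaling(A_blocks, x, beta, b_blocks)
        j2 = norm_scaling(A_blocks, 3.0 * x, 3.0 * beta, b_blocks)
        assert j1 == pytest.approx(j2, rel=1e-12)

    def test_reported_beta_has_unit_mean(self, rng):
        A_blocks = [np.abs(rng.normal(size=(30, 1))) + 0.1 for _ in range(4)]
        b_blocks = [(A @ [s]).ravel() + 0.01 * rng.normal(size=30)
                    for A, s in zip(A_blocks, [100.0, 150.0, 200.0, 300.0])]
        st = fit_parameter_scaling(A_blocks, b_blocks)
        assert np.mean(st.beta) == pytest.approx(1.0, rel=1e-12)

    def test_error_non_increasing_over_iterations(self, rng):
        A_blocks = [np.abs(rng.normal(size=(30, 1))) + 0.1 for _ in range(4)]
        b_blocks = [(A @ [s]).ravel() + 0.05 * rng.normal(size=30)
                    for A, s in zip(A_blocks, [100.0, 150.0, 200.0, 300.0])]
        errs = [
            fit_parameter_scaling(A_blocks, b_blocks, max_iter=k).error
            for k in (1, 2, 3, 5, 10)
        ]
        assert np.all(np.diff(errs) <= 1e-12)

    def test_scale_equivariance_of_one_test(self, rng):
        """Scaling one test's data by k scales its absolute parameters by k."""
        A_blocks = [np.abs(rng.normal(size=(30, 1))) + 0.1 for _ in range(3)]
        b_blocks = [(A @ [s]).ravel() for A, s in zip(A_blocks, [100.0, 150.0, 200.0])]
        st0 = fit_parameter_scaling(A_blocks, b_blocks)
        b_scaled = [b_blocks[0] * 5.0, b_blocks[1], b_blocks[2]]
        st1 = fit_parameter_scaling(A_blocks, b_scaled)
        assert st1.x_per_test[0, 0] == pytest.approx(5 * st0.x_per_test[0, 0], rel=1e-6)
        assert st1.x_per_test[1, 0] == pytest.approx(st0.x_per_test[1, 0], rel=1e-6)

    def test_equivalent_to_plain_lsq_for_single_test(self, rng):
        A = np.abs(rng.normal(size=(40, 2))) + 0.1
        b = (A @ [80.0, 120.0]).ravel() + 0.02 * rng.normal(size=40)
        st = fit_parameter_scaling([A], [b])
        x_plain = solve_linear_nonneg(A, b)
        assert np.allclose(st.x_per_test[0], x_plain, rtol=1e-6)

    def test_all_zero_block_rejected(self):
        with pytest.raises(ValueError):
            fit_parameter_scaling([np.ones((5, 1))], [np.zeros(5)])


class TestDesignSystem:
    def test_block_consistency_enforced(self):
        with pytest.raises(ValueError):
            DesignSystem([np.ones((5, 2))], [np.ones(4)])
        with pytest.raises(ValueError):
            DesignSystem([np.ones((5, 2)), np.ones((5, 1))],
                         [np.ones(5), np.ones(5)])
        ds = DesignSystem([np.ones((5, 2))], [np.ones(5)])
        A, b = ds.stacked()
        assert A.shape == (5, 2) and b.shape == (5,)


class TestSweepFit:
    def test_default_grids_match_protocol_ranges(self):
        a = default_alpha_grid()
        assert a.min() == pytest.approx(0.05) and a.max() == pytest.approx(1.0)
        fine = a[(a >= 0.15) & (a <= 0.40)]
        assert np.allclose(np.diff(fine), 0.01)
        assert default_b_grid("vog").max() == pytest.approx(14.0)
        assert default_b_grid("vexp").max() == pytest.approx(1.5)

    @pytest.mark.parametrize("norm", ["l2", "pointwise", "scaling"])
    def test_self_consistency_at_generating_node(self, noisefree_vexp, norm):
        """A noise-free dataset fit on a grid containing the generating node
        lands on that node with ~zero error."""
        res = sweep_fit(
            noisefree_vexp.traces, "vexp", norm,
            alpha_grid=[0.15, 0.2, 0.25], b_grid=[1.1, 1.3, 1.5],
        )
        assert res.alpha == pytest.approx(0.2)
        assert res.b == pytest.approx(1.3)
        assert res.error < 1e-6
        assert res.linear_parameters[0] == pytest.approx(300.0, rel=1e-6)

    def test_error_surface_is_flat_in_b_at_tiny_strain(self):
        """In the linear regime the nonlinear power is unidentifiable."""
        g = SampleGeometry(H=3e-3, R=10e-3, cs=0.10)
        proto = [TestCondition(geometry=g, gamma=1e-5, freq=1.0,
                               points_per_period=64, n_burnin=2, n_record=1)]
        cfg = SyntheticStudyConfig(
            true_params=MaterialParameters("vexp", delta=300.0, alpha=0.2, b=1.3),
            protocol=proto, noise_sd=0.0, seed=0,
        )
        ds = generate_dataset(cfg)
        res = sweep_fit(ds.traces, "vexp", "l2",
                        alpha_grid=[0.3], b_grid=[1.0, 2.0, 3.0])
        errs = res.surface["error"].to_numpy()
        assert np.ptp(errs) < 1e-4 * (1 + errs.mean())

    def test_invalid_inputs_rejected(self, noisefree_vexp):
        with pytest.raises(ValueError):
            sweep_fit(noisefree_vexp.traces, "vexp", "chi2")
        with pytest.raises(ValueError):
            sweep_fit([], "vexp", "l2")
        with pytest.raises(ValueError):
            sweep_fit(noisefree_vexp.traces, "vexp", "l2", alpha_grid=[])
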