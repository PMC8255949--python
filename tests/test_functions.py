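import math

import numpy as np
import pytest

from tomoopt.datamodel import BlockDataContainer, ImageGeometry, VectorGeometry
from tomoopt.functions import (
    BlockFunction,
    ConstantFunction,
    IndicatorBox,
    KullbackLeibler,
    L1Norm,
    L2NormSquared,
    LeastSquares,
    MixedL21Norm,
    OperatorCompositionFunction,
    ScaledFunction,
    SmoothMixedL21Norm,
    TotalVariation,
    WeightedL2NormSquared,
    ZeroFunction,
)
from tomoopt.operators import GradientOperator, IdentityOperator, MatrixOperator


def vec(values):
    values = np.asarray(values, dtype=np.float64)
    g = VectorGeometry(values.size)
    return g.allocate(0.0, dtype=np.float64).fill(values)


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences, the independent smoothness oracle."""
    arr = x.as_array()
    out = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy()
        xm = x.copy()
        xp.as_array()[idx] += eps
        xm.as_array()[idx] -= eps
        out[idx] = (f(xp) - f(xm)) / (2 * eps)
    return out


class TestLeastSquares:
    def test_minimizer_has_zero_gradient(self, rng):
        M = rng.standard_normal((5, 3))
        A = MatrixOperator(M)
        xstar = vec(rng.standard_normal(3))
        b = A.direct(xstar)
        f = LeastSquares(A, b)
        assert f(xstar) == pytest.approx(0.0, abs=1e-20)
        assert f.gradient(xstar).norm() == pytest.approx(0.0, abs=1e-10)

    def test_identity_operator_gradient(self):
        g = VectorGeometry(4)
        b = vec([1.0, 2.0, 3.0, 4.0])
        f = LeastSquares(IdentityOperator(g), b)
        u = vec([2.0, 2.0, 2.0, 2.0])
        assert np.allclose(f.gradient(u).as_array(), 2.0 * (u - b).as_array())

    def test_dense_case_against_normal_equations(self, rng):
        # oracle: hand matrix algebra, value and gradient from explicit matrices
        M = rng.standard_normal((3, 2))
        barr = rng.standard_normal(3)
        u = rng.standard_normal(2)
        f = LeastSquares(MatrixOperator(M), vec(barr))
        res = M @ u - barr
        assert f(vec(u)) == pytest.approx(res @ res, rel=1e-12)
        assert np.allclose(f.gradient(vec(u)).as_array(), 2.0 * M.T @ res)

    def test_lipschitz_constant(self, rng):
        M = rng.standard_normal((6, 4))
        f = LeastSquares(MatrixOperator(M), vec(rng.standard_normal(6)))
        assert f.L == pytest.approx(2.0 * np.linalg.norm(M, 2) ** 2, rel=1e-4)


class TestProxL1:
    def test_closed_form(self):
        g = ScaledFunction(1.0, L1Norm())
        out = g.proximal(vec([2.0]), 0.5)
        assert out.as_array()[0] == pytest.approx(1.5)

    def test_interior_maps_to_zero(self):
        out = L1Norm().proximal(vec([0.3, -0.4]), 0.5)
        assert np.all(out.as_array() == 0.0)

    def test_odd_symmetry(self, rng):
        x = vec(rng.standard_normal(20))
        g = L1Norm()
        assert np.allclose(g.proximal(-1.0 * x, 0.7).as_array(),
                           -g.proximal(x, 0.7).as_array())


class TestProxL2Squared:
    def test_b_zero_halves(self):
        out = L2NormSquared().proximal(vec([3.0, -1.0]), 0.5)
        assert np.allclose(out.as_array(), [1.5, -0.5])

    def test_tau_to_zero_limit(self):
        x = vec([1.0, 2.0])
        out = L2NormSquared().proximal(x, 1e-12)
        assert np.allclose(out.as_array(), x.as_array(), atol=1e-10)

    def test_fixed_point_at_b(self):
        b = vec([0.5, -0.5])
        out = L2NormSquared(b=b).proximal(b, 0.7)
        assert np.allclose(out.as_array(), b.as_array())


class TestProxMixedL21:
    def test_shrink_factor(self):
        X = BlockDataContainer(vec([3.0]), vec([4.0]))
        out = MixedL21Norm().proximal(X, 1.0)
        assert out[0].as_array()[0] == pytest.approx(2.4)
        assert out[1].as_array()[0] == pytest.approx(3.2)

    def test_small_vectors_vanish(self):
        X = BlockDataContainer(vec([0.3]), vec([0.4]))
        out = MixedL21Norm().proximal(X, 1.0)
        assert out[0].as_array()[0] == 0.0
        assert out[1].as_array()[0] == 0.0

    def test_direction_preserved(self, rng):
        a, b = rng.standard_normal(9), rng.standard_normal(9)
        X = BlockDataContainer(vec(a), vec(b))
        out = MixedL21Norm().proximal(X, 0.2)
        cross = out[0].as_array() * b - out[1].as_array() * a
        assert np.allclose(cross, 0.0, atol=1e-10)


class TestSmoothMixedL21:
    def test_value_at_zero(self):
        beta = 0.1
        X = BlockDataContainer(vec(np.zeros(7)), vec(np.zeros(7)))
        f = SmoothMixedL21Norm(beta)
        assert f(X) == pytest.approx(7 * beta)
        assert f.gradient(X).norm() == 0.0

    def test_beta_limit_approaches_l21(self, rng):
        X = BlockDataContainer(vec(rng.standard_normal(30)), vec(rng.standard_normal(30)))
        beta = 1e-6
        assert abs(SmoothMixedL21Norm(beta)(X) - MixedL21Norm()(X)) <= 30 * beta

    def test_gradient_matches_finite_differences(self, rng):
        f = SmoothMixedL21Norm(0.3)
        X = BlockDataContainer(vec(rng.standard_normal(4)), vec(rng.standard_normal(4)))
        grad = f.gradient(X)
        for k in range(2):
            num = numeric_gradient(lambda v: f(BlockDataContainer(
                v if k == 0 else X[0], v if k == 1 else X[1])), X[k])
            assert np.allclose(grad[k].as_array(), num, atol=1e-5)

    def test_beta_must_be_positive(self):
        with pytest.raises(ValueError):
            SmoothMixedL21Norm(0.0)


class TestKullbackLeibler:
    def test_zero_at_match(self):
        b = vec([1.0, 2.0, 3.0])
        f = KullbackLeibler(b)
        assert f(b) == pytest.approx(0.0, abs=1e-12)
        assert f.gradient(b).norm() == pytest.approx(0.0, abs=1e-12)

    def test_zero_count_convention(self):
        f = KullbackLeibler(vec([0.0]))
        assert f(vec([2.5])) == pytest.approx(2.5)

    def test_nonnegative_on_random_feasible(self, rng):
        # Gibbs inequality via sampling
        for _ in range(50):
            b = vec(rng.uniform(0, 5, size=6))
            v = vec(rng.uniform(0.1, 5, size=6))
            assert KullbackLeibler(b)(v) >= -1e-10

    def test_infeasible_rejected(self):
        f = KullbackLeibler(vec([1.0]))
        with pytest.raises(ValueError):
            f(vec([-2.0]))

    def test_gradient_formula(self, rng):
        b = vec(rng.uniform(0.5, 2, size=5))
        v = vec(rng.uniform(0.5, 2, size=5))
        f = KullbackLeibler(b, eta=0.1)
        num = numeric_gradient(f, v)
        assert np.allclose(f.gradient(v).as_array(), num, atol=1e-5)

    def test_proximal_solves_optimality(self, rng):
        b = vec(rng.uniform(0.5, 2, size=4))
        y = vec(rng.uniform(0.5, 3, size=4))
        f = KullbackLeibler(b, eta=0.2)
        tau = 0.7
        z = f.proximal(y, tau)
        # stationarity: (z - y)/tau + f'(z) = 0
        resid = (z - y).as_array() / tau + f.gradient(z).as_array()
        assert np.allclose(resid, 0.0, atol=1e-8)


class TestIndicatorBox:
    def test_clip_to_steel_wire_bounds(self):
        g = IndicatorBox(lower=0.0, upper=0.09)
        out = g.proximal(vec([0.12, -0.02, 0.05]), 1.0)
        assert np.allclose(out.as_array(), [0.09, 0.0, 0.05])

    def test_interior_unchanged(self):
        g = IndicatorBox(lower=-1.0, upper=1.0)
        x = vec([0.2, -0.7])
        assert np.allclose(g.proximal(x, 2.0).as_array(), x.as_array())

    def test_idempotent(self, rng):
        g = IndicatorBox(lower=0.0, upper=1.0)
        x = vec(rng.standard_normal(30))
        once = g.proximal(x, 1.0)
        twice = g.proximal(once, 1.0)
        assert np.array_equal(once.as_array(), twice.as_array())

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            IndicatorBox(lower=1.0, upper=0.0)


def tv_dual_oracle(u_arr, strength, iters=100_000):
    """Long-run plain projected gradient on the TV-prox dual problem.

    Independent of the package path: explicit finite-difference matrices and
    an unaccelerated projected-gradient loop on
    min_p 0.5*||u - D^T p||^2  s.t.  per-pixel ||p||_2 <= strength.
    """
    ny, nx = u_arr.shape
    n = ny * nx

    def dmat(axis):
        D = np.zeros((n, n))
        for iy in range(ny):
            for ix in range(nx):
                row = iy * nx + ix
                if axis == 0 and iy < ny - 1:
                    D[row, (iy + 1) * nx + ix] += 1
                    D[row, row] -= 1
                if axis == 1 and ix < nx - 1:
                    D[row, iy * nx + ix + 1] += 1
                    D[row, row] -= 1
        return D

    Dy, Dx = dmat(0), dmat(1)
    u = u_arr.ravel()
    py = np.zeros(n)
    px = np.zeros(n)
    step = 1.0 / 8.0
    for _ in range(iters):
        v = u - Dy.T @ py - Dx.T @ px
        py = py + step * (Dy @ v)
        px = px + step * (Dx @ v)
        norms = np.sqrt(py ** 2 + px ** 2)
        scale = strength / np.maximum(norms, strength)
        py *= scale
        px *= scale
    v = u - Dy.T @ py - Dx.T @ px
    return v.reshape(ny, nx)


class TestTotalVariation:
    def test_constant_image_value_zero(self):
        ig = ImageGeometry(voxel_num_x=6, voxel_num_y=6)
        assert TotalVariation()(ig.allocate(2.5)) == 0.0

    def test_two_by_two_value(self):
        # [[0,1],[0,1]]: horizontal diffs (1,0) per row, vertical diffs 0
        ig = ImageGeometry(voxel_num_x=2, voxel_num_y=2)
        u = ig.allocate(0.0, dtype=np.float64)
        u.as_array()[:] = [[0.0, 1.0], [0.0, 1.0]]
        assert TotalVariation()(u) == pytest.approx(2.0)

    def test_homogeneity(self, rng):
        ig = ImageGeometry(voxel_num_x=5, voxel_num_y=4)
        u = ig.allocate(0.0, dtype=np.float64).fill(rng.standard_normal((4, 5)))
        tv = TotalVariation()
        assert tv(-3.0 * u) == pytest.approx(3.0 * tv(u), rel=1e-10)

    def test_prox_of_constant_is_identity(self):
        ig = ImageGeometry(voxel_num_x=4, voxel_num_y=4)
        u = ig.allocate(1.7, dtype=np.float64)
        out = TotalVariation(max_iterations=50).proximal(u, 0.5)
        assert np.allclose(out.as_array(), u.as_array(), atol=1e-10)

    def test_large_strength_flattens_to_mean(self, rng):
        ig = ImageGeometry(voxel_num_x=4, voxel_num_y=4)
        arr = rng.standard_normal((4, 4))
        u = ig.allocate(0.0, dtype=np.float64).fill(arr)
        out = TotalVariation(max_iterations=20000, tolerance=0.0,
                             warm_start=False).proximal(u, 1e5)
        assert np.allclose(out.as_array(), arr.mean(), atol=1e-3)

    def test_prox_matches_dual_oracle(self, rng):
        ig = ImageGeometry(voxel_num_x=4, voxel_num_y=4)
        arr = rng.standard_normal((4, 4))
        u = ig.allocate(0.0, dtype=np.float64).fill(arr)
        strength = 0.3
        expected = tv_dual_oracle(arr, strength)
        out = TotalVariation(max_iterations=5000, tolerance=0.0,
                             warm_start=False).proximal(u, strength)
        rms = np.sqrt(np.mean((out.as_array() - expected) ** 2))
        assert rms <= 1e-4


class TestFunctionAlgebra:
    def test_composition_with_identity(self, rng):
        g = VectorGeometry(6)
        b = vec(rng.standard_normal(6))
        f = L2NormSquared(b=b)
        comp = OperatorCompositionFunction(f, IdentityOperator(g))
        x = vec(rng.standard_normal(6))
        assert np.allclose(comp.gradient(x).as_array(), f.gradient(x).as_array())

    def test_block_function_prox_is_componentwise(self, rng):
        x = BlockDataContainer(vec(rng.standard_normal(5)), vec(rng.standard_normal(5)))
        bf = BlockFunction(L1Norm(), L2NormSquared())
        out = bf.proximal(x, 0.4)
        assert np.allclose(out[0].as_array(), L1Norm().proximal(x[0], 0.4).as_array())
        assert np.allclose(out[1].as_array(), L2NormSquared().proximal(x[1], 0.4).as_array())

    def test_operator_composition_gradient_matches_fd(self, rng):
        M = rng.standard_normal((5, 3))
        b = vec(rng.standard_normal(5))
        comp = OperatorCompositionFunction(L2NormSquared(b=b), MatrixOperator(M))
        x = vec(rng.standard_normal(3))
        num = numeric_gradient(comp, x)
        rel = np.linalg.norm(comp.gradient(x).as_array() - num) / np.linalg.norm(num)
        assert rel <= 1e-5

    def test_scaled_function(self, rng):
        f = ScaledFunction(3.0, L2NormSquared())
        x = vec(rng.standard_normal(4))
        assert f(x) == pytest.approx(3.0 * x.squared_norm())
        assert f.L == pytest.approx(6.0)

    def test_sum_prox_unsupported(self):
        s = L1Norm() + L2NormSquared()
        with pytest.raises(NotImplementedError):
            s.proximal(vec([1.0]), 1.0)

    def test_weighted_l2(self, rng):
        w = vec([1.0, 2.0, 3.0])
        f = WeightedL2NormSquared(w)
        x = vec([1.0, 1.0, 1.0])
        assert f(x) == pytest.approx(6.0)
        assert np.allclose(f.gradient(x).as_array(), [2.0, 4.0, 6.0])
        num = numeric_gradient(f, vec(rng.standard_normal(3)))


PROXABLE = [
    (L1Norm(), "vector"),
    (L2NormSquared(), "vector"),
    (ScaledFunction(0.7, L1Norm()), "vector"),
    (IndicatorBox(lower=-0.5, upper=0.5), "vector"),
    (MixedL21Norm(), "block"),
    (KullbackLeibler(vec(np.linspace(0.5, 2.0, 8)), eta=0.1), "vector8"),
]


def _sample(kind, seed):
    rng = np.random.default_rng(seed)
    if kind == "block":
        return BlockDataContainer(vec(rng.standard_normal(8)), vec(rng.standard_normal(8)))
    if kind == "vector8":
        return vec(rng.standard_normal(8))
    return vec(rng.standard_normal(8))


@pytest.mark.parametrize("g,kind", PROXABLE, ids=lambda p: type(p).__name__ if isinstance(p, object) and not isinstance(p, str) else p)
class TestProxProperties:
    def test_prox_characterization(self, g, kind):
        # Eq-style inequality: x+ = prox minimizes tau*g(v) + 0.5||v - x||^2
        tau = 0.6
        x = _sample(kind, 1)
        xp = g.proximal(x, tau)
        obj_at_xp = tau * g(xp) + 0.5 * (xp - x).squared_norm()
        rng = np.random.default_rng(2)
        for k in range(100):
            v = xp + 0.3 * _sample(kind, 100 + k)
            try:
                gv = g(v)
            except ValueError:
                continue  # outside the domain (e.g. KL feasibility)
            assert obj_at_xp <= tau * gv + 0.5 * (v - x).squared_norm() + 1e-8

    def test_firm_nonexpansiveness(self, g, kind):
        for seed in range(10):
            x = _sample(kind, 3 * seed)
            y = _sample(kind, 3 * seed + 1)
            px = g.proximal(x, 0.8)
            py = g.proximal(y, 0.8)
            assert (px - py).norm() <= (x - y).norm() + 1e-10


MOREAU_CASES = [
    L1Norm(),
    L2NormSquared(),
    IndicatorBox(lower=-0.3, upper=1.1),
]


@pytest.mark.parametrize("g", MOREAU_CASES, ids=lambda g: type(g).__name__)
def test_moreau_identity(g, rng):
    # prox_{tau g}(x) + tau * prox_{g*/tau}(x/tau) = x
    x = vec(rng.standard_normal(12))
    tau = 0.9
    lhs = g.proximal(x, tau) + tau * g.proximal_conjugate(x * (1.0 / tau), 1.0 / tau)
    assert np.allclose(lhs.as_array(), x.as_array(), atol=1e-6)


def test_zero_function():
    z = ZeroFunction()
    x = vec([1.0, -2.0])
    assert z(x) == 0.0
    assert np.array_equal(z.proximal(x, 5.0).as_array(), x.as_array())


def test_constant_function_gradient():
    c = ConstantFunction(3.0)
    x = vec([1.0, 2.0])
    assert c(x) == 3.0
    assert c.gradient(x).norm() == 0.0
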