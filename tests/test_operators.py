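import numpy as np
import pytest

from tomoopt.datamodel import (
    BlockDataContainer,
    ImageGeometry,
    VectorGeometry,
    create_acquisition_geometry,
    default_image_geometry,
)
from tomoopt.operators import (
    BlockOperator,
    BlurringOperator,
    CompositionOperator,
    DiagonalOperator,
    FiniteDifferenceOperator,
    GradientOperator,
    IdentityOperator,
    MaskOperator,
    MatrixOperator,
    ProjectionOperator,
    ScaledOperator,
    SumOperator,
    ZeroOperator,
)


def adjoint_residual(A, seed):
    """|<Av,z> - <v,A*z>| relative to ||Av||*||z||."""
    v = A.domain.allocate("random", seed=seed, dtype=np.float64) - 0.5
    z = A.range.allocate("random", seed=seed + 1, dtype=np.float64) - 0.5
    Av = A.direct(v)
    Atz = A.adjoint(z)
    denom = Av.norm() * z.norm()
    if denom == 0:
        return 0.0
    return abs(Av.dot(z) - v.dot(Atz)) / denom


def make_all_operator_kinds():
    """One representative instance of every operator kind."""
    ig = ImageGeometry(voxel_num_x=11, voxel_num_y=9)
    ag = create_acquisition_geometry(
        beam_type="parallel2D", angles=np.linspace(0, 180, 7, endpoint=False),
        pixel_num_h=11)
    rng = np.random.default_rng(0)
    diag = ig.allocate("random", seed=8, dtype=np.float64) + 0.5
    mask = diag.clone_with(rng.random(ig.shape) > 0.4)
    kernel = rng.random((3, 5))
    proj = ProjectionOperator(default_image_geometry(ag), ag)
    fd = FiniteDifferenceOperator(ig, "horizontal_x")
    grad = GradientOperator(ig)
    return {
        "identity": IdentityOperator(ig),
        "zero": ZeroOperator(ig, ag),
        "diagonal": DiagonalOperator(diag),
        "mask": MaskOperator(mask),
        "matrix": MatrixOperator(rng.standard_normal((6, 4))),
        "finite_difference": fd,
        "gradient": grad,
        "blurring": BlurringOperator(kernel, ig),
        "projector": proj,
        "block": BlockOperator([[proj], [ScaledOperator(0.7, GradientOperator(proj.domain))]]),
        "scaled": ScaledOperator(-2.5, fd),
        "sum": SumOperator(fd, FiniteDifferenceOperator(ig, "horizontal_y")),
        "composition": CompositionOperator(DiagonalOperator(diag), fd),
    }


@pytest.mark.parametrize("kind", sorted(make_all_operator_kinds()))
def test_adjoint_contract_all_kinds(kind):
    A = make_all_operator_kinds()[kind]
    for seed in range(10):
        assert adjoint_residual(A, 100 + 2 * seed) <= 1e-6


class TestSimpleOperators:
    def test_identity(self, ig2d):
        v = ig2d.allocate("random", seed=0)
        assert np.array_equal(IdentityOperator(ig2d).direct(v).as_array(), v.as_array())

    def test_diagonal_elementwise(self):
        g = VectorGeometry(2)
        d = g.allocate(0.0, dtype=np.float64)
        d.as_array()[:] = [1.0, 3.0]
        A = DiagonalOperator(d)
        v = g.allocate(0.0, dtype=np.float64)
        v.as_array()[:] = [5.0, 7.0]
        assert np.allclose(A.direct(v).as_array(), [5.0, 21.0])

    def test_zero_maps_to_zero(self, ig2d, ag2d):
        A = ZeroOperator(ig2d, ag2d)
        assert A.direct(ig2d.allocate("random", seed=1)).norm() == 0.0

    def test_geometry_mismatch_on_composition(self, ig2d):
        small = ImageGeometry(voxel_num_x=3, voxel_num_y=3)
        with pytest.raises(ValueError):
            CompositionOperator(IdentityOperator(ig2d), IdentityOperator(small))


class TestFiniteDifference:
    def test_forward_stencil(self):
        g = VectorGeometry(3)
        u = g.allocate(0.0, dtype=np.float64)
        u.as_array()[:] = [1.0, 2.0, 4.0]
        D = FiniteDifferenceOperator(g, "index")
        assert np.allclose(D.direct(u).as_array(), [1.0, 2.0, 0.0])

    def test_adjoint_stencil(self):
        # from expanding <Du, v> = <u, D^T v> by hand
        g = VectorGeometry(3)
        v = g.allocate(0.0, dtype=np.float64)
        v.as_array()[:] = [1.0, 1.0, 0.0]
        D = FiniteDifferenceOperator(g, "index")
        assert np.allclose(D.adjoint(v).as_array(), [-1.0, 0.0, 1.0])

    def test_constant_input(self, ig2d):
        D = FiniteDifferenceOperator(ig2d, "horizontal_x")
        assert D.direct(ig2d.allocate(3.3)).norm() == 0.0

    def test_short_axis_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            FiniteDifferenceOperator(VectorGeometry(1), "index")


class TestGradient:
    def test_block_count_matches_dimensions(self, ig2d, ig3d):
        assert len(GradientOperator(ig2d).direct(ig2d.allocate(0.0))) == 2
        assert len(GradientOperator(ig3d).direct(ig3d.allocate(0.0))) == 3

    def test_constant_image(self, ig2d):
        assert GradientOperator(ig2d).direct(ig2d.allocate(1.0)).norm() == 0.0

    def test_norm_within_bound(self, ig2d):
        G = GradientOperator(ig2d)
        assert G.norm(iterations=50) <= G.norm_bound() + 1e-9


class TestBlockOperator:
    def test_tikhonov_stack_values(self, ig2d, ag2d):
        A = ProjectionOperator(ig2d, ag2d)
        D = GradientOperator(ig2d)
        alpha = 0.5
        B = BlockOperator([[A], [ScaledOperator(alpha, D)]])
        u = ig2d.allocate("random", seed=2)
        out = B.direct(u)
        assert np.allclose(out[0].as_array(), A.direct(u).as_array())
        assert np.allclose(out[1][0].as_array(), alpha * D.direct(u)[0].as_array())

    def test_zero_block_annihilates(self, ig2d, ag2d):
        A = ProjectionOperator(ig2d, ag2d)
        D = GradientOperator(ig2d)
        B = BlockOperator([[A], [D]])
        b = ag2d.allocate("random", seed=4, dtype=np.float64)
        zero_w = D.direct(ig2d.allocate(0.0, dtype=np.float64))
        stacked = BlockDataContainer(b, zero_w)
        assert np.allclose(B.adjoint(stacked).as_array(), A.adjoint(b).as_array())

    def test_four_row_stack_is_concatenation(self, ig3d, ag3d):
        # per-axis Tikhonov stack: residuals equal separately computed ones
        A = ProjectionOperator(ig3d, ag3d)
        ds = [FiniteDifferenceOperator(ig3d, lbl)
              for lbl in ("vertical", "horizontal_y", "horizontal_x")]
        alphas = (0.3, 0.7, 1.1)
        B = BlockOperator([[A]] + [[ScaledOperator(a, d)] for a, d in zip(alphas, ds)])
        u = ig3d.allocate("random", seed=5)
        out = B.direct(u)
        assert len(out) == 4
        assert np.allclose(out[0].as_array(), A.direct(u).as_array())
        for k, (a, d) in enumerate(zip(alphas, ds), start=1):
            assert np.allclose(out[k].as_array(), a * d.direct(u).as_array())

    def test_incompatible_grid(self, ig2d, ag2d):
        A = ProjectionOperator(ig2d, ag2d)
        small = IdentityOperator(ImageGeometry(voxel_num_x=3, voxel_num_y=3))
        with pytest.raises(ValueError):
            BlockOperator([[A], [small]])


class TestProjector:
    def test_disc_chord_length(self):
        from tomoopt.simulate_io import disc_phantom

        n = 64
        ag = create_acquisition_geometry(
            beam_type="parallel2D", angles=[0.0, 30.0, 117.0], pixel_num_h=n)
        ig = default_image_geometry(ag)
        r = 0.25 * n
        phantom, _ = disc_phantom(ig, radius=r)
        sino = ProjectionOperator(ig, ag).direct(phantom).as_array()
        centre = n // 2  # detector bin at s = +0.5 for even n
        s_centre = (centre - (n - 1) / 2.0)
        expected = 2.0 * np.sqrt(r ** 2 - s_centre ** 2)
        for row in sino:
            assert row[centre] == pytest.approx(expected, rel=0.01)

    def test_disc_rotation_invariance(self):
        from tomoopt.simulate_io import disc_phantom

        ag = create_acquisition_geometry(
            beam_type="parallel2D", angles=np.linspace(0, 180, 12, endpoint=False),
            pixel_num_h=64)
        ig = default_image_geometry(ag)
        phantom, _ = disc_phantom(ig)
        sino = ProjectionOperator(ig, ag).direct(phantom).as_array()
        ref = sino.mean(axis=0)
        for row in sino:
            assert np.sqrt(np.mean((row - ref) ** 2)) <= 0.01 * np.sqrt(np.mean(ref ** 2))

    def test_disc_profile_closed_form(self):
        from tomoopt.simulate_io import disc_phantom

        n = 64
        ag = create_acquisition_geometry(beam_type="parallel2D", angles=[20.0], pixel_num_h=n)
        ig = default_image_geometry(ag)
        r = 0.25 * n
        phantom, _ = disc_phantom(ig, radius=r)
        row = ProjectionOperator(ig, ag).direct(phantom).as_array()[0]
        s = np.arange(n) - (n - 1) / 2.0
        chord = 2.0 * np.sqrt(np.maximum(r ** 2 - s ** 2, 0.0))
        rms = np.sqrt(np.mean((row - chord) ** 2))
        assert rms <= 0.02 * np.sqrt(np.mean(chord ** 2))

    def test_zero_image_zero_sinogram(self, ig2d, ag2d):
        assert ProjectionOperator(ig2d, ag2d).direct(ig2d.allocate(0.0)).norm() == 0.0

    def test_zero_sinogram_zero_image(self, ig2d, ag2d):
        assert ProjectionOperator(ig2d, ag2d).adjoint(ag2d.allocate(0.0)).norm() == 0.0

    def test_single_angle_backprojection_constant_along_rays(self):
        ag = create_acquisition_geometry(beam_type="parallel2D", angles=[0.0], pixel_num_h=16)
        ig = default_image_geometry(ag)
        img = ProjectionOperator(ig, ag).adjoint(ag.allocate(1.0)).as_array()
        # at theta=0 rays run along x: rows of the interior should be constant
        interior = img[2:-2, 2:-2]
        assert np.allclose(interior, interior[:, :1], rtol=1e-9, atol=1e-9)

    def test_3d_matches_slicewise_2d(self, ig3d, ag3d):
        P3 = ProjectionOperator(ig3d, ag3d)
        u = ig3d.allocate("random", seed=6)
        sino3 = P3.direct(u).as_array()
        ag2 = ag3d.get_slice_geometry("vertical")
        ig2 = ig3d.get_slice_geometry("vertical")
        P2 = ProjectionOperator(ig2, ag2)
        for v in range(ag3d.pixel_num_v):
            u2 = ig2.allocate(0.0, dtype=np.float64).fill(u.as_array()[v])
            assert np.allclose(sino3[:, v, :], P2.direct(u2).as_array())

    def test_cone_rejected(self):
        ag = create_acquisition_geometry(
            beam_type="cone2D", angles=[0.0], pixel_num_h=8,
            source_position=(0, -10, 0), detector_position=(0, 5, 0))
        ig = ImageGeometry(voxel_num_x=8, voxel_num_y=8)
        with pytest.raises(ValueError, match="parallel"):
            ProjectionOperator(ig, ag)


class TestOperatorNorm:
    def test_identity_norm(self, ig2d):
        assert IdentityOperator(ig2d).norm() == pytest.approx(1.0, abs=1e-6)

    def test_diagonal_norm(self):
        g = VectorGeometry(2)
        d = g.allocate(0.0, dtype=np.float64)
        d.as_array()[:] = [1.0, 3.0]
        assert DiagonalOperator(d).norm() == pytest.approx(3.0, abs=1e-6)

    def test_matrix_norm_matches_svd(self, rng):
        M = rng.standard_normal((8, 5))
        A = MatrixOperator(M)
        assert A.norm(iterations=300) == pytest.approx(np.linalg.norm(M, 2), rel=1e-5)

    def test_scaling_homogeneity(self, ig2d, ag2d):
        A = ProjectionOperator(ig2d, ag2d)
        assert ScaledOperator(2.0, A).norm() == pytest.approx(2.0 * A.norm(), rel=1e-6)

    def test_zero_operator(self, ig2d):
        assert ZeroOperator(ig2d).norm() == 0.0

    def test_rayleigh_lower_bound(self, ig2d, ag2d):
        A = ProjectionOperator(ig2d, ag2d)
        nrm = A.norm(iterations=100)
        for seed in range(5):
            v = ig2d.allocate("random", seed=seed, dtype=np.float64)
            assert nrm >= A.direct(v).norm() / v.norm() - 1e-8


class TestOperatorAlgebra:
    def test_scaled_direct(self, ig2d):
        v = ig2d.allocate("random", seed=1)
        out = (2.0 * IdentityOperator(ig2d)).direct(v)
        assert np.allclose(out.as_array(), 2.0 * v.as_array())

    def test_composition_with_identity(self, ig2d):
        D = FiniteDifferenceOperator(ig2d, "horizontal_x")
        C = CompositionOperator(D, IdentityOperator(ig2d))
        v = ig2d.allocate("random", seed=2)
        assert np.allclose(C.direct(v).as_array(), D.direct(v).as_array())

    def test_sum_direct(self, ig2d):
        v = ig2d.allocate("random", seed=3)
        S = IdentityOperator(ig2d) + IdentityOperator(ig2d)
        assert np.allclose(S.direct(v).as_array(), 2.0 * v.as_array())
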