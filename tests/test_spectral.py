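"""Spectral filtering, kernel embedding, convolution and biconvolution."""

import numpy as np
import pytest

from stquat import (
    KEDGE,
    KSHARP,
    Quaternion,
    QuaternionArray,
    biconvolve,
    convolve_real,
    embed_kernel,
    make_rotation,
    rotation_kernels,
    spectral_filter,
)
from stquat.spectral import read_kernel_csv, write_kernel_csv

from .conftest import random_quaternions
from .oracles import spatial_biconvolve, spatial_convolve_real


def planes_of(q):
    return np.stack([q.a, q.b, q.c, q.d])


class TestBuiltinKernels:
    def test_sharpen_kernel_values(self):
        np.testing.assert_array_equal(
            KSHARP, [[0, -1, 0], [-1, 5, -1], [0, -1, 0]]
        )

    def test_edge_kernel_values(self):
        np.testing.assert_array_equal(
            KEDGE, [[-1, -1, -1], [-1, 8, -1], [-1, -1, -1]]
        )

    def test_rotation_kernel_structure_identity(self):
        KL, KR = rotation_kernels(make_rotation([1, 0, 0], 0.0))
        for row in range(3):
            assert KL[row, 0].allclose(Quaternion(1), atol=0)
            assert KL[row, 2].allclose(Quaternion(1), atol=0)
            assert float(KL[row, 1].norm()) == 0.0

    def test_rotation_kernel_half_turn_about_i(self):
        KL, KR = rotation_kernels(make_rotation([1, 0, 0], np.pi))
        for row in range(3):
            assert KL[row, 0].allclose(Quaternion(0, 1, 0, 0), atol=1e-15)
            assert KL[row, 2].allclose(Quaternion(0, -1, 0, 0), atol=1e-15)
            assert KR[row, 0].allclose(Quaternion(0, -1, 0, 0), atol=1e-15)
            assert KR[row, 2].allclose(Quaternion(0, 1, 0, 0), atol=1e-15)
            assert float(KL[row, 1].norm()) == 0.0
            assert float(KR[row, 1].norm()) == 0.0

    def test_rotation_kernels_require_unit(self):
        with pytest.raises(ValueError, match="unit"):
            rotation_kernels(Quaternion(1, 1, 0, 0))

    def test_kernel_csv_round_trip(self, tmp_path, rng):
        k = random_quaternions(rng, (3, 3))
        path = tmp_path / "kernel.csv"
        write_kernel_csv(k, path)
        assert read_kernel_csv(path).allclose(k, atol=0)


class TestSpectralFilter:
    def test_zero_components_is_identity(self, rng):
        q = random_quaternions(rng, (6, 6))
        out = spectral_filter(q, "lowpass", 0)
        assert out.allclose(q, atol=1e-10)

    def test_highpass_kills_constant(self):
        q = QuaternionArray(np.full((5, 5), 2.0), np.full((5, 5), -1.0),
                            np.zeros((5, 5)), np.ones((5, 5)))
        out = spectral_filter(q, "highpass", 1)
        assert float(out.norm().max()) < 1e-12

    def test_lowpass_keeps_constant(self):
        q = QuaternionArray.from_scalar(np.full((5, 5), 3.0))
        out = spectral_filter(q, "lowpass", 3)
        assert out.allclose(q, atol=1e-10)

    def test_too_many_components_rejected(self, rng):
        q = random_quaternions(rng, (4, 4))
        with pytest.raises(ValueError, match="exceeds"):
            spectral_filter(q, "lowpass", 1000)

    def test_low_and_high_bands_partition_energy(self, rng):
        q = random_quaternions(rng, (6, 6))
        # removing complementary band sets reconstructs the input
        rho = np.round(
            np.sqrt(np.add.outer(np.fft.fftfreq(6) ** 2, np.fft.fftfreq(6) ** 2)),
            12,
        )
        n_bands = len(np.unique(rho))
        k = 3
        low = spectral_filter(q, "highpass", k)       # keeps high bands
        high = spectral_filter(q, "lowpass", n_bands - k)  # keeps low bands
        assert (low + high).allclose(q, atol=1e-9)


class TestEmbedKernel:
    def test_delta(self):
        mask = embed_kernel(np.array([[1.0]]), 4, 4)
        assert mask.a[0, 0] == 1.0 and mask.a.sum() == 1.0

    def test_three_by_three_placement(self):
        k = np.arange(1.0, 10.0).reshape(3, 3)
        mask = embed_kernel(k, 8, 8)
        nz = np.argwhere(mask.a != 0)
        expect = {(r % 8, c % 8) for r in (-1, 0, 1) for c in (-1, 0, 1)}
        assert {tuple(p) for p in nz} == expect
        assert mask.a[7, 7] == k[0, 0]
        assert mask.a.sum() == k.sum()

    def test_kernel_larger_than_grid_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            embed_kernel(np.ones((3, 3)), 2, 4)


class TestConvolveReal:
    def test_delta_kernel_is_identity(self, rng):
        q = random_quaternions(rng, (5, 5))
        out = convolve_real(q, np.array([[1.0]]), vector_only=False)
        assert out.allclose(q, atol=1e-12)

    def test_edge_kernel_annihilates_constant_field(self):
        q = QuaternionArray(np.full((6, 6), 5.0), np.full((6, 6), 0.3),
                            np.full((6, 6), -0.7), np.full((6, 6), 0.1))
        out = convolve_real(q, KEDGE)
        assert np.abs(out.b).max() < 1e-12
        assert np.abs(out.c).max() < 1e-12
        assert np.abs(out.d).max() < 1e-12
        np.testing.assert_array_equal(out.a, q.a)  # vector_only passthrough

    @pytest.mark.parametrize("shape", [(5, 5), (6, 6), (7, 8), (8, 8)])
    def test_matches_spatial_oracle(self, rng, shape):
        q = random_quaternions(rng, shape)
        out = convolve_real(q, KEDGE, vector_only=False)
        expect = spatial_convolve_real(planes_of(q), KEDGE)
        scale = np.abs(expect).max()
        np.testing.assert_allclose(planes_of(out) / scale, expect / scale,
                                   atol=1e-9)

    def test_sharpen_kernel_against_oracle(self, rng):
        q = random_quaternions(rng, (6, 7))
        out = convolve_real(q, KSHARP, vector_only=False)
        expect = spatial_convolve_real(planes_of(q), KSHARP)
        np.testing.assert_allclose(planes_of(out), expect, atol=1e-9)


class TestBiconvolve:
    def test_identity_masks(self, rng):
        q = random_quaternions(rng, (5, 5))
        delta = QuaternionArray.zeros((5, 5))
        delta.a[0, 0] = 1.0
        out = biconvolve(delta, q, delta, vector_only=False)
        assert out.allclose(q, atol=1e-12)

    def test_vector_only_passes_real_plane_through(self, rng):
        q = random_quaternions(rng, (5, 5))
        delta = QuaternionArray.zeros((5, 5))
        delta.a[0, 0] = 1.0
        out = biconvolve(delta, q, delta, vector_only=True)
        np.testing.assert_array_equal(out.a, q.a)

    @pytest.mark.parametrize("trial", range(4))
    def test_random_quaternion_kernels_match_spatial_oracle(self, rng, trial):
        q = random_quaternions(rng, (5, 5))
        kl = random_quaternions(rng, (3, 3))
        kr = random_quaternions(rng, (3, 3))
        out = biconvolve(
            embed_kernel(kl, 5, 5), q, embed_kernel(kr, 5, 5), vector_only=False
        )
        expect = spatial_biconvolve(planes_of(kl), planes_of(q), planes_of(kr))
        scale = np.abs(expect).max()
        np.testing.assert_allclose(planes_of(out) / scale, expect / scale,
                                   atol=1e-9)

    def test_rotation_kernels_annihilate_constant_field(self):
        # KL row sums are r + r^-1 = 0 for a half-turn, so any uniform
        # vector field maps to zero.
        r = make_rotation([1, 0, 0], np.pi)
        KL, KR = rotation_kernels(r)
        vec = np.tile([1.0, 0.0, 0.0], (6, 6, 1))
        q = QuaternionArray.from_vector(np.zeros((6, 6)), vec)
        out = biconvolve(embed_kernel(KL, 6, 6), q, embed_kernel(KR, 6, 6))
        assert float(out.vector_norm().max()) < 1e-12


class TestRotationKernelEdgeSelectivity:
    """Axis-selective edge detection: the response orthogonal to the
    rotation axis vanishes for boundaries that differ only along the axis
    and fires for boundaries that differ orthogonally."""

    @staticmethod
    def _two_domain_field(v_left, v_right, rows=6, cols=6):
        vec = np.empty((rows, cols, 3))
        vec[:, : cols // 2] = v_left
        vec[:, cols // 2 :] = v_right
        return QuaternionArray.from_vector(np.zeros((rows, cols)), vec)

    @staticmethod
    def _off_axis_magnitude(out, axis):
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        v = out.vector()
        v_par = (v @ axis)[..., None] * axis
        return np.linalg.norm(v - v_par, axis=-1)

    def test_axis_aligned_boundary_ignored(self):
        r = make_rotation([1, 0, 0], np.pi)
        KL, KR = rotation_kernels(r)
        # domains differ only in the i (axis) component
        q = self._two_domain_field([0.6, 0.8, 0.0], [-0.6, 0.8, 0.0])
        out = biconvolve(embed_kernel(KL, 6, 6), q, embed_kernel(KR, 6, 6))
        assert self._off_axis_magnitude(out, [1, 0, 0]).max() <= 1e-9
        # and the (axis-parallel) output never leaves the axis direction
        assert np.abs(out.c).max() <= 1e-9 and np.abs(out.d).max() <= 1e-9

    def test_orthogonal_boundary_fires(self):
        r = make_rotation([1, 0, 0], np.pi)
        KL, KR = rotation_kernels(r)
        # domains differ only in the j component, orthogonal to the axis
        q = self._two_domain_field([0.8, 0.6, 0.0], [0.8, -0.6, 0.0])
        out = biconvolve(embed_kernel(KL, 6, 6), q, embed_kernel(KR, 6, 6))
        assert self._off_axis_magnitude(out, [1, 0, 0]).max() > 0.1

    def test_matches_spatial_oracle_on_two_domain_fixture(self):
        r = make_rotation([1, 0, 0], np.pi)
        KL, KR = rotation_kernels(r)
        q = self._two_domain_field([0.0, 1.0, 0.0], [0.0, 0.0, 1.0])
        out = biconvolve(
            embed_kernel(KL, 6, 6), q, embed_kernel(KR, 6, 6), vector_only=False
        )
        expect = spatial_biconvolve(
            np.stack([KL.a, KL.b, KL.c, KL.d]),
            np.stack([q.a, q.b, q.c, q.d]),
            np.stack([KR.a, KR.b, KR.c, KR.d]),
        )
        np.testing.assert_allclose(np.stack([out.a, out.b, out.c, out.d]),
                                   expect, atol=1e-9)
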