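"""Image metrics, angular accuracy, box summary, and the DTI fit."""

import math

import numpy as np
import pytest

import hosvdsr as h
from hosvdsr.phantom import tensor_from_fa

RNG = np.random.default_rng(5)


class TestPSNR:
    def test_identical_volumes_infinite(self):
        v = RNG.normal(size=(6, 6, 6))
        assert h.psnr(v, v) == math.inf

    def test_closed_form_peak_255(self):
        ref = np.zeros((10, 10, 10))
        test = np.ones((10, 10, 10))  # MSE = 1
        assert h.psnr(ref, test, peak=255.0) == pytest.approx(48.1308, abs=1e-4)

    def test_doubling_error_costs_6dB(self):
        ref = RNG.normal(size=(8, 8, 8)) + 10
        err = RNG.normal(size=(8, 8, 8))
        p1 = h.psnr(ref, ref + err, peak=100.0)
        p2 = h.psnr(ref, ref + 2 * err, peak=100.0)
        assert p1 - p2 == pytest.approx(20 * math.log10(2), abs=1e-10)

    def test_monotone_in_noise_level(self):
        ref = np.abs(RNG.normal(size=(12, 12, 12))) + 5
        rng = np.random.default_rng(0)
        noise = rng.normal(size=ref.shape)
        vals = [h.psnr(ref, ref + s * noise) for s in (0.1, 0.3, 1.0, 3.0)]
        assert vals == sorted(vals, reverse=True)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            h.psnr(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestSSIM:
    def test_identity_is_one_both_modes(self):
        x = RNG.normal(size=(20, 20))
        assert h.ssim(x, x, dynamic_range=float(np.ptp(x))) == pytest.approx(1.0)
        assert h.ssim(x, x, dynamic_range=1.0, mode="global") == pytest.approx(1.0)

    def test_constant_images_closed_form(self):
        c, d, L = 4.0, 6.0, 10.0
        x = np.full((16, 16), c)
        y = np.full((16, 16), d)
        c1 = (0.01 * L) ** 2
        expected = (2 * c * d + c1) / (c * c + d * d + c1)
        assert h.ssim(x, y, dynamic_range=L) == pytest.approx(expected, rel=1e-12)
        assert h.ssim(x, y, dynamic_range=L, mode="global") == pytest.approx(expected, rel=1e-12)

    def test_anticorrelated_zero_mean_nonpositive(self):
        x = RNG.normal(size=(32, 32))
        x -= x.mean()
        assert h.ssim(x, -x, dynamic_range=0.1, mode="global") <= 0.0

    def test_matches_skimage_oracle(self):
        """Cross-check the local-window index against scikit-image."""
        from skimage.metrics import structural_similarity

        x = RNG.normal(size=(24, 24)) + 10
        y = x + 0.3 * RNG.normal(size=(24, 24))
        ours = h.ssim(x, y, dynamic_range=5.0, win=7)
        theirs = structural_similarity(
            x, y, win_size=7, data_range=5.0, gaussian_weights=False
        )
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_3d_averages_axial_slices(self):
        x = RNG.normal(size=(16, 16, 3)) + 5
        y = x + 0.1 * RNG.normal(size=x.shape)
        per_slice = [h.ssim(x[:, :, z], y[:, :, z], dynamic_range=2.0) for z in range(3)]
        assert h.ssim(x, y, dynamic_range=2.0) == pytest.approx(np.mean(per_slice))


class TestAngularError:
    def test_parallel_orthogonal_antiparallel(self):
        e1 = np.array([1.0, 0, 0])
        e2 = np.array([0, 1.0, 0])
        assert h.angular_error(e1, e1) == pytest.approx(0.0)
        assert h.angular_error(e1, e2) == pytest.approx(90.0)
        assert h.angular_error(e1, -e1) == pytest.approx(0.0)  # axes are sign-free

    def test_sign_flip_invariance_and_bounds(self):
        for _ in range(20):
            a = RNG.normal(size=3)
            b = RNG.normal(size=3)
            a /= np.linalg.norm(a)
            b /= np.linalg.norm(b)
            e = h.angular_error(a, b)
            assert 0.0 <= e <= 90.0
            assert e == pytest.approx(h.angular_error(-a, b))
            assert e == pytest.approx(h.angular_error(a, -b))

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            h.angular_error(np.array([2.0, 0, 0]), np.array([1.0, 0, 0]))


class TestSummarizeErrors:
    def test_hundred_values_two_percent(self):
        stats = h.summarize_errors(np.arange(1.0, 101.0), outlier_fraction=0.02)
        assert stats.outliers == (99.0, 100.0)
        assert stats.whisker_high == 98.0
        assert stats.whisker_low == 1.0
        assert stats.median == pytest.approx(49.5)

    def test_all_equal(self):
        stats = h.summarize_errors([3.0] * 10)
        assert stats.mean == stats.median == stats.q25 == stats.q75 == 3.0
        assert stats.whisker_low == stats.whisker_high == 3.0

    def test_zero_fraction_keeps_everything(self):
        stats = h.summarize_errors([1.0, 5.0, 2.0], outlier_fraction=0.0)
        assert stats.outliers == ()
        assert stats.whisker_high == 5.0

    def test_retained_count(self):
        n = 137
        stats = h.summarize_errors(RNG.uniform(0, 90, n), outlier_fraction=0.02)
        assert len(stats.outliers) == math.floor(0.02 * n)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            h.summarize_errors([])


def _single_tensor_dwi(tensor, s0=100.0, b=700.0, shape=(3, 3, 3)):
    scheme = h.make_gradient_scheme(15, b, seed=4, include_b0=True)
    g, bv = scheme.directions, scheme.b_values
    att = np.exp(-bv * np.einsum("ni,ij,nj->n", g, tensor, g))
    sig = np.broadcast_to(s0 * att, shape + (len(scheme),)).copy()
    return h.DWIVolume(signal=sig, voxel_size=(1, 1, 1), scheme=scheme)


class TestDTIFit:
    def test_recovers_generating_tensor(self):
        d = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
        tensor = tensor_from_fa(d, 0.85, md=0.7e-3)
        fit = h.fit_dti(_single_tensor_dwi(tensor))
        assert fit.ok.all()
        np.testing.assert_allclose(fit.tensor[1, 1, 1], tensor, rtol=1e-8)
        assert h.fa(fit.tensor[0, 0, 0]) == pytest.approx(0.85, abs=1e-8)
        err = h.angular_error(d, h.principal_direction(fit.tensor[0, 0, 0]))
        assert err < 1e-6

    def test_isotropic_signal_zero_fa(self):
        fit = h.fit_dti(_single_tensor_dwi(0.7e-3 * np.eye(3)))
        assert h.fa(fit.tensor[0, 0, 0]) < 1e-6

    def test_nonpositive_signal_flags_voxel_only(self):
        dwi = _single_tensor_dwi(0.7e-3 * np.eye(3))
        sig = dwi.signal.copy()
        sig[0, 0, 0, 3] = 0.0
        fit = h.fit_dti(h.DWIVolume(signal=sig, voxel_size=(1, 1, 1), scheme=dwi.scheme))
        assert not fit.ok[0, 0, 0]
        assert fit.ok[1, 1, 1]
        assert np.all(fit.tensor[0, 0, 0] == 0)

    def test_too_few_directions_rejected(self):
        scheme = h.GradientScheme(
            directions=np.vstack([np.zeros(3), np.eye(3)]),
            b_values=[0.0, 700.0, 700.0, 700.0],
            includes_b0=True,
        )
        dwi = h.DWIVolume(
            signal=np.full((2, 2, 2, 4), 50.0), voxel_size=(1, 1, 1), scheme=scheme
        )
        with pytest.raises(ValueError):
            h.fit_dti(dwi)


class TestFAandDirections:
    def test_fa_closed_forms(self):
        assert h.fa(np.diag([1.0, 1.0, 1.0])) == 0.0
        assert h.fa(np.diag([1.0, 0.0, 0.0])) == pytest.approx(1.0)
        assert h.fa(np.diag([1.7e-3, 0.2e-3, 0.2e-3])) == pytest.approx(0.8704, abs=1e-4)
        assert h.fa(np.zeros((3, 3))) == 0.0

    def test_principal_direction_and_rotation(self):
        assert np.allclose(h.principal_direction(np.diag([3.0, 2.0, 1.0])), [1, 0, 0])
        _, degenerate = h.principal_direction(np.eye(3), return_degenerate=True)
        assert degenerate
        # similarity transform moves the principal axis with the rotation
        theta = 0.7
        r = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1.0]]
        )
        rotated = r @ np.diag([3.0, 2.0, 1.0]) @ r.T
        got = h.principal_direction(rotated)
        expected = r[:, 0] * np.sign(r[0, 0])
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_fa_colormap_conventions(self):
        d = np.array([1.0, 0.0, 0.0])
        t = tensor_from_fa(d, 0.8)
        fit = h.TensorFit(
            tensor=np.broadcast_to(t, (1, 1, 2, 3, 3)).copy(),
            s0_est=np.ones((1, 1, 2)),
            ok=np.array([[[True, False]]]),
        )
        rgb = h.fa_colormap(fit)
        np.testing.assert_allclose(rgb[0, 0, 0], [0.8, 0, 0], atol=1e-9)
        np.testing.assert_array_equal(rgb[0, 0, 1], [0, 0, 0])  # invalid voxel dark

    def test_oblique_fiber_equal_channels(self):
        d = np.ones(3) / np.sqrt(3)
        t = tensor_from_fa(d, 0.8)
        fit = h.TensorFit(
            tensor=t[None, None, None], s0_est=np.ones((1, 1, 1)),
            ok=np.ones((1, 1, 1), bool),
        )
        rgb = h.fa_colormap(fit)[0, 0, 0]
        assert rgb[0] == pytest.approx(rgb[1]) == pytest.approx(rgb[2])
        assert rgb[0] == pytest.approx(0.8 / np.sqrt(3))


class TestAngularErrorField:
    def test_perfect_fit_zero_errors(self):
        d = np.array([0.0, 1.0, 0.0])
        t = tensor_from_fa(d, 0.8)
        comp = h.FiberCompartment(direction=d, fraction=1.0, tensor=t)
        field = h.FiberField(shape=(2, 2, 2), compartments={(0, 1, 0): [comp]})
        fit = h.TensorFit(
            tensor=np.broadcast_to(t, (2, 2, 2, 3, 3)).copy(),
            s0_est=np.ones((2, 2, 2)), ok=np.ones((2, 2, 2), bool),
        )
        errors = h.angular_error_field(field, fit)
        assert errors[0, 1, 0] == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(errors[1, 1, 1])  # background

    def test_rigid_rotation_shifts_all_errors_equally(self):
        angle = np.radians(10.0)
        r = np.array(
            [[np.cos(angle), -np.sin(angle), 0],
             [np.sin(angle), np.cos(angle), 0],
             [0, 0, 1.0]]
        )
        d = np.array([1.0, 0.0, 0.0])
        t = tensor_from_fa(d, 0.8)
        comp = h.FiberCompartment(direction=d, fraction=1.0, tensor=t)
        field = h.FiberField(
            shape=(2, 2, 2),
            compartments={(i, j, 0): [comp] for i in range(2) for j in range(2)},
        )
        rt = r @ t @ r.T
        fit = h.TensorFit(
            tensor=np.broadcast_to(rt, (2, 2, 2, 3, 3)).copy(),
            s0_est=np.ones((2, 2, 2)), ok=np.ones((2, 2, 2), bool),
        )
        errors = h.angular_error_field(field, fit)
        finite = errors[np.isfinite(errors)]
        np.testing.assert_allclose(finite, 10.0, atol=1e-6)

    def test_crossing_voxel_mixed_match(self):
        d1 = np.array([1.0, 0.0, 0.0])
        d2 = np.array([0.0, 1.0, 0.0])
        t = tensor_from_fa(d1, 0.8)
        comps = [
            h.FiberCompartment(direction=d1, fraction=0.5, tensor=t),
            h.FiberCompartment(direction=d2, fraction=0.5, tensor=tensor_from_fa(d2, 0.8)),
        ]
        field = h.FiberField(shape=(1, 1, 1), compartments={(0, 0, 0): comps})
        fit = h.TensorFit(
            tensor=t[None, None, None], s0_est=np.ones((1, 1, 1)),
            ok=np.ones((1, 1, 1), bool),
        )
        # estimated axis matches d1 exactly and is 90 degrees from d2
        assert h.angular_error_field(field, fit)[0, 0, 0] == pytest.approx(45.0, abs=1e-9)
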