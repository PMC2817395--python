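"""Central-section sampling and shell-wise least-squares fitting."""

import numpy as np
import pytest

from osafrec import basis as B
from osafrec import fourier as F
from osafrec import simulate as S
from conftest import angles_of


def _random_directions(n, seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return angles_of(v)


def _synthesize_shell(basis, keys, f_true, n, seed, radius=0.1):
    """Forward synthesis F = sum f_{l,mu} O_{l,mu} (complex) at random points."""
    th, ph = _random_directions(n, seed)
    vals = np.zeros(n, dtype=complex)
    for k in keys:
        vals += f_true[k] * B.evaluate_complex(basis[k], th, ph)
    return F.FourierShellSamples(radius, th, ph, vals, 1)


class TestTransform:
    def test_dc_equals_sum_and_parseval(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(32, 32))
        t = F.transform_projection(img)
        assert t[16, 16] == pytest.approx(img.sum())
        assert np.sum(np.abs(t) ** 2) / 32**2 == pytest.approx(np.sum(img**2))

    def test_constant_image_concentrates_at_dc(self):
        t = F.transform_projection(np.full((16, 16), 3.0))
        off_dc = np.abs(t).copy()
        off_dc[8, 8] = 0.0
        assert np.max(off_dc) < 1e-9 * abs(t[8, 8])

    def test_friedel_symmetry(self):
        rng = np.random.default_rng(1)
        t = F.transform_projection(rng.normal(size=(16, 16)))
        # F(-u) = conj(F(u)) on the centered grid (skip the Nyquist row/col)
        inner = t[1:, 1:]
        np.testing.assert_allclose(inner[::-1, ::-1], np.conj(inner), atol=1e-10)

    def test_padding_refines_grid(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(16, 16))
        t1, t2 = F.transform_projection(img), F.transform_projection(img, pad=2)
        assert t2.shape == (32, 32)
        np.testing.assert_allclose(t2[::2, ::2][:-1, :-1], t1[:-1, :-1], atol=1e-9)
        assert t2[16, 16] == pytest.approx(img.sum())

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            F.transform_projection(np.zeros((8, 9)))


class TestCenterShift:
    def test_zero_shift_is_identity(self):
        rng = np.random.default_rng(3)
        t = F.transform_projection(rng.normal(size=(16, 16)))
        np.testing.assert_array_equal(F.apply_center_shift(t, 0, 0), t)

    def test_integer_shift_roundtrip_exact(self):
        rng = np.random.default_rng(4)
        img = rng.normal(size=(16, 16))
        t = F.transform_projection(img)
        shifted = S._fourier_shift_2d(img, 3.0, -2.0)
        t2 = F.apply_center_shift(F.transform_projection(shifted), 3.0, -2.0)
        np.testing.assert_allclose(t2, t, atol=1e-10)

    def test_half_pixel_shift_against_analytic_gaussian(self):
        # band-limited Gaussian: analytic shift available in closed form
        n, sigma = 32, 2.5
        ax = np.arange(n) - n // 2

        def gauss(cx, cy):
            return np.exp(
                -((ax[None, :] - cx) ** 2 + (ax[:, None] - cy) ** 2) / (2 * sigma**2)
            )

        shifted = S._fourier_shift_2d(gauss(0, 0), 0.5, -0.5)
        np.testing.assert_allclose(shifted, gauss(0.5, -0.5), atol=1e-6)
        t = F.apply_center_shift(F.transform_projection(shifted), 0.5, -0.5)
        ref = F.transform_projection(gauss(0, 0))
        assert np.max(np.abs(t - ref)) < 1e-5 * np.abs(ref).max()


class TestCentralSection:
    def test_identity_orientation_is_equatorial(self):
        t = F.transform_projection(np.ones((32, 32)))
        sh = F.sample_central_section(
            t, S.EulerTriplet(0, 0, 0), [4 / 32.0], voxel=1.0
        )[0]
        np.testing.assert_allclose(sh.theta, np.pi / 2, atol=1e-12)
        assert len(sh) == 16  # default rule 4k at k=4

    def test_sample_count_follows_rule(self):
        t = F.transform_projection(np.ones((32, 32)))
        radii = [k / 32.0 for k in (1, 3, 7)]
        shells = F.sample_central_section(
            t, S.EulerTriplet(0.2, 0.9, 1.1), radii, voxel=1.0,
            n_per_shell=lambda k: 6 * k,
        )
        assert [len(s) for s in shells] == [6, 18, 42]

    def test_spherical_object_gives_constant_shells(self):
        n, sigma = 64, 2.5
        ax = np.arange(n) - n // 2
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        vol = S.DensityVolume(
            np.exp(-(xx**2 + yy**2 + zz**2) / (2 * sigma**2)), 1.0
        )
        for e in S.random_orientations(2, seed=6):
            t = F.transform_projection(S.project(vol, e), pad=2)
            shells = F.sample_central_section(
                t, e, [k / n for k in (2, 5, 8)], voxel=1.0, pad=2
            )
            for sh in shells:
                mags = np.abs(sh.values)
                assert np.ptp(mags) / mags.mean() < 0.01

    def test_beyond_nyquist_rejected(self):
        t = F.transform_projection(np.ones((32, 32)))
        with pytest.raises(ValueError):
            F.sample_central_section(t, S.EulerTriplet(0, 0, 0), [0.49], voxel=1.0)


class TestSymmetryExpand:
    def test_count_multiplied_by_24(self, basis16, rotations):
        sh = _synthesize_shell(basis16, [(0, 1)], {(0, 1): 1.0}, 10, seed=1)
        assert len(F.symmetry_expand(sh, rotations)) == 240

    def test_identity_rotation_preserves_samples(self, basis16):
        sh = _synthesize_shell(basis16, [(4, 1)], {(4, 1): 2.0}, 10, seed=2)
        ex = F.symmetry_expand(sh, np.eye(3)[None])
        np.testing.assert_allclose(ex.theta, sh.theta)
        np.testing.assert_allclose(ex.values, sh.values)

    def test_expansion_leaves_fit_unchanged(self, basis16, rotations):
        keys = list(basis16.pairs(lmax=12))
        rng = np.random.default_rng(3)
        f_true = {k: rng.normal() for k in keys}
        sh = _synthesize_shell(basis16, keys, f_true, 40 * len(keys), seed=3)
        fit0 = F.fit_shell(sh, basis16, 12)
        fit1 = F.fit_shell(F.symmetry_expand(sh, rotations), basis16, 12)
        fit2 = F.fit_shell(
            F.symmetry_expand(F.symmetry_expand(sh, rotations), rotations),
            basis16,
            12,
        )
        for k in keys:
            a = fit0.f_even.get(k, fit0.f_odd.get(k))
            b = fit1.f_even.get(k, fit1.f_odd.get(k))
            c = fit2.f_even.get(k, fit2.f_odd.get(k))
            assert b == pytest.approx(a, abs=1e-10)
            assert c == pytest.approx(b, abs=1e-10)


class TestChooseLmax:
    def test_vanishing_radius_keeps_only_l0(self):
        assert F.choose_lmax(1e-9, 32.0, 1000, 30) == 0

    def test_monotone_in_object_radius(self):
        a = F.choose_lmax(0.1, 16.0, 10_000, 60)
        b = F.choose_lmax(0.1, 32.0, 10_000, 60)
        assert b >= a

    def test_unknown_cap_for_tiny_shells(self):
        full = F.choose_lmax(0.2, 32.0, 10_000, 30)
        capped = F.choose_lmax(0.2, 32.0, 12, 30)
        assert capped < full


class TestFitShell:
    def test_recovers_synthesized_coefficients(self, basis16):
        keys = list(basis16.pairs(lmax=16))
        rng = np.random.default_rng(4)
        f_true = {k: rng.normal() for k in keys}
        sh = _synthesize_shell(basis16, keys, f_true, 10 * len(keys), seed=4)
        fit = F.fit_shell(sh, basis16, 16)
        scale = max(abs(v) for v in f_true.values())
        for k in keys:
            got = fit.f_even.get(k, fit.f_odd.get(k))
            assert abs(got - f_true[k]) / scale < 1e-8
        assert fit.residual < 1e-8

    def test_zero_samples_give_zero_coefficients(self, basis16):
        th, ph = _random_directions(200, 5)
        sh = F.FourierShellSamples(0.1, th, ph, np.zeros(200, dtype=complex), 1)
        fit = F.fit_shell(sh, basis16, 12)
        assert all(v == 0 for v in fit.f_even.values())
        assert all(v == 0 for v in fit.f_odd.values())
        assert fit.residual == 0.0

    def test_pure_l0_shell(self, basis16):
        sh = _synthesize_shell(basis16, [(0, 1)], {(0, 1): 3.0}, 300, seed=6)
        fit = F.fit_shell(sh, basis16, 12)
        assert fit.f_even[(0, 1)] == pytest.approx(3.0, abs=1e-10)
        others = [v for k, v in fit.f_even.items() if k != (0, 1)]
        np.testing.assert_allclose(others, 0.0, atol=1e-10)

    def test_underdetermined_shell_fails_loudly(self, basis16):
        th, ph = _random_directions(5, 7)
        sh = F.FourierShellSamples(0.123, th, ph, np.ones(5, dtype=complex), 1)
        with pytest.raises(ValueError, match="0.123"):
            F.fit_shell(sh, basis16, 16)

    def test_residual_decreases_with_lmax(self, basis16):
        keys = list(basis16.pairs(lmax=16))
        rng = np.random.default_rng(8)
        f_true = {k: rng.normal() for k in keys}
        sh = _synthesize_shell(basis16, keys, f_true, 2000, seed=8)
        res = [F.fit_shell(sh, basis16, lm).residual for lm in (4, 8, 12, 16)]
        assert all(b <= a + 1e-12 for a, b in zip(res, res[1:]))

    def test_fit_invariant_under_within_order_basis_rotation(self, basis16):
        """Rotating the basis inside a mu >= 2 block changes individual
        coefficients but not the reconstructed F on the shell."""
        import math
        from osafrec.basis import HarmonicCoefficients, OSAFBasis

        a = math.radians(35.0)
        f1, f2 = basis16[(12, 1)], basis16[(12, 2)]
        ms = sorted(set(f1.coeffs) | set(f2.coeffs))

        def mix(c, s):
            vals = {
                m: c * f1.coeffs.get(m, 0.0) + s * f2.coeffs.get(m, 0.0) for m in ms
            }
            return vals

        rot_fns = []
        for f in basis16.functions:
            if f.l != 12:
                rot_fns.append(f)
        rot_fns.append(HarmonicCoefficients(12, 1, mix(math.cos(a), math.sin(a))))
        rot_fns.append(HarmonicCoefficients(12, 2, mix(-math.sin(a), math.cos(a))))
        rotated = OSAFBasis(lmax=16, functions=tuple(sorted(rot_fns, key=lambda f: (f.l, f.mu))))

        keys = list(basis16.pairs(lmax=12))
        rng = np.random.default_rng(11)
        f_true = {k: rng.normal() for k in keys}
        sh = _synthesize_shell(basis16, keys, f_true, 900, seed=11)
        pred = []
        for bb in (basis16, rotated):
            fit = F.fit_shell(sh, bb, 12)
            ke, ae, ko, ao = F.design_matrix(bb, 12, sh.theta, sh.phi)
            pred.append(
                ae @ np.array([fit.f_even[k] for k in ke])
                + 1j * (ao @ np.array([fit.f_odd[k] for k in ko]))
            )
        np.testing.assert_allclose(pred[0], pred[1], atol=1e-8)

    def test_friedel_mates_do_not_move_even_coefficients(self, basis16):
        """For a symmetric real object Re(F) is inversion-even; adding the
        Friedel mates must leave the even-l fit untouched."""
        keys = list(basis16.pairs(lmax=12))
        rng = np.random.default_rng(9)
        f_true = {k: rng.normal() for k in keys}
        sh = _synthesize_shell(basis16, keys, f_true, 800, seed=9)
        v = np.stack(
            [
                np.sin(sh.theta) * np.cos(sh.phi),
                np.sin(sh.theta) * np.sin(sh.phi),
                np.cos(sh.theta),
            ],
            axis=1,
        )
        tm, pm = angles_of(-v)
        mates = F.FourierShellSamples(
            sh.shell_radius, tm, pm, np.conj(sh.values), 1
        )
        both = F.FourierShellSamples.concatenate([sh, mates])
        fit_a = F.fit_shell(sh, basis16, 12)
        fit_b = F.fit_shell(both, basis16, 12)
        for k, val in fit_a.f_even.items():
            assert fit_b.f_even[k] == pytest.approx(val, abs=1e-8)
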