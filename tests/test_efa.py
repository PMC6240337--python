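import numpy as np
import pytest
from scipy.integrate import quad

from molshape import (EFACoefficients, Outline, efa_forward, efa_inverse,
                      efa_normalize, harmonic_power, mean_shape,
                      min_harmonics_for_power, read_coeffs_csv,
                      resample_outline, rotate_coefficients,
                      scale_coefficients, shift_start, write_coeffs_csv)
from molshape.errors import BadParameter, DegenerateShape, MixedBasis


def quad_oracle(outline: Outline, n_harmonics: int):
    """Independent numerical-integration oracle for the Fourier integrals of
    the arc-length-parameterized (piecewise linear) outline."""
    pts = np.vstack([outline.points, outline.points[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    T = t[-1]

    def coord(s, k):
        i = min(np.searchsorted(t, s, side="right") - 1, len(seg) - 1)
        frac = (s - t[i]) / seg[i]
        return pts[i, k] + frac * (pts[i + 1, k] - pts[i, k])

    def integrate(f):
        total = 0.0
        for i in range(len(seg)):  # integrate per segment (smooth pieces)
            total += quad(f, t[i], t[i + 1], limit=200, epsabs=1e-12)[0]
        return total

    res = {}
    for name, k, trig in (("a", 0, np.cos), ("b", 0, np.sin),
                          ("c", 1, np.cos), ("d", 1, np.sin)):
        res[name] = [
            (2.0 / T) * integrate(
                lambda s, n=n, k=k, trig=trig:
                coord(s, k) * trig(2.0 * np.pi * n * s / T))
            for n in range(1, n_harmonics + 1)]
    res["A0"] = integrate(lambda s: coord(s, 0)) / T
    res["C0"] = integrate(lambda s: coord(s, 1)) / T
    return res


class TestForward:
    def test_unit_circle_is_pure_first_harmonic(self, circle_outline):
        cf = efa_forward(circle_outline(2048), 5)
        assert cf.a[0] == pytest.approx(1.0, abs=1e-5)
        assert cf.d[0] == pytest.approx(1.0, abs=1e-5)
        assert abs(cf.b[0]) < 1e-9 and abs(cf.c[0]) < 1e-9
        for arr in (cf.a, cf.b, cf.c, cf.d):
            assert np.max(np.abs(arr[1:])) < 1e-6

    def test_axis_aligned_ellipse(self):
        t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        ell = Outline(np.column_stack([2 * np.cos(t), np.sin(t)]))
        cf = efa_forward(ell, 5)
        # constant-speed (arc length) traversal of an ellipse is not the
        # angle parameterization, so the first harmonic only approximates
        # the semi-axes; the symmetry zeros are exact
        assert cf.a[0] == pytest.approx(2.0, rel=0.1)
        assert cf.d[0] == pytest.approx(1.0, rel=0.1)
        assert cf.a[0] > cf.d[0]
        assert abs(cf.b[0]) < 1e-6 and abs(cf.c[0]) < 1e-6

    def test_random_polygon_matches_integration_oracle(self):
        rng = np.random.default_rng(12)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
        rad = rng.uniform(0.5, 1.5, 12)
        poly = Outline(np.column_stack([rad * np.cos(ang),
                                        rad * np.sin(ang)]), label="12gon")
        cf = efa_forward(poly, 5)
        oracle = quad_oracle(poly, 5)
        for name in "abcd":
            np.testing.assert_allclose(getattr(cf, name), oracle[name],
                                       atol=1e-8)
        assert cf.dc[0] == pytest.approx(oracle["A0"], abs=1e-8)
        assert cf.dc[1] == pytest.approx(oracle["C0"], abs=1e-8)

    def test_nyquist_bound_enforced(self, circle_outline):
        with pytest.raises(BadParameter):
            efa_forward(circle_outline(20), 11)


class TestInverse:
    def test_circle_coefficients_reconstruct_circle(self):
        cf = EFACoefficients(a=[1.0], b=[0.0], c=[0.0], d=[1.0])
        rec = efa_inverse(cf, 200)
        radii = np.hypot(rec.points[:, 0], rec.points[:, 1])
        assert np.max(np.abs(radii - 1.0)) < 1e-6

    def test_zero_harmonics_degenerate_at_dc(self):
        cf = EFACoefficients(a=[0.0], b=[0.0], c=[0.0], d=[0.0],
                             dc=(2.5, -1.5))
        rec = efa_inverse(cf, 10)
        assert rec.degenerate
        np.testing.assert_allclose(rec.points,
                                   np.tile([2.5, -1.5], (10, 1)))

    def test_truncation_error_below_residual_power_bound(self, blob_outline):
        blob = resample_outline(blob_outline(seed=9, n_points=512), 512)
        full = efa_forward(blob, 256)
        rec = efa_inverse(efa_forward(blob, 40), 512)
        dev = np.max(np.hypot(*(rec.points - blob.points).T))
        # sup-norm bound from the amplitudes of the dropped harmonics
        sl = slice(40, None)
        bound = (np.sum(np.hypot(full.a[sl], full.b[sl]))
                 + np.sum(np.hypot(full.c[sl], full.d[sl])))
        assert dev <= bound

    def test_full_rank_roundtrip_within_1e6_of_perimeter(self, blob_outline):
        blob = resample_outline(blob_outline(seed=5, amp=0.1,
                                             n_points=2048), 2048)
        rec = efa_inverse(efa_forward(blob, 1024), 2048)
        err = np.max(np.hypot(*(rec.points - blob.points).T))
        assert err < 1e-6 * blob.perimeter


class TestNormalize:
    @pytest.mark.parametrize("transform", [
        lambda c: rotate_coefficients(c, np.deg2rad(37)),
        lambda c: scale_coefficients(c, 3.0),
        lambda c: shift_start(c, 1.234),
        lambda c: scale_coefficients(rotate_coefficients(
            shift_start(c, 0.7), -1.1), 0.4),
    ])
    def test_invariance(self, blob_coeffs, transform):
        base = blob_coeffs(seed=2)
        n0 = efa_normalize(base)
        n1 = efa_normalize(transform(base))
        np.testing.assert_allclose(n1.flattened(), n0.flattened(), atol=1e-9)

    def test_circle_normalizes_to_unit_first_harmonic(self, circle_outline):
        cf = efa_normalize(efa_forward(circle_outline(1024), 4))
        assert cf.a[0] == 1.0 and cf.b[0] == 0.0 and cf.c[0] == 0.0
        assert cf.normalized

    def test_null_first_harmonic_rejected(self):
        cf = EFACoefficients(a=[0.0, 1.0], b=[0.0, 0.0], c=[0.0, 0.0],
                             d=[0.0, 0.5])
        with pytest.raises(DegenerateShape):
            efa_normalize(cf)


class TestHarmonicPower:
    def test_circle_all_power_in_first_harmonic(self, circle_outline):
        prof = harmonic_power(efa_forward(circle_outline(1024), 10))
        assert prof.cumulative_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_smooth_blob_reaches_99pct_within_20(self, blob_coeffs):
        cf = blob_coeffs(seed=4, n_harmonics=20)
        prof = harmonic_power(cf)
        # oracle: cumulative sum of the power definition
        p = 0.5 * (cf.a ** 2 + cf.b ** 2 + cf.c ** 2 + cf.d ** 2)
        np.testing.assert_allclose(prof.cumulative_fraction,
                                   np.cumsum(p) / p.sum(), atol=1e-12)
        assert min_harmonics_for_power(cf, 0.99) <= 20

    def test_noisy_polygon_has_power_beyond_20(self):
        rng = np.random.default_rng(8)
        ang = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        rad = 1.0 + 0.15 * rng.standard_normal(64)
        noisy = Outline(np.column_stack([rad * np.cos(ang),
                                         rad * np.sin(ang)]))
        prof = harmonic_power(efa_forward(noisy, 32))
        assert prof.cumulative_fraction[19] < prof.cumulative_fraction[31]

    def test_min_harmonics_monotone_in_threshold(self, blob_coeffs):
        cf = blob_coeffs(seed=6, n_harmonics=20)
        grid = [0.5, 0.8, 0.9, 0.95, 0.99, 1.0]
        needed = [min_harmonics_for_power(cf, th) for th in grid]
        assert needed == sorted(needed)
        assert needed[-1] <= cf.n_harmonics

    def test_threshold_domain(self, blob_coeffs):
        with pytest.raises(BadParameter):
            min_harmonics_for_power(blob_coeffs(1), 0.0)
        with pytest.raises(BadParameter):
            min_harmonics_for_power(blob_coeffs(1), 1.5)


class TestMeanShape:
    def test_identical_members_returned(self, blob_coeffs):
        cf = blob_coeffs(seed=1)
        m = mean_shape([cf, cf, cf])
        np.testing.assert_allclose(m.flattened(include_dc=True),
                                   cf.flattened(include_dc=True))

    def test_circles_radius_1_and_3_average_to_2(self):
        c1 = EFACoefficients(a=[1.0], b=[0.0], c=[0.0], d=[1.0])
        c3 = EFACoefficients(a=[3.0], b=[0.0], c=[0.0], d=[3.0])
        m = mean_shape([c1, c3])
        assert m.a[0] == pytest.approx(2.0) and m.d[0] == pytest.approx(2.0)

    def test_family_matches_elementwise_average(self, blob_coeffs):
        fam = [blob_coeffs(seed=s) for s in range(10)]
        m = mean_shape(fam)
        expected = np.mean([c.flattened(include_dc=True) for c in fam],
                           axis=0)
        np.testing.assert_allclose(m.flattened(include_dc=True), expected,
                                   atol=1e-12)

    def test_mixed_basis_rejected(self, blob_coeffs):
        with pytest.raises(MixedBasis):
            mean_shape([blob_coeffs(1, n_harmonics=8),
                        blob_coeffs(2, n_harmonics=6)])


class TestInvariants:
    def test_translation_moves_only_dc(self, blob_outline):
        blob = blob_outline(seed=7, n_points=200)
        cf = efa_forward(blob, 10)
        cf2 = efa_forward(blob.translated(3.0, -2.0), 10)
        np.testing.assert_allclose(cf2.flattened(), cf.flattened(),
                                   atol=1e-10)
        assert cf2.dc[0] - cf.dc[0] == pytest.approx(3.0, abs=1e-10)
        assert cf2.dc[1] - cf.dc[1] == pytest.approx(-2.0, abs=1e-10)

    def test_scaling_scales_all_harmonics(self, blob_outline):
        blob = blob_outline(seed=7, n_points=200)
        cf = efa_forward(blob, 10)
        cf2 = efa_forward(Outline(blob.points * 2.5), 10)
        np.testing.assert_allclose(cf2.flattened(), 2.5 * cf.flattened(),
                                   atol=1e-9)

    def test_harmonic_power_rotation_invariant(self, blob_coeffs):
        cf = blob_coeffs(seed=3)
        p1 = harmonic_power(cf).power
        p2 = harmonic_power(rotate_coefficients(cf, 1.1)).power
        np.testing.assert_allclose(p2, p1, atol=1e-12)


def test_coeffs_csv_roundtrip(tmp_path, blob_coeffs):
    fam = [blob_coeffs(seed=s, label=f"s{s}") for s in (1, 2, 3)]
    path = tmp_path / "coeffs.csv"
    write_coeffs_csv(fam, path)
    back = read_coeffs_csv(path)
    assert [c.label for c in back] == ["s1", "s2", "s3"]
    for orig, rec in zip(fam, back):
        np.testing.assert_allclose(rec.flattened(include_dc=True),
                                   orig.flattened(include_dc=True),
                                   rtol=1e-12)
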