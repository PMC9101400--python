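import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pollenraman import (
    PhantomSpec,
    PreprocessConfig,
    Spectrum,
    WavenumberAxis,
    area_normalize,
    builtin_templates,
    calibrate_axis,
    despike,
    interpolate_axis,
    preprocess,
    quality_filter,
    render_geometry,
    rubberband_baseline,
    sg_smooth,
    simulate_phantom,
    synthesize_image,
)
from pollenraman.core import window_trapz


def flat_image(image_factory, axis, n=4, value=1.0):
    return image_factory(axis, np.full((n, len(axis)), value), width=n,
                         height=1)


class TestCalibration:
    def test_identity_pairs_leave_axis_unchanged(self, toy_axis,
                                                 image_factory):
        img = flat_image(image_factory, toy_axis)
        pairs = [(500.0, 500.0), (1500.0, 1500.0), (2500.0, 2500.0)]
        out = calibrate_axis(img, pairs, degree=1)
        np.testing.assert_allclose(out.axis.values, toy_axis.values,
                                   atol=1e-9)

    def test_constant_offset_is_removed(self, toy_axis, image_factory):
        img = flat_image(image_factory, toy_axis)
        pairs = [(m + 3.0, m) for m in (500.0, 1200.0, 2000.0, 2800.0)]
        out = calibrate_axis(img, pairs, degree=1)
        np.testing.assert_allclose(out.axis.values, toy_axis.values - 3.0,
                                   atol=1e-9)
        fit = np.polyfit([p[0] for p in pairs], [p[1] for p in pairs], 1)
        for measured, ref in pairs:
            assert np.polyval(fit, measured) == pytest.approx(ref, abs=1e-9)

    def test_matches_normal_equations_oracle(self, toy_axis, image_factory):
        rng = np.random.default_rng(4)
        measured = np.sort(rng.uniform(500, 3000, 5))
        ref = measured * 1.002 - 1.5 + rng.normal(0, 0.3, 5)
        img = flat_image(image_factory, toy_axis)
        out = calibrate_axis(img, list(zip(measured, ref)), degree=1)
        # closed-form least squares via normal equations
        X = np.column_stack([measured, np.ones(5)])
        beta = np.linalg.solve(X.T @ X, X.T @ ref)
        np.testing.assert_allclose(
            out.axis.values, beta[0] * toy_axis.values + beta[1], rtol=1e-10)

    def test_too_few_pairs(self, toy_axis, image_factory):
        img = flat_image(image_factory, toy_axis)
        with pytest.raises(ValueError):
            calibrate_axis(img, [(500.0, 500.0), (600.0, 600.0)], degree=2)


class TestInterpolation:
    def test_identity(self, toy_axis, image_factory):
        img = flat_image(image_factory, toy_axis)
        out = interpolate_axis(img, toy_axis)
        np.testing.assert_array_equal(out.data, img.data)

    def test_linear_spectrum_exact(self, image_factory):
        src = WavenumberAxis(np.linspace(400, 3100, 55))
        img = image_factory(src, (2.0 * src.values + 7.0)[None, :])
        target = WavenumberAxis(np.linspace(450, 3000, 321))
        out = interpolate_axis(img, target)
        np.testing.assert_allclose(out.data[0], 2.0 * target.values + 7.0,
                                   rtol=1e-12)

    def test_matches_piecewise_linear_oracle(self, image_factory):
        rng = np.random.default_rng(8)
        src = WavenumberAxis(np.sort(rng.uniform(400, 3100, 40)))
        y = rng.standard_normal(40)
        img = image_factory(src, y[None, :])
        target = WavenumberAxis(np.sort(rng.uniform(src.values[0],
                                                    src.values[-1], 23)))
        out = interpolate_axis(img, target)
        for j, t in enumerate(target.values):
            i = np.searchsorted(src.values, t)
            if src.values[i] == t:
                expected = y[i]
            else:
                x0, x1 = src.values[i - 1], src.values[i]
                expected = y[i - 1] + (y[i] - y[i - 1]) * (t - x0) / (x1 - x0)
            assert out.data[0, j] == pytest.approx(expected, abs=1e-12)

    def test_extrapolation_rejected(self, toy_axis, image_factory):
        img = flat_image(image_factory, toy_axis)
        target = WavenumberAxis(np.linspace(300, 3100, 10))
        with pytest.raises(ValueError, match="extrapolation"):
            interpolate_axis(img, target)


def brute_force_lower_hull(x, y):
    """O(n²) oracle: i is a hull vertex iff no chord over it passes below."""
    n = len(x)
    verts = [0, n - 1]
    for i in range(1, n - 1):
        on_hull = True
        for a in range(n):
            for b in range(a + 1, n):
                if a < i < b:
                    chord = y[a] + (y[b] - y[a]) * (x[i] - x[a]) / (x[b] - x[a])
                    if chord < y[i] - 1e-12 * max(1.0, abs(y[i])):
                        on_hull = False
                        break
            if not on_hull:
                break
        if on_hull:
            verts.append(i)
    return np.sort(verts)


class TestRubberband:
    def test_linear_spectrum_fully_removed(self):
        ax = WavenumberAxis(np.linspace(400, 3100, 101))
        y = 0.5 * ax.values - 10.0
        base, corr = rubberband_baseline(Spectrum(ax, y))
        np.testing.assert_allclose(corr.intensities, 0.0, atol=1e-9)
        np.testing.assert_allclose(base.intensities, y, atol=1e-9)

    def test_flat_plus_peak(self):
        ax = WavenumberAxis(np.linspace(400, 3100, 301))
        peak = np.exp(-0.5 * ((ax.values - 1500) / 30) ** 2)
        y = 2.0 + peak
        base, corr = rubberband_baseline(Spectrum(ax, y))
        np.testing.assert_allclose(base.intensities, 2.0, atol=1e-12)
        np.testing.assert_allclose(corr.intensities, peak, atol=1e-12)

    def test_convex_quadratic_recovered_at_hull_vertices(self):
        rng = np.random.default_rng(12)
        ax = WavenumberAxis(np.linspace(400, 3100, 401))
        nu = ax.values
        quad = 1e-6 * (nu - 1700.0) ** 2 + 0.2
        peaks = np.zeros_like(nu)
        for c in rng.uniform(500, 3000, 6):
            peaks += np.clip(1 - np.abs(nu - c) / 40.0, 0, None)
        y = quad + peaks
        base, corr = rubberband_baseline(Spectrum(ax, y))
        verts = brute_force_lower_hull(nu, y)
        hull_is_quad = verts[peaks[verts] == 0]
        assert hull_is_quad.size > 10
        np.testing.assert_allclose(base.intensities[hull_is_quad],
                                   quad[hull_is_quad], rtol=1e-12)
        np.testing.assert_allclose(corr.intensities[verts], 0.0, atol=0.0)

    def test_matches_brute_force_hull_oracle(self):
        rng = np.random.default_rng(21)
        ax = WavenumberAxis(np.sort(rng.uniform(400, 3100, 60)))
        y = rng.standard_normal(60).cumsum()
        base, corr = rubberband_baseline(Spectrum(ax, y))
        verts = brute_force_lower_hull(ax.values, y)
        expected = np.interp(ax.values, ax.values[verts], y[verts])
        np.testing.assert_allclose(base.intensities,
                                   np.minimum(expected, y), atol=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_properties_hold_on_random_spectra(self, seed):
        """corrected >= 0, corrected + baseline == input exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        ax = WavenumberAxis(np.sort(rng.uniform(400, 3100, n)))
        y = rng.standard_normal(n) * rng.uniform(0.1, 10)
        base, corr = rubberband_baseline(Spectrum(ax, y))
        assert (corr.intensities >= 0).all()
        np.testing.assert_allclose(base.intensities + corr.intensities, y,
                                   rtol=0, atol=4 * np.finfo(float).eps *
                                   np.abs(y).max())

    def test_nonfinite_rejected(self):
        ax = WavenumberAxis(np.linspace(400, 500, 10))
        with pytest.raises(ValueError):
            rubberband_baseline((ax, np.r_[np.ones(9), np.nan]))


class TestDespike:
    def smooth_image(self, image_factory, n=3):
        ax = WavenumberAxis(np.linspace(400, 3100, 300))
        y = np.sin(ax.values / 200.0) + 2.0
        return image_factory(ax, np.tile(y, (n, 1)), width=n, height=1), ax

    def test_spike_free_spectrum_unchanged(self, image_factory):
        img, _ = self.smooth_image(image_factory)
        out, report = despike(img)
        assert report.n_spikes == 0
        np.testing.assert_array_equal(out.data, img.data)

    def test_single_spike_flagged_and_interpolated(self, image_factory):
        img, ax = self.smooth_image(image_factory)
        med = np.median(img.data[1])
        img.data[1, 150] += 50.0 * med
        out, report = despike(img)
        assert {(p, c) for p, c, _, _ in report.events} == {(1, 150)}
        lo, hi = sorted((out.data[1, 149], out.data[1, 151]))
        assert lo <= out.data[1, 150] <= hi
        # untouched channels and pixels are bit-identical
        np.testing.assert_array_equal(out.data[0], img.data[0])
        np.testing.assert_array_equal(np.delete(out.data[1], 150),
                                      np.delete(img.data[1], 150))

    def test_phantom_recall_and_precision(self):
        img, truth, _ = simulate_phantom(seed=2)
        _, report = despike(img)
        found = report.channels()
        true = set(map(tuple, truth.spikes))
        tp = len(found & true)
        assert tp / len(true) >= 0.95
        assert tp / len(found) >= 0.90

    def test_parameter_validation(self, image_factory):
        img, _ = self.smooth_image(image_factory)
        with pytest.raises(ValueError):
            despike(img, window=4)
        with pytest.raises(ValueError):
            despike(img, zmax=0.0)


class TestAreaNormalize:
    def test_constant_spectrum(self, image_factory):
        ax = WavenumberAxis(np.linspace(400.0, 3100.0, 1001))
        img = image_factory(ax, np.full((1, 1001), 7.3))
        out = area_normalize(img)
        np.testing.assert_allclose(out.data, 1.0 / 2700.0, rtol=1e-12)

    def test_idempotent_and_scale_invariant(self, default_phantom):
        img, _, _ = default_phantom
        once = area_normalize(img)
        twice = area_normalize(once)
        np.testing.assert_allclose(twice.data[twice.mask],
                                   once.data[once.mask], rtol=1e-12)
        scaled = img.copy_with(data=img.data * 17.3)
        np.testing.assert_allclose(area_normalize(scaled).data[once.mask],
                                   once.data[once.mask], rtol=1e-12)

    def test_unit_area_by_independent_quadrature(self, default_phantom):
        img, _, _ = default_phantom
        out = area_normalize(img)
        nu = out.axis.values
        sel = (nu >= 400) & (nu <= 3100)
        for row in out.data[out.mask][::97]:
            # plain summed-trapezoid oracle
            x, y = nu[sel], row[sel]
            area = float(np.sum((y[1:] + y[:-1]) * np.diff(x)) / 2.0)
            assert area == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_pixels_masked(self, image_factory):
        ax = WavenumberAxis(np.linspace(400.0, 3100.0, 101))
        data = np.vstack([np.ones(101), np.zeros(101)])
        img = image_factory(ax, data, width=2, height=1)
        out = area_normalize(img)
        assert out.mask.tolist() == [True, False]


class TestQualityFilter:
    def test_zero_pixel_removed_others_retained(self, image_factory):
        ax = WavenumberAxis(np.linspace(400.0, 3100.0, 500))
        spec = np.exp(-0.5 * ((ax.values - 2900) / 60) ** 2) + \
            0.3 * np.sin(ax.values / 150) + 0.4
        data = np.tile(spec, (9, 1))
        data[4] = 0.0
        img = image_factory(ax, data, width=3, height=3)
        out = quality_filter(img, threshold=0.75)
        assert not out.mask[4]
        assert out.mask.sum() == 8

    def test_phantom_accuracy_against_truth(self, default_phantom):
        img, truth, _ = default_phantom
        pre = preprocess(img)
        foreground = truth.labels != 0
        assert (pre.mask == foreground).mean() >= 0.95

    def test_monotone_in_threshold(self, default_phantom):
        img, _, _ = default_phantom
        cfg = PreprocessConfig(stages=("interpolate", "rubberband",
                                       "normalize"))
        base = preprocess(img, cfg)
        loose = quality_filter(base, threshold=0.75)
        try:
            n_strict = int(quality_filter(base, threshold=0.999).mask.sum())
        except ValueError:
            n_strict = 0  # every candidate failed the stricter correlation
        assert n_strict < loose.mask.sum()

    def test_all_substrate_image_has_no_foreground(self):
        spec = PhantomSpec(grain_radius=0.0, protrusion_amplitude=0.0)
        comps = builtin_templates()
        truth = render_geometry(spec, comps)
        img, _ = synthesize_image(truth, comps, spec)
        # QC sits after baseline removal and normalization in the chain
        base = preprocess(img, PreprocessConfig(
            stages=("rubberband", "despike", "normalize")))
        with pytest.raises(ValueError, match="no foreground"):
            quality_filter(base)


class TestSavitzkyGolay:
    def test_quadratic_preserved(self, image_factory):
        ax = WavenumberAxis(np.linspace(400, 3100, 200))
        y = 3.0 + 0.002 * ax.values + 1e-6 * ax.values ** 2
        img = image_factory(ax, y[None, :])
        out = sg_smooth(img, window=9, order=2)
        np.testing.assert_allclose(out.data[0][4:-4], y[4:-4], rtol=1e-9)

    def test_constant_unchanged(self, image_factory):
        ax = WavenumberAxis(np.linspace(400, 3100, 50))
        img = image_factory(ax, np.full((1, 50), 5.0))
        out = sg_smooth(img)
        np.testing.assert_allclose(out.data, 5.0, rtol=1e-12)

    def test_white_noise_variance_reduction(self, image_factory):
        from scipy.signal import savgol_coeffs
        rng = np.random.default_rng(6)
        n = 10_000
        ax = WavenumberAxis(np.arange(float(n)))
        noise = rng.standard_normal(n)
        img = image_factory(ax, noise[None, :])
        out = sg_smooth(img, window=9, order=2)
        h = savgol_coeffs(9, 2)
        ratio = out.data[0][4:-4].var() / noise.var()
        assert ratio == pytest.approx(float(np.sum(h ** 2)), rel=0.05)

    def test_window_longer_than_spectrum_rejected(self, image_factory):
        ax = WavenumberAxis(np.linspace(400, 500, 7))
        img = image_factory(ax, np.ones((1, 7)))
        with pytest.raises(ValueError):
            sg_smooth(img, window=9)


class TestFullChain:
    def test_all_stages_disabled_is_identity(self, default_phantom):
        img, _, _ = default_phantom
        out = preprocess(img, PreprocessConfig(stages=()))
        np.testing.assert_array_equal(out.data, img.data)
        assert (out.mask == img.mask).all()

    def test_history_records_every_stage(self, default_phantom):
        img, _, _ = default_phantom
        before = len(img.history)
        out = preprocess(img)
        ops = [h["op"] for h in out.history[before:]]
        assert ops == ["interpolate_axis", "rubberband", "despike",
                       "area_normalize", "quality_filter", "sg_smooth",
                       "area_normalize"]

    def test_final_output_unit_area_and_nonnegative_corrected(
            self, default_phantom):
        img, _, _ = default_phantom
        out = preprocess(img)
        areas = window_trapz(out.axis, out.data[out.mask], 400.0, 3100.0)
        np.testing.assert_allclose(areas, 1.0, atol=1e-9)

    def test_chain_is_deterministic(self, default_phantom):
        img, _, _ = default_phantom
        a = preprocess(img)
        b = preprocess(img)
        np.testing.assert_array_equal(a.data, b.data)
        assert (a.mask == b.mask).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sg_window=8)
        with pytest.raises(ValueError):
            PreprocessConfig(sg_order=9, sg_window=9)
        with pytest.raises(ValueError):
            PreprocessConfig(qc_threshold=1.5)
        with pytest.raises(ValueError):
            PreprocessConfig(stages=("interpolate", "mystery"))
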