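import numpy as np
import pandas as pd
import pytest

from congression import (
    SyntheticSpec,
    ValidationError,
    correlate_capture_with_disassembly,
    make_image_stack,
    make_intensity_traces,
    normalize_trace,
    patch_timing,
    quantify_stack,
    spherical_intensity,
)


def _count_voxels_in_sphere(radius, voxel):
    r = int(np.ceil(radius / voxel)) + 1
    g = (np.arange(-r, r + 1) + 0.0) * voxel
    gz, gy, gx = np.meshgrid(g, g, g, indexing="ij")
    return int(np.count_nonzero(gz**2 + gy**2 + gx**2 <= radius**2))


class TestSphericalIntensity:
    def test_uniform_image(self):
        frame = np.full((24, 24, 24), 3.0)
        center = (12.0, 12.0, 12.0)  # x, y, z in µm at voxel size 1
        res = spherical_intensity(frame, center, radius_um=2.5, voxel_size_um=1.0)
        assert res.total == pytest.approx(3.0 * res.n_voxels)
        assert res.coverage == 1.0
        # voxel centers at (i+0.5): center on a voxel corner
        expected_n = _count_voxels_in_sphere(2.5, 1.0)
        # shifted grid: count voxel centers at (i+0.5)-12 within 2.5
        g = np.arange(24) + 0.5 - 12.0
        gz, gy, gx = np.meshgrid(g, g, g, indexing="ij")
        assert res.n_voxels == np.count_nonzero(gz**2 + gy**2 + gx**2 <= 2.5**2)

    def test_gaussian_blob_mass_recovery(self):
        """A tight Gaussian centered in the ROI contributes >= 95% of its
        integrated intensity."""
        voxel = 0.5
        shape = (32, 32, 32)
        sigma = 0.7
        coords = (np.arange(32) + 0.5) * voxel
        cz = cy = cx = 8.0
        gz, gy, gx = np.meshgrid(coords - cz, coords - cy, coords - cx, indexing="ij")
        blob = np.exp(-(gz**2 + gy**2 + gx**2) / (2 * sigma**2))
        integral = blob.sum()
        res = spherical_intensity(blob, (cx, cy, cz), radius_um=2.5, voxel_size_um=voxel)
        assert res.total >= 0.95 * integral

    def test_poisson_background_statistics(self):
        lam = 20.0
        rng = np.random.default_rng(0)
        frame = rng.poisson(lam, size=(30, 30, 30)).astype(float)
        res = spherical_intensity(frame, (15.0, 15.0, 15.0), 2.5, 1.0)
        se = np.sqrt(lam * res.n_voxels)
        assert abs(res.total - lam * res.n_voxels) <= 3.0 * se

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        pattern = rng.random((9, 9, 9))
        big = np.zeros((40, 40, 40))
        res = []
        for offset in ((4, 6, 8), (20, 14, 25)):
            img = big.copy()
            img[offset[0] : offset[0] + 9, offset[1] : offset[1] + 9, offset[2] : offset[2] + 9] = pattern
            center = (offset[2] + 4.5, offset[1] + 4.5, offset[0] + 4.5)
            res.append(spherical_intensity(img, center, 3.5, 1.0))
        assert res[0].total == pytest.approx(res[1].total)
        assert res[0].n_voxels == res[1].n_voxels

    def test_partial_coverage_reported(self):
        frame = np.ones((20, 20, 20))
        res = spherical_intensity(frame, (0.5, 10.0, 10.0), 2.5, 1.0)  # near the x edge
        assert 0.0 < res.coverage < 1.0

    def test_sphere_outside_image_is_an_error(self):
        frame = np.ones((10, 10, 10))
        with pytest.raises(ValidationError, match="outside"):
            spherical_intensity(frame, (50.0, 50.0, 50.0), 2.5, 1.0)

    def test_radius_below_voxel_size_rejected(self):
        with pytest.raises(ValidationError, match="radius"):
            spherical_intensity(np.ones((10, 10, 10)), (5, 5, 5), 0.5, 1.0)


class TestNormalizeTrace:
    def test_constant_trace_normalizes_to_one(self):
        t = np.arange(-2.0, 10.0, 0.05)
        tr = normalize_trace(t, np.full_like(t, 123.0))
        assert np.allclose(tr.normalized, 1.0)
        assert tr.background == pytest.approx(123.0)

    def test_doubling_after_nebd(self):
        t = np.arange(-2.0, 10.0, 0.05)
        raw = np.where(t < 0, 50.0, 100.0)
        tr = normalize_trace(t, raw)
        assert tr.normalized[t >= 0][0] == pytest.approx(2.0)

    def test_scale_invariance(self):
        t = np.arange(-2.0, 10.0, 0.05)
        rng = np.random.default_rng(2)
        raw = 100.0 + 50.0 * rng.random(len(t))
        a = normalize_trace(t, raw).normalized
        b = normalize_trace(t, raw * 37.0).normalized
        assert np.allclose(a, b)

    def test_missing_pre_nebd_samples_demand_explicit_background(self):
        t = np.arange(0.0, 10.0, 0.05)
        with pytest.raises(ValidationError, match="background"):
            normalize_trace(t, np.ones_like(t))
        tr = normalize_trace(t, np.ones_like(t) * 4.0, background=2.0)
        assert np.allclose(tr.normalized, 2.0)


class TestPatchTiming:
    def test_flat_trace_has_no_patch(self):
        t = np.arange(-2.0, 12.0, 0.05)
        tr = normalize_trace(t, np.full_like(t, 10.0))
        timing = patch_timing(tr)
        assert timing.onset_min is None
        assert timing.peak_min is None
        assert timing.disassembly_min is None

    def test_noiseless_template_recovered_on_the_grid(self):
        spec = SyntheticSpec.control(seed=0, trace_noise=0.0, n_traces=5)
        traces, truth = make_intensity_traces(spec)
        for i, g in traces.groupby("trace"):
            tr = normalize_trace(g.t_min.to_numpy(), g.raw.to_numpy())
            timing = patch_timing(tr)
            assert timing.onset_min == pytest.approx(1.5, abs=0.15)
            assert timing.peak_min == pytest.approx(5.0, abs=0.3)
            assert timing.disassembly_min == pytest.approx(8.0, abs=0.15)

    def test_noisy_control_recovery(self):
        traces, _ = make_intensity_traces(SyntheticSpec.control(seed=7))
        rec = []
        for _, g in traces.groupby("trace"):
            timing = patch_timing(normalize_trace(g.t_min.to_numpy(), g.raw.to_numpy()))
            rec.append((timing.onset_min, timing.peak_min, timing.disassembly_min))
        rec = np.array(rec, dtype=float)
        onset, peak, ret = np.nanmean(rec, axis=0)
        assert 1.0 <= onset <= 2.0          # assembly within 1-2 min of NEBD
        assert peak == pytest.approx(5.0, abs=0.5)
        assert ret == pytest.approx(8.0, abs=0.5)

    def test_latrunculin_premature_disassembly(self):
        traces, _ = make_intensity_traces(SyntheticSpec.latrunculin(seed=7))
        rets = []
        for _, g in traces.groupby("trace"):
            timing = patch_timing(normalize_trace(g.t_min.to_numpy(), g.raw.to_numpy()))
            rets.append(timing.disassembly_min)
        assert np.nanmean(np.array(rets, dtype=float)) == pytest.approx(4.0, abs=0.5)

    def test_timing_independent_of_amplitude(self):
        """Timings must not move when patch amplitudes vary tenfold."""
        small = SyntheticSpec.control(seed=3, trace_noise=0.0, n_traces=10, amplitude_range=(1.5, 1.6))
        large = small.with_(amplitude_range=(15.0, 16.0))
        out = []
        for spec in (small, large):
            traces, _ = make_intensity_traces(spec)
            rec = []
            for _, g in traces.groupby("trace"):
                timing = patch_timing(normalize_trace(g.t_min.to_numpy(), g.raw.to_numpy()))
                rec.append((timing.onset_min, timing.peak_min, timing.disassembly_min))
            out.append(np.array(rec, dtype=float).mean(axis=0))
        assert np.allclose(out[0], out[1], atol=0.3)


class TestCorrelation:
    def test_identical_times_give_zero_lags(self):
        times = {0: 8.0, 1: 9.5, 2: 10.0}
        df, summary = correlate_capture_with_disassembly(times, dict(times))
        assert np.allclose(df["lag_min"], 0.0)
        assert summary.mean_min == pytest.approx(0.0)
        assert summary.unmatched == []

    def test_shifted_cohort_recovers_mean_lag(self):
        rng = np.random.default_rng(4)
        dis = {i: float(7.5 + rng.normal(0, 0.3)) for i in range(200)}
        cap = {i: dis[i] + float(rng.normal(1.0, 0.5)) for i in range(200)}
        _, summary = correlate_capture_with_disassembly(cap, dis)
        assert summary.mean_min == pytest.approx(1.0, abs=0.15)

    def test_unmatched_ids_reported_not_fatal(self):
        df, summary = correlate_capture_with_disassembly({0: 8.0, 1: 9.0}, {1: 4.0, 2: 5.0})
        assert summary.unmatched == [0, 2]
        assert len(df) == 1


class TestStackQuantification:
    def test_end_to_end_timing_recovery(self):
        spec = SyntheticSpec.control(seed=5)
        stack, positions, truth = make_image_stack(
            spec, shape_zyx=(40, 40, 40), voxel_size_um=0.5,
            n_frames=80, frame_interval_s=12.0, n_chromosomes=2,
        )
        traces = quantify_stack(stack, positions, radius_um=2.5, voxel_size_um=0.5, channel=1)
        for c, g in traces.groupby("chromosome"):
            tr = normalize_trace(g.t_min.to_numpy(), g.raw.to_numpy())
            timing = patch_timing(tr)
            assert timing.peak_min == pytest.approx(5.0, abs=0.5)
            assert timing.disassembly_min == pytest.approx(8.0, abs=0.5)

    def test_multichannel_requires_channel(self):
        stack = np.zeros((2, 2, 8, 8, 8))
        pos = pd.DataFrame({"chromosome": [0], "frame": [0], "t_min": [0.0],
                            "x_um": [4.0], "y_um": [4.0], "z_um": [4.0]})
        with pytest.raises(ValidationError, match="channel"):
            quantify_stack(stack, pos, radius_um=2.5, voxel_size_um=1.0)

    def test_noise_free_intensity_recovery(self):
        """ROI sum over the patch channel reproduces the injected template
        value after background normalization, within 5%."""
        spec = SyntheticSpec.control(seed=9, amplitude_range=(4.0, 4.0))
        stack, positions, _ = make_image_stack(
            spec, shape_zyx=(36, 36, 36), voxel_size_um=0.5,
            n_frames=40, frame_interval_s=24.0, n_chromosomes=1, noise=False,
        )
        traces = quantify_stack(stack, positions, radius_um=2.5, voxel_size_um=0.5, channel=1)
        tr = normalize_trace(traces.t_min.to_numpy(), traces.raw.to_numpy())
        # pre-onset frames at background (small wobble from the moving
        # sphere re-sampling the voxel grid)
        pre = tr.normalized[tr.times_min < 0.5]
        assert np.allclose(pre, 1.0, atol=0.02)
        # peak close to the injected 4x amplitude
        assert tr.normalized.max() == pytest.approx(4.0, rel=0.05)
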