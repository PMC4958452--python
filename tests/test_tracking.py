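import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import stenosim as st
from stenosim.errors import ConfigurationError
from stenosim.tracking import DisplacementTrace, error_table


def _speckle_patch(shape, rng):
    """Multiplicative (exponential) speckle on a unit background."""
    return rng.exponential(1.0, shape)


class TestSRAD:
    def test_constant_image_unchanged(self):
        img = np.full((40, 50), 3.3)
        out = st.srad(img, n_iter=20)
        np.testing.assert_allclose(out, img, rtol=1e-12)

    def test_speckle_cv_strictly_decreases(self):
        rng = np.random.default_rng(1)
        img = _speckle_patch((60, 60), rng)
        region = (15, 45, 15, 45)
        cv = []
        out = img
        for _ in range(5):
            out = st.srad(out, n_iter=10, rect_homogeneous_region=region)
            patch = out[15:45, 15:45]
            cv.append(patch.var() / patch.mean() ** 2)
        assert all(b < a for a, b in zip(cv, cv[1:]))

    def test_edge_preserved_vs_gaussian_blur(self):
        rng = np.random.default_rng(2)
        img = np.ones((50, 80))
        img[:, 40:] = 6.0
        img *= _speckle_patch(img.shape, rng) * 0.25 + 0.75
        region = (10, 40, 5, 30)
        srad_out = st.srad(img, n_iter=60, rect_homogeneous_region=region)
        var_target = srad_out[10:40, 5:30].var()
        # find the gaussian blur that reaches the same flat-region variance
        sigma = 0.5
        while gaussian_filter(img, sigma)[10:40, 5:30].var() > var_target and sigma < 20:
            sigma *= 1.3
        blur = gaussian_filter(img, sigma)
        slope_srad = np.abs(np.diff(srad_out, axis=1))[:, 35:45].max()
        slope_blur = np.abs(np.diff(blur, axis=1))[:, 35:45].max()
        assert slope_srad >= slope_blur

    def test_rejects_bad_input(self):
        with pytest.raises(ConfigurationError):
            st.srad(np.ones(10))  # not 2-D


class TestExtractWall:
    def _band_image(self, centers, depth, width=0.4e-3, amp=10.0, noise=None):
        img = np.full((depth.size, len(centers)), 0.05)
        for j, c in enumerate(centers):
            img[:, j] += amp * np.exp(-0.5 * ((depth - c) / width) ** 2)
        if noise is not None:
            img *= noise
        return img

    def test_sinusoidal_band_recovered(self):
        depth = np.linspace(3e-2, 4e-2, 300)
        t = np.linspace(0, 1, 128)
        z0 = 3.5e-2
        motion = 0.5e-3 * np.sin(2 * np.pi * 3 * t)
        img = self._band_image(z0 + motion, depth)
        tr = st.extract_wall(img, depth, t, lumen_depth=3.9e-2, side="near",
                             angle_deg=45.0, axis_depth=4.3e-2)
        spec = np.abs(np.fft.rfft(tr.displacement))
        assert spec.argmax() == 3
        # amplitude preserved through the 45-degree mapping
        expect = 0.5e-3 * np.sin(np.deg2rad(45.0))
        assert np.ptp(tr.position) == pytest.approx(2 * expect, rel=0.05)

    def test_threshold_invariance_on_clean_step(self):
        depth = np.linspace(3e-2, 4e-2, 500)
        t = np.arange(4.0)
        img = np.where((depth[:, None] > 3.4e-2) & (depth[:, None] < 3.6e-2), 1.0, 1e-4)
        img = np.broadcast_to(img, (depth.size, 4)).copy()
        results = [
            st.extract_wall(img, depth, t, lumen_depth=3.8e-2, side="near",
                            threshold_fraction=f, axis_depth=4.2e-2).position
            for f in (0.25, 0.5, 0.75)
        ]
        step = (depth[1] - depth[0]) * np.sin(np.deg2rad(45))
        assert np.ptp([r[0] for r in results]) <= step

    def test_stationary_band_zero_variance(self):
        depth = np.linspace(3e-2, 4e-2, 200)
        t = np.linspace(0, 1, 16)
        img = self._band_image(np.full(16, 3.5e-2), depth)
        tr = st.extract_wall(img, depth, t, lumen_depth=3.9e-2, axis_depth=4.3e-2)
        assert np.ptp(tr.position) < 1e-12

    def test_band_centroid_ignores_lumen_lobe(self):
        depth = np.linspace(3e-2, 4e-2, 300)
        t = np.arange(2.0)
        img = self._band_image([3.45e-2, 3.45e-2], depth)
        img[260:266, :] += 8.0  # bright isolated speckle lobe in the lumen
        tr = st.extract_wall(img, depth, t, lumen_depth=3.9e-2, side="near",
                             axis_depth=4.3e-2, method="band_centroid")
        r_expected = (4.3e-2 - 3.45e-2) * np.sin(np.deg2rad(45))
        np.testing.assert_allclose(tr.position, r_expected, atol=0.1e-3)

    def test_bad_arguments(self):
        depth = np.linspace(3e-2, 4e-2, 50)
        img = np.ones((50, 3))
        with pytest.raises(ConfigurationError):
            st.extract_wall(img, depth, np.arange(3.0), 3.5e-2, threshold_fraction=1.5)
        with pytest.raises(ConfigurationError):
            st.extract_wall(img, depth, np.arange(3.0), 3.5e-2, side="left")


class TestDisplacementErrors:
    def _trace(self, pos, t=None):
        t = np.linspace(0, 1, len(pos)) if t is None else t
        return DisplacementTrace(t, np.asarray(pos))

    def test_identical_traces(self):
        ref = self._trace(np.sin(np.linspace(0, 6, 50)))
        rep = st.displacement_errors(ref, ref)
        assert rep.mean_relative_error == 0.0
        assert rep.max_relative_error == 0.0

    def test_constant_offset_is_five_percent(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 100))
        ref = self._trace(base)
        est = self._trace(base + 0.05 * np.ptp(base))
        rep = st.displacement_errors(est, ref)
        assert rep.mean_relative_error == pytest.approx(5.0)
        assert rep.max_relative_error == pytest.approx(5.0)

    def test_rescaling_both_traces_is_invariant(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 64))
        est = base + 0.02 * np.cos(np.linspace(0, 4 * np.pi, 64))
        r1 = st.displacement_errors(self._trace(est), self._trace(base))
        r2 = st.displacement_errors(self._trace(7 * est), self._trace(7 * base))
        assert r1.mean_relative_error == pytest.approx(r2.mean_relative_error)
        assert r1.max_relative_error == pytest.approx(r2.max_relative_error)

    def test_zero_reference_span_rejected(self):
        flat = self._trace(np.zeros(10))
        with pytest.raises(ConfigurationError):
            st.displacement_errors(flat, flat)

    def test_averaging_reduces_spread(self):
        rng = np.random.default_rng(3)
        base = 1e-4 * np.sin(np.linspace(0, 2 * np.pi, 80))
        ref = self._trace(base)
        singles, avgs = [], []
        for _ in range(30):
            batch = base + 2e-5 * rng.standard_normal((10, 80))
            singles.append(
                st.displacement_errors(self._trace(batch[0]), ref).mean_relative_error
            )
            avgs.append(
                st.displacement_errors(self._trace(batch.mean(axis=0)), ref).mean_relative_error
            )
        assert np.std(avgs) < np.std(singles)
        assert np.mean(avgs) < np.mean(singles)

    def test_error_table_layout(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 50))
        rep = st.displacement_errors(
            self._trace(base + 0.01), self._trace(base)
        )
        tab = error_table({(15.0, 0.0): rep, (25.0, 1.5): rep})
        assert tab.shape == (4, 2)
        assert "1.5*omega0" in tab.columns
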