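"""Two-channel preprocessing: deinterleave, ΔF/F, correction, parcellation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cortexscope.synth as sy
from cortexscope.preprocess import (
    REFERENCE_TAG,
    SIGNAL_TAG,
    DialectError,
    RegionTraces,
    TwoChannelMovie,
    compute_dff,
    deinterleave,
    downsample,
    hemodynamic_correct,
    parcellate,
    preprocess_movie,
    smooth_reference,
)


def interleaved_movie(n_pairs, h=4, w=4, extra=0, rng=None):
    rng = rng or np.random.default_rng(0)
    frames = rng.uniform(50, 150, size=(2 * n_pairs + extra, h, w))
    tags = np.array([SIGNAL_TAG, REFERENCE_TAG] * n_pairs + [SIGNAL_TAG] * extra)
    return TwoChannelMovie(frames=frames, channel_tags=tags, fps_per_channel=11.7)


class TestDeinterleave:
    def test_even_split(self):
        movie = interleaved_movie(5)
        sig, ref = deinterleave(movie)
        assert sig.shape[0] == ref.shape[0] == 5
        assert np.array_equal(sig, movie.frames[0::2])

    def test_odd_tail_is_trimmed(self):
        movie = interleaved_movie(5, extra=1)
        sig, ref = deinterleave(movie)
        assert sig.shape[0] == ref.shape[0] == 5

    def test_non_alternating_tags_raise_with_frame_index(self):
        movie = interleaved_movie(4)
        movie.channel_tags[3] = movie.channel_tags[2]
        with pytest.raises(DialectError, match="frame 3"):
            deinterleave(movie)

    def test_roundtrip_with_renderer(self, short_cfg, atlas_small, saline_session):
        traces, _ = saline_session
        movie, _ = sy.render_movie(traces, atlas_small, short_cfg, 9)
        sig, ref = deinterleave(movie)
        assert np.array_equal(sig, movie.frames[0::2])
        assert np.array_equal(ref, movie.frames[1::2])


class TestDownsample:
    def test_constant_image_unchanged(self):
        x = np.full((3, 8, 8), 7.0)
        assert np.allclose(downsample(x, 4), 7.0)

    def test_block_mean_arithmetic(self):
        x = np.array([[1.0, 3.0], [5.0, 7.0]])
        assert downsample(x, 2) == pytest.approx(4.0)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(2, 512, 512))
        got = downsample(x, 4)
        for t in range(2):
            for i in range(0, 512, 128):  # spot-check a grid of blocks
                for j in range(0, 512, 128):
                    bi, bj = i // 4, j // 4
                    assert got[t, bi, bj] == pytest.approx(x[t, i : i + 4, j : j + 4].mean())

    def test_non_divisible_dimensions_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.zeros((2, 10, 10)), 4)


class TestComputeDff:
    def test_constant_pixel_gives_zero(self):
        x = np.full((10, 2, 2), 5.0)
        dff, ok = compute_dff(x)
        assert np.allclose(dff, 0.0)
        assert ok.all()

    def test_median_normalization(self):
        x = np.array([1.0, 1.0, 1.0, 3.0]).reshape(4, 1, 1)
        dff, _ = compute_dff(x)
        assert np.allclose(dff.ravel(), [0, 0, 0, 2])

    def test_matches_elementwise_oracle(self, rng):
        x = rng.uniform(1, 10, size=(50, 6, 6))
        dff, _ = compute_dff(x)
        med = np.median(x, axis=0)
        assert np.allclose(dff, (x - med) / med)

    def test_nonpositive_median_pixels_flagged(self):
        x = np.zeros((5, 1, 2))
        x[:, 0, 0] = 1.0
        dff, ok = compute_dff(x)
        assert ok[0, 0] and not ok[0, 1]
        assert np.all(dff[:, 0, 1] == 0)

    @given(gain=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_multiplicative_gain(self, gain):
        rng = np.random.default_rng(7)
        x = rng.uniform(1, 5, size=(30, 3, 3))
        base, _ = compute_dff(x)
        scaled, _ = compute_dff(gain * x)
        assert np.allclose(base, scaled, atol=1e-10)


class TestSmoothReference:
    def test_constant_trace_unchanged(self):
        x = np.full(50, 3.3)
        assert np.allclose(smooth_reference(x, 0.4, 11.7), 3.3)

    def test_impulse_spreads_over_window(self):
        x = np.zeros(21)
        x[10] = 1.0
        out = smooth_reference(x, window_s=5 / 11.7, fps=11.7)  # w = 5
        assert np.allclose(out[8:13], 0.2)
        assert out[7] == 0 and out[13] == 0

    def test_matches_sliding_window_oracle(self, rng):
        x = rng.normal(size=200)
        w = 5
        out = smooth_reference(x, window_s=w / 11.7, fps=11.7)
        for i in range(len(x)):
            lo, hi = max(0, i - 2), min(len(x), i + 3)
            assert out[i] == pytest.approx(x[lo:hi].mean())

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            smooth_reference(np.zeros(5), window_s=0.0)


class TestHemodynamicCorrect:
    def test_signal_equal_to_reference_cancels(self, rng):
        x = rng.normal(size=100)
        corrected, alpha, beta = hemodynamic_correct(x, x)
        assert np.allclose(corrected, 0.0, atol=1e-12)
        assert beta == pytest.approx(1.0)

    def test_independent_reference_leaves_signal(self, rng):
        sig = rng.normal(size=20_000)
        ref = rng.normal(size=20_000)
        corrected, _, beta = hemodynamic_correct(sig, ref)
        assert abs(beta) < 0.03
        assert np.allclose(corrected, sig - sig.mean(), atol=0.1)

    def test_constant_reference_warns_and_demeans(self, rng):
        sig = rng.normal(size=100)
        with pytest.warns(UserWarning):
            corrected, _, beta = hemodynamic_correct(sig, np.ones(100))
        assert beta == pytest.approx(0.0)
        assert np.allclose(corrected, sig - sig.mean())

    def test_planted_artifact_is_removed(self, rng):
        # pixel with artifact gains (2, 1) for (signal, reference)
        n = 7000
        neural = rng.normal(size=n)
        artifact = np.convolve(rng.normal(size=n), np.ones(50) / 50, mode="same")
        sig = neural + 2.0 * artifact
        ref = 1.0 * artifact + 0.05 * rng.normal(size=n)
        corrected, _, _ = hemodynamic_correct(sig, smooth_reference(ref, 0.4, 11.7))
        assert abs(np.corrcoef(corrected, artifact)[0, 1]) < 0.1
        assert np.corrcoef(corrected, neural)[0, 1] > 0.9


class TestParcellate:
    def test_uniform_frame_gives_uniform_traces(self, atlas_small):
        stack = np.full((3,) + atlas_small.label_image.shape, 4.2)
        traces = parcellate(stack, atlas_small, fps=11.7)
        assert traces.values.shape[0] == 12
        assert np.allclose(traces.values, 4.2)

    def test_region_average_is_unweighted_over_subdivisions(self, atlas_small):
        # give one L_F subdivision value 1 and the other three value 3:
        # pixel-weighted and unweighted differ unless subdivision areas match
        stack = np.zeros((1,) + atlas_small.label_image.shape)
        labels = atlas_small.labels_for_region("L_F")
        for k, lbl in enumerate(labels):
            stack[0][atlas_small.label_image == lbl] = 1.0 if k == 0 else 3.0
        traces = parcellate(stack, atlas_small, fps=11.7)
        i = traces.region_names.index("L_F")
        expected = (1.0 + 3.0 * (len(labels) - 1)) / len(labels)
        assert traces.values[i, 0] == pytest.approx(expected)

    def test_region_without_valid_pixels_is_an_error(self, atlas_small):
        stack = np.ones((2,) + atlas_small.label_image.shape)
        mask = np.ones(atlas_small.label_image.shape, dtype=bool)
        for lbl in atlas_small.labels_for_region("R_V"):
            mask[atlas_small.label_image == lbl] = False
        with pytest.raises(ValueError, match="R_V"):
            parcellate(stack, atlas_small, fps=11.7, valid_mask=mask)


class TestFullPipeline:
    def test_noise_free_roundtrip_is_exact(self, atlas_small):
        cfg = sy.SynthConfig(
            session_s=10.0, movie_shape=(68, 20), noise_sd_px=0.0,
            artifact=sy.ArtifactConfig(amplitude=0.0),
        )
        traces, _ = sy.generate_region_traces(cfg, "saline", 3)
        movie, _ = sy.render_movie(traces, atlas_small, cfg, 4)
        recovered = preprocess_movie(movie, atlas_small, hemo_correct=False)
        x = traces.values
        med = np.median(x, axis=1, keepdims=True)
        expected = cfg.dff_scale * (x - med) / (1 + cfg.dff_scale * med)
        rmse = np.sqrt(np.mean((recovered.values - expected) ** 2))
        assert rmse < 1e-6

    def test_correction_order_invariance_on_homogeneous_regions(self, atlas_small):
        # with region-constant pixels, pixelwise correction then parcellation
        # equals parcellation then trace-mode correction
        cfg = sy.SynthConfig(
            session_s=20.0, movie_shape=(68, 20), noise_sd_px=0.0,
            artifact=sy.ArtifactConfig(amplitude=0.05, gain_signal=2.0, gain_reference=1.0),
        )
        traces, _ = sy.generate_region_traces(cfg, "saline", 6)
        movie, _ = sy.render_movie(traces, atlas_small, cfg, 7)
        pixel_first = preprocess_movie(movie, atlas_small, hemo_correct=True)

        sig, ref = deinterleave(movie)
        sig_dff, ok_s = compute_dff(sig)
        ref_dff, ok_r = compute_dff(ref)
        sig_regions = parcellate(sig_dff, atlas_small, fps=11.7, valid_mask=ok_s & ok_r)
        ref_regions = parcellate(ref_dff, atlas_small, fps=11.7, valid_mask=ok_s & ok_r)
        trace_first = np.empty_like(sig_regions.values)
        for i in range(12):
            smoothed = smooth_reference(ref_regions.values[i], 0.4, 11.7)
            trace_first[i], _, _ = hemodynamic_correct(sig_regions.values[i], smoothed)
        assert np.allclose(pixel_first.values, trace_first, atol=1e-6)

    def test_traces_csv_roundtrip(self, tmp_path, saline_session):
        traces, _ = saline_session
        path = tmp_path / "traces.csv"
        traces.to_csv(path)
        back = RegionTraces.from_csv(path)
        assert back.region_names == traces.region_names
        assert back.fps == traces.fps
        assert np.allclose(back.values, traces.values)

    def test_movie_io_roundtrip(self, tmp_path, short_cfg, atlas_small, saline_session):
        cfg = sy.SynthConfig(session_s=5.0, movie_shape=(68, 20))
        traces, _ = sy.generate_region_traces(cfg, "saline", 8)
        movie, _ = sy.render_movie(traces, atlas_small, cfg, 8)
        for name in ["m.tif", "m.h5"]:
            movie.save(tmp_path / name, meta={"seed": 8})
            back = TwoChannelMovie.load(tmp_path / name)
            assert np.allclose(back.frames, movie.frames)
            assert list(back.channel_tags) == list(movie.channel_tags)
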