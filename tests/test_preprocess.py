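"""Filtering, band splitting, segmentation, interpolation, artifact removal."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import duformer as df
from duformer.montage import CHANNELS
from duformer.preprocess import (
    PipelineConfig,
    bandpass_filter,
    interpolate_bad_channels,
    preprocess_pipeline,
    remove_ocular_artifacts,
    segment,
    split_bands,
    suppress_myogenic_artifacts,
)
from duformer.recording import RawRecording
from duformer.synth import SynthConfig, generate_recording, inject_artifacts


def tone_recording(freqs_amps, fs=1000.0, duration=10.0, n_channels=2):
    t = np.arange(int(duration * fs)) / fs
    sig = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    data = np.tile(sig, (n_channels, 1))
    names = tuple(f"CH{i}" for i in range(n_channels))
    return RawRecording(data, names, fs, "S01", "pre")


def mid_rms(x: np.ndarray) -> float:
    n = x.shape[-1]
    return float(np.sqrt((x[..., n // 4: 3 * n // 4] ** 2).mean()))


class TestBandpassFilter:
    def test_passband_tone_unit_gain(self):
        rec = tone_recording([(10.0, 1.0)])
        out = bandpass_filter(rec, 0.5, 50.0)
        assert abs(mid_rms(out.data) / mid_rms(rec.data) - 1.0) < 0.02

    def test_octave_above_cutoff_attenuated_40db(self):
        # measure the 100 Hz component by quadrature projection in the middle
        # of the record, away from filter edge transients
        rec = tone_recording([(100.0, 1.0)], duration=20.0, n_channels=1)
        out = bandpass_filter(rec, 0.5, 50.0)
        n = rec.n_samples
        mid = slice(n // 4, 3 * n // 4)
        t = np.arange(n)[mid] / rec.sample_rate

        def tone_amp(x):
            c = 2 * (x[0, mid] * np.cos(2 * np.pi * 100.0 * t)).mean()
            s = 2 * (x[0, mid] * np.sin(2 * np.pi * 100.0 * t)).mean()
            return np.hypot(c, s)

        attenuation_db = 20 * np.log10(tone_amp(rec.data) / tone_amp(out.data))
        assert attenuation_db >= 40.0

    def test_dc_offset_removed(self):
        rec = tone_recording([(10.0, 1.0)])
        rec.data += 25.0
        out = bandpass_filter(rec, 0.5, 50.0)
        assert abs(out.data[:, 1000:-1000].mean()) < 0.05

    def test_zero_phase_preserves_impulse_centroid(self):
        data = np.zeros((1, 4000))
        data[0, 2000] = 1.0
        rec = RawRecording(data, ("CH0",), 1000.0)
        out = bandpass_filter(rec, 0.5, 50.0)
        energy = out.data[0] ** 2
        centroid = (np.arange(4000) * energy).sum() / energy.sum()
        assert abs(centroid - 2000) <= 2

    def test_cutoff_above_nyquist_rejected(self):
        rec = tone_recording([(10.0, 1.0)])
        with pytest.raises(ValueError):
            bandpass_filter(rec, 0.5, 600.0)


class TestSplitBands:
    def test_alpha_tone_routes_to_alpha1(self):
        rec = tone_recording([(10.0, 1.0)])
        out = split_bands(rec)
        powers = {name: mid_rms(r.data) ** 2 for name, r in out.items()}
        # >= 95% of the power across all band copies lands in Alpha1
        assert powers["Alpha1"] / sum(powers.values()) >= 0.95
        assert powers["Delta"] / mid_rms(rec.data) ** 2 <= 0.01

    def test_mixture_separates_per_band(self):
        rec = tone_recording([(2.0, 1.0), (40.0, 1.0)])
        out = split_bands(rec)
        # each band copy retains its own tone at ~unit amplitude
        assert abs(mid_rms(out["Delta"].data) - mid_rms(tone_recording([(2.0, 1.0)]).data)) \
            / mid_rms(tone_recording([(2.0, 1.0)]).data) < 0.05
        assert abs(mid_rms(out["Gamma"].data) - mid_rms(tone_recording([(40.0, 1.0)]).data)) \
            / mid_rms(tone_recording([(40.0, 1.0)]).data) < 0.05

    def test_empty_band_list(self):
        assert split_bands(tone_recording([(10.0, 1.0)]), []) == {}

    def test_canonical_bands_tile_one_to_fifty_hz(self):
        bands = sorted(df.CANONICAL_BANDS, key=lambda b: b.low)
        assert bands[0].low == 1.0 and bands[-1].high == 50.0
        for a, b in zip(bands, bands[1:]):
            assert a.high == b.low  # share boundaries, no gaps or overlap


class TestSegment:
    def test_ten_second_recording_gives_nine_segments(self):
        cfg = SynthConfig(n_subjects=1, duration_s=10.0, seed=0)
        rec = generate_recording(cfg, "S01", "post")
        segs = segment(rec)
        assert segs.segments.shape == (9, 16, 2000)
        assert (segs.labels == 1).all()
        assert (segs.subject_ids == "S01").all()

    def test_exact_window_boundary(self):
        rec = RawRecording(np.zeros((2, 2000)), ("A", "B"), 1000.0)
        assert len(segment(rec)) == 1

    def test_short_recording_warns_and_returns_empty(self):
        rec = RawRecording(np.zeros((2, 1999)), ("A", "B"), 1000.0)
        with pytest.warns(UserWarning):
            segs = segment(rec)
        assert len(segs) == 0

    @given(
        t=st.integers(min_value=1, max_value=500),
        w=st.integers(min_value=1, max_value=100),
        s=st.integers(min_value=1, max_value=50),
    )
    @settings(max_examples=60, deadline=None)
    def test_count_formula_holds(self, t, w, s):
        rec = RawRecording(np.zeros((1, t)), ("A",), 1.0)
        if t < w:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert len(segment(rec, window_s=w, step_s=s)) == 0
        else:
            segs = segment(rec, window_s=w, step_s=s)
            assert len(segs) == (t - w) // s + 1
            assert segs.segments.shape[2] == w
            if len(segs) >= 2 and s < w:  # consecutive windows overlap by w - s
                assert np.array_equal(segs.segments[0][:, s:], segs.segments[1][:, :w - s])


class TestInterpolation:
    def smooth_field_recording(self, seed=0):
        """A spatially smooth dipolar field sampled at the 16 positions."""
        from duformer.montage import positions_array

        rng = np.random.default_rng(seed)
        pos = positions_array()
        t = np.arange(500) / 1000.0
        comp = np.stack([np.sin(2 * np.pi * f * t) for f in (4.0, 7.0, 11.0)])
        direction = rng.standard_normal((3, 3))
        weights = pos @ direction.T  # smooth (linear) scalp pattern
        return RawRecording(weights @ comp, CHANNELS, 1000.0)

    def test_no_bad_channels_is_identity(self):
        rec = self.smooth_field_recording()
        out = interpolate_bad_channels(rec, [])
        assert np.array_equal(out.data, rec.data)

    def test_constant_field_reproduced(self):
        data = np.full((16, 300), 7.5)
        rec = RawRecording(data, CHANNELS, 1000.0)
        out = interpolate_bad_channels(rec, ["Cz"])
        cz = out.data[CHANNELS.index("Cz")]
        assert np.allclose(cz, 7.5, rtol=0.01)

    def test_beats_nearest_neighbor_on_smooth_field(self):
        from duformer.montage import positions_array

        rec = self.smooth_field_recording(seed=3)
        pos = positions_array()
        errs_spline, errs_nn = [], []
        for held_out in ("Cz", "Pz", "F3"):
            idx = CHANNELS.index(held_out)
            truth = rec.data[idx].copy()
            out = interpolate_bad_channels(rec, [held_out])
            errs_spline.append(np.sqrt(((out.data[idx] - truth) ** 2).mean()))
            dists = np.linalg.norm(pos - pos[idx], axis=1)
            dists[idx] = np.inf
            errs_nn.append(np.sqrt(((rec.data[np.argmin(dists)] - truth) ** 2).mean()))
        assert np.mean(errs_spline) < np.mean(errs_nn)

    def test_agrees_with_mne_reference(self):
        """Cross-check against mne's spherical spline interpolation."""
        import mne

        rec = self.smooth_field_recording(seed=5)
        info = mne.create_info(list(CHANNELS), 1000.0, ch_types="eeg")
        raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            montage = mne.channels.make_standard_montage("standard_1005")
        raw.set_montage(montage, verbose="error")
        raw.info["bads"] = ["Cz"]
        raw.interpolate_bads(reset_bads=True, verbose="error")
        ours = interpolate_bad_channels(rec, ["Cz"]).data[CHANNELS.index("Cz")]
        theirs = raw.get_data()[CHANNELS.index("Cz")] * 1e6
        r = np.corrcoef(ours, theirs)[0, 1]
        assert r > 0.95

    def test_all_channels_bad_rejected(self):
        rec = self.smooth_field_recording()
        with pytest.raises(ValueError):
            interpolate_bad_channels(rec, list(CHANNELS))

    def test_unknown_channel_rejected(self):
        rec = self.smooth_field_recording()
        with pytest.raises(ValueError):
            interpolate_bad_channels(rec, ["T7"])


@pytest.fixture(scope="module")
def contaminated():
    """A filtered synthetic recording with a known ocular artifact.

    The returned reference trace is filtered identically to the data, as the
    pipeline does.
    """
    from scipy import signal as sps

    cfg = SynthConfig(n_subjects=1, duration_s=21.0, seed=21)
    clean = generate_recording(cfg, "S01", "pre")
    dirty, trace = inject_artifacts(clean, "ocular", seed=1)
    dirty = bandpass_filter(dirty)
    clean_f = bandpass_filter(clean)
    sos = sps.butter(4, [0.5, 50.0], btype="bandpass", fs=1000.0, output="sos")
    return clean_f, dirty, sps.sosfiltfilt(sos, trace)


class TestOcularRemoval:
    def test_removes_component_and_reduces_residual(self, contaminated):
        clean_f, dirty, trace = contaminated
        out, report = remove_ocular_artifacts(dirty, trace, seed=0)
        assert report.converged
        assert len(report.removed_components) >= 1
        rmse_before = np.sqrt(((dirty.data - clean_f.data) ** 2).mean())
        rmse_after = np.sqrt(((out.data - clean_f.data) ** 2).mean())
        assert rmse_after < rmse_before

    def test_uncorrelated_reference_removes_nothing(self, contaminated):
        clean_f, dirty, _ = contaminated
        rng = np.random.default_rng(0)
        noise_ref = rng.standard_normal(dirty.n_samples)
        out, report = remove_ocular_artifacts(dirty, noise_ref, seed=0)
        assert report.removed_components == []
        scale = np.abs(dirty.data).max()
        assert np.abs(out.data - dirty.data).max() < 1e-6 * scale

    def test_unattainable_threshold_removes_nothing(self, contaminated):
        _, dirty, trace = contaminated
        out, report = remove_ocular_artifacts(dirty, trace, r_threshold=1.0, seed=0)
        assert report.removed_components == []

    def test_wrong_reference_length_rejected(self, contaminated):
        _, dirty, trace = contaminated
        with pytest.raises(ValueError):
            remove_ocular_artifacts(dirty, trace[:-5], seed=0)


class TestMyogenicSuppression:
    def test_narrowband_alpha_recording_untouched(self):
        cfg = SynthConfig(
            n_subjects=1, duration_s=21.0, seed=3,
            oscillation_amplitudes={"Alpha1": 10.0},
            background_amplitude=1.0,
        )
        rec = bandpass_filter(generate_recording(cfg, "S01", "pre"))
        out, report = suppress_myogenic_artifacts(rec, seed=0)
        assert report.removed_components == []

    def test_bursts_removed_and_hf_power_drops(self):
        cfg = SynthConfig(n_subjects=1, duration_s=21.0, seed=13)
        clean = generate_recording(cfg, "S01", "pre")
        dirty, _ = inject_artifacts(clean, "myogenic", seed=5, amplitude=400.0)
        dirty = bandpass_filter(dirty)
        out, report = suppress_myogenic_artifacts(dirty, seed=0)
        assert report.converged and len(report.removed_components) >= 1

        def hf_power(data):
            from scipy.signal import welch

            f, p = welch(data, fs=1000.0, nperseg=2048, axis=-1)
            return p[:, f > 30].sum()

        assert hf_power(out.data) < hf_power(dirty.data)

    def test_threshold_one_is_identity(self):
        cfg = SynthConfig(n_subjects=1, duration_s=11.0, seed=3)
        rec = bandpass_filter(generate_recording(cfg, "S01", "pre"))
        out, report = suppress_myogenic_artifacts(rec, hf_power_fraction_threshold=1.0, seed=0)
        assert report.removed_components == []
        assert np.abs(out.data - rec.data).max() < 1e-9


class TestPipeline:
    def test_per_band_counts_consistent(self):
        cfg = SynthConfig(n_subjects=1, duration_s=11.0, seed=0)
        rec = generate_recording(cfg, "S01", "pre")
        out, log = preprocess_pipeline(rec)
        expected = (11000 - 2000) // 1000 + 1
        assert {name: len(s) for name, s in out.items()} == {
            b: expected for b in df.BAND_NAMES
        }
        assert [entry["stage"] for entry in log][0] == "bandpass_filter"

    def test_deterministic_under_rerun(self):
        cfg = SynthConfig(n_subjects=1, duration_s=11.0, seed=1)
        rec = generate_recording(cfg, "S01", "pre")
        pcfg = PipelineConfig(remove_ocular=True, suppress_myogenic=True, ica_seed=5)
        dirty, trace = inject_artifacts(rec, "ocular", seed=2)
        a, _ = preprocess_pipeline(dirty, pcfg, reference_trace=trace)
        b, _ = preprocess_pipeline(dirty, pcfg, reference_trace=trace)
        for band in a:
            assert np.array_equal(a[band].segments, b[band].segments)

    def test_artifact_stages_are_the_only_difference(self):
        cfg = SynthConfig(n_subjects=1, duration_s=11.0, seed=2)
        rec = generate_recording(cfg, "S01", "pre")
        dirty, trace = inject_artifacts(rec, "ocular", seed=3)
        plain_cfg = PipelineConfig()
        removal_cfg = PipelineConfig(remove_ocular=True, ica_seed=0)
        plain, log_plain = preprocess_pipeline(dirty, plain_cfg)
        removed, log_removed = preprocess_pipeline(dirty, removal_cfg, reference_trace=trace)
        # the removal run logs an extra stage and changes the data
        stages_plain = [e["stage"] for e in log_plain]
        stages_removed = [e["stage"] for e in log_removed]
        assert set(stages_removed) - set(stages_plain) == {"remove_ocular_artifacts"}
        assert any(
            not np.array_equal(plain[b].segments, removed[b].segments) for b in plain
        )
        # re-running the plain variant reproduces it exactly
        plain2, _ = preprocess_pipeline(dirty, plain_cfg)
        for band in plain:
            assert np.array_equal(plain[band].segments, plain2[band].segments)

    def test_artifact_removal_preserves_shape(self, contaminated):
        _, dirty, trace = contaminated
        out, _ = remove_ocular_artifacts(dirty, trace, seed=0)
        assert out.data.shape == dirty.data.shape
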