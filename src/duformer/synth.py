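"""Synthetic 16-channel EEG with controllable band-specific class effects.

The generator emulates the structure the downstream pipeline expects from a
pre/post-training memory study: per subject, one "pre" and one "post"
recording of broadband EEG built from

* seven band-limited stochastic oscillations (narrowband-filtered Gaussian
  noise, one per canonical band, spatially mixed across electrodes through a
  fixed random mixing matrix),
* a 1/f^alpha background noise floor per channel, and
* optional ocular / myogenic artifact events.

The class contrast is a multiplicative power shift: in ``effect_band`` the
oscillation variance of "post" recordings is ``effect_ratio`` times that of
"pre" recordings. With ``effect_ratio == 1`` the two class generators are
distributionally identical, which is the null condition used for
calibration checks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bands import BAND_NAMES, CANONICAL_BANDS, get_band
from .montage import CHANNELS
from .recording import RawRecording

#: Class label encoding used everywhere downstream.
LABEL_CODES = {"pre": 0, "post": 1}

#: Default per-band oscillation amplitudes (standard deviation, uV).
#: Descending with frequency, mirroring the typical 1/f-like EEG spectrum.
DEFAULT_AMPLITUDES = {
    "Delta": 20.0,
    "Theta": 10.0,
    "Alpha1": 10.0,
    "Alpha2": 8.0,
    "Beta1": 6.0,
    "Beta2": 5.0,
    "Gamma": 4.0,
}

_SOURCES_PER_BAND = 3


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    ``duration_s`` of 21 s at the default 2 s / 1 s windowing yields 20
    segments per recording, so 10 subjects give 200 segments per class.
    """

    n_subjects: int = 17
    n_channels: int = 16
    sample_rate: float = 1000.0
    duration_s: float = 21.0
    effect_band: str = "Gamma"
    effect_ratio: float = 2.0
    background_exponent: float = 1.0
    background_amplitude: float = 3.0
    oscillation_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    artifact_rate: float = 0.0
    tone_components: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        get_band(self.effect_band)  # raises on unknown band
        unknown = set(self.oscillation_amplitudes) - set(BAND_NAMES)
        if unknown:
            raise ValueError(f"unknown bands in amplitude map: {sorted(unknown)}")
        if any(a < 0 for a in self.oscillation_amplitudes.values()):
            raise ValueError("oscillation amplitudes must be >= 0")
        if self.effect_ratio < 0:
            raise ValueError("effect_ratio must be >= 0")
        if self.duration_s < 2.0:
            raise ValueError("duration_s must cover at least one 2 s window")
        if self.sample_rate <= 0 or self.n_channels < 1:
            raise ValueError("invalid sample_rate or n_channels")

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.n_channels == len(CHANNELS):
            return CHANNELS
        return tuple(f"CH{i + 1}" for i in range(self.n_channels))


def _mixing_matrices(config: SynthConfig) -> dict[str, np.ndarray]:
    """Fixed per-band spatial mixing matrices, a function of the seed only.

    Columns are unit-variance source projections scaled so each channel's
    mixed oscillation has (expected) unit variance before amplitude scaling.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x51C]))
    out = {}
    for band in CANONICAL_BANDS:
        a = rng.standard_normal((config.n_channels, _SOURCES_PER_BAND))
        a /= np.linalg.norm(a, axis=1, keepdims=True)  # unit channel variance
        out[band.name] = a
    return out


def _band_sos(low: float, high: float, fs: float) -> np.ndarray:
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _narrowband_sources(
    rng: np.random.Generator, n_sources: int, n_samples: int, low: float, high: float, fs: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high] Hz."""
    white = rng.standard_normal((n_sources, n_samples))
    sos = _band_sos(low, min(high, 0.999 * fs / 2), fs)
    nb = signal.sosfiltfilt(sos, white, axis=-1)
    std = nb.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return nb / std


def _background_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float, alpha: float, amp: float
) -> np.ndarray:
    """Per-channel 1/f^alpha noise with standard deviation ``amp``."""
    if amp == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    pos = freqs > 0
    # flatten the spectral slope below 1 Hz so DC power stays bounded
    shape[pos] = np.maximum(freqs[pos], 1.0) ** (-alpha / 2.0)
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shape
    noise = np.fft.irfft(spec, n=n_samples, axis=-1)
    std = noise.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return amp * noise / std


def _recording_seed(config: SynthConfig, subject_id: str, class_label: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [config.seed, zlib.crc32(subject_id.encode()), LABEL_CODES[class_label], 0xEE6]
    )


def generate_recording(
    config: SynthConfig, subject_id: str, class_label: str
) -> RawRecording:
    """Generate one continuous recording for ``subject_id``.

    For ``class_label == "post"`` the oscillation variance in
    ``config.effect_band`` is multiplied by ``config.effect_ratio``
    (amplitude by its square root). Fully reproducible from
    ``(config.seed, subject_id, class_label)``.
    """
    if class_label not in LABEL_CODES:
        raise ValueError(f"class_label must be one of {sorted(LABEL_CODES)}")
    n = int(round(config.duration_s * config.sample_rate))
    rng = np.random.default_rng(_recording_seed(config, subject_id, class_label))
    mixing = _mixing_matrices(config)

    data = np.zeros((config.n_channels, n))
    for band in CANONICAL_BANDS:
        amp = config.oscillation_amplitudes.get(band.name, 0.0)
        if band.name == config.effect_band and class_label == "post":
            amp *= np.sqrt(config.effect_ratio)
        # draw sources even at zero amplitude so the RNG stream (and hence
        # every other component) is identical across class labels
        sources = _narrowband_sources(
            rng, _SOURCES_PER_BAND, n, band.low, band.high, config.sample_rate
        )
        if amp > 0:
            data += amp * (mixing[band.name] @ sources)

    data += _background_noise(
        rng, config.n_channels, n, config.sample_rate,
        config.background_exponent, config.background_amplitude,
    )

    t = np.arange(n) / config.sample_rate
    for freq, amp in config.tone_components:
        data += amp * np.sin(2 * np.pi * freq * t)

    rec = RawRecording(
        data=data,
        channel_names=config.channel_names,
        sample_rate=config.sample_rate,
        subject_id=subject_id,
        session=class_label,
    )
    if config.artifact_rate > 0:
        art_seed = int(rng.integers(2**31))
        rec, _ = inject_artifacts(rec, "ocular", art_seed, rate_per_min=config.artifact_rate)
    return rec


def generate_dataset(config: SynthConfig) -> list[RawRecording]:
    """One "pre" and one "post" recording per subject, deterministically."""
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    recordings = []
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:02d}"
        for label in ("pre", "post"):
            recordings.append(generate_recording(config, subject_id, label))
    return recordings


# ---------------------------------------------------------------------------
# Artifact injection

#: Frontally weighted spatial profile of ocular (blink) artifacts.
_OCULAR_WEIGHTS = {
    "Fp1": 1.0, "Fp2": 1.0, "F7": 0.45, "F8": 0.45, "F3": 0.4, "F4": 0.4,
    "Fz": 0.4, "FCz": 0.25, "C3": 0.15, "C4": 0.15, "Cz": 0.15,
    "P7": 0.05, "P8": 0.05, "Pz": 0.05, "O1": 0.03, "O2": 0.03,
}

#: Temporally weighted profile of myogenic (muscle) bursts.
_MYOGENIC_WEIGHTS = {
    "F7": 1.0, "F8": 1.0, "P7": 0.9, "P8": 0.9, "Fp1": 0.4, "Fp2": 0.4,
    "F3": 0.3, "F4": 0.3, "Fz": 0.2, "FCz": 0.2, "C3": 0.3, "C4": 0.3,
    "Cz": 0.2, "Pz": 0.2, "O1": 0.3, "O2": 0.3,
}


def _spatial_weights(channel_names: tuple[str, ...], table: dict[str, float]) -> np.ndarray:
    return np.asarray([table.get(name, 0.1) for name in channel_names])


def inject_artifacts(
    recording: RawRecording,
    kind: str,
    seed: int,
    rate_per_min: float = 15.0,
    amplitude: float = 150.0,
) -> tuple[RawRecording, np.ndarray]:
    """Add artifact events and return (contaminated recording, source trace).

    ``kind="ocular"`` adds slow (<4 Hz) blink-like transients with a
    frontally dominated spatial profile; ``kind="myogenic"`` adds >30 Hz
    noise bursts weighted toward temporal electrodes (default amplitude is
    scaled down to a typical EMG level). The clean signal and the trace are
    stored in ``extras`` for residual-error assessment.
    """
    if kind not in ("ocular", "myogenic"):
        raise ValueError("kind must be 'ocular' or 'myogenic'")
    rng = np.random.default_rng(seed)
    fs = recording.sample_rate
    n = recording.n_samples
    trace = np.zeros(n)
    n_events = rng.poisson(rate_per_min * recording.duration_s / 60.0)

    if kind == "ocular":
        weights = _spatial_weights(recording.channel_names, _OCULAR_WEIGHTS)
        width = int(0.30 * fs)  # ~300 ms blink
        tt = np.arange(-2 * width, 2 * width + 1)
        pulse = np.exp(-0.5 * (tt / (width / 2.0)) ** 2)
        for _ in range(n_events):
            center = rng.integers(0, n)
            a = amplitude * rng.uniform(0.7, 1.3)
            lo = max(0, center - 2 * width)
            hi = min(n, center + 2 * width + 1)
            trace[lo:hi] += a * pulse[(lo - center + 2 * width):(hi - center + 2 * width)]
    else:
        weights = _spatial_weights(recording.channel_names, _MYOGENIC_WEIGHTS)
        amplitude = amplitude / 5.0  # EMG bursts are far smaller than blinks
        sos = signal.butter(
            4, [30.0, min(120.0, 0.999 * fs / 2)], btype="bandpass", fs=fs, output="sos"
        )
        for _ in range(n_events):
            dur = int(rng.uniform(0.3, 0.8) * fs)
            start = int(rng.integers(0, max(1, n - dur)))
            burst = signal.sosfiltfilt(sos, rng.standard_normal(dur + 1))
            std = burst.std() or 1.0
            window = np.hanning(dur + 1)
            trace[start:start + dur + 1] += amplitude * window * burst / std

    contaminated = recording.data + np.outer(weights, trace)
    out = recording.copy_with(
        contaminated,
        clean=recording.data.copy(),
        artifact_trace=trace,
        artifact_kind=kind,
    )
    return out, trace
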