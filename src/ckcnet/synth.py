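"""Synthetic recordings for exercising the CKC and network pipelines.

Everything needed to run the package without clinical data is generated
here: jittered trigger trains, 21-channel scalp EEG with a trigger-locked
oscillatory response embedded in 1/f background, four classes of artifact
waveforms, and 58-parcel cortical signals with known directed coupling.

The study conditions emulated by the defaults: pneumatic hand stimulation
at 1.78 Hz (inter-stimulus interval 561 ms with ~2.9 ms SD), a
steady-state response at the first harmonic 3.56 Hz that is strongest over
the rolandic electrodes (C3/C4), and EEG resampled to 250 Hz.

All generators are deterministic under their ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .containers import CHANNELS_1020, ParcelSignals, Recording, default_parcel_metadata
from .errors import InvalidParameterError, UnknownChannelError

#: Pass bands (Hz) of the four artifact classes.
ARTIFACT_BANDS = {
    "emg": (5.0, 70.0),
    "device": (2.0, 125.0),
    "respiration": (1.0, 30.0),
    "ecg": (2.0, 35.0),
}


# ---------------------------------------------------------------------------
# trigger trains
# ---------------------------------------------------------------------------

def generate_trigger_train(rate, duration, isi_jitter_sd=0.0, seed=None, rng=None):
    """Stimulus onset times for a (jittered) periodic trigger train.

    Parameters
    ----------
    rate : float
        Nominal stimulation rate in Hz (1.78 for the pneumatic stimulator).
    duration : float
        Recording length in seconds; all triggers fall strictly before it.
    isi_jitter_sd : float
        SD of Gaussian jitter added to each inter-stimulus interval, in
        **milliseconds** (the stimulator's 561 +/- 2.9 ms regime).
    seed, rng
        Either an integer seed or a ``numpy.random.Generator``.

    Returns
    -------
    ndarray of trigger times in seconds; the first trigger is at t = 0 and
    with zero jitter the k-th trigger is exactly ``k / rate``.
    """
    if rate <= 0 or duration <= 0:
        raise InvalidParameterError("rate and duration must be positive")
    if isi_jitter_sd < 0:
        raise InvalidParameterError("isi_jitter_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_max = int(np.ceil(duration * rate)) + 8
    base = np.arange(n_max) / rate
    if isi_jitter_sd > 0:
        jit = rng.normal(0.0, isi_jitter_sd * 1e-3, n_max - 1)
        times = base + np.concatenate([[0.0], np.cumsum(jit)])
    else:
        times = base
    return times[times < duration]


# ---------------------------------------------------------------------------
# scalp recordings
# ---------------------------------------------------------------------------

def pink_noise(n_samples, n_channels=1, rng=None, seed=None):
    """Unit-RMS 1/f ("pink") noise, one independent trace per channel.

    Spectral shaping: Gaussian white noise whose rFFT amplitudes are scaled
    by ``f**-0.5`` (DC removed), giving a 1/f power spectrum.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / rms


@dataclass(frozen=True)
class SynthScalpConfig:
    """Configuration of a synthetic scalp recording.

    ``response_amplitude=None`` scales the sinusoid so that its power in
    the response band equals ``response_band_snr`` times the background
    power within ``response_band_match`` — the moderate-SNR regime in which
    the detection pipeline reaches its always-detected ceiling at around
    100 epochs, mirroring clinical recordings.  An explicit amplitude (uV)
    overrides this.  ``phase_jitter_sd`` is the SD (radians) of the
    wrapped-Gaussian per-trigger phase offset of the response; the expected
    inter-trial coherence of the offsets is ``exp(-sd**2 / 2)``.
    """

    n_channels: int = 21
    fs: float = 250.0
    duration: float = 120.0
    stim_rate: float = 1.78
    isi_jitter_sd: float = 2.9  # ms
    response_freq: float = 3.56
    response_channels: dict = field(default_factory=lambda: {"C3": 1.0, "C4": 1.0})
    response_amplitude: float | None = None  # uV; None -> band-SNR matched
    response_band_match: tuple = (3.06, 4.06)  # Hz
    response_band_snr: float = 2.0  # response/background band power ratio
    phase_jitter_sd: float = 1.0  # rad
    noise_amplitude: float = 20.0  # uV RMS per channel
    common_mode_mix: float = 0.3
    spike_epoch_fraction: float = 0.0
    spike_amplitude: float = 500.0  # uV
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_channels <= len(CHANNELS_1020):
            raise InvalidParameterError("n_channels must be in 1..21")
        if self.fs <= 2 * self.response_freq:
            raise InvalidParameterError("fs must exceed twice the response frequency")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be positive")
        if self.phase_jitter_sd < 0:
            raise InvalidParameterError("phase_jitter_sd must be >= 0")
        if self.noise_amplitude < 0:
            raise InvalidParameterError("noise_amplitude must be >= 0")
        labels = CHANNELS_1020[: self.n_channels]
        for ch in self.response_channels:
            if ch not in labels:
                raise UnknownChannelError(ch)


def _band_rms(x, fs, band):
    """RMS of ``x`` within a frequency band (4th-order zero-phase bandpass)."""
    from .preprocess import padlen_for

    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    pad = padlen_for(fs, band[0], x.shape[-1])
    return float(np.sqrt(np.mean(sps.sosfiltfilt(sos, x, axis=-1, padlen=pad) ** 2)))


def _spike_waveform(fs, width_s=0.04):
    """Biphasic spike (first derivative of a Gaussian), peak amplitude 1."""
    t = np.arange(-3 * width_s, 3 * width_s + 1 / fs, 1 / fs)
    w = -t * np.exp(-(t**2) / (2 * width_s**2))
    return w / np.abs(w).max()


def generate_scalp_recording(config: SynthScalpConfig) -> Recording:
    """Synthesise a trigger-locked scalp EEG recording.

    The background is spatially correlated pink noise (independent traces
    plus a shared common-mode term).  On each response channel every
    trigger re-phases a sinusoid at ``response_freq``: on the segment
    between trigger k and trigger k+1 the response is
    ``A * g_ch * cos(2*pi*f*(t - t_k) + phi_k)`` with ``phi_k`` drawn from
    a wrapped Gaussian of SD ``phase_jitter_sd``.

    Ground truth (trigger phases, spike times, resolved amplitude) is kept
    in ``Recording.meta``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = CHANNELS_1020[: config.n_channels]
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs

    triggers = generate_trigger_train(
        config.stim_rate, config.duration, config.isi_jitter_sd, rng=rng
    )

    # spatially correlated 1/f background
    if config.noise_amplitude > 0:
        indep = pink_noise(n, config.n_channels, rng=rng)
        common = pink_noise(n, 1, rng=rng)
        c = config.common_mode_mix
        bg = indep + c * common
        bg *= config.noise_amplitude / np.sqrt(
            np.mean(bg**2, axis=-1, keepdims=True)
        )
    else:
        bg = np.zeros((config.n_channels, n))

    amplitude = config.response_amplitude
    if amplitude is None:
        if config.noise_amplitude > 0:
            # sinusoid power A^2/2 = band_snr * background band power
            band_rms = _band_rms(bg, config.fs, config.response_band_match)
            amplitude = np.sqrt(2.0 * config.response_band_snr) * band_rms
        else:
            amplitude = 1.0

    # trigger-locked response, re-phased at every trigger
    phases = rng.normal(0.0, config.phase_jitter_sd, len(triggers))
    phases = np.angle(np.exp(1j * phases))  # wrap to (-pi, pi]
    response = np.zeros(n)
    bounds = np.concatenate([triggers, [config.duration + 1.0]])
    for k, t_k in enumerate(triggers):
        i0 = int(np.ceil(t_k * config.fs))
        i1 = min(int(np.ceil(bounds[k + 1] * config.fs)), n)
        if i0 >= i1:
            continue
        seg = t[i0:i1] - t_k
        response[i0:i1] = np.cos(
            2 * np.pi * config.response_freq * seg + phases[k]
        )

    data = bg
    for ch, gain in config.response_channels.items():
        data[labels.index(ch)] += amplitude * gain * response

    # optional high-amplitude spike contamination; with non-overlapping
    # 1.1 s epochs roughly every second trigger is epoched, so this yields
    # about spike_epoch_fraction of contaminated epochs
    spike_times = np.array([])
    if config.spike_epoch_fraction > 0:
        n_spikes = int(round(config.spike_epoch_fraction * len(triggers) / 2.0))
        lo, hi = 0.5, max(config.duration - 0.5, 0.6)
        spike_times = np.sort(rng.uniform(lo, hi, n_spikes))
        w = _spike_waveform(config.fs)
        gains = rng.uniform(0.5, 1.0, (n_spikes, config.n_channels))
        for s_t, g in zip(spike_times, gains):
            i0 = int(round(s_t * config.fs))
            i1 = min(i0 + len(w), n)
            data[:, i0:i1] += (
                config.spike_amplitude * g[:, None] * w[None, : i1 - i0]
            )

    meta = {
        "config": asdict(config),
        "response_phases": phases,
        "response_amplitude": amplitude,
        "spike_times": spike_times,
    }
    return Recording(data, config.fs, labels, triggers, meta)


# ---------------------------------------------------------------------------
# parcel signals with known directed coupling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthParcelConfig:
    """Narrowband parcel signals with optional lagged directed coupling.

    ``coupling_edges`` is a list of ``(source, target, lag_samples,
    strength)`` with parcels given by index or label; the target becomes
    the convex mixture ``(1 - s) * own_noise + s * lagged_source``
    (re-normalised to ``noise_sd``), so phase information flows
    source -> target with a known lag: at s = 1 the target is a pure
    lagged copy, at s = 0 there is no coupling.
    """

    n_parcels: int = 58
    fs: float = 250.0
    duration: float = 60.0
    carrier_freq: float = 3.56
    carrier_halfwidth: float = 0.5  # Hz
    coupling_edges: tuple = ()
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise InvalidParameterError("fs and duration must be positive")
        if not 0 < self.carrier_freq - self.carrier_halfwidth:
            raise InvalidParameterError("carrier band must stay above 0 Hz")
        for src, tgt, lag, strength in self.coupling_edges:
            if src == tgt:
                raise InvalidParameterError(f"self-loop edge on parcel {src!r}")
            if lag < 1:
                raise InvalidParameterError("coupling lag must be >= 1 sample")
            if not 0 <= strength <= 1:
                raise InvalidParameterError("coupling strength must be in [0, 1]")


def _lagged(x, lag):
    out = np.empty_like(x)
    out[:lag] = x[0]
    out[lag:] = x[:-lag]
    return out


def generate_parcel_signals(config: SynthParcelConfig) -> ParcelSignals:
    """Generate 58-parcel (or fewer) narrowband signals around the carrier."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels, hemi, lobe = default_parcel_metadata(config.n_parcels)
    n = int(round(config.duration * config.fs))
    band = (
        config.carrier_freq - config.carrier_halfwidth,
        config.carrier_freq + config.carrier_halfwidth,
    )
    sos = sps.butter(4, band, btype="bandpass", fs=config.fs, output="sos")
    data = sps.sosfiltfilt(sos, rng.standard_normal((config.n_parcels, n)), axis=-1)
    data *= config.noise_sd / np.std(data, axis=-1, keepdims=True)

    index = {lab: i for i, lab in enumerate(labels)}

    def _idx(p):
        return p if isinstance(p, (int, np.integer)) else index[p]

    # edges applied in order on the current signals, so chains propagate
    for src, tgt, lag, strength in config.coupling_edges:
        i, j = _idx(src), _idx(tgt)
        mixed = (1.0 - strength) * data[j] + strength * _lagged(data[i], int(lag))
        sd = np.std(mixed)
        if sd > 0:
            mixed *= config.noise_sd / sd
        data[j] = mixed
    return ParcelSignals(data, config.fs, labels, hemi, lobe)


# ---------------------------------------------------------------------------
# artifact waveforms
# ---------------------------------------------------------------------------

@dataclass
class ArtifactTemplate:
    """Unit-RMS multichannel artifact waveform band-limited to ``band``."""

    kind: str
    band: tuple
    waveform: np.ndarray  # (n_channels, n_samples)
    fs: float

    @property
    def n_samples(self) -> int:
        return self.waveform.shape[1]


def _bandlimit(x, fs, band, order=5):
    from .preprocess import padlen_for

    lo, hi = band
    nyq = fs / 2.0
    if hi >= nyq:  # upper edge at/above Nyquist: high-pass only
        sos = sps.butter(order, lo, btype="highpass", fs=fs, output="sos")
    else:
        sos = sps.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen_for(fs, lo, x.shape[-1]))


def generate_artifact(kind, n_channels, duration, fs, seed=None) -> ArtifactTemplate:
    """Synthesize one of the four artifact classes, unit RMS per channel.

    emg
        band-limited white noise (5-70 Hz).
    device
        mains fundamental (50 Hz) plus harmonic and broadband interference
        (2-125 Hz).
    respiration
        a slow periodic bump train (~0.8 Hz fundamental) whose harmonics
        fall in 1-30 Hz.
    ecg
        periodic sharp biphasic spikes at ~2.4 Hz (neonatal heart rate),
        band-limited to 2-35 Hz.
    """
    if kind not in ARTIFACT_BANDS:
        raise InvalidParameterError(
            f"unknown artifact kind {kind!r}; expected one of {sorted(ARTIFACT_BANDS)}"
        )
    if duration <= 0 or fs <= 0 or n_channels < 1:
        raise InvalidParameterError("n_channels, duration and fs must be positive")
    rng = np.random.default_rng(seed)
    band = ARTIFACT_BANDS[kind]
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    if kind == "emg":
        raw = rng.standard_normal((n_channels, n))
    elif kind == "device":
        ph = rng.uniform(0, 2 * np.pi, (n_channels, 2))
        raw = (
            np.sin(2 * np.pi * 50.0 * t + ph[:, :1])
            + 0.3 * np.sin(2 * np.pi * 100.0 * t + ph[:, 1:])
            + 0.5 * rng.standard_normal((n_channels, n))
        )
    elif kind == "respiration":
        f0 = 0.8
        ph = rng.uniform(0, 2 * np.pi, (n_channels, 1))
        cyc = 0.5 * (1 + np.cos(2 * np.pi * f0 * t + ph))
        raw = cyc**8 + 0.05 * rng.standard_normal((n_channels, n))
    else:  # ecg
        f0 = 2.4  # ~144 bpm, neonatal
        w = _spike_waveform(fs, width_s=0.012)
        raw = np.zeros((n_channels, n))
        # beat-to-beat (RR) variability smears the harmonic line spectrum,
        # as in real cardiac artifacts
        n_beats = int(duration * f0) + 4
        rr = (1.0 / f0) * (1.0 + rng.normal(0.0, 0.05, n_beats))
        beats = 0.2 + np.cumsum(np.abs(rr))
        beats = beats[beats < duration - 0.2]
        scale = rng.uniform(0.9, 1.1, (n_channels, len(beats)))
        for c in range(n_channels):
            for b, s in zip(beats, scale[c]):
                i0 = int(round(b * fs))
                i1 = min(i0 + len(w), n)
                raw[c, i0:i1] += s * w[: i1 - i0]

    x = _bandlimit(raw, fs, band)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    if np.any(rms == 0):
        raise InvalidParameterError("degenerate artifact waveform (zero RMS)")
    return ArtifactTemplate(kind, band, x / rms, fs)
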