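"""Filtering, resampling, trigger-locked epoching and amplitude rejection.

The pipeline mirrors routine clinical-EEG preprocessing for steady-state
response analysis: zero-phase Butterworth band limiting (0.5-30 Hz,
order 5), polyphase resampling to 250 Hz, segmentation into 1,100 ms
epochs starting 200 ms before each trigger with no overlap between
consecutive epochs, per-epoch mean removal, and optional peak-amplitude
epoch rejection.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import EpochArray, Recording
from .errors import AliasingError, EmptyEpochsError, InvalidParameterError


def padlen_for(fs: float, cutoff: float, n_samples: int) -> int:
    """Reflection-padding length for zero-phase IIR filtering.

    The default scipy padding is far too short for cut-offs well below the
    sampling rate (e.g. 0.5 Hz at 2 kHz); pad with ~3 time constants of
    the slowest pole instead, capped at the signal length.
    """
    return int(min(n_samples - 1, max(3.0 * fs / cutoff, 3 * fs * 0.05)))


def filter_and_resample(
    recording: Recording,
    low: float = 0.5,
    high: float = 30.0,
    order: int = 5,
    target_fs: float = 250.0,
) -> Recording:
    """Zero-phase band limiting followed by polyphase resampling.

    Separate high-pass (``low``) and low-pass (``high``) Butterworth
    filters of the given order are each applied forward and reverse
    (``sosfiltfilt``), then the signal is resampled to ``target_fs``.
    Trigger times are carried in seconds and therefore unaffected by
    resampling.
    """
    if low >= high:
        raise InvalidParameterError("low cut must be below high cut")
    if recording.fs < 2 * high:
        raise AliasingError(
            f"sampling rate {recording.fs} Hz cannot represent {high} Hz"
        )
    sos_hp = sps.butter(order, low, btype="highpass", fs=recording.fs, output="sos")
    sos_lp = sps.butter(order, high, btype="lowpass", fs=recording.fs, output="sos")
    n = recording.n_samples
    x = sps.sosfiltfilt(sos_hp, recording.signals, axis=-1,
                        padlen=padlen_for(recording.fs, low, n))
    x = sps.sosfiltfilt(sos_lp, x, axis=-1,
                        padlen=padlen_for(recording.fs, high, n))
    if target_fs != recording.fs:
        if target_fs < 2 * high:
            raise AliasingError("target_fs too low for the requested pass band")
        frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return Recording(
        x, float(target_fs), recording.channel_labels,
        recording.trigger_times, dict(recording.meta),
    )


def epoch(recording: Recording, pre: float = 200.0, post: float = 900.0) -> EpochArray:
    """Extract non-overlapping trigger-locked epochs and detrend them.

    Triggers are scanned in time order (greedy earliest-first): a trigger
    is accepted iff its window ``[t - pre, t + post]`` lies fully inside
    the recording and starts at/after the end of the previously accepted
    epoch.  Each epoch's per-channel mean is subtracted ("local mean"
    detrend).  ``pre``/``post`` are in milliseconds.
    """
    if pre < 0 or post <= 0:
        raise InvalidParameterError("pre must be >= 0 and post > 0")
    fs = recording.fs
    pre_s, post_s = pre / 1000.0, post / 1000.0
    n_samp = int(round((pre_s + post_s) * fs))
    duration = recording.duration

    kept, slabs, log = [], [], []
    last_end = -np.inf
    eps = 1e-9
    for idx, t in enumerate(np.sort(np.asarray(recording.trigger_times, float))):
        start_t, end_t = t - pre_s, t + post_s
        i0 = int(round(start_t * fs))
        if start_t < -eps or i0 < 0 or i0 + n_samp > recording.n_samples:
            log.append((idx, False, "outside_recording"))
            continue
        if start_t < last_end - eps:
            log.append((idx, False, "overlap"))
            continue
        kept.append(idx)
        slabs.append(recording.signals[:, i0 : i0 + n_samp])
        last_end = end_t
        log.append((idx, True, ""))
    if not kept:
        raise EmptyEpochsError("no trigger admits a full, non-overlapping epoch")

    data = np.stack(slabs)
    data = data - data.mean(axis=-1, keepdims=True)
    time_axis_ms = np.arange(n_samp) / fs * 1000.0 - pre
    return EpochArray(
        data=data,
        fs=fs,
        time_axis_ms=time_axis_ms,
        channel_labels=recording.channel_labels,
        kept_trigger_indices=np.array(kept, dtype=int),
        rejection_log=pd.DataFrame(log, columns=["trigger", "kept", "reason"]),
        units="uV",
    )


def reject_epochs(epochs: EpochArray, amplitude_threshold: float = 250.0) -> EpochArray:
    """Drop epochs whose absolute amplitude exceeds the threshold anywhere.

    A simple automated stand-in for visual artifact screening.  The
    returned ``rejection_log`` records the dropped fraction.
    """
    if amplitude_threshold <= 0:
        raise InvalidParameterError("amplitude threshold must be positive")
    peak = np.max(np.abs(epochs.data), axis=(1, 2))
    keep = peak <= amplitude_threshold
    if not keep.any():
        raise EmptyEpochsError("amplitude rejection removed every epoch")
    log = pd.DataFrame(
        {
            "epoch": np.arange(epochs.n_epochs),
            "kept": keep,
            "reason": np.where(keep, "", "amplitude"),
        }
    )
    log.attrs["dropped_fraction"] = float(1.0 - keep.mean())
    return EpochArray(
        data=epochs.data[keep],
        fs=epochs.fs,
        time_axis_ms=epochs.time_axis_ms,
        channel_labels=epochs.channel_labels,
        kept_trigger_indices=epochs.kept_trigger_indices[keep],
        rejection_log=log,
        units=epochs.units,
    )
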