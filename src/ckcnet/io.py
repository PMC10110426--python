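"""EDF import/export for :class:`~ckcnet.containers.Recording`.

Recordings are written as 16-bit EDF with physical units of microvolts and
the trigger train encoded as a rectangular pulse channel named ``TRIG``
(pulse height 1000, width 20 ms).  Reading goes through MNE's EDF reader;
trigger times are recovered by rising-edge threshold crossing at half the
pulse height.

The writer emits plain EDF records of 1 s, which requires an integer
sampling rate; the final partial second is zero-padded (the pad carries no
triggers and is dropped by epoching since no trigger falls inside it).
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from .containers import Recording
from .errors import InvalidParameterError

TRIG_LABEL = "TRIG"
TRIG_HEIGHT = 1000.0
TRIG_WIDTH_S = 0.020


def _ascii(value, width):
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    """Write a recording (plus a TRIG pulse channel) to an EDF file."""
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise InvalidParameterError("EDF export requires an integer sampling rate")
    fs = int(round(fs))

    trig = np.zeros(recording.n_samples)
    width = max(1, int(round(TRIG_WIDTH_S * fs)))
    for t in recording.trigger_times:
        i0 = int(round(t * fs))
        trig[i0 : min(i0 + width, recording.n_samples)] = TRIG_HEIGHT

    data = np.vstack([recording.signals, trig[None, :]])
    labels = list(recording.channel_labels) + [TRIG_LABEL]
    n_sig = data.shape[0]

    n_records = int(np.ceil(recording.n_samples / fs))
    padded = np.zeros((n_sig, n_records * fs))
    padded[:, : recording.n_samples] = data

    # per-channel symmetric physical range
    phys_max = np.maximum(np.max(np.abs(padded), axis=1), 1e-6)
    phys_max = np.array([float(f"{v:.6g}") * 1.000001 + 1e-9 for v in phys_max])
    digital = np.round(padded / phys_max[:, None] * 32767.0).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b""
    header += _ascii("0", 8)
    header += _ascii("X X X X", 80)
    header += _ascii("Startdate 01-JAN-2000 X X X", 80)
    header += _ascii(now.strftime("%d.%m.%y"), 8)
    header += _ascii(now.strftime("%H.%M.%S"), 8)
    header += _ascii(256 * (n_sig + 1), 8)
    header += _ascii("", 44)
    header += _ascii(n_records, 8)
    header += _ascii("1", 8)
    header += _ascii(n_sig, 4)

    def field(values, width):
        return b"".join(_ascii(v, width) for v in values)

    header += field(labels, 16)
    header += field([""] * n_sig, 80)                       # transducer
    header += field(["uV"] * n_sig, 8)                      # physical dim
    header += field([f"{-v:.6g}"[:8] for v in phys_max], 8)  # phys min
    header += field([f"{v:.6g}"[:8] for v in phys_max], 8)   # phys max
    header += field(["-32768"] * n_sig, 8)
    header += field(["32767"] * n_sig, 8)
    header += field([""] * n_sig, 80)                       # prefilter
    header += field([fs] * n_sig, 8)                        # samples / record
    header += field([""] * n_sig, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.astype("<i2").tobytes())


def read_edf(path, trig_label: str = TRIG_LABEL) -> Recording:
    """Read an EDF file into a Recording, extracting trigger times.

    The channel named ``trig_label`` (if present) is removed from the data
    and converted to trigger times via rising-edge crossings at half its
    maximum value.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    data = raw.get_data() * 1e6  # MNE stores EEG in volts
    fs = float(raw.info["sfreq"])

    triggers = np.array([])
    if trig_label in labels:
        k = labels.index(trig_label)
        trig = data[k]
        rest = [i for i in range(len(labels)) if i != k]
        data = data[rest]
        labels = [labels[i] for i in rest]
        peak = np.max(np.abs(trig))
        if peak > 0:
            above = trig > peak / 2.0
            edges = np.flatnonzero(~above[:-1] & above[1:]) + 1
            if above[0]:
                edges = np.concatenate([[0], edges])
            triggers = edges / fs
    return Recording(data, fs, labels, triggers, {"source": str(path)})
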