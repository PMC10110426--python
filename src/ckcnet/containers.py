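"""Core data containers shared by the processing modules.

The containers are deliberately thin: plain arrays plus the metadata the
pipelines need (sampling rate, labels, trigger times).  They are not tied
to any file format; :mod:`ckcnet.io` converts to/from EDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import IncompatibleInputsError, InvalidParameterError

#: The 21 electrode labels of the clinical 10-20 cap, in recording order.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "M1", "T3", "C3", "Cz",
    "C4", "T4", "M2", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)


@dataclass
class Recording:
    """Continuous multichannel EEG with stimulus trigger timestamps.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Scalp potentials in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        10-20 electrode names, unique, one per signal row.
    trigger_times : ndarray
        Stimulus (inflation) event times in seconds, within the recording.
    meta : dict
        Free-form provenance (generator config, ground-truth logs, ...).
    """

    signals: np.ndarray
    fs: float
    channel_labels: tuple
    trigger_times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.signals.ndim != 2:
            raise InvalidParameterError("signals must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.signals.shape[0]:
            raise IncompatibleInputsError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signals.shape[0]} signal rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidParameterError("channel labels must be unique")
        dur = self.duration
        if self.trigger_times.size and (
            self.trigger_times.min() < 0 or self.trigger_times.max() > dur
        ):
            raise InvalidParameterError("trigger times outside the recording")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.signals.shape[1] / self.fs


@dataclass
class EpochArray:
    """Trigger-locked epochs.

    ``data`` has shape (n_epochs, n_channels, n_samples) and the time axis
    is expressed in milliseconds relative to the trigger (−200 ... +900 by
    default).  ``units`` is ``"uV"`` for scalp potentials and ``"uV/m2"``
    after the current-source-density transform.
    """

    data: np.ndarray
    fs: float
    time_axis_ms: np.ndarray
    channel_labels: tuple
    kept_trigger_indices: np.ndarray
    rejection_log: pd.DataFrame
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidParameterError("epoch data must be 3-D")
        if self.data.shape[2] != len(self.time_axis_ms):
            raise IncompatibleInputsError("time axis does not match data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class ParcelSignals:
    """Cortical parcel time series (58 parcels, 29 per hemisphere)."""

    data: np.ndarray
    fs: float
    labels: tuple
    hemisphere: tuple
    lobe: tuple

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParameterError("parcel data must be 2-D")
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.hemisphere) == len(self.lobe) == n):
            raise IncompatibleInputsError("parcel metadata does not match data")
        if len(set(self.labels)) != n:
            raise InvalidParameterError("parcel labels must be unique")

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]


def load_parcel_table() -> pd.DataFrame:
    """Shipped 58-parcel table: label, hemisphere, lobe (F/C/T/O)."""
    with resources.files("ckcnet.data").joinpath("parcels_58.csv").open() as fh:
        return pd.read_csv(fh)


def default_parcel_metadata(n_parcels: int = 58):
    """Return (labels, hemisphere, lobe) tuples for ``n_parcels`` parcels.

    For the canonical 58 parcels this is the shipped table; smaller counts
    (used in toy examples/tests) take the first ``n_parcels`` rows.
    """
    tab = load_parcel_table()
    if n_parcels > len(tab):
        raise InvalidParameterError(f"at most {len(tab)} parcels available")
    tab = tab.iloc[:n_parcels]
    return tuple(tab.label), tuple(tab.hemisphere), tuple(tab.lobe)
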