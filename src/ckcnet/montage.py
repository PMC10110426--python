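"""Electrode montages: channel label -> position on the unit sphere.

The shipped default covers the 21-channel clinical 10-20 cap.  Positions
are unit vectors on a best-fit sphere; the physical head radius is a
separate parameter of the CSD transform.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import MontageError


def load_montage(path=None) -> dict:
    """Load a montage CSV (columns: label, x, y, z) as ``{label: xyz}``.

    Positions are normalised to the unit sphere on load.
    """
    if path is None:
        with resources.files("ckcnet.data").joinpath("montage_1020.csv").open() as fh:
            tab = pd.read_csv(fh)
    else:
        tab = pd.read_csv(path)
    out = {}
    for _, row in tab.iterrows():
        v = np.array([row.x, row.y, row.z], dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise MontageError(f"zero position for channel {row.label!r}")
        out[str(row.label)] = v / n
    return out


def montage_positions(labels, montage: dict | None = None) -> np.ndarray:
    """Stack unit-sphere positions for ``labels``; raise if any is missing."""
    if montage is None:
        montage = load_montage()
    missing = [lab for lab in labels if lab not in montage]
    if missing:
        raise MontageError(f"no electrode position for: {missing}")
    return np.array([montage[lab] for lab in labels])


#: Channels in each hemisphere of the 10-20 cap (midline excluded).
HEMISPHERE_CHANNELS = {
    "left": ("Fp1", "F7", "F3", "M1", "T3", "C3", "T5", "P3", "O1"),
    "right": ("Fp2", "F8", "F4", "M2", "T4", "C4", "T6", "P4", "O2"),
}
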