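"""Individual-level network metrics: Spreading Index, laterality, symmetry.

The Spreading Index (SI) quantifies how widely outbound-biased information
flow spreads from the parcels that respond most strongly to stimulation.
Each stimulation-condition dPTE edge is standardised against a reference
distribution pooled from the same subject's control recording,

    z_xy = (dPTE_xy - mu) / sigma,

significant outbound edges are counted with a right-tailed Z-test, the 4
parcels of the requested hemisphere with the most significant outbound
edges become "source nodes", and SI is the percentage of significant
edges among all valid edges originating from those sources (0-100%).

Laterality = 100 * contra / (contra + ipsi); symmetry = 100 * min / max
across stimulation sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .connectivity import InteractionMatrix
from .errors import (
    DegenerateSignalError,
    IncompatibleInputsError,
    InvalidParameterError,
    MissingControlError,
    UndefinedMetricError,
)


@dataclass(frozen=True)
class ReferenceDistribution:
    """Pooled control-condition dPTE mean and SD (typically ~0.5)."""

    mu: float
    sigma: float
    n_pooled: int


@dataclass
class SIResult:
    source_parcels: tuple
    si: float
    n_significant_from_sources: int
    n_possible_from_sources: int
    z_matrix: np.ndarray
    hemisphere: str


def reference_distribution(control: InteractionMatrix) -> ReferenceDistribution:
    """Mean/SD of all valid dPTE entries of the control interaction matrix."""
    if control is None:
        raise MissingControlError("no control recording; SI undefined")
    vals = control.valid_values()
    if vals.size < 30:
        raise InvalidParameterError(
            f"only {vals.size} pooled control values; need >= 30"
        )
    sigma = float(np.std(vals))
    if sigma == 0:
        raise DegenerateSignalError("constant control matrix (sigma = 0)")
    return ReferenceDistribution(float(np.mean(vals)), sigma, int(vals.size))


def edge_zscores(
    stim: InteractionMatrix,
    ref: ReferenceDistribution,
    alpha: float = 0.01,
):
    """Standardise stimulation dPTEs against the control reference.

    Returns ``(z, significant)`` matrices; significance is the right-tailed
    normal test at ``alpha`` (z > 2.326 for alpha = 0.01).  Masked entries
    are NaN / False.
    """
    if ref.sigma == 0:
        raise DegenerateSignalError("sigma = 0")
    z = (stim.dpte - ref.mu) / ref.sigma
    z[~stim.mask.valid] = np.nan
    crit = norm.isf(alpha)
    with np.errstate(invalid="ignore"):
        sig = z > crit
    return z, sig


def spreading_index(
    z: np.ndarray,
    significant: np.ndarray,
    stim: InteractionMatrix,
    hemisphere: str,
    parcel_hemisphere=None,
    n_sources: int = 4,
) -> SIResult:
    """Select source nodes and compute the Spreading Index.

    Parcels of ``hemisphere`` are ranked by their number of significant
    outbound edges (ties: larger summed outbound z, then label order);
    the top ``n_sources`` are the source nodes.  SI = 100 x (significant
    outbound edges from the sources) / (valid outbound edges from the
    sources).  ``parcel_hemisphere`` defaults to the matrix's own parcel
    metadata when the labels follow the shipped table.
    """
    if hemisphere not in ("left", "right"):
        raise InvalidParameterError("hemisphere must be 'left' or 'right'")
    if parcel_hemisphere is None:
        from .containers import load_parcel_table

        tab = load_parcel_table().set_index("label")
        try:
            parcel_hemisphere = [tab.loc[lab, "hemisphere"] for lab in stim.labels]
        except KeyError as err:
            raise IncompatibleInputsError(
                "parcel labels are not in the shipped table; pass "
                "parcel_hemisphere explicitly"
            ) from err
    parcel_hemisphere = list(parcel_hemisphere)

    valid = stim.mask.valid & ~np.isnan(z)
    sig = significant & valid
    candidates = [i for i, h in enumerate(parcel_hemisphere) if h == hemisphere
                  and valid[i].any()]
    if len(candidates) < n_sources:
        raise UndefinedMetricError(
            f"fewer than {n_sources} {hemisphere}-hemisphere parcels with "
            "valid outbound edges"
        )
    with np.errstate(invalid="ignore"):
        zsum = np.where(valid, z, 0.0).sum(axis=1)
    labels = list(stim.labels)
    ranked = sorted(
        candidates,
        key=lambda i: (-int(sig[i].sum()), -zsum[i], labels[i]),
    )
    sources = ranked[:n_sources]

    n_sig = int(sig[sources].sum())
    n_pos = int(valid[sources].sum())
    if n_pos == 0:
        raise UndefinedMetricError("source nodes have no valid outbound edges")
    return SIResult(
        source_parcels=tuple(labels[i] for i in sources),
        si=100.0 * n_sig / n_pos,
        n_significant_from_sources=n_sig,
        n_possible_from_sources=n_pos,
        z_matrix=z,
        hemisphere=hemisphere,
    )


def spreading_index_from_matrices(
    stim: InteractionMatrix,
    control: InteractionMatrix,
    hemisphere: str,
    alpha: float = 0.01,
    n_sources: int = 4,
) -> SIResult:
    """Convenience wrapper: reference -> z-scores -> SI in one call."""
    if not np.array_equal(stim.mask.valid, control.mask.valid):
        raise IncompatibleInputsError("stimulation and control masks differ")
    ref = reference_distribution(control)
    z, sig = edge_zscores(stim, ref, alpha=alpha)
    return spreading_index(z, sig, stim, hemisphere, n_sources=n_sources)


def laterality(contra_value: float, ipsi_value: float) -> float:
    """100 x contra / (contra + ipsi); 100 = fully contralateral response."""
    if contra_value < 0 or ipsi_value < 0:
        raise InvalidParameterError("laterality inputs must be non-negative")
    total = contra_value + ipsi_value
    if total == 0:
        raise UndefinedMetricError("both hemisphere values are zero")
    return 100.0 * contra_value / total


def symmetry(left_value: float, right_value: float) -> float:
    """100 x min / max across stimulation sides; 100 = perfectly symmetric."""
    if left_value < 0 or right_value < 0:
        raise InvalidParameterError("symmetry inputs must be non-negative")
    hi = max(left_value, right_value)
    if hi == 0:
        raise UndefinedMetricError("both side values are zero")
    return 100.0 * min(left_value, right_value) / hi


def hemispheric_ckc(result, side: str, mode: str = "max") -> float:
    """Summarise a CKCResult over one hemisphere's channels.

    ``mode`` is 'max' (default) or 'mean'; midline channels are excluded.
    Used to build the contralateral/ipsilateral inputs of laterality.
    """
    from .montage import HEMISPHERE_CHANNELS

    chans = [c for c in HEMISPHERE_CHANNELS[side] if c in result.channel_labels]
    if not chans:
        raise InvalidParameterError(f"no {side}-hemisphere channels present")
    vals = np.array([result.ckc[result.channel_labels.index(c)] for c in chans])
    return float(vals.max() if mode == "max" else vals.mean())
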