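"""Group-level Consistent Network estimation and nodal dPTE summaries.

Per subject, the fraction ``k`` (default 5%) of valid directed edges with
the highest dPTE is binarised; appearance counts across subjects are
tested edge-by-edge against a Binomial(n_subjects, k) null (right tail,
exact) with Benjamini-Hochberg FDR across the valid edges.  The surviving
edges form the Consistent Network (CN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .connectivity import InteractionMatrix
from .errors import IncompatibleInputsError, InvalidParameterError


@dataclass(frozen=True)
class CNConfig:
    k: float = 0.05
    alpha: float = 0.05
    fdr: bool = True

    def validate(self) -> None:
        if not 0 < self.k < 1:
            raise InvalidParameterError("k must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha must be in (0, 1)")


@dataclass
class ConsistentNetwork:
    """Edge table of the group CN plus the consistency-count matrix."""

    edges: pd.DataFrame  # source, target, count, p, significant
    counts: np.ndarray
    n_subjects: int
    config: CNConfig

    @property
    def significant_edges(self) -> pd.DataFrame:
        return self.edges[self.edges.significant]


def top_k_binarize(matrix: InteractionMatrix, k: float) -> np.ndarray:
    """Boolean matrix of the ceil(k * n_valid) largest dPTE edges.

    Ties are broken deterministically: larger raw PTE first, then
    lexicographic (row, column) order.
    """
    if not 0 < k <= 1:
        raise InvalidParameterError("k must be in (0, 1]")
    valid = matrix.mask.valid & ~np.isnan(matrix.dpte)
    idx = np.argwhere(valid)
    if idx.shape[0] == 0:
        raise InvalidParameterError("no valid edges to binarize")
    m = int(np.ceil(k * idx.shape[0]))  # >= 1 for any k > 0
    d = matrix.dpte[valid]
    praw = (matrix.pte_raw[valid] if matrix.pte_raw is not None
            else np.zeros_like(d))
    # sort descending by (dpte, pte_raw), ascending by (row, col)
    order = np.lexsort((idx[:, 1], idx[:, 0], -praw, -d))
    out = np.zeros_like(valid)
    chosen = idx[order[:m]]
    out[chosen[:, 0], chosen[:, 1]] = True
    return out


def consistent_network(matrices, config: CNConfig = CNConfig()) -> ConsistentNetwork:
    """Edge-by-edge binomial test of per-subject top-k membership.

    All matrices must share parcel labels and fidelity mask.  The per-edge
    P value is the exact right tail P(X >= count) with X ~
    Binomial(n_subjects, k).
    """
    config.validate()
    matrices = list(matrices)
    if len(matrices) < 2:
        raise InvalidParameterError("need at least 2 subjects")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.labels != ref.labels or not np.array_equal(
            m.mask.valid, ref.mask.valid
        ):
            raise IncompatibleInputsError("matrices differ in labels or mask")

    n = len(matrices)
    counts = np.zeros(ref.dpte.shape, dtype=int)
    for m in matrices:
        counts += top_k_binarize(m, config.k)

    valid = ref.mask.valid
    idx = np.argwhere(valid)
    c = counts[valid]
    p = binom.sf(c - 1, n, config.k)  # P(X >= c), exact
    if config.fdr:
        sig = multipletests(p, alpha=config.alpha, method="fdr_bh")[0]
    else:
        sig = p < config.alpha
    labels = list(ref.labels)
    edges = pd.DataFrame(
        {
            "source": [labels[i] for i in idx[:, 0]],
            "target": [labels[j] for j in idx[:, 1]],
            "count": c,
            "p": p,
            "significant": sig,
        }
    )
    return ConsistentNetwork(edges, counts, n, config)


def nodal_dpte(matrix: InteractionMatrix) -> pd.Series:
    """Per-parcel mean dPTE over its valid outbound edges.

    Values above 0.5 mark net information sources, below 0.5 net sinks;
    parcels without valid edges get NaN.
    """
    d = np.where(matrix.mask.valid, matrix.dpte, np.nan)
    counts = np.sum(~np.isnan(d), axis=1)
    sums = np.nansum(d, axis=1)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(means, index=list(matrix.labels), name="nodal_dpte")
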