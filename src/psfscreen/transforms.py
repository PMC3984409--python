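"""Community-matrix transformations and dissimilarities.

The pipeline convention is Hellinger first, Bray-Curtis second: the Hellinger
transformation (square root of row-relative abundance) removes run-to-run
differences in total fingerprint intensity, and Bray-Curtis dissimilarities
are then computed on the transformed rows.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from psfscreen.data_model import DissimilarityMatrix, OTUTable, ValidationError

__all__ = ["HellingerTable", "hellinger", "bray_curtis"]


class HellingerTable(OTUTable):
    """OTU table whose rows are Hellinger-transformed: h_ij = sqrt(x_ij / row_sum_i).

    Every row satisfies sum_j h_ij**2 == 1.
    """


def hellinger(table: OTUTable) -> HellingerTable:
    """Hellinger-transform a community table.

    Raises
    ------
    ValidationError
        If any row has zero total abundance (the transform is undefined).
    """
    sums = table.values.sum(axis=1)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValidationError(f"zero-sum row {table.sample_ids[zero[0]]!r}")
    h = np.sqrt(table.values / sums[:, None])
    return HellingerTable(
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        values=h,
        group=table.group,
        trial_id=table.trial_id,
    )


def bray_curtis(table: OTUTable) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarities among rows.

    d(a, b) = sum_j |a_j - b_j| / sum_j (a_j + b_j); 0 for identical rows,
    1 for rows with disjoint support. Accepts raw or Hellinger-transformed
    tables (the pipeline always passes Hellinger rows).

    Raises
    ------
    ValidationError
        If two all-zero rows make a pair undefined. (An all-zero row cannot
        occur in a valid OTUTable, but defensively re-checked here because a
        zero pair yields 0/0.)
    """
    x = table.values
    if np.any(~(x > 0).any(axis=1)):
        raise ValidationError("all-zero row: Bray-Curtis undefined for a zero pair")
    d = squareform(pdist(x, metric="braycurtis"))
    return DissimilarityMatrix(ids=list(table.sample_ids), d=d)
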