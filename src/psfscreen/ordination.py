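"""Principal coordinates and constrained ordination (CAP) for the affinity index.

The affinity index is built in four steps, always on the 20 "home" pots of a
trial (those communities have seen three successive rounds of selection by one
plant): principal-coordinate analysis of the Bray-Curtis matrix; a constrained
(canonical) analysis with the plant identity as the single explanatory factor,
which for a binary factor yields exactly one canonical axis; orientation of
that axis so ragweed-conditioned communities sit on the negative side; and
weighted-average fitting of each OTU onto the axis using its Hellinger
abundances as weights. The fitted OTU score is the index of affinity:
negative = ragweed-associated, positive = sunflower-associated.

Negative PCoA eigenvalues (Bray-Curtis is non-Euclidean) are discarded without
correction; total inertia is the sum of the retained positive eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from psfscreen.data_model import DissimilarityMatrix, PotMetadata, ValidationError
from psfscreen.transforms import HellingerTable

__all__ = [
    "PCoAResult",
    "CAPResult",
    "pcoa",
    "cap_constrained",
    "orient_ragweed_negative",
    "wa_affinity_scores",
]

EIG_RTOL = 1e-8  # eigenvalue retention threshold, relative to the largest


@dataclass
class PCoAResult:
    """Principal coordinates of a dissimilarity matrix.

    ``coordinates`` has one column per retained positive eigenvalue, each
    eigenvector scaled by the square root of its eigenvalue, so Euclidean
    distances among rows approximate the input dissimilarities.
    """

    ids: list[str]
    eigenvalues: np.ndarray
    coordinates: np.ndarray
    total_inertia: float


@dataclass
class CAPResult:
    """First (only) canonical axis of a binary-constrained PCoA.

    ``affinity_variance_fraction`` is the constrained eigenvalue over total
    inertia: the share of community turnover attributable to plant affinity.
    """

    ids: list[str]
    site_scores: np.ndarray
    constrained_eigenvalue: float
    total_inertia: float
    affinity_variance_fraction: float
    oriented: bool = False


def pcoa(dmat: DissimilarityMatrix) -> PCoAResult:
    """Classical (metric) multidimensional scaling via Gower centering.

    B = -1/2 * J D^(2) J with J the centering projector; eigenvalues below
    ``EIG_RTOL`` times the largest are dropped, as are negative ones.
    """
    d = dmat.d
    n = d.shape[0]
    b = d**2
    b -= b.mean(axis=0)
    b -= b.mean(axis=1)[:, None]
    b *= -0.5
    # b is symmetric up to rounding after double centering
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > EIG_RTOL * max(evals[0], 0.0)
    if not np.any(keep):
        raise ValidationError("no positive eigenvalues: degenerate dissimilarity matrix")
    evals, evecs = evals[keep], evecs[:, keep]
    coords = evecs * np.sqrt(evals)
    return PCoAResult(
        ids=list(dmat.ids),
        eigenvalues=evals,
        coordinates=coords,
        total_inertia=float(evals.sum()),
    )


def cap_constrained(pc: PCoAResult, constraint: Sequence[int] | np.ndarray) -> CAPResult:
    """Constrain principal coordinates on a binary factor.

    The PCoA coordinates are regressed on the centered indicator by least
    squares and the fitted values eigen-analyzed; a binary factor spans a
    one-dimensional constraint space, so exactly one canonical axis has a
    nonzero eigenvalue. Site scores are the projections of the (full) sample
    coordinates onto that axis.
    """
    x = np.asarray(constraint, dtype=float)
    if x.shape != (pc.coordinates.shape[0],):
        raise ValidationError("constraint length does not match the number of samples")
    if np.allclose(x, x[0]):
        raise ValidationError("constraint is constant: both plant levels must be present")
    xc = x - x.mean()
    y = pc.coordinates
    # rank-1 least squares fit: yhat = xc (xc'y) / (xc'xc)
    beta = xc @ y / (xc @ xc)
    yhat = np.outer(xc, beta)
    # eigen-analysis of the fitted cross-product; rank 1 by construction
    s = yhat.T @ yhat
    evals, evecs = np.linalg.eigh((s + s.T) / 2.0)
    k = int(np.argmax(evals))
    lam = float(evals[k])
    v = evecs[:, k]
    site_scores = y @ v
    lam = max(lam, 0.0)
    return CAPResult(
        ids=list(pc.ids),
        site_scores=site_scores,
        constrained_eigenvalue=lam,
        total_inertia=pc.total_inertia,
        affinity_variance_fraction=lam / pc.total_inertia,
    )


def orient_ragweed_negative(cap: CAPResult, meta: Sequence[PotMetadata]) -> CAPResult:
    """Flip the canonical axis, if needed, so ragweed pots score negative.

    Idempotent; an exact tie of the two group means leaves the axis as is.
    """
    plant_of = {m.pot_id: m.training_plant for m in meta}
    missing = [s for s in cap.ids if s not in plant_of]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:5]}")
    rag = np.array([plant_of[s] == "ragweed" for s in cap.ids])
    if not rag.any() or rag.all():
        raise ValidationError("orientation needs pots from both plants")
    if cap.site_scores[rag].mean() > cap.site_scores[~rag].mean():
        return replace(cap, site_scores=-cap.site_scores, oriented=True)
    return replace(cap, oriented=True)


def wa_affinity_scores(h: HellingerTable, site_scores: np.ndarray) -> np.ndarray:
    """Weighted-average OTU scores on the canonical axis: the affinity index.

    affinity_j = sum_i h_ij * u_i / sum_i h_ij, with u the site scores of the
    same pots. OTUs absent from every pot (zero column sum) get ``nan``.
    By convexity every finite affinity lies within [min(u), max(u)].
    """
    u = np.asarray(site_scores, dtype=float)
    if u.shape != (h.n_samples,):
        raise ValidationError("site score length does not match the table rows")
    w = h.values
    colsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        aff = (w.T @ u) / colsum
    aff[colsum == 0] = np.nan
    return aff
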