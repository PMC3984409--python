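"""First-component partial least squares regression: the effect index.

Plant dry biomass is modeled as a function of Hellinger-transformed community
composition with projection to latent structures (PLS) regression, using the
20 home + away pots of one plant in one trial. Only the first latent variable
is used: it is the direction in community space with maximal covariance with
biomass. The X-loadings of the OTUs on that latent variable are the index of
effect -- under the sign convention cov(t1, y) >= 0, a positive effect index
means the OTU tends to occur in pots with larger plants.

For a single component the solution is closed-form (and algorithm-invariant):
with column-centered X and centered y,

    w1 = X'y / ||X'y||        (unit weight vector)
    t1 = X w1                 (sample scores)
    p1 = X't1 / (t1't1)       (X-loadings = effect index)

Columns are centered but not scaled: Hellinger values already share a scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from psfscreen.data_model import ValidationError
from psfscreen.transforms import HellingerTable

__all__ = ["PLSRResult", "fit_plsr1", "effect_index"]


class NoCovarianceError(ValidationError):
    """y is orthogonal to every predictor column; the first component is undefined."""


@dataclass
class PLSRResult:
    otu_ids: list[str]
    weights_w1: np.ndarray
    loadings_p1: np.ndarray
    scores_t1: np.ndarray
    x_variance_fraction: float
    y_variance_fraction: float
    y_mean: float
    x_means: np.ndarray


def fit_plsr1(h: HellingerTable, y: np.ndarray) -> PLSRResult:
    """Fit the first PLS component of biomass on community composition.

    ``x_variance_fraction`` is the share of total (centered) community
    variance reconstructed by the rank-one model t1 p1'; it measures how much
    of the microbial turnover covaries with biomass. ``y_variance_fraction``
    is the squared correlation of t1 with y: the share of biomass variance
    the component explains.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (h.n_samples,):
        raise ValidationError("biomass vector length does not match the table rows")
    if h.n_samples < 3:
        raise ValidationError("need at least 3 samples")
    if np.allclose(y, y[0]):
        raise ValidationError("biomass is constant: no response variance to model")
    x_means = h.values.mean(axis=0)
    x = h.values - x_means
    y_mean = float(y.mean())
    yc = y - y_mean
    xty = x.T @ yc
    norm = np.linalg.norm(xty)
    if norm == 0.0:
        raise NoCovarianceError("biomass is orthogonal to every OTU column")
    w1 = xty / norm
    t1 = x @ w1
    tt = float(t1 @ t1)
    p1 = x.T @ t1 / tt
    x_total = float((x**2).sum())
    x_var = tt * float(p1 @ p1) / x_total
    r = float(t1 @ yc) / np.sqrt(tt * float(yc @ yc))
    return PLSRResult(
        otu_ids=list(h.otu_ids),
        weights_w1=w1,
        loadings_p1=p1,
        scores_t1=t1,
        x_variance_fraction=x_var,
        y_variance_fraction=r**2,
        y_mean=y_mean,
        x_means=x_means,
    )


def effect_index(plsr: PLSRResult) -> np.ndarray:
    """Per-OTU effect index: X-loadings on the first latent variable.

    OTU columns that were identically zero in the fitted pots have no
    information about biomass; their loading is reported as ``nan`` rather
    than a silent 0 (mirroring the affinity index for absent taxa).
    """
    eff = plsr.loadings_p1.copy()
    # an absent OTU has zero column variance: centered column identically 0
    absent = (plsr.x_means == 0.0) & (eff == 0.0)
    eff[absent] = np.nan
    return eff
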