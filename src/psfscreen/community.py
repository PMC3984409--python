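"""Whole-community statistics: multi-factor perMANOVA and NMDS.

The permutational MANOVA partitions the Gower-centered inner-product matrix of
a dissimilarity matrix into sequential (Type I) sums of squares for an ordered
list of model terms, computes a pseudo-F for each term against the residual,
and assesses significance by free permutation of observations. Term R-squared
values are SS_term / SS_total and are additive with the residual.

NMDS minimizes Kruskal stress-1 over k-dimensional configurations, with one
principal-coordinate-seeded start plus random restarts; the returned
configuration is centered and principal-axis rotated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from psfscreen.data_model import DissimilarityMatrix, PotMetadata, ValidationError
from psfscreen.ordination import pcoa

__all__ = ["PermanovaTable", "NMDSResult", "permanova", "permanova_from_metadata", "nmds"]

DEFAULT_TERMS = (
    ("trial",),
    ("training",),
    ("final",),
    ("trial", "training"),
    ("trial", "final"),
    ("training", "final"),
    ("trial", "training", "final"),
)


@dataclass
class PermanovaTable:
    table: pd.DataFrame  # rows: terms + Residual + Total
    n_perm: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


@dataclass
class NMDSResult:
    ids: list[str]
    coordinates: np.ndarray
    stress: float
    converged: bool
    n_starts: int


def _gower(d: np.ndarray) -> np.ndarray:
    b = d.astype(float) ** 2
    b -= b.mean(axis=0)
    b -= b.mean(axis=1)[:, None]
    return -0.5 * b


def _dummy(levels: Sequence[str]) -> np.ndarray:
    uniq = sorted(set(levels))
    idx = {u: i for i, u in enumerate(uniq)}
    x = np.zeros((len(levels), len(uniq)))
    for i, v in enumerate(levels):
        x[i, idx[v]] = 1.0
    return x


def _term_block(factors: Mapping[str, Sequence[str]], term: Sequence[str]) -> np.ndarray:
    combo = list(zip(*(factors[f] for f in term)))
    return _dummy(["\x1f".join(c) for c in combo])


def _sequential_basis(
    factors: Mapping[str, Sequence[str]], terms: Sequence[Sequence[str]], n: int
) -> tuple[np.ndarray, list[slice], list[int]]:
    """Orthonormal bases for each term, sequentially orthogonalized."""
    cols = [np.full((n, 1), 1.0 / np.sqrt(n))]
    slices, dfs = [], []
    start = 0  # offset excluding the intercept column
    for term in terms:
        b = _term_block(factors, term)
        scale = np.linalg.norm(b)
        prev = np.hstack(cols)
        b = b - prev @ (prev.T @ b)
        b = b - prev @ (prev.T @ b)  # second pass guards orthogonality
        u, s, _ = np.linalg.svd(b, full_matrices=False)
        rank = int((s > 1e-8 * scale).sum())  # relative to the un-projected block
        if rank == 0:
            name = ":".join(term)
            raise ValidationError(f"term {name!r} is aliased with preceding terms")
        q = u[:, :rank]
        cols.append(q)
        slices.append(slice(start, start + rank))
        dfs.append(rank)
        start += rank
    basis = np.hstack(cols[1:])  # drop intercept; G is already centered
    return basis, slices, dfs


def permanova(
    dmat: DissimilarityMatrix,
    factors: Mapping[str, Sequence[str]],
    terms: Sequence[Sequence[str]] = DEFAULT_TERMS,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermanovaTable:
    """Sequential-SS permutational MANOVA on a dissimilarity matrix.

    Parameters
    ----------
    factors : mapping factor name -> per-sample level labels, aligned with
        ``dmat.ids``.
    terms : ordered model terms, each a tuple of factor names (interactions
        as multi-factor tuples). Single-level factors in ``terms`` that add
        no model dimension raise a ``ValidationError`` naming the term.
    n_perm : permutations for the p-values; the estimator is
        (1 + #{F_perm >= F_obs}) / (1 + n_perm), so p is never 0.
    """
    n = dmat.n
    for name, lv in factors.items():
        if len(lv) != n:
            raise ValidationError(f"factor {name!r} has {len(lv)} labels for {n} samples")
    # terms containing a constant factor add no model dimension; drop them
    terms = [tuple(t) for t in terms if all(len(set(factors[f])) > 1 for f in t)]
    if not terms:
        raise ValidationError("no non-constant model terms")
    g = _gower(dmat.d)
    ss_total = float(np.trace(g))
    basis, slices, dfs = _sequential_basis(factors, terms, n)

    def term_ss(gmat: np.ndarray) -> np.ndarray:
        t = gmat @ basis
        per_col = np.einsum("ij,ij->j", basis, t)
        return np.array([per_col[s].sum() for s in slices])

    ss = term_ss(g)
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValidationError("saturated model: no residual degrees of freedom")
    ss_res = ss_total - ss.sum()
    ms_res = ss_res / df_res
    f_obs = (ss / np.array(dfs)) / ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ssp = term_ss(gp)
        msp_res = (ss_total - ssp.sum()) / df_res
        fp = (ssp / np.array(dfs)) / msp_res
        exceed += fp >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    names = [":".join(t) for t in terms]
    rows = []
    for name, df, s, f, p in zip(names, dfs, ss, f_obs, pvals):
        rows.append((name, df, s, f, s / ss_total, p))
    rows.append(("Residual", df_res, ss_res, np.nan, ss_res / ss_total, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, 1.0, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "ss", "pseudo_F", "r_squared", "p_value"]
    ).set_index("term")
    return PermanovaTable(table=table, n_perm=n_perm)


def permanova_from_metadata(
    dmat: DissimilarityMatrix,
    meta: Sequence[PotMetadata],
    n_perm: int = 1000,
    seed: int = 0,
    terms: Sequence[Sequence[str]] = DEFAULT_TERMS,
) -> PermanovaTable:
    """Three-way trial x training x final perMANOVA from pot metadata."""
    by_id = {m.pot_id: m for m in meta}
    missing = [s for s in dmat.ids if s not in by_id]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:5]}")
    factors = {
        "trial": [by_id[s].trial_id for s in dmat.ids],
        "training": [by_id[s].training_plant for s in dmat.ids],
        "final": [by_id[s].final_plant for s in dmat.ids],
    }
    return permanova(dmat, factors, terms=terms, n_perm=n_perm, seed=seed)


def kruskal_stress1(d: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against dissimilarities.

    Disparities are the isotonic (primary/weak ties) regression of
    configuration distances on the dissimilarities.
    """
    iu = np.triu_indices_from(d, k=1)
    dvec = d[iu]
    dc = pdist(coords)
    order = np.argsort(dvec, kind="stable")
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(dc)
    dhat[order] = iso.fit_transform(dvec[order], dc[order])
    denom = float((dc**2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(((dc - dhat) ** 2).sum() / denom))


def nmds(
    dmat: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> NMDSResult:
    """Nonmetric multidimensional scaling, best of several starts.

    The first start is seeded with the k leading principal coordinates; the
    remaining ``n_starts - 1`` use random configurations. The start with the
    lowest Kruskal stress-1 is kept; its configuration is centered and
    rotated onto its principal axes.
    """
    n = dmat.n
    if n < k + 2:
        raise ValidationError(f"need at least k + 2 = {k + 2} samples")
    d = dmat.d
    iu = np.triu_indices(n, k=1)
    if np.allclose(d[iu], d[iu][0]):
        warnings.warn("all dissimilarities equal: NMDS configuration is degenerate", stacklevel=2)
    pc = pcoa(dmat)
    init0 = np.zeros((n, k))
    m = min(k, pc.coordinates.shape[1])
    init0[:, :m] = pc.coordinates[:, :m]

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, bool] | None = None
    for s in range(n_starts):
        init = init0 if s == 0 else rng.normal(size=(n, k))
        coords, _, n_iter = smacof(
            d,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            random_state=0,
            normalized_stress=True,
            return_n_iter=True,
        )
        stress = kruskal_stress1(d, coords)
        converged = n_iter < max_iter
        if best is None or stress < best[0]:
            best = (stress, coords, converged)
    stress, coords, converged = best
    coords = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    return NMDSResult(
        ids=list(dmat.ids),
        coordinates=coords,
        stress=stress,
        converged=converged,
        n_starts=n_starts,
    )
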