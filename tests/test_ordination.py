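import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa as skbio_pcoa

from psfscreen.data_model import DissimilarityMatrix, PotMetadata, ValidationError
from psfscreen.ordination import (
    cap_constrained,
    orient_ragweed_negative,
    pcoa,
    wa_affinity_scores,
)
from psfscreen.transforms import bray_curtis, hellinger
from tests.conftest import random_table


def dmat_from_points(points):
    d = squareform(pdist(np.atleast_2d(points)))
    return DissimilarityMatrix([f"s{i}" for i in range(d.shape[0])], d)


class TestPCoA:
    def test_collinear_points(self):
        pc = pcoa(dmat_from_points(np.array([[0.0], [1.0], [2.0]])))
        np.testing.assert_allclose(pc.eigenvalues, [2.0], atol=1e-12)
        coords = pc.coordinates[:, 0]
        sign = np.sign(coords[2]) or 1.0
        np.testing.assert_allclose(sign * coords, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_equilateral_simplex(self):
        n = 5
        d = np.full((n, n), 0.7)
        np.fill_diagonal(d, 0.0)
        pc = pcoa(DissimilarityMatrix([f"s{i}" for i in range(n)], d))
        assert pc.eigenvalues.shape == (n - 1,)
        np.testing.assert_allclose(pc.eigenvalues, pc.eigenvalues[0], rtol=1e-10)

    def test_euclidean_reconstruction(self, rng):
        pts = rng.normal(size=(9, 4))
        pc = pcoa(dmat_from_points(pts))
        np.testing.assert_allclose(
            squareform(pdist(pc.coordinates)), squareform(pdist(pts)), atol=1e-9
        )

    def test_matches_skbio_on_bray_curtis(self, rng):
        """Eigenvalues and total inertia agree with an independent PCoA."""
        t = random_table(rng, n=12, m=30)
        d = bray_curtis(hellinger(t))
        pc = pcoa(d)
        ref = skbio_pcoa(d.d, number_of_dimensions=0)
        ref_pos = ref.eigvals[ref.eigvals > 1e-8 * ref.eigvals.max()].to_numpy()
        np.testing.assert_allclose(np.sort(pc.eigenvalues), np.sort(ref_pos), atol=1e-8)
        # coordinates agree up to per-axis sign where eigenvalues are distinct
        k = min(3, pc.coordinates.shape[1])
        for j in range(k):
            a = pc.coordinates[:, j]
            b = ref.samples.to_numpy()[:, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-7

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValidationError):
            DissimilarityMatrix(["a", "b"], [[0.0, 0.3], [0.2, 0.0]])


class TestCAP:
    def test_coincident_centroids_no_separation(self):
        pts = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        pc = pcoa(dmat_from_points(pts))
        cap = cap_constrained(pc, [0, 0, 1, 1])
        # both group centroids coincide at the origin
        assert cap.constrained_eigenvalue == pytest.approx(0.0, abs=1e-12)

    def test_aligned_axis_variance_fraction(self):
        # group separation purely along the first coordinate axis
        pts = np.array([[0.0, 0.3], [0.2, -0.3], [4.0, 0.3], [4.2, -0.3]])
        pc = pcoa(dmat_from_points(pts))
        cap = cap_constrained(pc, [0, 0, 1, 1])
        assert 0.0 < cap.affinity_variance_fraction < 1.0
        # brute force: SS of fitted values over total inertia
        y = pc.coordinates
        x = np.array([0.0, 0, 1, 1]) - 0.5
        yhat = np.outer(x, x @ y / (x @ x))
        np.testing.assert_allclose(
            cap.constrained_eigenvalue, np.linalg.eigvalsh(yhat.T @ yhat).max(), atol=1e-10
        )

    def test_site_scores_match_dense_oracle(self, rng):
        t = random_table(rng, n=8, m=20)
        pc = pcoa(bray_curtis(hellinger(t)))
        g = np.array([0, 1, 0, 1, 1, 0, 1, 0], dtype=float)
        cap = cap_constrained(pc, g)
        # independent dense-algebra reconstruction via explicit hat matrix
        x = (g - g.mean())[:, None]
        hat = x @ np.linalg.inv(x.T @ x) @ x.T
        yhat = hat @ pc.coordinates
        evals, evecs = np.linalg.eigh(yhat.T @ yhat)
        v = evecs[:, np.argmax(evals)]
        expected = pc.coordinates @ v
        assert cap.constrained_eigenvalue == pytest.approx(evals.max(), abs=1e-10)
        assert min(
            np.abs(cap.site_scores - expected).max(), np.abs(cap.site_scores + expected).max()
        ) < 1e-10

    def test_equals_rda_on_euclidean_distances(self, rng):
        """On Euclidean distances, constrained inertia equals the RDA fitted SS."""
        pts = rng.normal(size=(10, 5))
        g = np.array([0] * 5 + [1] * 5, dtype=float)
        pc = pcoa(dmat_from_points(pts))
        cap = cap_constrained(pc, g)
        z = pts - pts.mean(axis=0)
        x = (g - g.mean())[:, None]
        zhat = x @ np.linalg.lstsq(x, z, rcond=None)[0]
        np.testing.assert_allclose(cap.constrained_eigenvalue, (zhat**2).sum(), rtol=1e-10)

    def test_constant_constraint_rejected(self, rng):
        pc = pcoa(dmat_from_points(rng.normal(size=(5, 2))))
        with pytest.raises(ValidationError, match="constant"):
            cap_constrained(pc, [1, 1, 1, 1, 1])


def _meta_for(ids, plants):
    return [PotMetadata(s, "T01", p, p, 1.0) for s, p in zip(ids, plants)]


class TestOrientation:
    def test_flips_when_ragweed_positive(self):
        cap_like = cap_constrained(
            pcoa(dmat_from_points(np.array([[1.0], [1.1], [-1.0], [-1.1]]))), [0, 0, 1, 1]
        )
        meta = _meta_for(cap_like.ids, ["ragweed", "ragweed", "sunflower", "sunflower"])
        oriented = orient_ragweed_negative(cap_like, meta)
        rag_mean = oriented.site_scores[:2].mean()
        sun_mean = oriented.site_scores[2:].mean()
        assert rag_mean < sun_mean

    def test_idempotent(self):
        cap_like = cap_constrained(
            pcoa(dmat_from_points(np.array([[1.0], [1.1], [-1.0], [-1.1]]))), [0, 0, 1, 1]
        )
        meta = _meta_for(cap_like.ids, ["ragweed", "ragweed", "sunflower", "sunflower"])
        once = orient_ragweed_negative(cap_like, meta)
        twice = orient_ragweed_negative(once, meta)
        np.testing.assert_array_equal(once.site_scores, twice.site_scores)

    def test_tie_means_no_flip(self):
        cap_like = cap_constrained(
            pcoa(dmat_from_points(np.array([[1.0], [-1.0], [1.0 + 1e-9], [-1.0 - 1e-9]]))),
            [0, 1, 0, 1],
        )
        # symmetric scores, alternating plants -> equal means
        meta = _meta_for(cap_like.ids, ["ragweed", "ragweed", "sunflower", "sunflower"])
        before = cap_like.site_scores.copy()
        rag_mean = before[:2].mean()
        sun_mean = before[2:].mean()
        if rag_mean <= sun_mean:  # already oriented or tied: unchanged
            after = orient_ragweed_negative(cap_like, meta)
            np.testing.assert_array_equal(after.site_scores, before)


class TestWeightedAverageScores:
    def test_single_pot_otu_gets_pot_score(self, rng):
        t = random_table(rng, n=6, m=8)
        t.values[:, 3] = 0.0
        t.values[2, 3] = 50.0
        h = hellinger(t)
        u = rng.normal(size=6)
        aff = wa_affinity_scores(h, u)
        assert aff[3] == pytest.approx(u[2], abs=1e-12)

    def test_uniform_otu_gets_weighted_mean(self):
        from psfscreen.data_model import OTUTable

        vals = np.full((4, 2), 3.0)
        t = OTUTable([f"s{i}" for i in range(4)], ["A", "B"], vals, "bacteria", "T")
        h = hellinger(t)
        u = np.array([-1.0, -0.5, 0.5, 1.0])  # centered scores
        aff = wa_affinity_scores(h, u)
        assert aff[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        t = random_table(rng, n=10, m=40)
        h = hellinger(t)
        u = rng.normal(size=10)
        aff = wa_affinity_scores(h, u)
        for j in range(h.n_otus):
            w = h.values[:, j]
            if w.sum() == 0:
                assert np.isnan(aff[j])
            else:
                assert aff[j] == pytest.approx((w * u).sum() / w.sum(), abs=1e-12)

    def test_convexity_bounds(self, rng):
        t = random_table(rng, n=15, m=60)
        h = hellinger(t)
        u = rng.normal(size=15)
        aff = wa_affinity_scores(h, u)
        finite = aff[np.isfinite(aff)]
        assert finite.min() >= u.min() - 1e-12
        assert finite.max() <= u.max() + 1e-12

    def test_absent_otu_is_missing(self, rng):
        t = random_table(rng, n=5, m=6)
        t.values[:, 4] = 0.0
        aff = wa_affinity_scores(hellinger(t), np.arange(5.0))
        assert np.isnan(aff[4]) and np.isfinite(np.delete(aff, 4)).all()
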