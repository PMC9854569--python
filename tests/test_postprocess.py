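import numpy as np
import pytest

from spcnet.geometry import StarPolygon, polygon_iou
from spcnet.postprocess import (
    PostprocessConfig,
    ProposalSet,
    extract_proposals,
    object_density,
    pa_nms,
    proposal_density,
    segment_image,
)


def simulate_algorithm(polygons, scores, densities, Nt):
    """Literal list-based simulation of the adaptive NMS pseudocode."""
    B = list(polygons)
    S = list(scores)
    D = list(densities)
    F, FS = [], []
    while B:
        m = int(np.argmax(S))
        M, s, dM = B[m], S[m], D[m]
        NM = max(Nt, dM)
        F.append(M)
        FS.append(s)
        del B[m], S[m], D[m]
        keep = [i for i, p in enumerate(B) if polygon_iou(M, p) < NM]
        B = [B[i] for i in keep]
        S = [S[i] for i in keep]
        D = [D[i] for i in keep]
    return F, FS


def make_set(polygons, scores, densities=None):
    return ProposalSet(
        centers=np.array([p.center for p in polygons]),
        dists=np.array([p.distances for p in polygons]),
        scores=np.array(scores),
        densities=None if densities is None else np.array(densities),
    )


def random_proposals(rng, n, span=30.0, n_rays=8):
    polys, scores = [], []
    for _ in range(n):
        center = tuple(rng.uniform(5, span, 2))
        polys.append(StarPolygon(center, rng.uniform(1.0, 6.0, n_rays)))
        scores.append(float(rng.uniform(0.3, 1.0)))
    return polys, scores


class TestExtractProposals:
    def test_all_below_threshold(self):
        prob = np.full((8, 8), 0.1)
        dist = np.ones((8, 8, 4))
        ps = extract_proposals(prob, dist)
        assert len(ps) == 0

    def test_single_pixel(self):
        prob = np.zeros((8, 8))
        prob[3, 5] = 0.9
        dist = np.arange(8 * 8 * 4, dtype=float).reshape(8, 8, 4)
        ps = extract_proposals(prob, dist)
        assert len(ps) == 1
        assert ps.scores[0] == pytest.approx(0.9)
        np.testing.assert_array_equal(ps.centers[0], [3, 5])
        np.testing.assert_array_equal(ps.dists[0], dist[3, 5])

    def test_count_matches_threshold(self, rng):
        prob = rng.random((16, 16))
        dist = rng.random((16, 16, 4)) * 5
        ps = extract_proposals(prob, dist, prob_threshold=0.3, top_k=None)
        assert len(ps) == int(np.count_nonzero(prob >= 0.3))

    def test_sorted_and_truncated(self, rng):
        prob = rng.random((16, 16))
        dist = rng.random((16, 16, 4)) * 5
        ps = extract_proposals(prob, dist, prob_threshold=0.1, top_k=20)
        assert len(ps) == 20
        assert (np.diff(ps.scores) <= 0).all()

    def test_misaligned(self):
        with pytest.raises(ValueError):
            extract_proposals(np.zeros((4, 4)), np.zeros((5, 4, 8)))


class TestDensity:
    def test_singleton_zero(self):
        ps = make_set([StarPolygon((5, 5), np.full(8, 2.0))], [0.9])
        np.testing.assert_array_equal(proposal_density(ps), [0.0])

    def test_identical_pair(self):
        p = StarPolygon((5.0, 5.0), np.full(8, 2.0))
        ps = make_set([p, StarPolygon(p.center, p.distances)], [0.9, 0.8])
        np.testing.assert_allclose(proposal_density(ps), [1.0, 1.0], atol=1e-9)

    def test_three_polygons_vs_exhaustive(self):
        polys = [
            StarPolygon((10.0, 10.0), np.full(8, 4.0)),
            StarPolygon((10.0, 13.0), np.full(8, 4.0)),
            StarPolygon((30.0, 30.0), np.full(8, 3.0)),
        ]
        ps = make_set(polys, [0.9, 0.8, 0.7])
        dens = proposal_density(ps)
        expected = [
            max(polygon_iou(polys[i], polys[j]) for j in range(3) if j != i) for i in range(3)
        ]
        np.testing.assert_allclose(dens, expected, atol=1e-9)

    def test_random_vs_exhaustive(self, rng):
        polys, scores = random_proposals(rng, 12)
        ps = make_set(polys, scores)
        dens = proposal_density(ps)
        n = len(polys)
        expected = [
            max(polygon_iou(polys[i], polys[j]) for j in range(n) if j != i) for i in range(n)
        ]
        np.testing.assert_allclose(dens, expected, atol=1e-7)


class TestObjectDensity:
    def test_singleton_zero(self):
        ps = make_set([StarPolygon((5, 5), np.full(8, 2.0))], [0.9])
        np.testing.assert_array_equal(object_density(ps), [0.0])

    def test_isolated_cells_near_zero(self):
        polys = [StarPolygon((10.0 * i + 6, 6.0), np.full(8, 2.0)) for i in range(4)]
        ps = make_set(polys, [0.9, 0.8, 0.7, 0.6])
        assert object_density(ps).max() == pytest.approx(0.0, abs=1e-9)

    def test_duplicates_of_one_object_stay_low(self):
        # many near-duplicates of a single cell: pairwise density saturates,
        # object density must not (there is no *other* object)
        base = StarPolygon((10.0, 10.0), np.full(8, 5.0))
        polys = [StarPolygon((10.0 + 0.2 * i, 10.0), base.distances) for i in range(10)]
        ps = make_set(polys, list(np.linspace(0.9, 0.5, 10)))
        assert proposal_density(ps).min() > 0.9
        assert object_density(ps, Nt=0.4).max() < 0.4

    def test_straddling_proposal_sees_neighbor(self):
        # two crowded objects plus a proposal overlapping both
        a = StarPolygon((10.0, 10.0), np.full(8, 5.0))
        b = StarPolygon((10.0, 17.0), np.full(8, 5.0))
        straddle = StarPolygon((10.0, 13.5), np.full(8, 5.0))
        ps = make_set([a, b, straddle], [0.9, 0.85, 0.5])
        dens = object_density(ps, Nt=0.4)
        assert dens[2] > 0.2  # runner-up object overlap registered


class TestPANMS:
    def test_invalid_nt(self):
        ps = make_set([StarPolygon((2, 2), np.ones(4))], [0.5], [0.0])
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                pa_nms(ps, Nt=bad)

    def test_disjoint_all_kept_sorted(self, rng):
        polys = [StarPolygon((10.0 * i + 5, 5.0), np.full(6, 2.0)) for i in range(5)]
        scores = [0.4, 0.9, 0.6, 0.8, 0.5]
        kept = pa_nms(make_set(polys, scores, [0.0] * 5), Nt=0.4)
        assert len(kept) == 5
        np.testing.assert_allclose(kept.scores, sorted(scores, reverse=True))

    def test_identical_duplicates_adaptive_threshold(self):
        # densities 1.0 raise N_M to 1.0; IoU 1.0 >= 1.0 still suppresses
        p = StarPolygon((5.0, 5.0), np.full(8, 2.0))
        ps = make_set([p, StarPolygon(p.center, p.distances)], [0.9, 0.8], [1.0, 1.0])
        kept = pa_nms(ps, Nt=0.4)
        assert len(kept) == 1
        assert kept.scores[0] == pytest.approx(0.9)

    def test_low_density_equals_standard_nms(self, rng):
        polys, scores = random_proposals(rng, 15)
        ps = make_set(polys, scores, [0.0] * 15)  # densities <= Nt
        kept = pa_nms(ps, Nt=0.4)
        ref_polys, ref_scores = simulate_algorithm(polys, scores, [0.0] * 15, 0.4)
        assert len(kept) == len(ref_polys)
        np.testing.assert_allclose(kept.scores, ref_scores)
        for i, p in enumerate(ref_polys):
            np.testing.assert_allclose(kept.centers[i], p.center)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_literal_simulation(self, seed):
        rng = np.random.default_rng(seed)
        polys, scores = random_proposals(rng, 20, span=25.0)
        ps = make_set(polys, scores)
        dens = proposal_density(ps)
        ps.densities = dens
        kept = pa_nms(ps, Nt=0.4)
        ref_polys, ref_scores = simulate_algorithm(polys, scores, list(dens), 0.4)
        assert len(kept) == len(ref_polys)
        np.testing.assert_allclose(kept.scores, ref_scores, atol=1e-12)
        for i, p in enumerate(ref_polys):
            np.testing.assert_allclose(kept.centers[i], p.center, atol=1e-12)
            np.testing.assert_allclose(kept.dists[i], p.distances, atol=1e-12)

    def test_score_tie_broken_by_lower_index(self):
        a = StarPolygon((5.0, 5.0), np.full(8, 3.0))
        b = StarPolygon((5.0, 6.0), np.full(8, 3.0))
        ps = make_set([a, b], [0.7, 0.7], [0.0, 0.0])
        kept = pa_nms(ps, Nt=0.4)
        assert len(kept) == 1
        np.testing.assert_allclose(kept.centers[0], a.center)

    def test_subset_and_ordering_property(self, rng):
        polys, scores = random_proposals(rng, 25)
        ps = make_set(polys, scores)
        ps.densities = proposal_density(ps)
        kept = pa_nms(ps, Nt=0.4)
        assert len(kept) <= len(ps)
        assert (np.diff(kept.scores) <= 1e-12).all()
        in_scores = set(np.round(ps.scores, 12))
        assert all(round(s, 12) in in_scores for s in kept.scores)

    def test_nt_monotonicity(self, rng):
        polys, scores = random_proposals(rng, 20)
        ps = make_set(polys, scores, [0.0] * 20)
        sizes = [len(pa_nms(ps, Nt=nt)) for nt in (0.2, 0.4, 0.6, 0.8)]
        assert sizes == sorted(sizes)

    def test_idempotent_with_carried_densities(self, rng):
        # with unchanged densities the second pass sees the same thresholds and
        # every surviving pair already cleared them
        polys, scores = random_proposals(rng, 20)
        ps = make_set(polys, scores)
        ps.densities = proposal_density(ps)
        kept = pa_nms(ps, Nt=0.4)
        again = pa_nms(kept, Nt=0.4)
        assert len(again) == len(kept)
        np.testing.assert_allclose(again.scores, kept.scores)
        np.testing.assert_allclose(again.centers, kept.centers)

    def test_idempotent_in_standard_regime_with_recomputation(self, rng):
        # densities on a subset only shrink, so when the originals were already
        # <= Nt the recomputed ones are too and both passes reduce to NMS(Nt)
        polys, scores = random_proposals(rng, 20)
        ps = make_set(polys, scores, [0.0] * 20)
        kept = pa_nms(ps, Nt=0.4)
        dens2 = proposal_density(kept)
        assert (dens2 <= 0.4 + 1e-12).all()
        again = pa_nms(ProposalSet(kept.centers, kept.dists, kept.scores, dens2), Nt=0.4)
        assert len(again) == len(kept)
        np.testing.assert_allclose(again.scores, kept.scores)


class _StubModel:
    """Stands in for a network: predict() returns canned maps."""

    def __init__(self, prob, dist):
        self._prob, self._dist = prob, dist

    def predict(self, image):
        return self._prob, self._dist


class TestSegmentImage:
    def test_blank_image(self):
        model = _StubModel(np.zeros((32, 32)), np.zeros((32, 32, 8)))
        labels, kept = segment_image(model, np.zeros((32, 32)))
        assert labels.shape == (32, 32)
        assert not labels.any()
        assert len(kept) == 0

    def test_two_cells_segmented(self):
        prob = np.zeros((40, 40))
        dist = np.zeros((40, 40, 8))
        for center in ((10, 10), (28, 28)):
            prob[center] = 0.95
            dist[center[0], center[1], :] = 6.0
        model = _StubModel(prob, dist)
        labels, kept = segment_image(model, np.zeros((40, 40)))
        assert len(kept) == 2
        assert set(np.unique(labels)) == {0, 1, 2}
        assert labels[10, 10] == 1 or labels[10, 10] == 2

    def test_score_rank_wins_contested_pixels(self):
        prob = np.zeros((30, 30))
        dist = np.zeros((30, 30, 8))
        prob[15, 13], prob[15, 17] = 0.6, 0.9
        dist[15, 13, :] = 5.0
        dist[15, 17, :] = 5.0
        model = _StubModel(prob, dist)
        cfg = PostprocessConfig(nt=0.4)
        labels, kept = segment_image(model, np.zeros((30, 30)), cfg)
        if len(kept) == 2:  # if not suppressed, overlap pixels belong to id 1 (higher score)
            assert labels[15, 16] == 1
            assert kept.scores[0] == pytest.approx(0.9)

    def test_pairwise_density_mode_and_bad_mode(self):
        prob = np.zeros((30, 30))
        dist = np.zeros((30, 30, 8))
        prob[10, 10] = 0.9
        dist[10, 10, :] = 4.0
        model = _StubModel(prob, dist)
        labels, kept = segment_image(model, np.zeros((30, 30)), PostprocessConfig(density="pairwise"))
        assert len(kept) == 1 and labels.max() == 1
        with pytest.raises(ValueError):
            segment_image(model, np.zeros((30, 30)), PostprocessConfig(density="bogus"))

    def test_standard_nms_mode(self):
        prob = np.zeros((30, 30))
        dist = np.zeros((30, 30, 8))
        prob[10, 10], prob[10, 11] = 0.9, 0.8
        dist[10, 10, :] = 5.0
        dist[10, 11, :] = 5.0
        model = _StubModel(prob, dist)
        _, kept = segment_image(model, np.zeros((30, 30)), PostprocessConfig(use_pa_nms=False))
        assert len(kept) == 1  # near-duplicate suppressed at Nt

    def test_every_kept_id_present_unless_occluded(self, rng):
        prob = (rng.random((32, 32)) > 0.97) * rng.uniform(0.5, 1.0, (32, 32))
        dist = rng.uniform(2, 5, (32, 32, 8))
        model = _StubModel(prob, dist)
        labels, kept = segment_image(model, np.zeros((32, 32)))
        present = set(np.unique(labels)) - {0}
        assert present <= set(range(1, len(kept) + 1))
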