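"""Decode network outputs into polygon proposals and suppress duplicates.

Every pixel whose predicted object probability clears a threshold proposes the
star polygon written in its distance channels, scored by that probability.
Proposals are then filtered with polygon-based adaptive NMS: the greedy
suppression threshold for the current best proposal M is raised from the base
``Nt`` to ``max(Nt, d_M)``, where ``d_M`` is M's detection density, so crowded
true objects survive while duplicates on the same object are still removed.

Two density estimates are provided. :func:`proposal_density` is the raw
pairwise form, ``d_i = max_{j != i} IoU(b_i, b_j)``. With one proposal per
foreground pixel that form saturates near 1 (each proposal's nearest neighbor
is its own near-duplicate at the adjacent pixel), which disables adaptive
suppression; :func:`object_density` therefore estimates crowding at the object
level — the IoU of a proposal with the nearest *other* object, where objects
are approximated by a standard-NMS pass — and is what :func:`segment_image`
uses by default. No auxiliary density network is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.strtree import STRtree

from spcnet.geometry import StarPolygon, ray_directions

__all__ = [
    "ProposalSet",
    "extract_proposals",
    "proposal_density",
    "object_density",
    "pa_nms",
    "segment_image",
]


@dataclass
class ProposalSet:
    """Parallel arrays of star-polygon proposals (B), scores (S), densities (D)."""

    centers: np.ndarray  # (P, 2) float, (row, col)
    dists: np.ndarray  # (P, n_rays) float
    scores: np.ndarray  # (P,) float in [0, 1]
    densities: np.ndarray | None = None  # (P,) float in [0, 1]

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.float64))
        self.dists = np.atleast_2d(np.asarray(self.dists, dtype=np.float64))
        self.scores = np.atleast_1d(np.asarray(self.scores, dtype=np.float64))
        if self.densities is not None:
            self.densities = np.atleast_1d(np.asarray(self.densities, dtype=np.float64))
        n = len(self.scores)
        if self.centers.shape[0] != n or self.dists.shape[0] != n:
            raise ValueError("B, S (and D) must be parallel lists")
        if self.densities is not None and len(self.densities) != n:
            raise ValueError("B, S (and D) must be parallel lists")

    def __len__(self) -> int:
        return int(self.scores.size)

    @classmethod
    def empty(cls, n_rays: int) -> "ProposalSet":
        return cls(
            centers=np.zeros((0, 2)),
            dists=np.zeros((0, n_rays)),
            scores=np.zeros(0),
            densities=np.zeros(0),
        )

    def polygon(self, i: int) -> StarPolygon:
        return StarPolygon(tuple(self.centers[i]), self.dists[i], score=float(self.scores[i]))

    @property
    def polygons(self) -> list[StarPolygon]:
        return [self.polygon(i) for i in range(len(self))]

    def subset(self, indices) -> "ProposalSet":
        indices = np.asarray(indices)
        return ProposalSet(
            centers=self.centers[indices],
            dists=self.dists[indices],
            scores=self.scores[indices],
            densities=None if self.densities is None else self.densities[indices],
        )

    def geometries(self) -> np.ndarray:
        """Vectorized shapely polygons ((x, y) = (col, row)), validity-repaired."""
        if len(self) == 0:
            return np.empty(0, dtype=object)
        dirs = ray_directions(self.dists.shape[1])
        verts = self.centers[:, None, :] + self.dists[:, :, None] * dirs[None, :, :]
        xy = verts[:, :, ::-1]  # (P, n, 2) as (col, row)
        geoms = shapely.polygons(xy)
        bad = ~shapely.is_valid(geoms)
        if bad.any():
            geoms[bad] = shapely.make_valid(geoms[bad])
        return geoms


def extract_proposals(
    prob: np.ndarray,
    dist: np.ndarray,
    prob_threshold: float = 0.3,
    top_k: int | None = 5000,
) -> ProposalSet:
    """One scored star polygon per pixel with probability >= the threshold.

    Proposals are sorted by score descending (stable, so ties keep raster
    order) and truncated to ``top_k`` (None disables the cap).
    """
    prob = np.asarray(prob)
    dist = np.asarray(dist)
    if prob.shape != dist.shape[:2]:
        raise ValueError(f"prob {prob.shape} and dist {dist.shape} are misaligned")
    rows, cols = np.nonzero(prob >= prob_threshold)
    if rows.size == 0:
        return ProposalSet.empty(dist.shape[2])
    scores = prob[rows, cols].astype(np.float64)
    order = np.argsort(-scores, kind="stable")
    if top_k is not None:
        order = order[:top_k]
    rows, cols, scores = rows[order], cols[order], scores[order]
    return ProposalSet(
        centers=np.column_stack([rows, cols]).astype(np.float64),
        dists=dist[rows, cols, :].astype(np.float64),
        scores=np.clip(scores, 0.0, 1.0),
    )


def _pairwise_iou_sparse(geoms: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(i, j, iou) for all pairs with intersecting bounding geometry, i != j."""
    tree = STRtree(geoms)
    ii, jj = tree.query(geoms, predicate="intersects")
    keep = ii != jj
    ii, jj = ii[keep], jj[keep]
    if ii.size == 0:
        return ii, jj, np.zeros(0)
    areas = shapely.area(geoms)
    inter = shapely.area(shapely.intersection(geoms[ii], geoms[jj]))
    union = areas[ii] + areas[jj] - inter
    iou = np.where((union > 0) & (areas[ii] > 0) & (areas[jj] > 0), inter / np.maximum(union, 1e-300), 0.0)
    return ii, jj, np.clip(iou, 0.0, 1.0)


def proposal_density(ps: ProposalSet, geoms: np.ndarray | None = None) -> np.ndarray:
    """Per-proposal density: maximum IoU against any other proposal (0 for a
    singleton)."""
    n = len(ps)
    dens = np.zeros(n)
    if n < 2:
        return dens
    if geoms is None:
        geoms = ps.geometries()
    ii, _, iou = _pairwise_iou_sparse(geoms)
    np.maximum.at(dens, ii, iou)
    return dens


def _nms_survivors(
    geoms: np.ndarray, areas: np.ndarray, scores: np.ndarray, Nt: float
) -> list[int]:
    """Greedy standard NMS at a fixed threshold; returns kept indices."""
    n = len(scores)
    tree = STRtree(geoms)
    alive = np.ones(n, dtype=bool)
    kept: list[int] = []
    masked = np.where(np.isfinite(scores), scores, -np.inf)
    while alive.any():
        m = int(np.argmax(np.where(alive, masked, -np.inf)))
        kept.append(m)
        alive[m] = False
        if areas[m] == 0.0 or not alive.any():
            continue
        cand = tree.query(geoms[m], predicate="intersects")
        cand = cand[alive[cand]]
        if cand.size == 0:
            continue
        inter = shapely.area(shapely.intersection(geoms[m], geoms[cand]))
        union = areas[cand] + areas[m] - inter
        ok = (union > 0) & (areas[cand] > 0)
        iou = np.zeros(cand.size)
        iou[ok] = inter[ok] / union[ok]
        alive[cand[iou >= Nt]] = False
    return kept


def object_density(ps: ProposalSet, Nt: float = 0.4, geoms: np.ndarray | None = None) -> np.ndarray:
    """Object-level crowding: IoU of each proposal with the nearest other object.

    Objects are approximated by the survivors of a standard NMS pass at ``Nt``;
    for proposal i, ``d_i`` is its maximum IoU over those representatives
    excluding the one that best explains i (its own object). Isolated cells get
    ~0; proposals straddling adhered cells pick up the neighbor's overlap.
    """
    n = len(ps)
    dens = np.zeros(n)
    if n < 2:
        return dens
    if geoms is None:
        geoms = ps.geometries()
    areas = shapely.area(geoms)
    reps = _nms_survivors(geoms, areas, ps.scores.astype(np.float64), Nt)
    if len(reps) < 2:
        return dens
    rep_geoms = geoms[reps]
    rep_areas = areas[reps]
    tree = STRtree(rep_geoms)
    ii, rr = tree.query(geoms, predicate="intersects")  # (proposal, rep) pairs
    if ii.size == 0:
        return dens
    inter = shapely.area(shapely.intersection(geoms[ii], rep_geoms[rr]))
    union = areas[ii] + rep_areas[rr] - inter
    ok = (union > 0) & (areas[ii] > 0) & (rep_areas[rr] > 0)
    iou = np.zeros(ii.size)
    iou[ok] = inter[ok] / union[ok]
    # per proposal: best rep explains it; the runner-up measures crowding
    best = np.zeros(n)
    second = np.zeros(n)
    order = np.argsort(iou, kind="stable")
    for k in order:  # ascending, so the final assignments hold the two largest
        i = ii[k]
        if iou[k] >= best[i]:
            second[i] = best[i]
            best[i] = iou[k]
        elif iou[k] > second[i]:
            second[i] = iou[k]
    return second


def pa_nms(ps: ProposalSet, Nt: float = 0.4) -> ProposalSet:
    """Polygon-based adaptive NMS.

    Greedily pop the highest-score proposal M (score ties broken by lower
    index), adapt the threshold to ``N_M = max(Nt, d_M)``, and remove every
    remaining proposal whose polygon IoU with M is >= N_M. Returns the kept
    proposals in pop order (scores non-increasing).
    """
    if not 0.0 < Nt < 1.0:
        raise ValueError(f"Nt must be in (0, 1), got {Nt}")
    n = len(ps)
    if n == 0:
        return ps.subset(np.zeros(0, dtype=int))
    dens = ps.densities if ps.densities is not None else proposal_density(ps)
    geoms = ps.geometries()
    areas = shapely.area(geoms)
    tree = STRtree(geoms)
    alive = np.ones(n, dtype=bool)
    masked_scores = ps.scores.astype(np.float64).copy()
    kept: list[int] = []
    while alive.any():
        scores_view = np.where(alive, masked_scores, -np.inf)
        m = int(np.argmax(scores_view))  # argmax takes the lowest index on ties
        kept.append(m)
        alive[m] = False
        if not alive.any():
            break
        n_m = max(Nt, float(dens[m]))
        cand = tree.query(geoms[m], predicate="intersects")
        cand = cand[alive[cand]]
        if cand.size == 0 or areas[m] == 0.0:
            continue
        # keep the argument order of polygon_IoU(M, p): GEOS results can differ
        # in the last ulp between argument orders, and the adaptive threshold
        # N_M = d_M sits exactly on that boundary for M's densest partner
        inter = shapely.area(shapely.intersection(geoms[m], geoms[cand]))
        union = areas[cand] + areas[m] - inter
        ok = (union > 0) & (areas[cand] > 0)
        iou = np.zeros(cand.size)
        iou[ok] = inter[ok] / union[ok]
        alive[cand[np.clip(iou, 0.0, 1.0) >= n_m]] = False
    out = ps.subset(np.asarray(kept, dtype=int))
    if out.densities is None:
        out.densities = dens[np.asarray(kept, dtype=int)]
    return out


@dataclass
class PostprocessConfig:
    prob_threshold: float = 0.3
    nt: float = 0.4
    top_k: int | None = 5000
    use_pa_nms: bool = True  # False -> standard NMS at Nt (all densities 0)
    density: str = "object"  # "object" (crowding by other objects) or "pairwise"


def segment_image(model, image: np.ndarray, config: PostprocessConfig | None = None):
    """Full inference: forward pass, proposals, density, PA-NMS, label map.

    Kept polygons are rasterized in descending score order (earlier polygons
    win contested pixels) with instance ids 1..K assigned by rank. Returns
    ``(label_map, kept ProposalSet)``.
    """
    from spcnet.geometry import rasterize_polygon  # local import avoids cycle at module load

    cfg = config or PostprocessConfig()
    prob, dist = model.predict(image)
    labels = np.zeros(prob.shape, dtype=np.uint16)
    ps = extract_proposals(prob, dist, cfg.prob_threshold, cfg.top_k)
    if len(ps) == 0:
        return labels, ps
    if not cfg.use_pa_nms:
        ps.densities = np.zeros(len(ps))
    elif cfg.density == "object":
        ps.densities = object_density(ps, cfg.nt)
    elif cfg.density == "pairwise":
        ps.densities = proposal_density(ps)
    else:
        raise ValueError(f"unknown density mode: {cfg.density!r}")
    kept = pa_nms(ps, cfg.nt)
    for rank in range(len(kept)):
        mask = rasterize_polygon(kept.polygon(rank), labels.shape)
        labels[mask & (labels == 0)] = rank + 1
    return labels, kept
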