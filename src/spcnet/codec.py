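"""Encode instance label maps into network targets and decode them back.

Targets are an object probability map (per-instance normalized Euclidean
distance to the nearest background pixel) and an ``n_rays``-channel radial
distance map (per-pixel star-convex distance to the instance boundary). The
image border counts as background throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from spcnet.geometry import StarPolygon, ray_directions

__all__ = [
    "fill_holes",
    "object_probability_map",
    "radial_distance_maps",
    "encode_targets",
    "decode_pixel_polygon",
]

# Bisection iterations for the final ray-march step: 2^-7 < 0.01 px.
_REFINE_ITERS = 7


def fill_holes(labels: np.ndarray) -> np.ndarray:
    """Fill interior holes of every instance, preserving instance ids.

    A hole is a background region not connected to the image border through
    background; it is assigned the id of the instance enclosing it.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels must be a 2-D integer map")
    out = labels.copy()
    for k in np.unique(labels):
        if k == 0:
            continue
        filled = ndimage.binary_fill_holes(labels == k)
        out[filled & (out == 0)] = k
    return out


def object_probability_map(labels: np.ndarray, per_instance: bool = True) -> np.ndarray:
    """Per-pixel object probability: normalized EDT to the nearest background.

    Background pixels map to 0. Foreground pixel p of instance k maps to
    ``EDT(p) / max_{q in k} EDT(q)`` (per-instance normalization, so each cell
    attains probability 1 at its core); with ``per_instance=False`` the
    normalizer is the global EDT maximum. The image border counts as
    background.
    """
    labels = np.asarray(labels)
    fg = labels > 0
    if not fg.any():
        return np.zeros(labels.shape, dtype=np.float32)
    # pad with background so the border participates in the EDT
    padded = np.pad(fg, 1, mode="constant", constant_values=False)
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    prob = np.zeros(labels.shape, dtype=np.float32)
    if per_instance:
        ids = np.unique(labels[fg])
        maxima = ndimage.maximum(edt, labels=labels, index=ids)
        lut = np.zeros(int(labels.max()) + 1, dtype=np.float64)
        lut[ids] = maxima
        norm = lut[labels[fg]]
        prob[fg] = edt[fg] / norm
    else:
        prob[fg] = edt[fg] / edt[fg].max()
    return prob


def radial_distance_maps(labels: np.ndarray, n_rays: int = 32) -> np.ndarray:
    """Star-convex distance of every foreground pixel along each ray.

    From pixel p with id k, march along ray j in unit steps; the distance is
    the step length at the first sampled position whose nearest pixel does not
    carry id k (or that leaves the image), refined by bisection to < 0.01 px.
    Background pixels get all-zero rows. Returns ``(H, W, n_rays)`` float32.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    dirs = ray_directions(n_rays)
    dist = np.zeros((h, w, n_rays), dtype=np.float32)
    fg = labels > 0
    if not fg.any():
        return dist
    pts = np.argwhere(fg).astype(np.float64)  # (P, 2)
    ids = labels[fg]
    rows, cols = pts[:, 0], pts[:, 1]
    max_steps = int(np.ceil(np.hypot(h, w))) + 1

    def inside_same(r: np.ndarray, c: np.ndarray, want: np.ndarray) -> np.ndarray:
        """Whether sampled position (r, c) still lies on instance `want`."""
        ri = np.rint(r).astype(np.intp)
        ci = np.rint(c).astype(np.intp)
        ok = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
        res = np.zeros(r.shape, dtype=bool)
        if ok.any():
            res[ok] = labels[ri[ok], ci[ok]] == want[ok]
        return res

    for j in range(n_rays):
        dr, dc = dirs[j]
        exit_step = np.zeros(len(pts), dtype=np.float64)
        active = np.arange(len(pts))
        t = 1.0
        while active.size and t <= max_steps:
            same = inside_same(rows[active] + t * dr, cols[active] + t * dc, ids[active])
            exited = ~same
            exit_step[active[exited]] = t
            active = active[same]
            t += 1.0
        exit_step[active] = t  # ran off the sampling budget (cannot happen in-image)
        # bisection refinement on the final unit step
        lo = exit_step - 1.0
        hi = exit_step.copy()
        for _ in range(_REFINE_ITERS):
            mid = 0.5 * (lo + hi)
            same = inside_same(rows + mid * dr, cols + mid * dc, ids)
            lo = np.where(same, mid, lo)
            hi = np.where(same, hi, mid)
        dist[fg, j] = hi.astype(np.float32)
    return dist


def encode_targets(labels: np.ndarray, n_rays: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Fill holes, then compute the probability and radial-distance targets."""
    filled = fill_holes(labels)
    return object_probability_map(filled), radial_distance_maps(filled, n_rays)


def decode_pixel_polygon(
    prob: np.ndarray, dist: np.ndarray, pixel: tuple[int, int]
) -> StarPolygon:
    """The star polygon proposed by one pixel of a (prob, dist) encoding."""
    i, j = int(pixel[0]), int(pixel[1])
    score = float(np.clip(prob[i, j], 0.0, 1.0))
    return StarPolygon((float(i), float(j)), np.maximum(dist[i, j, :], 0.0), score=score)
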