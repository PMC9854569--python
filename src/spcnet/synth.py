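"""Seeded generator of adherent-cell images with instance ground truth.

Images mimic the structure the segmentation method targets: 256x256 grayscale
scenes of 3-9 circular-like cells with smoothly irregular outlines that may
touch (adhere) but never overlap, rendered as bright blobs with an interior
intensity gradient on a darker noisy background. Cells are parametric
star-convex polygons, so every instance is exactly representable by the label
codec.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from spcnet.geometry import StarPolygon, rasterize_polygon

__all__ = ["GeneratorConfig", "generate_cell", "generate_image", "generate_dataset"]


@dataclass
class GeneratorConfig:
    image_size: tuple[int, int] = (256, 256)
    cells_per_image: tuple[int, int] = (3, 9)
    radius_range: tuple[float, float] = (12.0, 40.0)
    irregularity: float = 0.25  # relative amplitude of the radial perturbation
    n_harmonics: int = 3
    n_rays: int = 64  # outline resolution of generated cells
    adhesion: bool = True
    p_adhere: float = 0.8  # chance a later cell is slid into contact
    background_level: float = 40.0
    cell_level_range: tuple[float, float] = (110.0, 170.0)
    cell_gradient_gain: float = 60.0
    noise_sd: float = 8.0
    max_retries: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_image[0] < 1:
            raise ValueError("minimum cells per image must be >= 1")
        if self.radius_range[0] <= 0:
            raise ValueError("radii must be positive")
        if not 0.0 <= self.irregularity < 1.0:
            raise ValueError("irregularity must be in [0, 1)")


def _smooth_perturbation(rng: np.random.Generator, n_rays: int, n_harmonics: int) -> np.ndarray:
    """Low-frequency periodic profile over angle, normalized to max |.| = 1."""
    theta = 2.0 * np.pi * np.arange(n_rays) / n_rays
    prof = np.zeros(n_rays)
    for k in range(1, n_harmonics + 1):
        amp = rng.uniform(0.3, 1.0) / k
        phase = rng.uniform(0.0, 2.0 * np.pi)
        prof += amp * np.cos(k * theta + phase)
    peak = np.abs(prof).max()
    return prof / peak if peak > 0 else prof


def generate_cell(
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
    center: tuple[float, float] | None = None,
) -> StarPolygon:
    """One random star-convex cell outline.

    Distances are ``r0 * (1 + a * s(theta))`` for a base radius r0 drawn from
    the configured range and a smooth periodic perturbation s with |s| <= 1,
    so all distances stay within ``[r0*(1-a), r0*(1+a)]`` and the polygon is
    star-convex about its center by construction.
    """
    cfg = config or GeneratorConfig()
    h, w = cfg.image_size
    r0 = rng.uniform(*cfg.radius_range)
    if center is None:
        margin = cfg.radius_range[0] * 0.5
        center = (rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin))
    perturb = _smooth_perturbation(rng, cfg.n_rays, cfg.n_harmonics)
    distances = r0 * (1.0 + cfg.irregularity * perturb)
    return StarPolygon(center, distances)


def _slide_into_contact(poly: StarPolygon, labels: np.ndarray, anchor: tuple[float, float]):
    """Step the polygon toward `anchor` until just before its mask overlaps."""
    shape = labels.shape
    occupied = labels > 0
    vec = np.asarray(anchor, dtype=np.float64) - np.asarray(poly.center)
    dist = np.hypot(*vec)
    if dist < 1e-6:
        return None
    step = vec / dist
    best = None
    center = np.asarray(poly.center, dtype=np.float64)
    for _ in range(int(dist) + 1):
        cand = StarPolygon(tuple(center), poly.distances)
        mask = rasterize_polygon(cand, shape)
        if not mask.any():
            return None
        if (mask & occupied).any():
            return best  # previous position was the last non-overlapping one
        best = (cand, mask)
        center = center + step
    return best


def generate_image(
    rng: np.random.Generator, config: GeneratorConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One grayscale image and its aligned instance label map.

    Cells are placed by rejection sampling; with adhesion enabled, later cells
    are slid toward an existing cell until their masks touch without sharing a
    pixel. Placement failure after the retry budget yields fewer cells, never
    an overlap.
    """
    cfg = config or GeneratorConfig()
    h, w = cfg.image_size
    labels = np.zeros((h, w), dtype=np.uint16)
    lo, hi = cfg.cells_per_image
    n_cells = int(rng.integers(lo, hi + 1))
    polygons: list[StarPolygon] = []
    next_id = 1
    for _ in range(n_cells):
        placed = False
        for _attempt in range(cfg.max_retries):
            poly = generate_cell(rng, cfg)
            adhere = cfg.adhesion and polygons and rng.random() < cfg.p_adhere
            if adhere:
                anchor = polygons[int(rng.integers(len(polygons)))]
                result = _slide_into_contact(poly, labels, anchor.center)
                if result is None:
                    continue
                poly, mask = result
            else:
                mask = rasterize_polygon(poly, (h, w))
            if not mask.any() or (mask & (labels > 0)).any():
                continue
            labels[mask] = next_id
            polygons.append(poly)
            next_id += 1
            placed = True
            break
        if not placed:
            continue

    image = np.full((h, w), cfg.background_level, dtype=np.float64)
    fg = labels > 0
    if fg.any():
        padded = np.pad(fg, 1, mode="constant")
        edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
        ids = np.unique(labels[fg])
        maxima = ndimage.maximum(edt, labels=labels, index=ids)
        lut = np.ones(int(labels.max()) + 1)
        lut[ids] = np.maximum(maxima, 1e-9)
        base = np.ones(int(labels.max()) + 1)
        base[ids] = rng.uniform(*cfg.cell_level_range, size=ids.size)
        image[fg] = base[labels[fg]] + cfg.cell_gradient_gain * (edt[fg] / lut[labels[fg]] - 0.5)
    image += rng.normal(0.0, cfg.noise_sd, size=(h, w))
    return np.clip(np.rint(image), 0, 255).astype(np.uint8), labels


def touching_pairs(labels: np.ndarray) -> int:
    """Number of instance pairs whose masks are within a 1-pixel dilation."""
    ids = [k for k in np.unique(labels) if k > 0]
    count = 0
    struct = np.ones((3, 3), dtype=bool)
    for idx, k in enumerate(ids):
        dil = ndimage.binary_dilation(labels == k, structure=struct)
        neigh = np.unique(labels[dil])
        count += sum(1 for j in neigh if j > k)
    return count


def generate_dataset(
    n_images: int,
    seed: int = 0,
    out_dir: str | Path | None = None,
    config: GeneratorConfig | None = None,
):
    """Generate ``n_images`` image/label pairs, optionally writing them to disk.

    With ``out_dir`` set, writes ``img_XXXX.tif`` (uint8), ``lbl_XXXX.tif``
    (uint16) and a ``manifest.csv`` of (filename, n_cells, seed); output is
    byte-reproducible from the seed. Returns the manifest rows and, when not
    writing, the in-memory pairs.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    manifest: list[tuple[str, int, int]] = []
    pairs = []
    writer = None
    if out_dir is not None:
        import tifffile

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        writer = tifffile
    for i in range(n_images):
        image, labels = generate_image(rng, cfg)
        n_cells = int(np.max(labels))
        name = f"img_{i:04d}.tif"
        if writer is not None:
            writer.imwrite(out_dir / name, image)
            writer.imwrite(out_dir / f"lbl_{i:04d}.tif", labels)
        else:
            pairs.append((image, labels))
        manifest.append((name, n_cells, seed))
    if out_dir is not None:
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["filename", "n_cells", "seed"])
            w.writerows(manifest)
        return manifest
    return manifest, pairs
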