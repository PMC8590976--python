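"""Polygon helpers: random blob generation and rasterization.

Coordinates are (x, y) in pixels throughout, matching image columns/rows.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import GeometryCollection, MultiPolygon, Polygon, box

__all__ = ["random_blob", "mask_from_geometry", "clip_to_canvas"]


def random_blob(center: tuple[float, float], mean_radius: float, rng: np.random.Generator,
                irregularity: float = 0.18, n_vertices: int = 64) -> Polygon:
    """A star-shaped simple polygon: a circle with low-order radial harmonics.

    Star-shapedness (radius perturbation well below 100%) guarantees the
    polygon is simple, which downstream rasterization relies on.
    """
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.full_like(theta, float(mean_radius))
    for k in (2, 3, 5):
        amp = irregularity * mean_radius * rng.uniform(0.3, 1.0) / k
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.2 * mean_radius, None)
    xs = center[0] + r * np.cos(theta)
    ys = center[1] + r * np.sin(theta)
    poly = Polygon(np.column_stack([xs, ys]))
    if not poly.is_valid:  # pragma: no cover - star-shaped blobs are simple
        poly = poly.buffer(0)
    return poly


def mask_from_geometry(geom, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a shapely geometry into a boolean (H, W) mask.

    A pixel is set when its center falls inside the filled exterior of any
    polygon part and outside its holes.
    """
    from PIL import Image, ImageDraw

    if geom is None or geom.is_empty:
        return np.zeros(shape, dtype=bool)
    if isinstance(geom, (MultiPolygon, GeometryCollection)):
        parts = [g for g in geom.geoms if isinstance(g, Polygon)]
    elif isinstance(geom, Polygon):
        parts = [geom]
    else:
        return np.zeros(shape, dtype=bool)
    img = Image.new("1", (shape[1], shape[0]), 0)
    draw = ImageDraw.Draw(img)
    # offset by half a pixel so the fill decision applies to pixel centers
    for part in parts:
        xy = [(x - 0.5, y - 0.5) for x, y in part.exterior.coords]
        if len(xy) >= 3:
            draw.polygon(xy, fill=1)
        for ring in part.interiors:
            xy = [(x - 0.5, y - 0.5) for x, y in ring.coords]
            if len(xy) >= 3:
                draw.polygon(xy, fill=0)
    return np.asarray(img, dtype=bool)


def clip_to_canvas(geom, width_px: int, height_px: int):
    """Intersect a geometry with the image rectangle."""
    return shapely.intersection(geom, box(0, 0, width_px, height_px))
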