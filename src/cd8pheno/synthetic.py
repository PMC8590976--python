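"""Synthetic chromogenic-IHC slide generator with exact ground truth.

Renders desk-scale stand-ins for CD8-stained melanoma sections: hematoxylin
-blue nuclei everywhere in tissue, an Alkaline-Phosphatase-red ring around
CD8+ cells, tumor nests embedded in stroma, and optional pigment /
hemorrhage-necrosis artifact patches. Cells are placed by a homogeneous
Poisson process per tumor compartment (hard-core rejection against overlap)
at phenotype-conditional densities, so every downstream stage — stain
separation, tissue classification, nucleus detection, compartment geometry,
density phenotyping — can be validated against exact ground truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import shapely
import tifffile
import yaml
from shapely.geometry import Polygon
from skimage.draw import ellipse as _draw_ellipse

from . import compartments as comp
from .geometry import clip_to_canvas, mask_from_geometry, random_blob
from .stains import ODMaps, StainVectors, od_to_rgb
from .tissue import TissueClass, TissueClassMap

__all__ = ["PhenotypeSpec", "SlideLayout", "GroundTruthCell", "SyntheticSlide",
           "PHENOTYPE_PRESETS", "generate_layout", "place_cells", "render_image",
           "class_raster", "layout_annotations", "generate_slide",
           "CellPlacementError"]


class CellPlacementError(RuntimeError):
    """Requested density incompatible with non-overlapping placement."""


@dataclass(frozen=True)
class PhenotypeSpec:
    """Phenotype-conditional CD8+ densities (cells/um^2) per compartment."""

    phenotype: str
    icd8_density: float       # intratumoral tumor center
    scd8_density: float       # stromal tumor center
    imcd8_density: float      # invasive margin
    background_nucleus_density: float = 2e-3  # CD8- cells, all tissue

    def __post_init__(self):
        densities = (self.icd8_density, self.scd8_density, self.imcd8_density,
                     self.background_nucleus_density)
        if any(d < 0 for d in densities):
            raise ValueError("densities must be non-negative")
        if self.phenotype not in ("desert", "excluded", "inflamed"):
            raise ValueError(f"unknown phenotype '{self.phenotype}'")
        if self.phenotype == "inflamed" and self.icd8_density <= 0:
            raise ValueError("inflamed phenotype requires icd8_density > 0")
        if self.phenotype == "desert" and max(densities[:3]) > self.background_nucleus_density:
            raise ValueError("desert phenotype cannot exceed background density")


#: discovery-cohort mean densities per phenotype (cells/um^2)
PHENOTYPE_PRESETS: dict[str, PhenotypeSpec] = {
    "desert": PhenotypeSpec("desert", icd8_density=2e-5, scd8_density=2e-4,
                            imcd8_density=6e-4),
    "excluded": PhenotypeSpec("excluded", icd8_density=2e-4, scd8_density=2e-3,
                              imcd8_density=2e-3),
    "inflamed": PhenotypeSpec("inflamed", icd8_density=6e-4, scd8_density=5e-3,
                              imcd8_density=3e-3),
}


@dataclass
class SlideLayout:
    """Geometry of one synthetic slide (pixel coordinates)."""

    width_px: int
    height_px: int
    mpp: float
    tissue_polygon: Polygon
    tumor_polygons: list[Polygon]
    intratumoral_stroma_polygons: list[Polygon]
    artifact_polygons: list[tuple[Polygon, str]]
    margin_halfwidth_um: float
    rng_seed: int


@dataclass
class GroundTruthCell:
    centroid: tuple[float, float]  # (x, y) px
    nucleus_radius: float          # um
    is_cd8_positive: bool
    true_compartment: str          # iTC | sTC | IM | outside


@dataclass
class SyntheticSlide:
    image: np.ndarray
    layout: SlideLayout
    cells: list[GroundTruthCell]
    annotations: comp.AnnotationSet
    spec: PhenotypeSpec
    class_map: TissueClassMap
    compartment_mask: comp.CompartmentMask
    margin: object = None


def generate_layout(width_px: int, height_px: int, mpp: float, n_tumor_nests: int,
                    stroma_fraction: float, artifact_fraction: float, seed: int,
                    tumor_coverage: float = 0.4,
                    margin_halfwidth_um: float = 40.0) -> SlideLayout:
    """Seeded random slide geometry.

    Tumor nests are star-shaped blobs totalling ``tumor_coverage`` of the
    canvas, embedded in a tissue blob surrounded by glass; intratumoral
    stroma blobs cover ``stroma_fraction`` of each nest; artifact patches
    (pigment / hemorrhage-necrosis) cover ``artifact_fraction`` of the
    canvas outside the tumor. Identical arguments and seed give an
    identical layout.
    """
    if width_px < 256 or height_px < 256:
        raise ValueError("canvas must be at least 256 x 256 px")
    if not (0 <= stroma_fraction < 1):
        raise ValueError("stroma_fraction must lie in [0, 1)")
    if not (0 <= artifact_fraction < 1):
        raise ValueError("artifact_fraction must lie in [0, 1)")
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    if not (0 < tumor_coverage < 0.8):
        raise ValueError("tumor_coverage must lie in (0, 0.8)")
    rng = np.random.default_rng(seed)
    cx, cy = width_px / 2.0, height_px / 2.0

    tissue = random_blob((cx, cy), 0.62 * min(width_px, height_px), rng,
                         irregularity=0.10)
    tissue = clip_to_canvas(tissue, width_px, height_px)

    nest_area = tumor_coverage * width_px * height_px / max(1, n_tumor_nests)
    nest_r = float(np.sqrt(nest_area / np.pi))
    pad = min(1.15 * nest_r, min(width_px, height_px) / 2.0 - 1)
    # spacing ladder: prefer well-separated nests, relax when the canvas is
    # too crowded (slight overlaps then merge into larger nests)
    centers: list[tuple[float, float]] | None = None
    for spacing in (2.4, 2.2, 2.0, 1.85, 1.7, 1.5):
        for _restart in range(40):
            attempt: list[tuple[float, float]] = []
            for _ in range(n_tumor_nests):
                for _try in range(60):
                    px = rng.uniform(pad, width_px - pad)
                    py = rng.uniform(pad, height_px - pad)
                    if all(np.hypot(px - qx, py - qy) > spacing * nest_r
                           for qx, qy in attempt):
                        attempt.append((px, py))
                        break
                else:
                    break
            if len(attempt) == n_tumor_nests:
                centers = attempt
                break
        if centers is not None:
            break
    if centers is None:
        raise ValueError(
            f"could not place {n_tumor_nests} non-overlapping tumor nests "
            f"at coverage {tumor_coverage}")
    tumor_polygons = [random_blob(c, nest_r, rng, irregularity=0.15)
                      for c in centers]

    stroma_polygons: list[Polygon] = []
    if stroma_fraction > 0:
        for nest in tumor_polygons:
            target = stroma_fraction * nest.area
            core = nest.buffer(-4.0)
            if core.is_empty:
                continue
            minx, miny, maxx, maxy = core.bounds
            covered = None
            for _try in range(300):
                if covered is not None and covered.area >= target:
                    break
                br = rng.uniform(0.10, 0.20) * nest_r
                bx = rng.uniform(minx, maxx)
                by = rng.uniform(miny, maxy)
                if not core.contains(shapely.Point(bx, by)):
                    continue
                blob = shapely.intersection(random_blob((bx, by), br, rng), core)
                if blob.is_empty:
                    continue
                new_piece = blob if covered is None else shapely.difference(blob, covered)
                if new_piece.is_empty or new_piece.area < 4:
                    continue
                covered = blob if covered is None else shapely.union(covered, blob)
                for geom in getattr(new_piece, "geoms", [new_piece]):
                    if isinstance(geom, Polygon) and geom.area >= 4:
                        stroma_polygons.append(geom)

    artifact_polygons: list[tuple[Polygon, str]] = []
    if artifact_fraction > 0:
        target = artifact_fraction * width_px * height_px
        tumor_union = shapely.unary_union(tumor_polygons).buffer(8.0)
        area_sum = 0.0
        labels = ("pigment", "hemorrhage_necrosis")
        for _try in range(400):
            if area_sum >= target:
                break
            br = rng.uniform(0.02, 0.05) * min(width_px, height_px)
            bx = rng.uniform(br, width_px - br)
            by = rng.uniform(br, height_px - br)
            blob = random_blob((bx, by), br, rng)
            blob = shapely.difference(shapely.intersection(blob, tissue), tumor_union)
            for geom in getattr(blob, "geoms", [blob]):
                if isinstance(geom, Polygon) and geom.area > 25:
                    artifact_polygons.append(
                        (geom, labels[len(artifact_polygons) % 2]))
                    area_sum += geom.area

    return SlideLayout(width_px=width_px, height_px=height_px, mpp=mpp,
                       tissue_polygon=tissue, tumor_polygons=tumor_polygons,
                       intratumoral_stroma_polygons=stroma_polygons,
                       artifact_polygons=artifact_polygons,
                       margin_halfwidth_um=margin_halfwidth_um, rng_seed=seed)


def class_raster(layout: SlideLayout) -> TissueClassMap:
    """Ground-truth six-class tissue raster implied by the layout."""
    shape = (layout.height_px, layout.width_px)
    labels = np.full(shape, int(TissueClass.GLASS), dtype=np.uint8)
    labels[mask_from_geometry(layout.tissue_polygon, shape)] = int(
        TissueClass.DESMOPLASTIC_STROMA)
    labels[mask_from_geometry(shapely.unary_union(layout.tumor_polygons), shape)] = int(
        TissueClass.TUMOR)
    for poly in layout.intratumoral_stroma_polygons:
        labels[mask_from_geometry(poly, shape)] = int(TissueClass.IMMUNE_STROMA)
    for poly, kind in layout.artifact_polygons:
        cls = TissueClass.PIGMENT if kind == "pigment" else TissueClass.HEMORRHAGE_NECROSIS
        labels[mask_from_geometry(poly, shape)] = int(cls)
    return TissueClassMap(labels=labels, mpp=layout.mpp)


def layout_annotations(layout: SlideLayout) -> comp.AnnotationSet:
    """Pathologist-style annotations implied by the layout (tumor border +
    artifact exclusions)."""
    return comp.AnnotationSet(
        tumor_border=list(layout.tumor_polygons),
        exclusions=[(poly, "artifact") for poly, _ in layout.artifact_polygons],
        mpp=layout.mpp)


def ground_truth_compartments(layout: SlideLayout,
                              cmap: TissueClassMap | None = None):
    """Margin band + compartment mask computed from the layout's own
    annotations and class raster (single code path shared with real data)."""
    cmap = cmap or class_raster(layout)
    annots = layout_annotations(layout)
    margin = comp.build_margin_band(annots, layout.margin_halfwidth_um,
                                    canvas_px=(layout.width_px, layout.height_px))
    mask = comp.build_compartment_mask(annots, cmap, margin)
    return annots, margin, mask


_NUCLEUS_RADIUS_MEAN_UM = 3.5
_NUCLEUS_RADIUS_SD_UM = 0.5
_NUCLEUS_RADIUS_RANGE_UM = (2.0, 6.0)
_HARDCORE_FACTOR = 1.2


def _sample_radius(rng: np.random.Generator) -> float:
    lo, hi = _NUCLEUS_RADIUS_RANGE_UM
    for _ in range(100):
        r = rng.normal(_NUCLEUS_RADIUS_MEAN_UM, _NUCLEUS_RADIUS_SD_UM)
        if lo <= r <= hi:
            return float(r)
    return _NUCLEUS_RADIUS_MEAN_UM


class _HardCoreIndex:
    """Grid hash enforcing a minimum center distance between nuclei."""

    def __init__(self, cell_px: float = 40.0):
        self.cell = cell_px
        self.grid: dict[tuple[int, int], list[tuple[float, float, float]]] = {}

    def conflicts(self, x: float, y: float, r_px: float) -> bool:
        gx, gy = int(x // self.cell), int(y // self.cell)
        for ix in (gx - 1, gx, gx + 1):
            for iy in (gy - 1, gy, gy + 1):
                for ox, oy, orad in self.grid.get((ix, iy), ()):
                    if np.hypot(x - ox, y - oy) < _HARDCORE_FACTOR * (r_px + orad):
                        return True
        return False

    def add(self, x: float, y: float, r_px: float) -> None:
        key = (int(x // self.cell), int(y // self.cell))
        self.grid.setdefault(key, []).append((x, y, r_px))


def place_cells(layout: SlideLayout, spec: PhenotypeSpec, seed: int,
                mask: comp.CompartmentMask | None = None,
                max_tries: int = 200) -> list[GroundTruthCell]:
    """Homogeneous Poisson placement per compartment at the spec densities.

    The expected count in each compartment is density x area (um^2); the
    realized count is Poisson. Centers respect a hard-core distance of
    1.2 x the summed nucleus radii and never fall in artifact patches or
    glass. Raises :class:`CellPlacementError` when a density is too high
    for non-overlapping placement.
    """
    cmap = class_raster(layout)
    if mask is None:
        _, _, mask = ground_truth_compartments(layout, cmap)
    rng = np.random.default_rng(seed)
    index = _HardCoreIndex()
    px_area = layout.mpp**2
    cells: list[GroundTruthCell] = []

    tissue_classes = (int(TissueClass.TUMOR), int(TissueClass.DESMOPLASTIC_STROMA),
                      int(TissueClass.IMMUNE_STROMA))
    in_tissue = np.isin(cmap.labels, tissue_classes)

    def compartment_name(x: float, y: float) -> str:
        lbl = comp.Compartment(mask.labels[int(round(y)), int(round(x))])
        name = comp.COMPARTMENT_NAMES[lbl]
        return name if name in ("iTC", "sTC", "IM") else "outside"

    def scatter(region_mask: np.ndarray, density: float, cd8: bool) -> None:
        candidates = np.flatnonzero(region_mask)
        if candidates.size == 0 or density == 0:
            return
        area_um2 = candidates.size * px_area
        n = rng.poisson(density * area_um2)
        w = layout.width_px
        for _ in range(n):
            for attempt in range(max_tries):
                # re-sample the radius each try: a large nucleus that cannot
                # fit locally may still fit as a smaller one elsewhere
                r_um = _sample_radius(rng)
                r_px = r_um / layout.mpp
                flat = int(candidates[rng.integers(candidates.size)])
                y, x = divmod(flat, w)
                x += rng.uniform(-0.5, 0.5)
                y += rng.uniform(-0.5, 0.5)
                if not index.conflicts(x, y, r_px):
                    index.add(x, y, r_px)
                    cells.append(GroundTruthCell(
                        centroid=(x, y), nucleus_radius=r_um,
                        is_cd8_positive=cd8,
                        true_compartment=compartment_name(x, y)))
                    break
            else:
                raise CellPlacementError(
                    f"failed to place a nucleus after {max_tries} tries "
                    f"(density {density:g} cells/um^2 too high for hard-core "
                    f"placement)")

    lab = mask.labels
    scatter((lab == int(comp.Compartment.ITC)), spec.icd8_density, True)
    scatter((lab == int(comp.Compartment.STC)), spec.scd8_density, True)
    scatter((lab == int(comp.Compartment.IM)) & in_tissue, spec.imcd8_density, True)
    scatter(in_tissue, spec.background_nucleus_density, False)
    return cells


_CLASS_BASE_OD = {
    # (hematoxylin, ap_red, residual) base optical densities per tissue class
    int(TissueClass.GLASS): (0.010, 0.000, 0.010),
    int(TissueClass.TUMOR): (0.180, 0.000, 0.060),
    int(TissueClass.DESMOPLASTIC_STROMA): (0.050, 0.000, 0.200),
    int(TissueClass.IMMUNE_STROMA): (0.130, 0.000, 0.100),
    int(TissueClass.PIGMENT): (0.550, 0.250, 0.650),
    int(TissueClass.HEMORRHAGE_NECROSIS): (0.040, 0.030, 0.380),
}

_NUCLEUS_OD = 0.85
_MARKER_RING_OD = 0.80
_MARKER_RING_WIDTH_UM = 1.5


def render_image(layout: SlideLayout, cells: list[GroundTruthCell],
                 stain_params: StainVectors | None = None,
                 cmap: TissueClassMap | None = None,
                 return_od: bool = False):
    """Render the slide to 8-bit RGB through the Beer-Lambert forward model.

    CD8- nuclei appear in hematoxylin only; CD8+ cells additionally carry an
    AP-red ring just outside the nucleus; artifact patches and glass get
    their characteristic colors. Per-class base OD plus seeded low-frequency
    texture emulates tissue; the render is deterministic given the layout.
    """
    if stain_params is None:
        stain_params = StainVectors()
    if not isinstance(stain_params, StainVectors):
        raise TypeError("stain_params must be a StainVectors instance")
    cmap = cmap or class_raster(layout)
    shape = (layout.height_px, layout.width_px)
    rng = np.random.default_rng(np.random.SeedSequence([layout.rng_seed, 0x5EED]))

    base = np.asarray([_CLASS_BASE_OD[k] for k in range(6)], dtype=np.float32)
    od = base[cmap.labels]  # (H, W, 3) stain concentrations
    from scipy.ndimage import gaussian_filter, zoom
    coarse = rng.standard_normal((shape[0] // 8 + 1, shape[1] // 8 + 1)).astype(np.float32)
    texture = zoom(gaussian_filter(coarse, 1.5), 8, order=1)[:shape[0], :shape[1]]
    od *= (1.0 + 0.18 * texture)[..., None]
    od += rng.uniform(0.0, 0.02, size=od.shape).astype(np.float32)

    hema = od[..., 0]
    ap = od[..., 1]
    for cell in cells:
        x, y = cell.centroid
        r_px = cell.nucleus_radius / layout.mpp
        f = rng.uniform(0.95, 1.25)
        rot = rng.uniform(0, np.pi)
        rr, cc = _draw_ellipse(y, x, r_px / f, r_px * f, shape=shape, rotation=rot)
        hema[rr, cc] += _NUCLEUS_OD * rng.uniform(0.9, 1.1)
        if cell.is_cd8_positive:
            # membranous/cytoplasmic chromogen: elliptical annulus hugging
            # the nuclear boundary
            ring_px = _MARKER_RING_WIDTH_UM / layout.mpp
            r_max = r_px * f + ring_px + 2
            y0, x0 = max(int(y - r_max), 0), max(int(x - r_max), 0)
            y1 = min(int(y + r_max) + 2, shape[0])
            x1 = min(int(x + r_max) + 2, shape[1])
            local_shape = (y1 - y0, x1 - x0)
            if local_shape[0] > 0 and local_shape[1] > 0:
                ring = np.zeros(local_shape, dtype=bool)
                ro, co = _draw_ellipse(y - y0, x - x0, r_px / f + ring_px,
                                       r_px * f + ring_px, shape=local_shape,
                                       rotation=rot)
                ring[ro, co] = True
                ri, ci = _draw_ellipse(y - y0, x - x0, r_px / f, r_px * f,
                                       shape=local_shape, rotation=rot)
                ring[ri, ci] = False
                ap[y0:y1, x0:x1][ring] += _MARKER_RING_OD
    np.clip(od, 0.0, 3.0, out=od)

    rgb_od = od.reshape(-1, 3) @ stain_params.matrix.astype(np.float32)
    image = od_to_rgb(rgb_od.reshape(shape + (3,)))
    if return_od:
        return image, ODMaps(hematoxylin=od[..., 0].astype(float),
                             ap_red=od[..., 1].astype(float), mpp=layout.mpp)
    return image


def generate_slide(phenotype: str | PhenotypeSpec, width_px: int = 2048,
                   height_px: int = 2048, mpp: float = 0.25,
                   n_tumor_nests: int = 3, stroma_fraction: float = 0.3,
                   artifact_fraction: float = 0.0, seed: int = 0,
                   tumor_coverage: float = 0.4,
                   margin_halfwidth_um: float = 40.0,
                   stain_params: StainVectors | None = None) -> SyntheticSlide:
    """End-to-end synthesis: layout, cells, render, ground truth containers."""
    spec = (PHENOTYPE_PRESETS[phenotype] if isinstance(phenotype, str) else phenotype)
    layout = generate_layout(width_px, height_px, mpp, n_tumor_nests,
                             stroma_fraction, artifact_fraction, seed,
                             tumor_coverage=tumor_coverage,
                             margin_halfwidth_um=margin_halfwidth_um)
    cmap = class_raster(layout)
    annots, margin, mask = ground_truth_compartments(layout, cmap)
    cells = place_cells(layout, spec, seed=seed + 1, mask=mask)
    image = render_image(layout, cells, stain_params=stain_params, cmap=cmap)
    return SyntheticSlide(image=image, layout=layout, cells=cells,
                          annotations=annots, spec=spec, class_map=cmap,
                          compartment_mask=mask, margin=margin)


# ---------------------------------------------------------------------------
# persistence


def save_slide(slide: SyntheticSlide, outdir, stem: str = "slide") -> dict:
    """Write image (TIFF), ground-truth cells (CSV), annotations (GeoJSON),
    and the phenotype spec (YAML); returns the path map."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "image": os.path.join(outdir, f"{stem}.tiff"),
        "cells": os.path.join(outdir, f"{stem}_cells.csv"),
        "annotations": os.path.join(outdir, f"{stem}_annotations.geojson"),
        "spec": os.path.join(outdir, f"{stem}_spec.yaml"),
        "class_map": os.path.join(outdir, f"{stem}_classmap.tiff"),
    }
    tifffile.imwrite(paths["image"], slide.image)
    from .tissue import write_class_map
    write_class_map(slide.class_map, paths["class_map"])
    with open(paths["cells"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "radius_um", "cd8", "compartment"])
        for cell in slide.cells:
            writer.writerow([f"{cell.centroid[0]:.3f}", f"{cell.centroid[1]:.3f}",
                             f"{cell.nucleus_radius:.3f}",
                             int(cell.is_cd8_positive), cell.true_compartment])
    comp.write_annotations_geojson(slide.annotations, paths["annotations"])
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump({"phenotype": slide.spec.phenotype,
                        "icd8_density": slide.spec.icd8_density,
                        "scd8_density": slide.spec.scd8_density,
                        "imcd8_density": slide.spec.imcd8_density,
                        "background_nucleus_density":
                            slide.spec.background_nucleus_density}, fh)
    return paths
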