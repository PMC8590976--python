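"""Tumor-compartment geometry: tumor center, invasive margin, exclusions.

Scoring uses three disjoint compartments built from the pathologist's
tumor-border annotation and the tissue class map:

* iTC — intratumoral tumor center: tumor-cell regions of the tumor center
  (tumor cells without intervening intratumoral stroma);
* sTC — stromal tumor center: intratumoral stroma without tumor cells;
* IM  — invasive margin: a band of configurable halfwidth centered on the
  annotated tumor border (1 mm total width by convention).

Pixels inside exclusion polygons (artifacts, tertiary lymphoid structures,
preexisting lymphoid tissue of lymph nodes) or classed as glass, pigment, or
hemorrhage/necrosis are excluded and enter no density denominator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import shapely
from shapely.geometry import Polygon, mapping, shape

from .geometry import clip_to_canvas, mask_from_geometry
from .tissue import TissueClass, TissueClassMap

__all__ = [
    "Compartment",
    "AnnotationSet",
    "CompartmentMask",
    "build_margin_band",
    "build_compartment_mask",
    "assign_cells",
    "read_annotations_geojson",
    "write_annotations_geojson",
]

EXCLUSION_REASONS = frozenset(
    {"artifact", "tertiary_lymphoid_structure", "preexisting_lymphoid", "other"})


class Compartment(IntEnum):
    OUTSIDE = 0
    ITC = 1
    STC = 2
    IM = 3
    EXCLUDED = 4


COMPARTMENT_NAMES = {
    Compartment.ITC: "iTC",
    Compartment.STC: "sTC",
    Compartment.IM: "IM",
    Compartment.EXCLUDED: "excluded",
    Compartment.OUTSIDE: "outside",
}
_NAME_TO_COMPARTMENT = {v: k for k, v in COMPARTMENT_NAMES.items()}


@dataclass
class AnnotationSet:
    """Pathologist-style annotations in pixel coordinates.

    `tumor_border` polygons delineate the tumor; `exclusions` are
    (polygon, reason) pairs removed from all scoring.
    """

    tumor_border: list[Polygon]
    exclusions: list[tuple[Polygon, str]] = field(default_factory=list)
    mpp: float = 0.25

    def __post_init__(self):
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        for poly in self.tumor_border:
            if not poly.is_valid:
                raise ValueError("tumor border polygon is not simple/valid")
        for poly, reason in self.exclusions:
            if reason not in EXCLUSION_REASONS:
                raise ValueError(f"unknown exclusion reason '{reason}'")
            if not poly.is_valid:
                raise ValueError("exclusion polygon is not simple/valid")

    @property
    def tumor_union(self):
        return shapely.unary_union(self.tumor_border)


@dataclass
class CompartmentMask:
    """Per-pixel compartment labels plus physical areas per compartment."""

    labels: np.ndarray  # (H, W) of Compartment values
    mpp: float

    def __post_init__(self):
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        self.labels = np.asarray(self.labels)

    @property
    def areas(self) -> dict[str, float]:
        px2 = self.mpp**2
        return {name: float(np.count_nonzero(self.labels == int(comp))) * px2
                for comp, name in COMPARTMENT_NAMES.items()}

    def area_um2(self, comp: Compartment) -> float:
        return float(np.count_nonzero(self.labels == int(comp))) * self.mpp**2


def build_margin_band(annotations: AnnotationSet, band_halfwidth_um: float = 500.0,
                      canvas_px: tuple[int, int] | None = None):
    """The invasive-margin region: within `band_halfwidth_um` of the tumor
    border on both sides (1 mm total width at the default), clipped to the
    canvas when given.

    When the tumor is thinner than the inner offset the inner ring collapses
    and the whole tumor side of the band is kept, with a warning.
    """
    if not annotations.tumor_border:
        raise ValueError("margin band requires a tumor border annotation")
    if band_halfwidth_um < 0:
        raise ValueError("band halfwidth must be >= 0")
    if band_halfwidth_um == 0:
        return Polygon()
    half_px = band_halfwidth_um / annotations.mpp
    tumor = annotations.tumor_union
    outer = tumor.buffer(half_px)
    inner = tumor.buffer(-half_px)
    if inner.is_empty:
        warnings.warn("tumor thinner than the inner margin offset; "
                      "band covers the whole tumor interior")
    band = shapely.difference(outer, inner)
    if canvas_px is not None:
        band = clip_to_canvas(band, canvas_px[0], canvas_px[1])
    return band


def build_compartment_mask(annotations: AnnotationSet, class_map: TissueClassMap,
                           margin=None) -> CompartmentMask:
    """Combine annotations, tissue classes, and the margin band into the
    compartment label raster.

    Precedence (highest first): exclusion polygons > artifact/glass tissue
    classes > invasive margin > tumor-center subdivision > outside. Inside
    the tumor border and outside the margin, tumor-classed pixels become
    iTC and stroma-classed pixels sTC.
    """
    if abs(class_map.mpp - annotations.mpp) > 1e-9:
        raise ValueError("annotation and class-map mpp differ")
    h, w = class_map.labels.shape
    tumor_mask = mask_from_geometry(annotations.tumor_union, (h, w))
    labels = np.full((h, w), int(Compartment.OUTSIDE), dtype=np.uint8)

    tissue = class_map.labels
    is_tumor_cls = tissue == int(TissueClass.TUMOR)
    is_stroma_cls = ((tissue == int(TissueClass.DESMOPLASTIC_STROMA))
                     | (tissue == int(TissueClass.IMMUNE_STROMA)))
    labels[tumor_mask & is_tumor_cls] = int(Compartment.ITC)
    labels[tumor_mask & is_stroma_cls] = int(Compartment.STC)

    if margin is not None and not margin.is_empty:
        margin_mask = mask_from_geometry(margin, (h, w))
        labels[margin_mask] = int(Compartment.IM)

    # glass/pigment/hemorrhage-necrosis pixels never enter a density
    # denominator, wherever they fall
    labels[~(is_tumor_cls | is_stroma_cls)] = int(Compartment.EXCLUDED)

    for poly, _reason in annotations.exclusions:
        excl = mask_from_geometry(poly, (h, w))
        labels[excl] = int(Compartment.EXCLUDED)
    return CompartmentMask(labels=labels, mpp=class_map.mpp)


def assign_cells(cells, mask: CompartmentMask):
    """Set each detection's compartment to the mask label at its centroid.

    Out-of-bounds centroids are labeled outside with a warning. Returns the
    same list (detections mutated in place).
    """
    h, w = mask.labels.shape
    for cell in cells:
        x, y = cell.centroid
        xi, yi = int(round(x)), int(round(y))
        if not (0 <= xi < w and 0 <= yi < h):
            warnings.warn(f"cell centroid ({x:.1f}, {y:.1f}) outside mask bounds")
            cell.compartment = COMPARTMENT_NAMES[Compartment.OUTSIDE]
        else:
            cell.compartment = COMPARTMENT_NAMES[Compartment(mask.labels[yi, xi])]
    return cells


# ---------------------------------------------------------------------------
# GeoJSON annotation I/O


def write_annotations_geojson(annotations: AnnotationSet, path) -> None:
    features = []
    for poly in annotations.tumor_border:
        features.append({"type": "Feature", "geometry": mapping(poly),
                         "properties": {"role": "tumor_border"}})
    for poly, reason in annotations.exclusions:
        features.append({"type": "Feature", "geometry": mapping(poly),
                         "properties": {"role": "exclusion", "reason": reason}})
    doc = {"type": "FeatureCollection", "metadata": {"mpp": annotations.mpp},
           "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_annotations_geojson(path) -> AnnotationSet:
    with open(path) as fh:
        doc = json.load(fh)
    mpp = float(doc.get("metadata", {}).get("mpp", 0.25))
    border: list[Polygon] = []
    exclusions: list[tuple[Polygon, str]] = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        role = feat.get("properties", {}).get("role")
        if role == "tumor_border":
            border.append(geom)
        elif role in ("exclusion", "artifact"):
            reason = feat.get("properties", {}).get("reason", "other")
            exclusions.append((geom, reason))
    return AnnotationSet(tumor_border=border, exclusions=exclusions, mpp=mpp)
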