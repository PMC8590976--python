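"""Reproduction workflows: self-contained experiments that exercise the
whole pipeline and report its headline numbers.

Each function builds its own inputs (validation-cohort counts, synthetic
slides at the preset densities, closed-form geometry) and measures the
result by running the package end to end.
"""

from __future__ import annotations

import numpy as np

from .compartments import AnnotationSet, build_margin_band
from .evaluation import class_metrics, cross_tabulate
from .geometry import mask_from_geometry
from .pipeline import PipelineConfig, run_pipeline
from .synthetic import PhenotypeSpec, generate_slide

__all__ = ["validation_cohort_metrics", "phenotype_recovery",
           "density_estimation_error", "margin_band_geometry_error"]

#: validation-cohort cross-tabulation: class sizes 10 desert / 18 excluded /
#: 5 inflamed; desert and inflamed fully concordant, 3 excluded cases
#: predicted inflamed
VALIDATION_TRUTH = ["desert"] * 10 + ["excluded"] * 18 + ["inflamed"] * 5
VALIDATION_PREDICTED = (["desert"] * 10 + ["excluded"] * 15
                        + ["inflamed"] * 3 + ["inflamed"] * 5)


def validation_cohort_metrics() -> dict:
    """Per-class one-vs-rest metrics of the validation-cohort pattern."""
    cm = cross_tabulate(VALIDATION_PREDICTED, VALIDATION_TRUTH)
    metrics = class_metrics(cm)
    out: dict = {"n": cm.total, "confusion": cm.counts.tolist()}
    for cls, m in metrics.per_class.items():
        for key in ("sensitivity", "specificity", "precision"):
            out[f"{cls}_{key}_pct"] = round(100.0 * m[key], 4)
    return out


def phenotype_recovery(seed: int, n_per_phenotype: int = 10,
                       width_px: int = 2048, height_px: int = 2048,
                       progress=None):
    """Full-pipeline phenotype recovery on a synthetic cohort.

    Slides are generated at the preset per-phenotype densities, tissue is
    classified by the trained patch classifier (not ground truth), cut-offs
    are derived from the measured profiles, and the fraction of slides whose
    digital diagnosis matches the generating phenotype is returned.
    """
    cfg = PipelineConfig(seed=seed)
    cfg.cohort.update({"n_per_phenotype": n_per_phenotype,
                       "width_px": width_px, "height_px": height_px})
    report = run_pipeline(cfg, progress=progress)
    return report


def density_estimation_error(seed: int, n_seeds: int = 10,
                             width_px: int = 2048, height_px: int = 2048,
                             mpp: float = 0.5) -> dict:
    """Median relative error of estimated compartment densities.

    Uses one large tumor nest and CD8+ densities sized so the expected
    count in every compartment is >= 600 cells (realized counts stay
    >= 500 across seeds), so the measurement error reflects the
    detection/scoring/geometry chain rather than Poisson noise.
    """
    spec = PhenotypeSpec("inflamed", icd8_density=2.4e-3, scd8_density=5e-3,
                         imcd8_density=2.4e-3, background_nucleus_density=1e-3)
    from .detection import (DetectionParams, detect_nuclei, filter_candidates,
                            score_marker)
    from .phenotyping import compute_densities
    from .compartments import assign_cells
    from .stains import deconvolve_stains

    seeds = [int(s % (2**31)) for s in
             np.random.SeedSequence(seed).generate_state(n_seeds)]
    errors = {"icd8": [], "scd8": [], "imcd8": []}
    min_count = None
    params = DetectionParams()
    for s in seeds:
        slide = generate_slide(spec, width_px=width_px, height_px=height_px,
                               mpp=mpp, n_tumor_nests=1, stroma_fraction=0.3,
                               tumor_coverage=0.5, margin_halfwidth_um=50.0,
                               seed=s)
        od = deconvolve_stains(slide.image, mpp=mpp)
        cells = score_marker(filter_candidates(detect_nuclei(od, params),
                                               params), od, params)
        cells = assign_cells(cells, slide.compartment_mask)
        profile = compute_densities(cells, slide.compartment_mask)
        truth_counts = {"iTC": 0, "sTC": 0, "IM": 0}
        for c in slide.cells:
            if c.is_cd8_positive and c.true_compartment in truth_counts:
                truth_counts[c.true_compartment] += 1
        low = min(truth_counts.values())
        min_count = low if min_count is None else min(min_count, low)
        for attr, target in (("icd8", spec.icd8_density),
                             ("scd8", spec.scd8_density),
                             ("imcd8", spec.imcd8_density)):
            measured = getattr(profile, attr)
            errors[attr].append(abs(measured - target) / target)
    return {
        "median_rel_error": {k: float(np.median(v)) for k, v in errors.items()},
        "worst_median_rel_error": float(max(np.median(v)
                                            for v in errors.values())),
        "min_cd8_count_per_compartment": int(min_count),
        "n_seeds": n_seeds,
    }


def margin_band_geometry_error(radius_um: float = 2000.0,
                               halfwidth_um: float = 500.0,
                               mpp: float = 2.0) -> dict:
    """Rasterized invasive-margin area vs. the closed-form annulus."""
    from shapely.geometry import Point

    r_px = radius_um / mpp
    pad = (halfwidth_um + 100.0) / mpp
    side = int(2 * (r_px + pad))
    center = side / 2.0
    annots = AnnotationSet(
        tumor_border=[Point(center, center).buffer(r_px, quad_segs=256)],
        mpp=mpp)
    band = build_margin_band(annots, halfwidth_um, canvas_px=(side, side))
    area = mask_from_geometry(band, (side, side)).sum() * mpp**2
    expected = np.pi * ((radius_um + halfwidth_um) ** 2
                        - (radius_um - halfwidth_um) ** 2)
    return {"area_um2": float(area), "expected_um2": float(expected),
            "rel_error_pct": float(100.0 * abs(area - expected) / expected)}
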