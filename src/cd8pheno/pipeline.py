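"""End-to-end cohort driver: synthesis or real slides through detection,
compartments, densities, diagnosis, and diagnostic-accuracy evaluation.

The driver is fully seeded: a master seed deterministically derives every
per-slide seed, so repeated runs with the same config produce byte-identical
outputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .compartments import (AnnotationSet, CompartmentMask, assign_cells,
                           build_compartment_mask, build_margin_band,
                           read_annotations_geojson)
from .detection import (DetectionParams, detect_nuclei, filter_candidates,
                        score_marker)
from .evaluation import (ClassMetrics, ConfusionMatrix, class_metrics,
                         cross_tabulate, format_percent)
from .phenotyping import (DEFAULT_CUTOFFS, CutoffConfig, DensityProfile,
                          ImmuneDiagnosis, classify_phenotype,
                          compute_densities, derive_cutoffs)
from .stains import StainVectors, deconvolve_stains
from .synthetic import generate_slide
from .tissue import (TissueClassifier, classify_tissue, extract_patches,
                     train_tissue_classifier)

__all__ = ["PipelineConfig", "CohortReport", "run_pipeline", "process_slide"]


DEFAULT_COHORT = {
    "n_per_phenotype": 10,
    "phenotypes": ["desert", "excluded", "inflamed"],
    "width_px": 2048,
    "height_px": 2048,
    "mpp": 0.25,
    "n_tumor_nests": 2,
    "stroma_fraction": 0.3,
    "artifact_fraction": 0.0,
    "tumor_coverage": 0.45,
    "margin_halfwidth_um": 40.0,
}


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline` (YAML-friendly)."""

    mode: str = "synthetic"                 # "synthetic" or "slides"
    cohort: dict = field(default_factory=lambda: dict(DEFAULT_COHORT))
    slides: list = field(default_factory=list)  # mode="slides" entries
    detection: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=lambda: {"patch_px": 64, "stride": 64,
                                                      "max_per_class": 150})
    use_ground_truth_tissue: bool = False
    cutoffs: dict | None = None             # {"c_i": .., "c_s": ..} or None→derive
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key '{key}'")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    def to_dict(self) -> dict:
        return {"mode": self.mode, "cohort": self.cohort, "slides": self.slides,
                "detection": self.detection, "classifier": self.classifier,
                "use_ground_truth_tissue": self.use_ground_truth_tissue,
                "cutoffs": self.cutoffs, "seed": self.seed}


@dataclass
class SlideResult:
    slide_id: str
    profile: DensityProfile
    diagnosis: ImmuneDiagnosis | None = None
    true_label: str | None = None
    n_cells: int = 0
    n_cd8: int = 0


@dataclass
class CohortReport:
    results: list[SlideResult]
    cutoffs: CutoffConfig
    confusion: ConfusionMatrix | None = None
    metrics: ClassMetrics | None = None
    agreement: float | None = None
    manifest: dict = field(default_factory=dict)


def _slide_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def process_slide(image: np.ndarray, annotations: AnnotationSet,
                  class_map, margin_halfwidth_um: float,
                  detection_params: DetectionParams,
                  stain_vectors: StainVectors | None = None,
                  slide_id: str = "") -> tuple[DensityProfile, list, CompartmentMask]:
    """One slide through stain separation, detection, compartments, densities."""
    od = deconvolve_stains(image, stain_vectors, mpp=annotations.mpp)
    margin = build_margin_band(annotations, margin_halfwidth_um,
                               canvas_px=(image.shape[1], image.shape[0]))
    mask = build_compartment_mask(annotations, class_map, margin)
    cells = detect_nuclei(od, detection_params)
    cells = filter_candidates(cells, detection_params)
    cells = score_marker(cells, od, detection_params)
    cells = assign_cells(cells, mask)
    profile = compute_densities(cells, mask, slide_id=slide_id)
    return profile, cells, mask


def _train_cohort_classifier(cohort: dict, classifier_cfg: dict, seed: int,
                             seeds: list[int], phenotypes: list[str]) -> TissueClassifier:
    """Train the tissue classifier on ground-truth patches from the first
    slide of each phenotype (the slides regenerate identically later)."""
    datasets = []
    patch_px = classifier_cfg.get("patch_px", 64)
    for k, phen in enumerate(phenotypes):
        slide = _generate_cohort_slide(cohort, phen, seeds[k * cohort["n_per_phenotype"]])
        ds = extract_patches(slide.image, slide.class_map.labels, patch_px,
                             stride=classifier_cfg.get("stride", patch_px),
                             seed=seed + k,
                             max_per_class=classifier_cfg.get("max_per_class", 150))
        datasets.extend(ds.patches)
    from .tissue import PatchDataset
    merged = PatchDataset(patches=datasets, patch_px=patch_px)
    return train_tissue_classifier(merged, config=classifier_cfg.get("model", {}),
                                   seed=seed, mpp=cohort["mpp"])


def _generate_cohort_slide(cohort: dict, phenotype: str, seed: int):
    return generate_slide(
        phenotype, width_px=cohort["width_px"], height_px=cohort["height_px"],
        mpp=cohort["mpp"], n_tumor_nests=cohort["n_tumor_nests"],
        stroma_fraction=cohort["stroma_fraction"],
        artifact_fraction=cohort["artifact_fraction"], seed=seed,
        tumor_coverage=cohort["tumor_coverage"],
        margin_halfwidth_um=cohort["margin_halfwidth_um"])


def run_pipeline(config: PipelineConfig, outdir=None,
                 progress=None) -> CohortReport:
    """Run the full cohort pipeline and optionally write all artifacts.

    In synthetic mode the generating phenotype of each slide is the
    reference label: cut-offs are derived on the measured profiles unless
    fixed in config, and the cohort confusion matrix compares the digital
    diagnosis to the generating phenotype.
    """
    det_params = DetectionParams(**config.detection)
    results: list[SlideResult] = []

    if config.mode == "synthetic":
        cohort = {**DEFAULT_COHORT, **config.cohort}
        phenotypes = list(cohort["phenotypes"])
        n_per = int(cohort["n_per_phenotype"])
        seeds = _slide_seeds(config.seed, n_per * len(phenotypes))
        classifier = None
        if not config.use_ground_truth_tissue:
            classifier = _train_cohort_classifier(cohort, config.classifier,
                                                  config.seed, seeds, phenotypes)
        idx = 0
        for phen in phenotypes:
            for j in range(n_per):
                slide_id = f"{phen}_{j:02d}"
                slide = _generate_cohort_slide(cohort, phen, seeds[idx])
                if classifier is None:
                    cmap = slide.class_map
                else:
                    cmap = classify_tissue(slide.image, classifier)
                profile, cells, _mask = process_slide(
                    slide.image, slide.annotations, cmap,
                    cohort["margin_halfwidth_um"], det_params, slide_id=slide_id)
                results.append(SlideResult(
                    slide_id=slide_id, profile=profile, true_label=phen,
                    n_cells=len(cells),
                    n_cd8=sum(c.is_cd8_positive for c in cells)))
                if progress:
                    progress(slide_id)
                idx += 1
    elif config.mode == "slides":
        if not config.slides:
            raise FileNotFoundError("mode 'slides' requires a non-empty slide list")
        import tifffile
        from .tissue import read_class_map
        for entry in config.slides:
            for key in ("image", "annotations", "class_map"):
                if key not in entry or not os.path.exists(entry[key]):
                    raise FileNotFoundError(
                        f"slide entry missing readable '{key}': {entry}")
        for entry in config.slides:
            image = tifffile.imread(entry["image"])
            annots = read_annotations_geojson(entry["annotations"])
            cmap = read_class_map(entry["class_map"])
            slide_id = entry.get("id", os.path.basename(entry["image"]))
            profile, cells, _mask = process_slide(
                image, annots, cmap,
                entry.get("margin_halfwidth_um", 500.0), det_params,
                slide_id=slide_id)
            results.append(SlideResult(
                slide_id=slide_id, profile=profile,
                true_label=entry.get("label"), n_cells=len(cells),
                n_cd8=sum(c.is_cd8_positive for c in cells)))
            if progress:
                progress(slide_id)
    else:
        raise ValueError(f"unknown pipeline mode '{config.mode}'")

    profiles = [r.profile for r in results]
    labels = [r.true_label for r in results]
    have_labels = all(lbl is not None for lbl in labels) and len(set(labels)) >= 2

    if config.cutoffs:
        cutoffs = CutoffConfig(**config.cutoffs)
    elif have_labels and len(profiles) >= 5:
        cutoffs = derive_cutoffs(profiles, labels)
    else:
        cutoffs = DEFAULT_CUTOFFS

    for r in results:
        r.diagnosis = classify_phenotype(r.profile, cutoffs)

    confusion = metrics = agreement = None
    if have_labels:
        predicted = [r.diagnosis.category for r in results]
        confusion = cross_tabulate(predicted, labels)
        metrics = class_metrics(confusion)
        agreement = float(np.mean([p == t for p, t in zip(predicted, labels)]))

    manifest = {
        "config": _jsonable(config.to_dict()),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(config.to_dict()), sort_keys=True).encode()
        ).hexdigest()[:12],
        "version": __version__,
        "n_slides": len(results),
        "cutoffs": {"c_i": cutoffs.c_i, "c_s": cutoffs.c_s},
    }
    report = CohortReport(results=results, cutoffs=cutoffs, confusion=confusion,
                          metrics=metrics, agreement=agreement, manifest=manifest)
    if outdir is not None:
        write_report(report, outdir)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_report(report: CohortReport, outdir) -> None:
    """CSV tables, plain-text confusion matrix, JSON manifest."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "densities.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_id", "icd8", "scd8", "imcd8", "area_itc",
                         "area_stc", "area_im", "category", "true_label",
                         "c_i", "c_s"])
        for r in report.results:
            p = r.profile
            writer.writerow([
                r.slide_id, f"{p.icd8:.8g}", f"{p.scd8:.8g}",
                "" if p.imcd8 is None else f"{p.imcd8:.8g}",
                f"{p.area_itc:.6g}", f"{p.area_stc:.6g}", f"{p.area_im:.6g}",
                r.diagnosis.category if r.diagnosis else "",
                r.true_label or "", f"{report.cutoffs.c_i:.8g}",
                f"{report.cutoffs.c_s:.8g}"])
    if report.confusion is not None:
        with open(os.path.join(outdir, "confusion_matrix.txt"), "w") as fh:
            fh.write(report.confusion.to_text() + "\n")
        with open(os.path.join(outdir, "class_metrics.csv"), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class", "TP", "TN", "FP", "FN", "sensitivity",
                             "specificity", "precision", "sensitivity_pct",
                             "specificity_pct", "precision_pct"])
            for cls, m in report.metrics.per_class.items():
                writer.writerow([
                    cls, m["TP"], m["TN"], m["FP"], m["FN"],
                    *("" if m[k] is None else f"{m[k]:.8g}"
                      for k in ("sensitivity", "specificity", "precision")),
                    *(format_percent(m[k])
                      for k in ("sensitivity", "specificity", "precision"))])
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(_jsonable(report.manifest), fh, indent=2, sort_keys=True)
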