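# cd8pheno

Quantitative immune phenotyping of CD8-stained tumor sections by digital
pathology.

The density and spatial distribution of CD8+ tumor-infiltrating T cells is
one of the strongest predictive biomarkers in immuno-oncology: tumors whose
parenchyma is infiltrated by cytotoxic T cells ("inflamed", clinically hot)
respond best to immune checkpoint inhibition, while tumors where T cells are
absent ("desert") or stopped in the stroma and margin ("excluded") respond
poorly. `cd8pheno` implements a standardized pipeline that turns a
chromogenic CD8 immunohistochemistry slide (hematoxylin counterstain,
Alkaline-Phosphatase red chromogen) plus a pathologist's tumor-border
annotation into compartment-resolved CD8+ densities and a categorical
immune diagnosis. It is written for computational pathology researchers and
biomarker developers who need a reproducible, fully testable reference
implementation.

## Method

1. **Stain separation.** The RGB image is converted to optical density
   (OD = −log₁₀ T) and unmixed into hematoxylin and AP-red channels by a
   3×3 stain-basis inversion (absorbances add linearly in OD space).
2. **Tissue classification.** Patches are classified into six classes —
   tumor, desmoplastic stroma, immune-infiltrated stroma, glass, pigment,
   hemorrhage/necrosis — by a color/texture random forest; sliding-window
   majority voting yields a dense class map.
3. **Cell detection.** Nuclei are segmented by a seeded watershed on the
   smoothed hematoxylin OD, filtered by pathologist-style morphometric
   rules (nuclear area, roundness 4πA/P², optical density), and CD8
   positivity is called from the mean AP-red OD in a peri-nuclear annulus.
4. **Compartments.** From the tumor-border annotation and the class map,
   three disjoint scoring compartments are built: the intratumoral tumor
   center **iTC** (tumor cells without intervening stroma), the stromal
   tumor center **sTC** (intratumoral stroma), and the invasive margin
   **IM** (a band of ±500 µm about the annotated border — 1 mm total — by
   the Immuno-Oncology Biomarker Working Group convention). Exclusion
   polygons (artifacts, tertiary lymphoid structures, preexisting lymphoid
   tissue) and artifact-classed pixels enter no denominator.
5. **Diagnosis.** Compartment densities iCD8, sCD8, imCD8 (cells/µm²) feed
   a two-cut-off decision rule:

       inflamed   if iCD8 ≥ c_i
       excluded   elif sCD8 ≥ c_s
       desert     otherwise

   The invasive margin is deliberately not required, so biopsies without a
   margin remain diagnosable. Cut-offs are derived from a labeled cohort by
   exhaustive midpoint search maximizing balanced accuracy.

A synthetic slide generator renders desk-scale chromogenic slides with
exact ground truth (cell positions, CD8 status, compartments, tissue
classes) at phenotype-conditional densities, so every stage is testable
without clinical material.

## Worked example

```python
from cd8pheno import (generate_slide, deconvolve_stains, detect_nuclei,
                      filter_candidates, score_marker, assign_cells,
                      compute_densities, classify_phenotype, DEFAULT_CUTOFFS)

slide = generate_slide("inflamed", seed=42)  # 2048 x 2048 px at 0.25 um/px
od = deconvolve_stains(slide.image, mpp=slide.layout.mpp)
cells = score_marker(filter_candidates(detect_nuclei(od)), od)
cells = assign_cells(cells, slide.compartment_mask)
profile = compute_densities(cells, slide.compartment_mask)
diagnosis = classify_phenotype(profile, DEFAULT_CUTOFFS)
print(f"iCD8 {profile.icd8:.2e}  sCD8 {profile.scd8:.2e}  "
      f"imCD8 {profile.imcd8:.2e} cells/um^2 -> {diagnosis.category}")
```

Output:

```
iCD8 6.96e-04  sCD8 4.33e-03  imCD8 2.99e-03 cells/um^2 -> inflamed
```

The measured densities sit near the generating preset for the inflamed
phenotype (iCD8 6×10⁻⁴, sCD8 5×10⁻³, imCD8 3×10⁻³ cells/µm²), and the
intratumoral density clears the default intratumoral cut-off
(c_i ≈ 3.5×10⁻⁴), so the slide is diagnosed inflamed.

The same pipeline is scriptable from the shell:

```sh
cd8pheno simulate --outdir cohort --seed 4 --n-per-phenotype 2
cd8pheno detect --image cohort/inflamed_00.tiff --out cells.csv
cd8pheno run --config config.yaml --seed 1 --outdir report
```

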