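# Methods

This note documents the models, parameters, and design choices behind
`cd8pheno`, and what the synthetic-data tests do and do not establish about
clinical material.

## Stain model and deconvolution

Chromogenic CD8 slides carry a hematoxylin nuclear counterstain and an
Alkaline-Phosphatase (AP) red chromogen. In transmitted light, absorbances
add linearly in optical density, OD = −log₁₀(I/I₀), so a pixel's OD vector
is a non-negative combination of per-stain unit absorbance vectors. The
default basis uses the standard hematoxylin vector (0.650, 0.704, 0.286)
and a fast-red-like AP vector (0.120, 0.788, 0.604), both unit-norm, with a
residual channel completing the basis (normalized cross product, clipped to
non-negative components). The published workflow's commercial platform
performs this unmixing internally and states no vectors, so the basis is a
documented, overridable default rather than a reproduction. Deconvolution
inverts the 3×3 basis and clips negative projections at zero; on its own
forward model it is exact for float input and accurate to ~0.01 OD after
8-bit quantization.

## Tissue classification

The slide is partitioned into six classes: tumor, desmoplastic stroma,
immune-infiltrated stroma, glass background, pigment deposition, and
hemorrhage/necrosis. The original platform used a DenseNet on 256-px
patches; those weights are unavailable, and the contract here is the
six-class map, not the architecture, so the default classifier is a compact
color + texture feature extractor (per-patch RGB and stain-OD means, SDs,
90th percentiles, and hematoxylin gradient statistics; 17 features) with a
random-forest head (100 trees, seeded). Patches default to 64 px for
synthetic material, whose textures are simpler than tissue; both patch size
and model are configurable. Dense maps come from sliding-window majority
voting at stride patch/2, ties broken by the fixed priority tumor >
immune stroma > desmoplastic stroma > pigment > hemorrhage/necrosis >
glass, which is deterministic and biased toward not missing tumor. Training
requires ≥ 2 classes and ≥ 10 patches per class. The published
active-learning correction loop has no computable specification; it is
represented only by the ability to retrain on edited label rasters.

## Nucleus detection and CD8 scoring

Nuclei are segmented by a seeded watershed on the hematoxylin OD channel,
Gaussian-smoothed with σ = 1 µm (4 px at 0.25 µm/px) to suppress pixel
noise. The foreground mask is `smoothed OD > min_nuclear_od` (default
0.30). Seeds are local maxima, with a minimum separation of 3 µm, of the
relief `distance transform + σ_px × smoothed OD`: the distance term places
one seed per touching nucleus (two centers separated by a saddle), while
the intensity term removes plateau ridges inside elongated nuclei that a
pure distance transform would over-seed. The watershed floods the negated
relief inside the mask.

Candidates are filtered by inclusive morphometric rules: nuclear area in
[10, 120] µm², roundness 4πA/P² ≥ 0.4 (the standard isoperimetric form;
clipped to 1 on pixelated boundaries), mean nuclear OD ≥ 0.30. The
published workflow's pathologist-set values are not printed anywhere, so
these defaults are lymphocyte-scale calibration choices, all overridable.

CD8 positivity is called from the AP-red OD in a peri-nuclear annulus,
because the chromogen is membranous/cytoplasmic and a nuclear mask would
miss it. The annulus runs from 0.9 × the equivalent nuclear radius
r = √(A/π) to r + 1.5 µm; starting slightly inside the boundary keeps the
signal in the window when the watershed boundary is a little off. A cell is
CD8+ when the mean annulus OD ≥ 0.25 (default). Cells whose annulus falls
entirely outside the image are flagged unscored and treated as negative.

## Compartment geometry

Scoring uses three disjoint compartments. The invasive margin is the
region within ±500 µm of the annotated tumor border (1 mm total width),
following the Working Group convention of centering the margin on the
border; whether the band should instead be one-sided is not specified in
the source workflow, so the halfwidth and symmetry are configurable. Inside
the border and outside the band, tumor-classed pixels form the intratumoral
tumor center (iTC) and stroma-classed pixels the stromal tumor center
(sTC). Precedence: exclusion polygons > artifact/glass tissue classes >
margin > tumor-center subdivision > outside; excluded pixels never enter a
density denominator. Lymph-node preexisting lymphoid tissue is handled as a
pathologist-drawn exclusion polygon, not auto-detected. A cell's
compartment is the mask label at its centroid pixel — simple,
deterministic, and consistent with area-normalized density semantics.

## Densities and the diagnostic rule

Per compartment, density = CD8+ count / compartment area (cells/µm²);
CD8− cells and excluded/outside cells are ignored. A slide without
measurable iTC or sTC area is unscorable. The diagnosis is a total,
deterministic decision tree with inclusive thresholds:

    inflamed  if iCD8 ≥ c_i;  excluded  elif sCD8 ≥ c_s;  desert  otherwise.

The intratumoral test comes first: giving iCD8 priority reproduces the
clinically observed error mode in which excluded cases are occasionally
over-called inflamed, which a stroma-first reading could not produce. The
invasive margin never enters the rule, so margin-free biopsy material
remains diagnosable. Shipped default cut-offs are geometric midpoints
between adjacent published phenotype class means (c_i = √(2×10⁻⁴·6×10⁻⁴) ≈
3.5×10⁻⁴, c_s = √(2×10⁻⁴·2×10⁻³) ≈ 6.3×10⁻⁴ cells/µm²); they are package
defaults, not published values — the published figure's numeric cut-offs
are not printed in its text, and its "0.06 cells/µm²" reference line cannot
be reconciled with the 10⁻⁵–10⁻³ cells/µm² scale of the class means, so
cut-offs are treated strictly as configuration. Where labels exist,
`derive_cutoffs` grid-searches midpoints of adjacent observed densities per
axis (plus brackets beyond the extremes), maximizing balanced accuracy,
ties broken toward the smallest (c_i, then c_s).

## Synthetic slides

The generator emulates — at desk scale — the features the pipeline relies
on: hematoxylin-blue elliptical nuclei (radius ~ N(3.5, 0.5) µm truncated
to [2, 6] µm), an AP-red elliptical annulus around CD8+ cells, tumor nests
versus stroma texture, glass background, and pigment / hemorrhage-necrosis
patches, all through the same Beer-Lambert forward model the deconvolution
inverts. Cells follow a homogeneous Poisson process per compartment with a
hard-core rejection at 1.2 × the summed radii (no clustering statistics are
published for these cohorts, so the Poisson law is a stand-in, not a claim
about tissue). Per-phenotype density presets are the published discovery
class means (iCD8/sCD8/imCD8, cells/µm²: desert 2×10⁻⁵/2×10⁻⁴/6×10⁻⁴;
excluded 2×10⁻⁴/2×10⁻³/2×10⁻³; inflamed 6×10⁻⁴/5×10⁻³/3×10⁻³); the CD8−
background nucleus density defaults to 2×10⁻³/µm², a typical soft-tissue
nuclear density. The default canvas is 2048² px at 0.25 µm/px (0.26 mm²),
a desk-scale stand-in for ~73 mm² clinical sections; because a 512 µm-wide
canvas cannot hold a 1 mm margin band, synthetic layouts scale the margin
halfwidth down (default 40 µm) while the compartment builder keeps the
clinical 500 µm default for real annotations.

What passing tests show: the detection, scoring, geometry, and decision
chain is numerically correct on material whose appearance model matches the
renderer. What they do not show: robustness to real-tissue nuisance —
nuclear texture and pleomorphism, stain variability across scanners,
sectioning artifacts, spindle-cell morphologies (excluded from the source
workflow), or lymph-node lymphoid stroma. The tissue classifier's ≥ 90%
synthetic accuracy does not transfer to clinical slides without retraining.

## Statistics

Group differences in densities use pairwise Welch t-tests per compartment
(the published analysis names a two-way-ANOVA Holm–Šídák posttest but not
the cell-comparison statistic) with Holm–Šídák step-down adjustment across
the whole family: with p-values sorted ascending, adjusted_(k) = max_{j≤k}
1 − (1 − p_(j))^(m−j+1), clipped at 1. Diagnostic accuracy uses one-vs-rest
TP/TN/FP/FN per class with sensitivity, specificity, and precision;
undefined ratios are reported as not-applicable, never 0. Display rounding
is integer percent except exact halves (e.g. 62.5%); raw ratios are always
stored unrounded. Regressions of repeated scorings use ordinary least
squares with Pearson r; categorical diagnoses are coded desert = 1,
excluded = 2, inflamed = 3 when regressed. One published discussion
sentence swaps the inflamed class's specificity and precision relative to
its own table; the implementation follows the table and reports both
numbers so the discrepancy stays visible.

## Problem sizes and numerical choices

The reproduction workflows in `cd8pheno.benchmarks` use a 30-slide cohort
(10 per phenotype, 2048² px) for end-to-end recovery, and 10 replicate
slides at 0.5 µm/px (2048² px ≈ 1 mm²) with elevated densities
(2–4.5×10⁻³ cells/µm²) for the density-fidelity measurement, sized so each
compartment holds ≥ 500 CD8+ cells and measurement error reflects the
pipeline rather than Poisson noise. Margin geometry is validated against a
closed-form annulus (radius 2000 µm, ±500 µm band) rasterized at 2 µm/px.
All randomness flows from explicit seeds; reruns are byte-identical.
Degenerate inputs fail loudly: zero-area tumor-center compartments,
single-class cohorts, singular stain bases, and out-of-range parameters
raise typed errors before any computation is reported.

## Known limitations

- Tumor-border delineation remains a pathologist task; no automatic
  delineation is attempted.
- Cut-offs ship as configuration defaults derived from published class
  means; they lack clinical validation.
- The synthetic appearance model is deliberately simple (no nuclear
  texture, no pyramidal WSI formats, single resolution per slide).
- "Dual immune phenotype" cases are out of scope, as is any survival or
  treatment-response analysis.
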