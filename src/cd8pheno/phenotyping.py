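"""CD8 density profiles and the immune-diagnosis decision rule.

A slide's CD8+ T-cell counts are normalized by compartment area to give
densities (cells/um^2): iCD8 in the intratumoral tumor center, sCD8 in the
stromal tumor center, imCD8 in the invasive margin. Two cut-offs on the
tumor-center densities translate a profile into the immune diagnosis:

    inflamed  if iCD8 >= c_i
    excluded  elif sCD8 >= c_s
    desert    otherwise

The invasive margin never enters the decision, so biopsies without a margin
remain diagnosable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .compartments import Compartment, CompartmentMask

__all__ = ["PHENOTYPES", "DensityProfile", "CutoffConfig", "ImmuneDiagnosis",
           "DEFAULT_CUTOFFS", "compute_densities", "classify_phenotype",
           "derive_cutoffs"]

PHENOTYPES = ("desert", "excluded", "inflamed")


@dataclass
class DensityProfile:
    """Per-compartment CD8+ densities (cells/um^2) with areas and counts.

    ``imcd8`` is None for material without an invasive margin (area_im = 0),
    e.g. metastatic biopsies.
    """

    icd8: float
    scd8: float
    imcd8: float | None
    area_itc: float
    area_stc: float
    area_im: float
    count_itc: int = 0
    count_stc: int = 0
    count_im: int = 0
    slide_id: str = ""

    def __post_init__(self):
        if self.icd8 < 0 or self.scd8 < 0 or (self.imcd8 or 0) < 0:
            raise ValueError("densities must be non-negative")
        if (self.imcd8 is None) != (self.area_im == 0):
            raise ValueError("imcd8 must be absent exactly when area_im = 0")


@dataclass(frozen=True)
class CutoffConfig:
    """Density cut-offs (cells/um^2) for the tumor-center compartments."""

    c_i: float
    c_s: float

    def __post_init__(self):
        if self.c_i <= 0 or self.c_s <= 0:
            raise ValueError("cut-offs must be positive")


#: geometric midpoints between adjacent phenotype class means of the
#: discovery cohort (iCD8 2e-4 vs 6e-4; sCD8 2e-4 vs 2e-3). These are
#: package defaults derived from published class means, not published
#: cut-off values; derive cohort-specific cut-offs where labels exist.
DEFAULT_CUTOFFS = CutoffConfig(c_i=math.sqrt(2e-4 * 6e-4), c_s=math.sqrt(2e-4 * 2e-3))


@dataclass
class ImmuneDiagnosis:
    category: str
    cutoffs_used: CutoffConfig
    profile: DensityProfile


class UnscorableSlideError(ValueError):
    """Raised when a slide lacks a measurable tumor-center compartment."""


def compute_densities(cells, mask: CompartmentMask, slide_id: str = "") -> DensityProfile:
    """Count CD8+ cells per compartment and normalize by compartment area.

    CD8- cells and cells in excluded/outside regions are ignored. Requires
    positive iTC and sTC areas: the diagnosis needs both tumor-center
    sub-compartments. A zero-area invasive margin yields ``imcd8=None``.
    """
    area_itc = mask.area_um2(Compartment.ITC)
    area_stc = mask.area_um2(Compartment.STC)
    area_im = mask.area_um2(Compartment.IM)
    if area_itc == 0 or area_stc == 0:
        raise UnscorableSlideError(
            "slide has no measurable iTC or sTC area; cannot compute a profile")
    counts = {"iTC": 0, "sTC": 0, "IM": 0}
    for cell in cells:
        if cell.is_cd8_positive and cell.compartment in counts:
            counts[cell.compartment] += 1
    return DensityProfile(
        icd8=counts["iTC"] / area_itc,
        scd8=counts["sTC"] / area_stc,
        imcd8=(counts["IM"] / area_im) if area_im > 0 else None,
        area_itc=area_itc, area_stc=area_stc, area_im=area_im,
        count_itc=counts["iTC"], count_stc=counts["sTC"], count_im=counts["IM"],
        slide_id=slide_id)


def classify_phenotype(profile: DensityProfile,
                       cutoffs: CutoffConfig = DEFAULT_CUTOFFS) -> ImmuneDiagnosis:
    """Total, deterministic, margin-free decision rule (inclusive thresholds)."""
    if profile.icd8 < 0 or profile.scd8 < 0:
        raise ValueError("densities must be non-negative")
    if profile.icd8 >= cutoffs.c_i:
        category = "inflamed"
    elif profile.scd8 >= cutoffs.c_s:
        category = "excluded"
    else:
        category = "desert"
    return ImmuneDiagnosis(category=category, cutoffs_used=cutoffs, profile=profile)


def derive_cutoffs(profiles: list[DensityProfile], labels: list[str],
                   objective: str = "balanced_accuracy") -> CutoffConfig:
    """Exhaustive grid search for the cut-off pair best separating a labeled
    cohort.

    Candidates are midpoints of adjacent sorted observed densities (plus a
    bracket beyond the extremes) for each axis; the pair maximizing the
    objective of :func:`classify_phenotype` against the labels wins, ties
    broken by the smallest (c_i, then c_s).
    """
    if len(profiles) != len(labels):
        raise ValueError("profiles and labels differ in length")
    if len(profiles) < 5:
        raise ValueError("cut-off derivation needs >= 5 profiles")
    present = set(labels)
    if not present <= set(PHENOTYPES):
        raise ValueError(f"unknown labels: {sorted(present - set(PHENOTYPES))}")
    if len(present) < 2:
        raise ValueError("degenerate cohort: a single diagnosis cannot define cut-offs")
    if objective not in ("balanced_accuracy", "accuracy"):
        raise ValueError(f"unknown objective '{objective}'")

    def candidates(values: np.ndarray) -> np.ndarray:
        vals = np.unique(values)
        mids = (vals[:-1] + vals[1:]) / 2.0
        eps = 1e-12
        lo = max(vals[0] / 2.0, eps) if vals[0] > 0 else eps
        hi = vals[-1] * 1.5 + eps
        return np.unique(np.concatenate([[lo], mids[mids > 0], [hi]]))

    icd8 = np.array([p.icd8 for p in profiles])
    scd8 = np.array([p.scd8 for p in profiles])
    y = np.asarray(labels)

    def score(pred: np.ndarray) -> float:
        if objective == "accuracy":
            return float(np.mean(pred == y))
        recalls = [np.mean(pred[y == cls] == cls) for cls in sorted(present)]
        return float(np.mean(recalls))

    best: tuple[float, float, float] | None = None
    for c_i, c_s in itertools.product(candidates(icd8), candidates(scd8)):
        pred = np.where(icd8 >= c_i, "inflamed",
                        np.where(scd8 >= c_s, "excluded", "desert"))
        s = score(pred)
        key = (-s, c_i, c_s)
        if best is None or key < best:
            best = key
    assert best is not None
    return CutoffConfig(c_i=best[1], c_s=best[2])
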