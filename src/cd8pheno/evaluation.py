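"""Diagnostic-accuracy evaluation and cohort statistics.

Per-class performance follows the one-vs-rest convention (each class in
turn treated as positive): sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), precision = TP/(TP+FP). Density differences between phenotype
groups are tested per compartment with pairwise Welch t-tests and
Holm-Sidak step-down adjustment across the comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .phenotyping import PHENOTYPES, DensityProfile

__all__ = ["ConfusionMatrix", "ClassMetrics", "ComparisonResult",
           "cross_tabulate", "class_metrics", "holm_sidak_adjust",
           "compare_density_groups", "correlate_scorings", "format_percent"]


@dataclass
class ConfusionMatrix:
    """Counts[i][j] = cases predicted classes[i] with truth classes[j]."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be a square class-by-class table")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_text(self) -> str:
        width = max(10, *(len(c) for c in self.classes)) + 2
        head = "predicted \\ truth".ljust(20) + "".join(c.rjust(width) for c in self.classes)
        lines = [head]
        for i, cls in enumerate(self.classes):
            lines.append(cls.ljust(20)
                         + "".join(str(int(n)).rjust(width) for n in self.counts[i]))
        return "\n".join(lines)


@dataclass
class ClassMetrics:
    """One-vs-rest counts and ratios for every class.

    Undefined ratios (zero denominator) are None, never 0.
    """

    per_class: dict[str, dict] = field(default_factory=dict)

    def macro_average(self, metric: str) -> float | None:
        vals = [m[metric] for m in self.per_class.values() if m[metric] is not None]
        return float(np.mean(vals)) if vals else None


def cross_tabulate(predicted, truth, classes=PHENOTYPES) -> ConfusionMatrix:
    """Cross-tabulate predicted against reference (gold standard) diagnoses."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth differ in length")
    index = {c: i for i, c in enumerate(classes)}
    bad = [v for v in predicted + truth if v not in index]
    if bad:
        raise ValueError(f"labels outside the class set: {sorted(set(bad))}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, t in zip(predicted, truth):
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def _ratio(num: int, den: int) -> float | None:
    return (num / den) if den > 0 else None


def format_percent(x: float | None) -> str:
    """Display convention: integer percent except exact halves (e.g. 62.5%)."""
    if x is None:
        return "n/a"
    pct = 100.0 * x
    if abs(pct * 2 - round(pct * 2)) < 1e-9 and round(pct) != round(pct * 2) / 2:
        return f"{round(pct * 2) / 2:.1f}%"
    return f"{round(pct):.0f}%"


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest TP/TN/FP/FN, sensitivity, specificity, precision per class."""
    total = cm.total
    out = ClassMetrics()
    for i, cls in enumerate(cm.classes):
        tp = int(cm.counts[i, i])
        fp = int(cm.counts[i, :].sum() - tp)
        fn = int(cm.counts[:, i].sum() - tp)
        tn = total - tp - fp - fn
        out.per_class[cls] = {
            "TP": tp, "TN": tn, "FP": fp, "FN": fn,
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
            "precision": _ratio(tp, tp + fp),
        }
    return out


def holm_sidak_adjust(p) -> np.ndarray:
    """Holm-Sidak step-down adjustment, returned in the input order.

    With p-values sorted ascending, adjusted_(k) = max_{j<=k}
    1 - (1 - p_(j))^(m - j + 1), clipped at 1; the running maximum enforces
    monotonicity along the step-down ordering.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D list of p-values")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    adjusted_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(adjusted_sorted), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


@dataclass
class ComparisonResult:
    """Pairwise group comparisons of densities per compartment."""

    comparisons: list[dict]  # compartment, group_a, group_b, mean_diff, p_raw
    p_adjusted: np.ndarray

    def as_records(self) -> list[dict]:
        return [{**c, "p_adjusted": float(q)}
                for c, q in zip(self.comparisons, self.p_adjusted)]


def compare_density_groups(profiles: list[DensityProfile], labels: list[str],
                           compartments=("icd8", "scd8", "imcd8")) -> ComparisonResult:
    """Pairwise Welch t-tests of densities between phenotype groups per
    compartment, Holm-Sidak-adjusted across the whole comparison family.

    Profiles without an invasive margin drop out of the imcd8 comparisons.
    """
    if len(profiles) != len(labels):
        raise ValueError("profiles and labels differ in length")
    labels_arr = np.asarray(labels)
    groups = [g for g in PHENOTYPES if g in set(labels)]
    if len(groups) < 2:
        raise ValueError("need >= 2 phenotype groups")
    comparisons = []
    pvals = []
    for comp in compartments:
        values = np.array([getattr(p, comp) if getattr(p, comp) is not None
                           else np.nan for p in profiles])
        for a, b in ((x, y) for i, x in enumerate(groups) for y in groups[i + 1:]):
            va = values[(labels_arr == a) & ~np.isnan(values)]
            vb = values[(labels_arr == b) & ~np.isnan(values)]
            if len(va) < 2 or len(vb) < 2:
                raise ValueError(
                    f"group '{a if len(va) < 2 else b}' has < 2 observations "
                    f"for {comp}")
            if np.var(va) == 0 and np.var(vb) == 0 and va.mean() == vb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(va, vb, equal_var=False)
            comparisons.append({"compartment": comp, "group_a": a, "group_b": b,
                                "mean_diff": float(va.mean() - vb.mean()),
                                "p_raw": float(p)})
            pvals.append(float(p))
    return ComparisonResult(comparisons=comparisons,
                            p_adjusted=holm_sidak_adjust(pvals))


def correlate_scorings(score_a, score_b):
    """OLS fit + Pearson correlation between two repeated scorings.

    Returns (slope, intercept, r, r_squared); all None when either vector
    has zero variance (correlation undefined).
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("scorings must be equal-length 1-D vectors")
    if np.var(a) == 0 or np.var(b) == 0:
        return None, None, None, None
    res = stats.linregress(a, b)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue), float(res.rvalue**2))


#: ordinal coding used when regressing categorical diagnoses
ORDINAL_CODING = {"desert": 1, "excluded": 2, "inflamed": 3}


def encode_ordinal(categories) -> np.ndarray:
    return np.array([ORDINAL_CODING[c] for c in categories], dtype=float)
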