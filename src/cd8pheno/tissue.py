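"""Six-class tissue segmentation from labeled patches.

The slide is partitioned into cancer tissue, desmoplastic stroma,
immune-infiltrated stroma, glass background, pigment deposition, and
hemorrhage/necrosis. A compact color + texture feature extractor with a
random-forest head stands behind the patch-classifier contract; the
interface is the dense class map, not a particular architecture.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import joblib
import numpy as np
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier

from .stains import StainVectors, rgb_to_od

__all__ = [
    "TissueClass",
    "TissueClassMap",
    "PatchDataset",
    "TissueClassifier",
    "extract_patches",
    "train_tissue_classifier",
    "classify_tissue",
]


class TissueClass(IntEnum):
    TUMOR = 0
    DESMOPLASTIC_STROMA = 1
    IMMUNE_STROMA = 2
    GLASS = 3
    PIGMENT = 4
    HEMORRHAGE_NECROSIS = 5


#: sliding-window vote tie-break order (first wins); favors not missing tumor
CLASS_PRIORITY = (
    TissueClass.TUMOR,
    TissueClass.IMMUNE_STROMA,
    TissueClass.DESMOPLASTIC_STROMA,
    TissueClass.PIGMENT,
    TissueClass.HEMORRHAGE_NECROSIS,
    TissueClass.GLASS,
)

CLASS_NAMES = {
    TissueClass.TUMOR: "tumor",
    TissueClass.DESMOPLASTIC_STROMA: "desmoplastic_stroma",
    TissueClass.IMMUNE_STROMA: "immune_stroma",
    TissueClass.GLASS: "glass",
    TissueClass.PIGMENT: "pigment",
    TissueClass.HEMORRHAGE_NECROSIS: "hemorrhage_necrosis",
}


@dataclass
class TissueClassMap:
    """Dense per-pixel tissue labels with physical pixel size."""

    labels: np.ndarray  # (H, W) of TissueClass values
    mpp: float

    def __post_init__(self):
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        self.labels = np.asarray(self.labels)

    def area_um2(self, cls: TissueClass) -> float:
        return float(np.count_nonzero(self.labels == int(cls))) * self.mpp**2

    def area_report(self) -> dict[str, float]:
        return {CLASS_NAMES[c]: self.area_um2(c) for c in TissueClass}


@dataclass
class PatchDataset:
    """Labeled image patches for training/evaluating the tissue classifier."""

    patches: list[tuple[np.ndarray, int]]
    patch_px: int

    def __len__(self):
        return len(self.patches)

    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for _, lbl in self.patches:
            counts[lbl] = counts.get(lbl, 0) + 1
        return counts


def extract_patches(image: np.ndarray, class_labels: np.ndarray, patch_px: int,
                    stride: int | None = None, seed: int | None = None,
                    max_per_class: int | None = None) -> PatchDataset:
    """Tile a slide into labeled patches.

    Each tile fully inside the image is labeled by the majority ground-truth
    class over its pixels. `max_per_class` (seeded) subsamples to balance
    classes.
    """
    if patch_px < 32:
        raise ValueError("patch_px must be >= 32")
    stride = stride or patch_px
    img = np.asarray(image)
    labels = np.asarray(class_labels)
    if img.shape[:2] != labels.shape:
        raise ValueError("image and label raster shapes differ")
    h, w = labels.shape
    patches: list[tuple[np.ndarray, int]] = []
    if h < patch_px or w < patch_px:
        warnings.warn("region smaller than patch size; no patches extracted")
        return PatchDataset(patches=patches, patch_px=patch_px)
    for y in range(0, h - patch_px + 1, stride):
        for x in range(0, w - patch_px + 1, stride):
            tile_labels = labels[y:y + patch_px, x:x + patch_px]
            majority = int(np.bincount(tile_labels.ravel()).argmax())
            patches.append((img[y:y + patch_px, x:x + patch_px], majority))
    if max_per_class is not None:
        rng = np.random.default_rng(seed)
        by_class: dict[int, list[int]] = {}
        for i, (_, lbl) in enumerate(patches):
            by_class.setdefault(lbl, []).append(i)
        keep: list[int] = []
        for lbl in sorted(by_class):
            idx = by_class[lbl]
            if len(idx) > max_per_class:
                idx = list(rng.choice(idx, size=max_per_class, replace=False))
            keep.extend(idx)
        patches = [patches[i] for i in sorted(keep)]
    return PatchDataset(patches=patches, patch_px=patch_px)


def patch_features(patch: np.ndarray, vectors: StainVectors | None = None) -> np.ndarray:
    """Color + texture summary of one RGB patch.

    Features: mean/std of each RGB channel, mean/std/90th percentile of the
    three stain OD channels, and mean local gradient magnitude of the
    hematoxylin channel (texture).
    """
    if vectors is None:
        vectors = StainVectors()
    img = np.asarray(patch, dtype=float)
    od = rgb_to_od(img)
    conc = np.clip(od.reshape(-1, 3) @ vectors.inverse, 0, None)
    grad = ndi.gaussian_gradient_magnitude(
        conc[:, 0].reshape(img.shape[:2]), sigma=2.0)
    feats = [
        img.reshape(-1, 3).mean(axis=0), img.reshape(-1, 3).std(axis=0),
        conc.mean(axis=0), conc.std(axis=0),
        np.percentile(conc, 90, axis=0),
        [grad.mean(), grad.std()],
    ]
    return np.concatenate([np.atleast_1d(np.asarray(f, dtype=float)) for f in feats])


@dataclass
class TissueClassifier:
    """Serializable patch classifier (random-forest over color/texture features)."""

    model: RandomForestClassifier
    patch_px: int
    mpp: float
    config: dict = field(default_factory=dict)
    version: str = "1"

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()).hexdigest()[:12]

    def predict(self, patches: list[np.ndarray]) -> np.ndarray:
        X = np.stack([patch_features(p) for p in patches])
        return self.model.predict(X)

    def save(self, path) -> None:
        joblib.dump({"version": self.version, "config": self.config,
                     "config_hash": self.config_hash, "patch_px": self.patch_px,
                     "mpp": self.mpp, "model": self.model}, path)

    @classmethod
    def load(cls, path) -> "TissueClassifier":
        blob = joblib.load(path)
        return cls(model=blob["model"], patch_px=blob["patch_px"],
                   mpp=blob["mpp"], config=blob["config"], version=blob["version"])


def train_tissue_classifier(train: PatchDataset, config: dict | None = None,
                            seed: int = 0, mpp: float = 0.25) -> TissueClassifier:
    """Fit the tissue classifier on labeled patches.

    Requires at least two classes and at least 10 patches per present class.
    """
    config = dict(config or {})
    counts = train.class_counts()
    if len(counts) < 2:
        raise ValueError("training requires >= 2 tissue classes")
    for lbl, n in sorted(counts.items()):
        if n < 10:
            name = CLASS_NAMES.get(TissueClass(lbl), str(lbl))
            raise ValueError(f"class '{name}' has only {n} patches (minimum 10)")
    X = np.stack([patch_features(p) for p, _ in train.patches])
    y = np.array([lbl for _, lbl in train.patches])
    model = RandomForestClassifier(
        n_estimators=config.get("n_estimators", 100),
        max_depth=config.get("max_depth"),
        random_state=seed, n_jobs=1)
    model.fit(X, y)
    return TissueClassifier(model=model, patch_px=train.patch_px, mpp=mpp,
                            config=config)


def classify_tissue(image: np.ndarray, classifier: TissueClassifier,
                    patch_px: int | None = None, stride: int | None = None,
                    mpp: float | None = None) -> TissueClassMap:
    """Produce a dense tissue-class raster by sliding-window voting.

    Windows of the training patch size are classified on a grid with the
    given stride (default half-window); each window votes on its central
    half, each pixel takes the majority vote over the blocks covering it
    (ties broken by `CLASS_PRIORITY`), and uncovered border pixels inherit
    the nearest vote.
    """
    patch_px = patch_px or classifier.patch_px
    if patch_px != classifier.patch_px:
        raise ValueError("classifier was trained with a different patch size")
    mpp = mpp if mpp is not None else classifier.mpp
    if abs(mpp - classifier.mpp) / classifier.mpp > 0.25:
        raise ValueError(
            f"slide resolution {mpp} um/px incompatible with training "
            f"resolution {classifier.mpp} um/px")
    stride = stride or max(1, patch_px // 2)
    img = np.asarray(image)
    h, w = img.shape[:2]
    if h < patch_px or w < patch_px:
        raise ValueError("image smaller than classifier window")
    ys = sorted(set(list(range(0, h - patch_px + 1, stride)) + [h - patch_px]))
    xs = sorted(set(list(range(0, w - patch_px + 1, stride)) + [w - patch_px]))
    tiles = [img[y:y + patch_px, x:x + patch_px] for y in ys for x in xs]
    preds = classifier.predict(tiles).reshape(len(ys), len(xs))
    # each window votes on its central half only: boundary bleed then spans
    # ~patch/4 instead of ~patch/2
    q = max(1, patch_px // 4)
    votes = np.zeros((len(TissueClass), h, w), dtype=np.uint16)
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            votes[preds[i, j], y + q:y + patch_px - q, x + q:x + patch_px - q] += 1
    order = [int(c) for c in CLASS_PRIORITY]
    stacked = votes[order]  # ties resolved by priority position via argmax
    winner = np.asarray(order, dtype=np.uint8)[stacked.argmax(axis=0)]
    # border pixels outside every central block inherit the nearest vote
    covered = votes.sum(axis=0) > 0
    if not covered.all():
        _, (iy, ix) = ndi.distance_transform_edt(~covered, return_indices=True)
        winner = winner[iy, ix]
    return TissueClassMap(labels=winner, mpp=mpp)


def write_class_map(cmap: TissueClassMap, path) -> None:
    """Indexed single-channel TIFF plus a JSON legend sidecar."""
    import tifffile

    tifffile.imwrite(path, cmap.labels.astype(np.uint8))
    legend = {"mpp": cmap.mpp,
              "classes": {str(int(c)): CLASS_NAMES[c] for c in TissueClass}}
    with open(str(path) + ".legend.json", "w") as fh:
        json.dump(legend, fh, indent=2)


def read_class_map(path) -> TissueClassMap:
    import tifffile

    labels = tifffile.imread(path)
    with open(str(path) + ".legend.json") as fh:
        legend = json.load(fh)
    return TissueClassMap(labels=labels, mpp=float(legend["mpp"]))
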