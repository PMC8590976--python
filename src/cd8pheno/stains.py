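"""Optical-density stain separation for chromogenic IHC.

Chromogenic slides considered here carry a hematoxylin nuclear counterstain
(blue) and an Alkaline-Phosphatase red chromogen marking CD8. Beer-Lambert
absorbance is additive in optical density (OD = -log10 transmittance), so a
3x3 change of basis separates the RGB image into per-stain OD channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StainVectors", "ODMaps", "deconvolve_stains", "od_to_rgb"]

_EPS = 1e-6


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length stain vector")
    return v / n


def _default_residual(h: np.ndarray, r: np.ndarray) -> np.ndarray:
    res = np.cross(h, r)
    res = np.clip(res, 0.0, None)
    if np.linalg.norm(res) < 1e-8:
        # fall back to the coordinate axis least represented by the stains
        res = np.zeros(3)
        res[int(np.argmin(h + r))] = 1.0
    return _unit(res)


@dataclass(frozen=True)
class StainVectors:
    """Unit OD absorbance vectors spanning the stain space.

    Defaults: the standard hematoxylin vector of Ruifrok & Johnston-style
    deconvolution and a fast-red-like vector for the AP chromogen (absorbs
    green/blue, transmits red). The residual completes the basis.
    """

    hematoxylin_od: np.ndarray = field(default_factory=lambda: _unit([0.650, 0.704, 0.286]))
    ap_red_od: np.ndarray = field(default_factory=lambda: _unit([0.120, 0.788, 0.604]))
    residual_od: np.ndarray | None = None

    def __post_init__(self):
        h = _unit(self.hematoxylin_od)
        r = _unit(self.ap_red_od)
        object.__setattr__(self, "hematoxylin_od", h)
        object.__setattr__(self, "ap_red_od", r)
        res = self.residual_od
        res = _default_residual(h, r) if res is None else _unit(res)
        object.__setattr__(self, "residual_od", res)
        if np.any(self.matrix < -1e-12):
            raise ValueError("stain vectors must be componentwise non-negative")
        if abs(np.linalg.det(self.matrix)) < 1e-6:
            raise ValueError("stain vectors are linearly dependent")

    @property
    def matrix(self) -> np.ndarray:
        """Rows = stain OD vectors (hematoxylin, AP red, residual)."""
        return np.stack([self.hematoxylin_od, self.ap_red_od, self.residual_od])

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


@dataclass
class ODMaps:
    """Per-stain optical-density rasters (same shape as the source image)."""

    hematoxylin: np.ndarray
    ap_red: np.ndarray
    mpp: float

    def __post_init__(self):
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if self.hematoxylin.shape != self.ap_red.shape:
            raise ValueError("OD channel shapes differ")

    @property
    def shape(self):
        return self.hematoxylin.shape


def rgb_to_od(image: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Convert an RGB image (8-bit or float in [0, i0]) to optical density."""
    img = np.asarray(image, dtype=float)
    return -np.log10(np.clip(img, _EPS, None) / i0)


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`; returns uint8 RGB."""
    t = i0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.rint(t), 0, 255).astype(np.uint8)


def deconvolve_stains(image: np.ndarray, vectors: StainVectors | None = None,
                      *, mpp: float, i0: float = 255.0) -> ODMaps:
    """Unmix an RGB image into hematoxylin and AP-red OD channels.

    OD is computed per RGB channel as -log10((I + eps) / I0) and projected
    onto the stain basis; negative projections (noise) are clipped at zero.

    Parameters
    ----------
    image : (H, W, 3) array, uint8 or float
    vectors : StainVectors, optional
        Stain basis; defaults are used when omitted.
    mpp : float
        Microns per pixel, carried through so downstream morphometrics and
        densities have physical units.
    """
    if vectors is None:
        vectors = StainVectors()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    od = rgb_to_od(img, i0=i0)
    conc = od.reshape(-1, 3) @ vectors.inverse
    conc = np.clip(conc, 0.0, None).reshape(img.shape)
    return ODMaps(hematoxylin=conc[..., 0], ap_red=conc[..., 1], mpp=mpp)
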