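"""The 11-descriptor feature vector computed per validated RoI.

Geometric group: semiAxm (minor semi-axis of the second-central-moments
ellipse), axm / axM (side lengths of the minimum-area oriented bounding
box), ecc (eccentricity sqrt(axM^2 - axm^2)/axM, 0 for a circle and 1 for a
line), solidity (area / convex-hull area), areap (pixel count), perimeter
(morphological-contour pixel count).

Texture group, from the 256-bin grey-level histogram h of the RoI pixels,
normalized to x = h / sum(h): histIndex (population std of the 256
normalized bin values), stdg (sqrt(sum x_i (i - mu)^2), the grey-level
standard deviation), ent (Shannon entropy -sum x ln x, in nats), contrast
(|gInt - gExt| / (gInt + gExt) where gInt / gExt are the mean grey levels
inside the RoI and inside the oriented bounding box but outside the RoI).

All descriptors cost linear time in the RoI pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon as draw_polygon

from .imaging import RoI

FEATURE_NAMES: tuple[str, ...] = (
    "semiAxm",
    "axm",
    "axM",
    "ecc",
    "solidity",
    "areap",
    "perimeter",
    "histIndex",
    "stdg",
    "ent",
    "contrast",
)

#: short feature codes accepted as aliases (as used in evolved expressions)
FEATURE_ALIASES: dict[str, str] = {
    "sAxm": "semiAxm",
    "sol": "solidity",
    "per": "perimeter",
    "hstI": "histIndex",
    "ctrs": "contrast",
}


class FeatureError(ValueError):
    pass


@dataclass
class RoIHistogram:
    """Grey-level histogram of an RoI and derived interior/exterior means."""

    h: np.ndarray  # 256 integer counts
    x: np.ndarray  # normalized histogram h / sum(h)
    mu_grey: float
    g_int: float
    g_ext: float
    g_ext_empty: bool = False


@dataclass
class FeatureVector:
    semiAxm: float
    axm: float
    axM: float
    ecc: float
    solidity: float
    areap: float
    perimeter: float
    histIndex: float
    stdg: float
    ent: float
    contrast: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in FEATURE_NAMES}


def _obb_interior_mask(roi: RoI, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the oriented bounding box as a boolean mask."""
    (cy, cx), ang = roi.obb_center, roi.obb_angle
    hl, hs = roi.axM / 2.0, roi.axm / 2.0
    # the box angle is the long side's direction in (row, col) coordinates:
    # unit vectors du (long side) and dv (short side)
    du = np.array([np.cos(ang), np.sin(ang)])
    dv = np.array([-np.sin(ang), np.cos(ang)])
    center = np.array([cy, cx])
    corners = np.array(
        [
            center + hl * du + hs * dv,
            center + hl * du - hs * dv,
            center - hl * du - hs * dv,
            center - hl * du + hs * dv,
        ]
    )
    rr, cc = draw_polygon(corners[:, 0], corners[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def roi_histogram(img: np.ndarray, roi: RoI) -> RoIHistogram:
    """Grey-level histogram of the RoI pixels plus interior/exterior means.

    g_ext averages the pixels inside the oriented bounding box but outside
    the RoI; if that set is empty (box equals the blob) g_ext is 0 and
    flagged.
    """
    a = np.asarray(img)
    pix = roi.blob.pixels
    if len(pix) == 0:
        raise FeatureError("degenerate RoI: no member pixels")
    vals = a[pix[:, 0], pix[:, 1]].astype(int)
    h = np.bincount(vals, minlength=256)[:256]
    x = h / h.sum()
    levels = np.arange(256)
    mu = float((levels * x).sum())
    g_int = float(vals.mean())

    box = _obb_interior_mask(roi, a.shape)
    box[pix[:, 0], pix[:, 1]] = False
    ext = a[box]
    if ext.size == 0:
        return RoIHistogram(h, x, mu, g_int, 0.0, g_ext_empty=True)
    return RoIHistogram(h, x, mu, g_int, float(ext.mean()))


def _convex_area(pixels: np.ndarray) -> float:
    """Area of the convex hull of the pixel set, counting unit footprints.

    The hull is taken over the four corners of every pixel square so a
    filled convex shape has solidity 1 up to rasterization.
    """
    pts = pixels.astype(float)
    corners = np.vstack(
        [pts + off for off in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    try:
        return float(ConvexHull(corners).volume)
    except QhullError:
        return float(len(pixels))


def _ellipse_semi_minor(pixels: np.ndarray) -> float:
    """Minor semi-axis of the ellipse with the pixel set's second moments."""
    pts = pixels.astype(float)
    d = pts - pts.mean(axis=0)
    # +1/12: second moment of the unit pixel footprint
    cov = d.T @ d / len(pts) + np.eye(2) / 12.0
    eigmin = float(np.linalg.eigvalsh(cov)[0])
    return 2.0 * np.sqrt(max(eigmin, 0.0))


def compute_features(img: np.ndarray, roi: RoI) -> FeatureVector:
    """All 11 descriptors for one validated RoI."""
    hist = roi_histogram(img, roi)
    x = hist.x
    levels = np.arange(256)

    axM, axm = roi.axM, roi.axm
    ecc = float(np.sqrt(max(axM**2 - axm**2, 0.0)) / axM) if axM > 0 else 0.0
    areap = float(roi.blob.area_px)
    hull_area = _convex_area(roi.blob.pixels)
    solidity = float(min(areap / hull_area, 1.0)) if hull_area > 0 else 1.0
    perimeter = float(len(roi.blob.contour))
    semi_axm = _ellipse_semi_minor(roi.blob.pixels)

    hist_index = float(x.std())  # population std of 256 normalized bins
    var_g = float((x * (levels - hist.mu_grey) ** 2).sum())
    stdg = float(np.sqrt(var_g))
    nz = x[x > 0]
    ent = float(-(nz * np.log(nz)).sum())
    denom = hist.g_int + hist.g_ext
    contrast = float(abs(hist.g_int - hist.g_ext) / denom) if denom > 0 else 0.0

    return FeatureVector(
        semiAxm=semi_axm,
        axm=float(axm),
        axM=float(axM),
        ecc=ecc,
        solidity=solidity,
        areap=areap,
        perimeter=perimeter,
        histIndex=hist_index,
        stdg=stdg,
        ent=ent,
        contrast=contrast,
    )
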