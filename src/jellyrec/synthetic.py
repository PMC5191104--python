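"""Seeded synthetic imagery and labelled feature tables.

The survey imagery this package was designed around is not public, so this
module emulates its structure for ground-truthed testing: 640x480 8-bit
frames of a uniform, low-textured water column (smooth illumination
gradient + Gaussian sensor noise, sigma ~ 3 grey levels) populated with

* jellies       - bright, sharp-contoured lobed-ellipse blobs,
* particulate   - small, heavily blurred bright dots,
* reflections   - large, very diffuse bright patches,
* fish          - elongated darker shapes (never brighter than the water,
                  so they vanish at the one-sided segmentation stage).

Feature tables emulate the 545-RoI labelled set's statistical skeleton:
class-conditional Gaussians on a stated informative subset (default
semiAxm, axm, ecc) and one shared distribution on the remaining noise
features.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dataset import Dataset
from .features import FEATURE_NAMES


class SyntheticError(ValueError):
    pass


@dataclass
class ObjectSpec:
    cls: str  # jelly | particulate | reflection | fish
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # semi-axes (long, short), px
    angle: float = 0.0
    intensity: float = 80.0  # offset over background (negative for fish)
    blur_sigma: float = 0.0
    lobes: int = 0  # sinusoidal boundary lobes (jellies)
    lobe_amp: float = 0.0


@dataclass
class SceneSpec:
    shape: tuple[int, int] = (480, 640)
    bg_mean: float = 60.0
    bg_gradient: float = 10.0  # peak-to-peak smooth illumination drift
    noise_sigma: float = 3.0
    objects: list[ObjectSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        for o in self.objects:
            r, c = o.center
            if not (0 <= r < h and 0 <= c < w):
                raise SyntheticError(f"object at {o.center} outside {self.shape}")
            if o.blur_sigma < 0:
                raise SyntheticError("blur_sigma must be >= 0")


def _object_layer(o: ObjectSpec, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one object as an intensity-offset layer."""
    h, w = shape
    a, b = max(o.axes), min(o.axes)
    pad = int(np.ceil(max(a, b) + 4 * o.blur_sigma + 2))
    r0 = max(0, int(o.center[0]) - pad)
    r1 = min(h, int(o.center[0]) + pad + 1)
    c0 = max(0, int(o.center[1]) - pad)
    c1 = min(w, int(o.center[1]) + pad + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - o.center[0]
    dx = cc - o.center[1]
    ca, sa = np.cos(o.angle), np.sin(o.angle)
    u = dy * ca + dx * sa  # along the long axis
    v = -dy * sa + dx * ca
    rad = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if o.lobes > 0 and o.lobe_amp > 0:
        theta = np.arctan2(v / b, u / a)
        rad = rad / (1.0 + o.lobe_amp * np.sin(o.lobes * theta))
    inside = (rad <= 1.0).astype(float)
    if o.blur_sigma > 0:
        inside = ndimage.gaussian_filter(inside, o.blur_sigma)
    layer = np.zeros(shape)
    layer[r0:r1, c0:c1] = inside * o.intensity
    return layer


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, list[dict]]:
    """Render an 8-bit greyscale frame and its ground-truth annotations.

    Returns (image, truth) with one truth record per object: class,
    center, axes, angle.  Bit-identical given the same spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    # smooth illumination drift: a random-orientation linear ramp
    ang = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (yy / h) * np.cos(ang) + (xx / w) * np.sin(ang)
    img = spec.bg_mean + spec.bg_gradient * (ramp - ramp.mean())
    for o in spec.objects:
        img = img + _object_layer(o, spec.shape)
    img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    truth = [
        {"class": o.cls, "center": o.center, "axes": o.axes, "angle": o.angle}
        for o in spec.objects
    ]
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), truth


def random_scene(seed: int, n_jelly: int = 2, n_particulate: int = 5,
                 n_reflection: int = 0, n_fish: int = 0,
                 shape: tuple[int, int] = (480, 640),
                 max_tries: int = 2000) -> SceneSpec:
    """A packed scene with non-overlapping randomly placed objects."""
    rng = np.random.default_rng(seed)
    h, w = shape
    objects: list[ObjectSpec] = []
    placed: list[tuple[float, float, float]] = []  # (r, c, radius)

    def place(radius: float) -> tuple[float, float]:
        for _ in range(max_tries):
            r = rng.uniform(radius + 10, h - radius - 10)
            c = rng.uniform(radius + 10, w - radius - 10)
            if all(np.hypot(r - pr, c - pc) > radius + prad + 12
                   for pr, pc, prad in placed):
                placed.append((r, c, radius))
                return r, c
        raise SyntheticError("could not place object: scene too packed")

    for _ in range(n_jelly):
        a = rng.uniform(18, 35)
        b = a * rng.uniform(0.35, 0.7)
        r, c = place(a)
        objects.append(ObjectSpec(
            "jelly", (r, c), (a, b), angle=rng.uniform(0, np.pi),
            intensity=rng.uniform(70, 110), blur_sigma=0.4,
            lobes=int(rng.integers(4, 8)), lobe_amp=0.08,
        ))
    for _ in range(n_particulate):
        a = rng.uniform(4, 8)
        r, c = place(a * 3)
        objects.append(ObjectSpec(
            "particulate", (r, c), (a, a * rng.uniform(0.8, 1.0)),
            intensity=rng.uniform(60, 90), blur_sigma=0.9 * a,
        ))
    for _ in range(n_reflection):
        a = rng.uniform(40, 70)
        r, c = place(a)
        objects.append(ObjectSpec(
            "reflection", (r, c), (a, a * rng.uniform(0.6, 0.9)),
            angle=rng.uniform(0, np.pi),
            intensity=rng.uniform(30, 50), blur_sigma=20.0,
        ))
    for _ in range(n_fish):
        a = rng.uniform(25, 45)
        r, c = place(a)
        objects.append(ObjectSpec(
            "fish", (r, c), (a, a * rng.uniform(0.15, 0.3)),
            angle=rng.uniform(0, np.pi),
            intensity=-rng.uniform(20, 40), blur_sigma=0.8,
        ))
    return SceneSpec(shape=shape, objects=objects, seed=seed)


# ----------------------------------------------------------------------
# labelled feature tables
# ----------------------------------------------------------------------

def _default_informative() -> dict[str, tuple[float, float, float]]:
    # feature -> (positive mean, negative mean, shared sigma); a 2-sigma
    # shift per feature: individually weak, jointly well separable
    return {
        "semiAxm": (1.0, -1.0, 1.0),
        "axm": (1.0, -1.0, 1.0),
        "ecc": (1.0, -1.0, 1.0),
    }


@dataclass
class FeatureTableSpec:
    n_per_class: int = 200
    informative: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_informative
    )
    noise_mean: float = 0.0
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise SyntheticError("n_per_class must be >= 1")
        for f, (_, _, s) in self.informative.items():
            if f not in FEATURE_NAMES:
                raise SyntheticError(f"unknown informative feature {f!r}")
            if s <= 0:
                raise SyntheticError("informative sigma must be > 0")


def simulate_feature_table(spec: FeatureTableSpec) -> Dataset:
    """Balanced binary table: class-conditional Gaussians on the
    informative features, one shared Gaussian on the rest."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class
    y = np.concatenate([np.ones(n, int), np.zeros(n, int)])
    X = rng.normal(spec.noise_mean, spec.noise_sigma, size=(2 * n, len(FEATURE_NAMES)))
    for f, (mu_pos, mu_neg, sigma) in spec.informative.items():
        j = FEATURE_NAMES.index(f)
        X[:n, j] = rng.normal(mu_pos, sigma, size=n)
        X[n:, j] = rng.normal(mu_neg, sigma, size=n)
    perm = rng.permutation(2 * n)
    return Dataset(X[perm], y[perm])


def separable_table(seed: int = 0, n_per_class: int = 30) -> Dataset:
    """Linearly separable fixture: positives semiAxm ~ N(15, 1),
    negatives ~ N(3, 1); every other feature uninformative."""
    spec = FeatureTableSpec(
        n_per_class=n_per_class,
        informative={"semiAxm": (15.0, 3.0, 1.0)},
        seed=seed,
    )
    return simulate_feature_table(spec)


def recovery_table(seed: int = 0, n_per_class: int = 200) -> Dataset:
    """The 3-informative / 8-noise recovery fixture (default n = 400)."""
    return simulate_feature_table(FeatureTableSpec(n_per_class=n_per_class, seed=seed))
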