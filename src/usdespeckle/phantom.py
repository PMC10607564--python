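"""Seeded synthetic ultrasound-like phantoms.

Real clinical ultrasound contains no noise-free ground truth, so every
experiment here runs on phantoms: smooth dark backgrounds with a
depth-dependent intensity gradient and elliptical lesions that are hypo-
or hyper-echoic relative to their surroundings.  Benign lesions have
smooth elliptical boundaries; malignant ones add a seeded low-order
radial Fourier perturbation, giving them the spiculated margins that make
the two classes separable by a boundary-irregularity statistic
(perimeter^2 / area).

The images are deliberately *clean* — no pixel-level noise — so that the
simulated multiplicative speckle applied downstream is the only noise
present.  They make no claim to acoustic realism (no point-spread
function, no beamforming); see the methods note for what that implies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as _cc_label
from skimage.measure import perimeter_crofton

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_labeled_set",
    "boundary_irregularity",
]

LESION_CLASSES = ("benign", "malignant", "none")

# axis lengths as fraction of the shorter image side
_AXIS_FRAC = (0.05, 0.25)
_MAX_AXIS_RATIO = 2.0
# malignant boundary perturbation: harmonics 4..8, per-harmonic amplitude
_MALIGNANT_HARMONICS = (4, 5, 6, 7, 8)
_MALIGNANT_AMPLITUDE = (0.06, 0.10)


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic recipe for one phantom image."""

    height: int = 128
    width: int = 128
    n_lesions: int = 1
    lesion_class: str = "benign"
    background_level: float = 100.0
    gradient_strength: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ValueError(
                f"phantom must be at least 32x32 (two 2x downsamplings), "
                f"got {self.height}x{self.width}"
            )
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if self.lesion_class not in LESION_CLASSES:
            raise ValueError(f"lesion_class must be one of {LESION_CLASSES}")
        if not 0.0 <= self.background_level <= 255.0:
            raise ValueError("background_level must lie in [0, 255]")
        if not 0.0 <= self.gradient_strength <= 1.0:
            raise ValueError("gradient_strength must lie in [0, 1]")


def _lesion_mask(shape, center, axes, angle, rng, malignant: bool) -> np.ndarray:
    """Boolean mask of one (possibly radially perturbed) ellipse."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    rho = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    a, b = axes
    # polar radius of the rotated ellipse at each pixel's angle
    rel = phi - angle
    r_ell = a * b / np.sqrt((b * np.cos(rel)) ** 2 + (a * np.sin(rel)) ** 2)
    if malignant:
        bump = np.zeros_like(phi)
        for k in _MALIGNANT_HARMONICS:
            amp = rng.uniform(*_MALIGNANT_AMPLITUDE)
            bump += amp * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
        r_ell = r_ell * (1.0 + bump)
    return rho <= r_ell


def generate_phantom(
    spec: PhantomSpec, *, return_mask: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Render the clean phantom for ``spec``; bit-identical under a fixed seed.

    With ``return_mask=True`` also returns the integer-labelled lesion mask
    (0 = background, 1..n_lesions = lesion id).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    image = np.full((h, w), spec.background_level, dtype=np.float64)

    if spec.gradient_strength > 0:
        # depth gradient: darker with depth, as attenuation would produce
        ramp = np.linspace(0.5, -0.5, h)[:, None] * 60.0 * spec.gradient_strength
        image += ramp
        # band-limited large-scale texture (still noise-free at pixel scale)
        coarse = rng.normal(0.0, 1.0, size=(6, 6))
        field = ndimage.zoom(coarse, (h / 6, w / 6), order=3, grid_mode=True,
                             mode="nearest")
        image += 8.0 * spec.gradient_strength * field

    labels = np.zeros((h, w), dtype=np.int32)
    side = min(h, w)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, clearance radius)
    for i in range(spec.n_lesions):
        malignant = spec.lesion_class == "malignant"
        for _ in range(200):
            a = rng.uniform(_AXIS_FRAC[0], _AXIS_FRAC[1]) * side / 2
            b = rng.uniform(max(a / _MAX_AXIS_RATIO, _AXIS_FRAC[0] * side / 2), a)
            a, b = max(a, 3.0), max(b, 3.0)
            angle = rng.uniform(0, np.pi)
            reach = a * (1.5 if malignant else 1.0) + 2.0
            if h - 2 * reach <= 0 or w - 2 * reach <= 0:
                continue
            cy = rng.uniform(reach, h - reach)
            cx = rng.uniform(reach, w - reach)
            if all(np.hypot(cy - py, cx - px) > reach + pr + 2 for py, px, pr in placed):
                placed.append((cy, cx, reach))
                break
        else:
            raise ValueError(
                f"could not place {spec.n_lesions} non-overlapping lesions "
                f"in a {h}x{w} phantom"
            )
        mask = _lesion_mask((h, w), (cy, cx), (a, b), angle, rng, malignant)
        labels[mask] = i + 1

        magnitude = rng.uniform(30.0, 60.0)
        sign = -1.0 if rng.random() < 0.5 else 1.0
        # keep the lesion inside [0, 255] given gradient/texture headroom
        if sign < 0 and spec.background_level - magnitude < 10.0:
            sign = 1.0
        if sign > 0 and spec.background_level + magnitude > 245.0:
            sign = -1.0
        offset = np.zeros((h, w))
        offset[mask] = sign * magnitude
        image += ndimage.gaussian_filter(offset, 0.8)

    np.clip(image, 0.0, 255.0, out=image)
    return (image, labels) if return_mask else image


def generate_labeled_set(
    n_per_class: int, base_spec: PhantomSpec = PhantomSpec(), seed: int = 0
) -> list[tuple[np.ndarray, str]]:
    """Balanced benign/malignant phantom set with per-item derived seeds."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        2 * n_per_class, dtype=np.uint32
    ) >> 1
    n_lesions = max(base_spec.n_lesions, 1)
    items: list[tuple[np.ndarray, str]] = []
    for i in range(n_per_class):
        for j, cls in enumerate(("benign", "malignant")):
            spec = dataclasses.replace(
                base_spec,
                lesion_class=cls,
                n_lesions=n_lesions,
                seed=int(child_seeds[2 * i + j]),
            )
            items.append((generate_phantom(spec), cls))
    return items


def boundary_irregularity(mask: np.ndarray) -> float:
    """Normalized perimeter^2 / (4 pi area) of the largest component; circle = 1."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty mask")
    lab = _cc_label(mask)
    largest = lab == np.argmax(np.bincount(lab.ravel())[1:]) + 1
    area = float(largest.sum())
    perim = float(perimeter_crofton(largest, directions=4))
    return perim * perim / (4.0 * np.pi * area)
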