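"""Classic despeckling baselines: the Median filter and the Lee filter.

The Lee filter shrinks each pixel toward its local window mean in
proportion to how much of the window variance can be attributed to
structure rather than noise:

    P = Kbar + W * (C - Kbar),   W = sigma_k^2 / (sigma_k^2 + sigma_i^2)

with Kbar the window mean, C the centre pixel, sigma_k^2 the window
variance and sigma_i^2 a single scalar per image.  Following the source
formulation literally, sigma_i^2 defaults to the global variance of the
whole image (classical Lee uses an estimated noise variance instead; an
override argument is provided).  Since W is in [0, 1], every output pixel
is a convex combination of Kbar and C; flat regions (W -> 0) return the
window mean, busy regions (W -> 1) are left untouched, which preserves
edges.

Local moments use the population (divide-by-n) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_BORDER_MODES = {"reflect": "reflect", "edge": "nearest"}


@dataclass(frozen=True)
class FilterSpec:
    """Square sliding-window configuration shared by both filters."""

    window: int = 7
    border_mode: str = "reflect"

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd integer >= 3, got {self.window}")
        if self.border_mode not in _BORDER_MODES:
            raise ValueError(f"border_mode must be one of {sorted(_BORDER_MODES)}")


def _check_size(image: np.ndarray, spec: FilterSpec) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if min(image.shape) < spec.window:
        raise ValueError(
            f"window {spec.window} exceeds image extent {image.shape}"
        )
    return image


def median_filter(image: np.ndarray, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Replace each pixel by the median of its window neighbourhood."""
    image = _check_size(image, spec)
    return ndimage.median_filter(
        image, size=spec.window, mode=_BORDER_MODES[spec.border_mode]
    )


def lee_filter(
    image: np.ndarray,
    spec: FilterSpec = FilterSpec(),
    *,
    image_variance: float | None = None,
) -> np.ndarray:
    """Adaptive Lee filter; ``image_variance`` overrides the global sigma_i^2."""
    image = _check_size(image, spec)
    mode = _BORDER_MODES[spec.border_mode]
    local_mean = ndimage.uniform_filter(image, size=spec.window, mode=mode)
    local_sq = ndimage.uniform_filter(image * image, size=spec.window, mode=mode)
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    sigma_i2 = float(np.var(image)) if image_variance is None else float(image_variance)
    denom = local_var + sigma_i2
    with np.errstate(invalid="ignore"):
        weight = np.where(denom > 0, local_var / np.where(denom > 0, denom, 1.0), 0.0)
    return local_mean + weight * (image - local_mean)
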