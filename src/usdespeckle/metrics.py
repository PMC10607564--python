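"""Full-reference image quality metrics and binary classification metrics.

SSIM is computed *globally* by default — one set of image-wide moments per
image pair:

    SSIM(x, y) = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
                 / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

rather than the sliding-window mean-SSIM variant (available via
``windowed=True``, backed by scikit-image).  PSNR uses the convention that
``peakval`` is the maximum intensity actually present in the reference
image; pass ``peakval=255`` for the fixed-range convention used by most
other software.  Identical images have infinite PSNR, which is raised as
:class:`InfinitePSNRError` rather than returned as a number.

Classification metrics (accuracy, sensitivity, specificity, PPV, NPV, F1,
MCC) are evaluated from raw confusion counts; any metric whose denominator
is zero is reported as ``None`` ("undefined"), never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity as _skimage_ssim

__all__ = [
    "SsimConstants",
    "QualityReport",
    "ConfusionCounts",
    "InfinitePSNRError",
    "ssim",
    "psnr",
    "evaluate_set",
    "classification_metrics",
    "CLASSIFICATION_METRIC_NAMES",
]


class InfinitePSNRError(ZeroDivisionError):
    """Raised when MSE is exactly zero, i.e. PSNR is infinite."""


@dataclass(frozen=True)
class SsimConstants:
    """Stabilizers c1 = (K1 L)^2, c2 = (K2 L)^2 for an L-unit dynamic range."""

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 255.0

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("SSIM stabilizers must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def _as_pair(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def ssim(x, y, consts: SsimConstants = SsimConstants(), *, windowed: bool = False) -> float:
    """Structural similarity between two images; 1.0 iff identical."""
    x, y = _as_pair(x, y)
    if windowed:
        return float(
            _skimage_ssim(x, y, data_range=consts.dynamic_range,
                          K1=consts.k1, K2=consts.k2)
        )
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    c1, c2 = consts.c1, consts.c2
    return float(
        (2 * mx * my + c1) * (2 * cov + c2)
        / ((mx * mx + my * my + c1) * (vx + vy + c2))
    )


def psnr(x, y, *, peakval: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB, reference ``x`` vs candidate ``y``.

    ``peakval`` defaults to the maximum intensity present in the reference.
    """
    x, y = _as_pair(x, y)
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        raise InfinitePSNRError("identical images: MSE = 0, PSNR is infinite")
    peak = float(np.max(x)) if peakval is None else float(peakval)
    return 10.0 * math.log10(peak * peak / mse)


@dataclass
class QualityReport:
    """Per-image SSIM/PSNR plus their mean +/- std over a set."""

    per_image: list[tuple[str, float, float]] = field(default_factory=list)
    ssim_mean: float = math.nan
    ssim_std: float = math.nan
    psnr_mean_db: float = math.nan
    psnr_std_db: float = math.nan

    @classmethod
    def from_pairs(cls, entries: list[tuple[str, float, float]]) -> "QualityReport":
        s = np.array([e[1] for e in entries], dtype=float)
        p = np.array([e[2] for e in entries], dtype=float)
        return cls(
            per_image=list(entries),
            ssim_mean=float(s.mean()),
            ssim_std=float(s.std()),
            psnr_mean_db=float(p.mean()),
            psnr_std_db=float(p.std()),
        )


def evaluate_set(references, candidates, consts: SsimConstants = SsimConstants(),
                 *, identifiers=None, peakval: float | None = None,
                 windowed: bool = False) -> QualityReport:
    """Score each candidate against its index-aligned reference."""
    if len(references) != len(candidates):
        raise ValueError(
            f"length mismatch: {len(references)} references vs {len(candidates)} candidates"
        )
    if identifiers is None:
        identifiers = [str(i) for i in range(len(references))]
    entries = []
    for ident, ref, cand in zip(identifiers, references, candidates):
        try:
            p = psnr(ref, cand, peakval=peakval)
        except InfinitePSNRError:
            p = math.inf
        entries.append((ident, ssim(ref, cand, consts, windowed=windowed), p))
    return QualityReport.from_pairs(entries)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; the malignant class is the positive one."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("at least one count must be positive")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


CLASSIFICATION_METRIC_NAMES = (
    "accuracy", "sensitivity", "specificity", "ppv", "npv", "f1", "mcc",
)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def classification_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """The seven standard binary metrics; undefined ratios come back None."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sens = _ratio(tp, tp + fn)
    ppv = _ratio(tp, tp + fp)
    if ppv is None or sens is None or (ppv + sens) == 0:
        f1 = None
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den
    return {
        "accuracy": _ratio(tp + tn, counts.total),
        "sensitivity": sens,
        "specificity": _ratio(tn, tn + fp),
        "ppv": ppv,
        "npv": _ratio(tn, tn + fn),
        "f1": f1,
        "mcc": mcc,
    }
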