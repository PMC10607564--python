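"""Benign/malignant lesion classification harness.

This is the "does despeckling help downstream?" arm of the package: a CNN
classifier is trained under stratified k-fold cross-validation on images
that have been passed through different despeckling front-ends (original,
autoencoder-denoised at each sigma, Median- or Lee-filtered, or
deliberately noised), and the resulting confusion counts are summarized
with the seven standard binary metrics.  Malignant is the positive class
throughout.

Preprocessing follows the classification pipeline exactly: per-image
clipping at the 5th/95th intensity percentiles, min-max normalization to
[0, 255], and a resize to 256 x 256 (configurable so desk-scale runs can
use smaller inputs).

The classifier itself is four conv/batch-norm/ReLU/max-pool blocks with
kernels 9/7/5/3 and 16/32/64/128 channels, a 128-unit dense layer,
dropout 0.5 and a single-logit binary head (sigmoid at 0.5 threshold).
Training hyperparameters are not dictated by the despeckling stage; we
reuse the same Adam constants with a desk-scale epoch default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import nn
from .autoencoder import LayerSpec, NetworkSpec, TrainSpec, realize
from .filters import FilterSpec, lee_filter, median_filter
from .imgio import resize_image
from .metrics import CLASSIFICATION_METRIC_NAMES, ConfusionCounts, classification_metrics
from .speckle import NoiseSpec, add_speckle, normalize_to_range

__all__ = [
    "FoldPlan",
    "preprocess",
    "build_classifier",
    "make_folds",
    "cross_validate",
    "run_variant_experiment",
    "VARIANT_NAMES",
]

POSITIVE_CLASS = "malignant"

VARIANT_NAMES = (
    "original",
    "ae_0.05", "ae_0.1", "ae_0.2", "ae_0.5",
    "median_denoised", "lee_denoised",
    "noised_0.5",
)


def preprocess(image: np.ndarray, size: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Percentile-clip, normalize to [0, 255], and resize."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = np.percentile(image, [5.0, 95.0])
    image = np.clip(image, lo, hi)
    return resize_image(normalize_to_range(image), size)


def build_classifier(input_shape: tuple[int, int, int] = (256, 256, 1)) -> NetworkSpec:
    """Declare the four-block CNN with a single-logit binary head."""
    rows, cols = input_shape[0], input_shape[1]
    if rows % 16 or cols % 16:
        raise ValueError(
            f"input dims must be divisible by 16 (four 2x poolings), got {rows}x{cols}"
        )
    layers: list[LayerSpec] = [LayerSpec("input")]
    for kernel, channels in ((9, 16), (7, 32), (5, 64), (3, 128)):
        layers += [
            LayerSpec("conv", kernel=(kernel, kernel), channels=channels,
                      activation="linear", padding="same"),
            LayerSpec("batchnorm"),
            LayerSpec("relu"),
            LayerSpec("maxpool", kernel=(2, 2)),
        ]
    layers += [
        LayerSpec("flatten"),
        LayerSpec("dense", channels=128, activation="relu"),
        LayerSpec("dropout", rate=0.5),
        LayerSpec("dense", channels=1, activation="linear"),
    ]
    return NetworkSpec(layers=tuple(layers), input_shape=(rows, cols, 1))


@dataclass(frozen=True)
class FoldPlan:
    """Stratified partition: ``assignments[i]`` is item i's test fold."""

    k: int
    assignments: tuple[int, ...]
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignments) == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignments) != fold)


def make_folds(labels, k: int, seed: int) -> FoldPlan:
    """Stratified k-fold assignment, deterministic under the seed."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small!r} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=tuple(int(a) for a in assignments), seed=seed)


def _train_eval_fold(x: np.ndarray, y: np.ndarray, net: NetworkSpec,
                     train_spec: TrainSpec, train_idx, test_idx) -> ConfusionCounts:
    init_seed, shuffle_seed = (
        int(s) for s in
        np.random.SeedSequence(train_spec.seed).generate_state(2) >> np.uint32(1)
    )
    model = realize(net, seed=init_seed)
    optimizer = nn.Adam(model, lr=train_spec.learning_rate, beta1=train_spec.beta1,
                        beta2=train_spec.beta2, epsilon=train_spec.epsilon)
    nn.fit(model, x[train_idx], y[train_idx], epochs=train_spec.epochs,
           batch_size=train_spec.batch_size, optimizer=optimizer, loss="bce",
           shuffle_seed=shuffle_seed)
    logits = model.forward(x[test_idx], training=False)[:, 0]
    pred = (logits > 0.0).astype(int)  # sigmoid(z) > 0.5  <=>  z > 0
    truth = y[test_idx][:, 0].astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
    )


def cross_validate(images, labels, folds: FoldPlan, train_spec: TrainSpec,
                   input_shape=(256, 256, 1)):
    """k-fold CV of the classifier; returns per-fold confusion counts."""
    net = build_classifier(input_shape)
    x = (np.stack([np.asarray(im, dtype=np.float64) for im in images])
         / 255.0).astype(np.float32)[..., None]
    y = np.asarray([1.0 if lab == POSITIVE_CLASS else 0.0 for lab in labels],
                   dtype=np.float32)[:, None]
    per_fold = []
    for fold in range(folds.k):
        spec = dataclasses.replace(train_spec, seed=train_spec.seed + fold)
        per_fold.append(_train_eval_fold(x, y, net, spec,
                                         folds.train_indices(fold),
                                         folds.test_indices(fold)))
    return per_fold


def summarize_folds(per_fold) -> dict[str, tuple[float, float]]:
    """Mean +/- std of each metric over folds (undefined folds dropped)."""
    table: dict[str, list[float]] = {m: [] for m in CLASSIFICATION_METRIC_NAMES}
    for counts in per_fold:
        for name, value in classification_metrics(counts).items():
            if value is not None:
                table[name].append(value)
    return {
        name: (float(np.mean(vals)), float(np.std(vals))) if vals
        else (float("nan"), float("nan"))
        for name, vals in table.items()
    }


def _apply_variant(image: np.ndarray, variant: str, denoisers, filter_spec,
                   noise_seed: int, index: int) -> np.ndarray:
    if variant == "original":
        return image
    if variant.startswith("ae_"):
        sigma = float(variant[3:])
        if denoisers is None or sigma not in denoisers:
            raise ValueError(
                f"no trained denoiser for sigma={sigma}; train one first and "
                f"pass it in `denoisers`"
            )
        return denoisers[sigma].denoise(image)
    if variant == "median_denoised":
        return median_filter(image, filter_spec)
    if variant == "lee_denoised":
        return lee_filter(image, filter_spec)
    if variant.startswith("noised_"):
        sigma = float(variant[7:])
        return add_speckle(image, NoiseSpec(sigma=sigma, seed=noise_seed + index))
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANT_NAMES}")


def run_variant_experiment(clean_set, variants, folds: FoldPlan,
                           train_spec: TrainSpec, *, denoisers=None,
                           filter_spec: FilterSpec = FilterSpec(),
                           noise_seed: int = 0,
                           image_size: tuple[int, int] = (256, 256)) -> pd.DataFrame:
    """Cross-validate the classifier once per input variant.

    Each variant transform is applied identically to every image (train and
    test folds alike) at native size, then the standard preprocessing
    (clip / normalize / resize) runs.  Autoencoder variants require their
    trained denoiser in ``denoisers`` (a sigma -> TrainedDenoiser map).
    Returns a DataFrame with one row per variant and mean/std columns for
    the seven metrics.
    """
    images = [np.asarray(im, dtype=np.float64) for im, _ in clean_set]
    labels = [lab for _, lab in clean_set]
    if len(folds.assignments) != len(images):
        raise ValueError("fold plan does not match the dataset size")
    rows = []
    for variant in variants:
        transformed = [
            preprocess(_apply_variant(img, variant, denoisers, filter_spec,
                                      noise_seed, i), size=image_size)
            for i, img in enumerate(images)
        ]
        per_fold = cross_validate(transformed, labels, folds, train_spec,
                                  input_shape=(image_size[0], image_size[1], 1))
        summary = summarize_folds(per_fold)
        row: dict[str, float | str] = {"variant": variant}
        for name in CLASSIFICATION_METRIC_NAMES:
            row[f"{name}_mean"], row[f"{name}_std"] = summary[name]
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")
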