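"""Classifier architecture, preprocessing, fold plans, and the variant harness."""

import numpy as np
import pytest

from usdespeckle import (
    PhantomSpec,
    TrainSpec,
    build_classifier,
    count_parameters,
    generate_labeled_set,
    make_folds,
    preprocess,
    propagate_shapes,
    run_variant_experiment,
)
from usdespeckle.metrics import CLASSIFICATION_METRIC_NAMES


def test_preprocess_output_shape_and_range(phantom_128):
    out = preprocess(phantom_128)
    assert out.shape == (256, 256)
    assert out.min() >= 0.0 and out.max() <= 255.0


def test_preprocess_constant_image():
    out = preprocess(np.full((100, 80), 9.0))
    assert out.shape == (256, 256)
    assert np.all(out == 0.0)


def test_preprocess_percentile_clipping_on_ramp():
    ramp = np.arange(1000, dtype=float).reshape(25, 40)
    out = preprocess(ramp, size=(25, 40))  # same size: no resize blending
    p5, p95 = np.percentile(ramp, [5, 95])
    assert np.all(out[ramp <= p5] == 0.0)
    assert np.all(out[ramp >= p95] == 255.0)
    interior = out[(ramp > p5) & (ramp < p95)]
    assert np.all(np.diff(interior) >= 0) and interior.min() > 0 and interior.max() < 255


def test_classifier_parameter_counts():
    rows, _ = count_parameters(build_classifier())
    counts = [c for _, c in rows if c > 0]
    # conv/batchnorm blocks then the two dense layers
    assert counts == [1312, 64, 25120, 128, 51264, 256, 73856, 512, 4194432, 129]


def test_classifier_shape_propagation():
    net = build_classifier()
    shapes = propagate_shapes(net)
    assert shapes[0] == (256, 256, 1)
    assert (256, 256, 16) in shapes and (128, 128, 32) in shapes
    assert (64, 64, 64) in shapes and (32, 32, 128) in shapes
    assert (32768,) in shapes  # flatten
    assert shapes[-1] == (1,)


def test_classifier_rejects_indivisible_input():
    with pytest.raises(ValueError):
        build_classifier((100, 100, 1))


def test_folds_exact_stratification():
    labels = ["benign"] * 50 + ["malignant"] * 50
    plan = make_folds(labels, k=5, seed=1)
    for fold in range(5):
        test_labels = [labels[i] for i in plan.test_indices(fold)]
        assert test_labels.count("benign") == 10
        assert test_labels.count("malignant") == 10


def test_folds_near_stratification_with_uneven_classes():
    labels = ["benign"] * 52 + ["malignant"] * 48
    plan = make_folds(labels, k=5, seed=1)
    for fold in range(5):
        test_labels = [labels[i] for i in plan.test_indices(fold)]
        assert abs(test_labels.count("benign") - 52 / 5) <= 1
        assert abs(test_labels.count("malignant") - 48 / 5) <= 1


def test_folds_partition_and_determinism():
    labels = ["benign"] * 13 + ["malignant"] * 9
    plan = make_folds(labels, k=3, seed=7)
    seen = np.concatenate([plan.test_indices(f) for f in range(3)])
    assert sorted(seen) == list(range(22))
    assert make_folds(labels, k=3, seed=7).assignments == plan.assignments


def test_folds_reject_small_class():
    with pytest.raises(ValueError):
        make_folds(["benign"] * 10 + ["malignant"] * 3, k=5, seed=0)


@pytest.fixture(scope="module")
def labeled_32():
    base = PhantomSpec(height=32, width=32, n_lesions=1, gradient_strength=0.2)
    return generate_labeled_set(9, base, seed=21)


def test_variant_experiment_layout_and_machinery(labeled_32):
    """Two variants, tiny classifier: table layout and metric columns."""
    labels = [lab for _, lab in labeled_32]
    folds = make_folds(labels, k=3, seed=2)
    spec = TrainSpec(epochs=2, seed=3, batch_size=6)
    table = run_variant_experiment(
        labeled_32, ["original", "noised_0.5"], folds, spec, image_size=(32, 32)
    )
    assert list(table.index) == ["original", "noised_0.5"]
    for name in CLASSIFICATION_METRIC_NAMES:
        assert f"{name}_mean" in table.columns
        assert f"{name}_std" in table.columns
    acc = table.loc["original", "accuracy_mean"]
    assert 0.0 <= acc <= 1.0


def test_variant_experiment_requires_trained_denoiser(labeled_32):
    labels = [lab for _, lab in labeled_32]
    folds = make_folds(labels, k=3, seed=2)
    with pytest.raises(ValueError, match="train"):
        run_variant_experiment(labeled_32, ["ae_0.1"], folds,
                               TrainSpec(epochs=1), image_size=(32, 32))


def test_easily_separable_classes_reach_high_accuracy():
    """Sanity ceiling: a huge structural margin should classify near-perfectly.

    Per-image normalization erases absolute brightness, so the classes
    differ in structure: malignant images carry a large bright block.
    """
    rng = np.random.default_rng(0)
    images, labels = [], []
    for i in range(16):
        img = rng.normal(100.0, 5.0, (32, 32))
        if i % 2:
            img[4:28, 4:16] += 150.0
        images.append(np.clip(img, 0, 255))
        labels.append("malignant" if i % 2 else "benign")
    folds = make_folds(labels, k=4, seed=0)
    table = run_variant_experiment(
        list(zip(images, labels)), ["original"], folds,
        TrainSpec(epochs=15, seed=1, batch_size=4), image_size=(32, 32),
    )
    assert table.loc["original", "accuracy_mean"] >= 0.9
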