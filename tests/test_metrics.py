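"""SSIM / PSNR and the seven classification metrics vs direct-formula oracles."""

import math

import numpy as np
import pytest

from usdespeckle import (
    ConfusionCounts,
    InfinitePSNRError,
    SsimConstants,
    classification_metrics,
    evaluate_set,
    psnr,
    ssim,
)


def ssim_oracle(x, y, consts):
    """Direct evaluation of the global-statistics formula."""
    mx, my = np.mean(x), np.mean(y)
    vx = np.mean((x - mx) ** 2)
    vy = np.mean((y - my) ** 2)
    cov = np.mean((x - mx) * (y - my))
    c1, c2 = consts.c1, consts.c2
    return ((2 * mx * my + c1) * (2 * cov + c2)
            / ((mx**2 + my**2 + c1) * (vx + vy + c2)))


def test_ssim_identity_is_one(phantom_128):
    assert ssim(phantom_128, phantom_128) == pytest.approx(1.0, abs=1e-12)


def test_ssim_symmetry(rng):
    consts = SsimConstants()
    for _ in range(10):
        x = rng.random((16, 16)) * 255
        y = rng.random((16, 16)) * 255
        assert ssim(x, y, consts) == pytest.approx(ssim(y, x, consts), abs=1e-12)


def test_ssim_matches_direct_formula_oracle():
    consts = SsimConstants()
    x = np.array([[10., 50., 90., 130.],
                  [20., 60., 100., 140.],
                  [30., 70., 110., 150.],
                  [40., 80., 120., 160.]])
    y = np.array([[12., 47., 95., 128.],
                  [25., 66., 98., 135.],
                  [28., 75., 105., 155.],
                  [45., 85., 115., 170.]])
    assert ssim(x, y, consts) == pytest.approx(ssim_oracle(x, y, consts), abs=1e-12)


def test_ssim_below_one_for_different_images(rng):
    x = rng.random((16, 16)) * 255
    y = x + rng.normal(0, 5, x.shape)
    assert ssim(x, y) < 1.0


def test_ssim_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        ssim(np.zeros((4, 4)), np.zeros((5, 5)))


def test_psnr_closed_form_spot_check():
    x = np.full((8, 8), 255.0)
    y = np.full((8, 8), 254.0)
    # MSE = 1, peakval = 255 -> 10 log10(65025) = 48.1308 dB
    assert psnr(x, y) == pytest.approx(10 * math.log10(255**2), abs=1e-9)
    assert psnr(x, y) == pytest.approx(48.1308, abs=1e-3)


def test_psnr_quadrupled_residuals_drop_by_12dB(rng):
    x = rng.random((16, 16)) * 200
    resid = rng.normal(0, 3, x.shape)
    drop = psnr(x, x + resid) - psnr(x, x + 4 * resid)
    assert drop == pytest.approx(10 * math.log10(16), abs=1e-9)


def test_psnr_identical_images_signal_infinite():
    x = np.ones((4, 4))
    with pytest.raises(InfinitePSNRError):
        psnr(x, x)


def test_psnr_peakval_uses_reference_maximum(rng):
    x = rng.random((8, 8)) * 100  # max well below 255
    y = x + 1.0
    assert psnr(x, y) == pytest.approx(20 * math.log10(x.max()), abs=1e-9)
    assert psnr(x, y, peakval=255) == pytest.approx(20 * math.log10(255), abs=1e-9)


def test_psnr_decreases_with_noise_magnitude(rng):
    x = rng.random((32, 32)) * 255
    values = [psnr(x, x + rng.normal(0, s, x.shape)) for s in (1, 4, 16, 64)]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_evaluate_set_aggregation(rng, small_phantoms):
    noisy = [img + rng.normal(0, 4, img.shape) for img in small_phantoms]
    report = evaluate_set(small_phantoms, noisy)
    ssims = np.array([e[1] for e in report.per_image])
    psnrs = np.array([e[2] for e in report.per_image])
    assert report.ssim_mean == pytest.approx(ssims.mean())
    assert report.ssim_std == pytest.approx(ssims.std())
    assert report.psnr_mean_db == pytest.approx(psnrs.mean())
    assert report.psnr_std_db == pytest.approx(psnrs.std())


def test_evaluate_set_identical_candidates(small_phantoms):
    report = evaluate_set(small_phantoms, small_phantoms)
    assert report.ssim_mean == pytest.approx(1.0, abs=1e-12)
    assert report.ssim_std == pytest.approx(0.0, abs=1e-12)
    assert math.isinf(report.psnr_mean_db)


def test_evaluate_set_single_pair(small_phantoms):
    report = evaluate_set(small_phantoms[:1], [small_phantoms[0] + 1.0])
    assert len(report.per_image) == 1
    assert report.ssim_std == 0.0


def test_evaluate_set_length_mismatch_rejected(small_phantoms):
    with pytest.raises(ValueError):
        evaluate_set(small_phantoms, small_phantoms[:-1])


def test_perfect_classifier_metrics_are_one():
    metrics = classification_metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
    assert all(v == pytest.approx(1.0) for v in metrics.values())


def test_classification_metrics_worked_example():
    metrics = classification_metrics(ConfusionCounts(tp=50, tn=40, fp=10, fn=20))
    assert metrics["accuracy"] == pytest.approx(0.75)
    assert metrics["sensitivity"] == pytest.approx(5 / 7)
    assert metrics["specificity"] == pytest.approx(0.8)
    assert metrics["ppv"] == pytest.approx(5 / 6)
    assert metrics["npv"] == pytest.approx(2 / 3)
    assert metrics["f1"] == pytest.approx(10 / 13)
    assert metrics["mcc"] == pytest.approx(1800 / math.sqrt(60 * 70 * 50 * 60))
    assert metrics["mcc"] == pytest.approx(0.5071, abs=5e-4)


def test_undefined_metrics_signalled_not_zeroed():
    metrics = classification_metrics(ConfusionCounts(tp=0, tn=5, fp=3, fn=0))
    assert metrics["sensitivity"] is None  # TP + FN = 0
    assert metrics["f1"] is None
    assert metrics["mcc"] is None
    assert metrics["specificity"] is not None


def test_metrics_match_bruteforce_from_predictions(rng):
    """Counts-based formulas agree with recomputation from labeled lists."""
    for _ in range(100):
        n = int(rng.integers(4, 60))
        truth = rng.integers(0, 2, n)
        pred = rng.integers(0, 2, n)
        counts = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (truth == 1))),
            tn=int(np.sum((pred == 0) & (truth == 0))),
            fp=int(np.sum((pred == 1) & (truth == 0))),
            fn=int(np.sum((pred == 0) & (truth == 1))),
        )
        metrics = classification_metrics(counts)
        if metrics["accuracy"] is not None:
            assert metrics["accuracy"] == pytest.approx(np.mean(pred == truth))
        if metrics["sensitivity"] is not None:
            assert metrics["sensitivity"] == pytest.approx(
                np.mean(pred[truth == 1] == 1))
        if metrics["specificity"] is not None:
            assert metrics["specificity"] == pytest.approx(
                np.mean(pred[truth == 0] == 0))


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionCounts(tp=-1, tn=1, fp=0, fn=0)
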