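"""End-to-end despeckling experiments on phantom sets.

``run_despeckle_experiment`` reproduces the full evaluation design at any
scale: generate (or load) a clean dataset, split it 70/30 into train and
validation, and for each noise level sigma train one autoencoder on
noised/clean training pairs, then score Median, Lee and autoencoder
outputs on the noised validation set against the clean originals.  The
result is one quality row per (sigma, method), each SSIM/PSNR as
mean +/- std over validation images.

Every run is reproducible from its :class:`ExperimentConfig` and seed;
when an output directory is given, all intermediate image sets (noised,
filtered, denoised) are written as float TIFF with a manifest so any
table cell can be recomputed in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import GroupShuffleSplit, train_test_split

from .autoencoder import TrainSpec, build_cnn_ae, train_denoiser
from .filters import FilterSpec, lee_filter, median_filter
from .imgio import write_image, write_manifest
from .metrics import QualityReport, SsimConstants, evaluate_set
from .phantom import PhantomSpec, generate_phantom
from .speckle import DEFAULT_SIGMAS, NoiseSpec, add_speckle, normalize_to_range

logger = logging.getLogger("usdespeckle")

__all__ = ["ExperimentConfig", "split_dataset", "run_despeckle_experiment"]

METHODS = ("median", "lee", "cnn_ae")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun one despeckling experiment."""

    n_images: int = 80
    image_size: tuple[int, int] = (128, 128)
    sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    train_spec: TrainSpec = field(default_factory=lambda: TrainSpec(epochs=50))
    split: float = 0.70
    seed: int = 0
    n_lesions: int = 2
    output_dir: str | None = None

    def __post_init__(self):
        if not 0.0 < self.split < 1.0:
            raise ValueError("split fraction must lie in (0, 1)")
        if self.image_size[0] % 4 or self.image_size[1] % 4:
            raise ValueError("image_size dims must be divisible by 4")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "image_size" in raw:
            raw["image_size"] = tuple(raw["image_size"])
        if "sigmas" in raw:
            raw["sigmas"] = tuple(raw["sigmas"])
        if "filter_spec" in raw:
            raw["filter_spec"] = FilterSpec(**raw["filter_spec"])
        if "train_spec" in raw:
            raw["train_spec"] = TrainSpec(**raw["train_spec"])
        return cls(**raw)


def split_dataset(items: list, fraction: float, seed: int, groups=None):
    """Seeded train/validation split; grouped items never straddle it."""
    if not items:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    idx = np.arange(len(items))
    if groups is None:
        train_idx, val_idx = train_test_split(
            idx, train_size=fraction, random_state=seed, shuffle=True
        )
    else:
        splitter = GroupShuffleSplit(n_splits=1, train_size=fraction,
                                     random_state=seed)
        train_idx, val_idx = next(splitter.split(idx, groups=groups))
    return [items[i] for i in train_idx], [items[i] for i in val_idx]


def _phantom_set(config: ExperimentConfig) -> list[np.ndarray]:
    seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_images, dtype=np.uint32
    ) >> 1
    h, w = config.image_size
    return [
        generate_phantom(PhantomSpec(height=h, width=w, n_lesions=config.n_lesions,
                                     seed=int(s)))
        for s in seeds
    ]


def _dump_set(out_dir: Path, name: str, images: list[np.ndarray], seed: int) -> None:
    rows = []
    for i, img in enumerate(images):
        rel = f"{name}/{i:04d}.tiff"
        write_image(out_dir / rel, img)
        rows.append({"path": rel, "label": name, "seed": seed})
    write_manifest(out_dir / f"{name}.manifest.tsv", rows)


def run_despeckle_experiment(
    config: ExperimentConfig,
    clean_images: list[np.ndarray] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[float, str], QualityReport]]:
    """Train one autoencoder per sigma and score all three methods.

    Returns a tidy table (rows indexed by sigma, mean/std columns per
    method and metric) plus the full per-image QualityReport per cell.
    ``clean_images`` overrides the built-in phantom recipe.
    """
    t_start = time.perf_counter()
    if clean_images is None:
        clean_images = _phantom_set(config)
    train_clean, val_clean = split_dataset(clean_images, config.split, config.seed)
    # originals are min-max normalized up front, exactly like the noised and
    # filtered sets: the *normalized* originals are the training targets and
    # the evaluation references, so every comparison shares one scale
    train_clean = [normalize_to_range(img) for img in train_clean]
    val_clean = [normalize_to_range(img) for img in val_clean]
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        _dump_set(out_dir, "clean_val", val_clean, config.seed)

    net = build_cnn_ae((config.image_size[0], config.image_size[1], 1))
    consts = SsimConstants()
    reports: dict[tuple[float, str], QualityReport] = {}
    rows = []
    for si, sigma in enumerate(config.sigmas):
        noise_base = config.seed * 1000 + si * 100
        noised_train = [
            add_speckle(img, NoiseSpec(sigma, seed=noise_base + i))
            for i, img in enumerate(train_clean)
        ]
        noised_val = [
            add_speckle(img, NoiseSpec(sigma, seed=noise_base + 50000 + i))
            for i, img in enumerate(val_clean)
        ]
        logger.info("sigma=%s: training autoencoder on %d pairs", sigma,
                    len(noised_train))
        t0 = time.perf_counter()
        model = train_denoiser(list(zip(noised_train, train_clean)), net,
                               config.train_spec)
        logger.info("sigma=%s: trained in %.1fs (final loss %.5f)", sigma,
                    time.perf_counter() - t0, model.history[-1])

        references = val_clean
        outputs = {
            "median": [normalize_to_range(median_filter(img, config.filter_spec))
                       for img in noised_val],
            "lee": [normalize_to_range(lee_filter(img, config.filter_spec))
                    for img in noised_val],
            "cnn_ae": [model.denoise(img) for img in noised_val],
        }
        row: dict[str, float] = {"sigma": sigma}
        for method, images in outputs.items():
            report = evaluate_set(references, images, consts)
            reports[(sigma, method)] = report
            row[f"{method}_ssim_mean"] = report.ssim_mean
            row[f"{method}_ssim_std"] = report.ssim_std
            row[f"{method}_psnr_mean"] = report.psnr_mean_db
            row[f"{method}_psnr_std"] = report.psnr_std_db
            if out_dir is not None:
                _dump_set(out_dir, f"sigma_{sigma}_{method}", images, config.seed)
        if out_dir is not None:
            _dump_set(out_dir, f"sigma_{sigma}_noised_val", noised_val, config.seed)
        rows.append(row)

    table = pd.DataFrame(rows).set_index("sigma")
    if out_dir is not None:
        table.to_csv(out_dir / "report.csv")
        (out_dir / "run.json").write_text(json.dumps({
            "seed": config.seed,
            "n_images": config.n_images,
            "sigmas": list(config.sigmas),
            "wall_time_s": time.perf_counter() - t_start,
        }, indent=2))
    return table, reports
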