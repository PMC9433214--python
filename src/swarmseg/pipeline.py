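"""Six-scenario benchmark runner.

Runs any subset of {fcm, kmeans, fcm-pso, kmeans-pso, fcm-cnn, kmeans-cnn}
over a directory of image/mask pairs or over generated phantom sets,
scores every prediction against its ground truth, and writes per-image
masks, a long-format metric CSV, an aggregated summary/pivot CSV and a JSON
run manifest.  Every output except wall-clock timings is a pure function
of (config, seed).

Accuracy-style columns are per-image means (each image scored separately,
then averaged within a method x set-size cell), not pooled pixel counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .clustering import (
    EmptyROIWarning,
    fcm_segment,
    kmeans_segment,
    partition_to_mask,
)
from .cnn_refine import CNNMaskRefiner, fcm_cnn_segment, kmeans_cnn_segment
from .metrics import METRIC_COLUMNS, aggregate, confusion, score
from .phantoms import (
    PhantomSpec,
    derive_seed,
    generate_benchmark_set,
    generate_phantom,
    load_pairs,
)
from .preprocess import FormatError, prepare_image
from .swarm import PSOParams, fcm_pso_segment, kmeans_pso_segment

__all__ = ["METHODS", "RunConfig", "run_benchmark", "segment_one", "segment_with_method"]

logger = logging.getLogger(__name__)

METHODS = ("fcm", "kmeans", "fcm-pso", "kmeans-pso", "fcm-cnn", "kmeans-cnn")


@dataclass
class RunConfig:
    """Serializable benchmark configuration (YAML round-trips losslessly)."""

    methods: list[str] = field(default_factory=lambda: list(METHODS))
    input_dir: str | None = None
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    counts: list[int] = field(default_factory=lambda: [10])
    n_clusters: int = 2
    fuzziness: float = 2.0
    tol: float = 1e-4
    max_iter: int = 100
    pso: dict = field(default_factory=dict)  # PSOParams overrides
    cnn: dict = field(default_factory=dict)  # CNNMaskRefiner overrides
    cnn_checkpoints: dict = field(default_factory=dict)  # method -> path
    cnn_train_count: int = 50
    enhance: bool = True
    select: str = "brightest"
    seed: int = 0
    out_dir: str = "swarmseg_out"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; valid: {METHODS}")
        for method, ckpt in self.cnn_checkpoints.items():
            if method in self.methods and not Path(ckpt).exists():
                raise FileNotFoundError(
                    f"checkpoint for {method} does not exist: {ckpt}"
                )

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _pso_params(config: RunConfig) -> PSOParams:
    return PSOParams(**config.pso)


def train_cnn_for(
    config: RunConfig, proposal_method: str, seed_tag: int
) -> CNNMaskRefiner:
    """Train a refiner on phantoms derived from the run seed."""
    spec = PhantomSpec(**{**config.phantom, "seed": 0})
    train_seed = derive_seed(config.seed, 7000 + seed_tag)
    samples = [
        generate_phantom(
            dataclasses.replace(spec, seed=derive_seed(train_seed, i))
        )
        for i in range(config.cnn_train_count)
    ]
    model = CNNMaskRefiner(
        proposal_method=proposal_method,
        n_clusters=config.n_clusters,
        fuzziness=config.fuzziness,
        apply_enhance=config.enhance,
        random_state=train_seed,
        **config.cnn,
    )
    model.fit(samples)
    return model


def _get_models(config: RunConfig) -> dict[str, CNNMaskRefiner]:
    models: dict[str, CNNMaskRefiner] = {}
    for tag, method in enumerate(("fcm-cnn", "kmeans-cnn")):
        if method not in config.methods:
            continue
        ckpt = config.cnn_checkpoints.get(method)
        if ckpt:
            models[method] = CNNMaskRefiner.load(ckpt)
        else:
            logger.info("no checkpoint for %s; training a refiner in-run", method)
            models[method] = train_cnn_for(config, method.split("-")[0], tag)
    return models


def segment_with_method(
    img: np.ndarray,
    method: str,
    config: RunConfig,
    seed: int,
    model: CNNMaskRefiner | None = None,
) -> np.ndarray:
    """Full preprocess -> segment -> (refine) -> binary mask path."""
    mask_kwargs = dict(select=config.select)
    if method in ("fcm-cnn", "kmeans-cnn"):
        if model is None:
            raise ValueError(f"method {method} needs a trained CNN refiner")
        fn = fcm_cnn_segment if method == "fcm-cnn" else kmeans_cnn_segment
        return fn(img, model, seed=seed, **mask_kwargs)

    gray = prepare_image(img, apply_enhance=config.enhance)
    common = dict(n_clusters=config.n_clusters, tol=config.tol,
                  max_iter=config.max_iter, seed=seed)
    if method == "fcm":
        part = fcm_segment(gray, fuzziness=config.fuzziness, **common)
        return partition_to_mask(part, gray, **mask_kwargs)
    if method == "kmeans":
        part = kmeans_segment(gray, **common)
        return partition_to_mask(part, gray, **mask_kwargs)
    if method == "fcm-pso":
        _, mask = fcm_pso_segment(
            gray, fuzziness=config.fuzziness, pso_params=_pso_params(config),
            **common, **mask_kwargs,
        )
        return mask
    if method == "kmeans-pso":
        _, mask = kmeans_pso_segment(
            gray, pso_params=_pso_params(config), **common, **mask_kwargs
        )
        return mask
    raise ValueError(f"unknown method {method!r}")


def _save_mask(mask: np.ndarray, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask.astype(np.uint8) * 255).save(path)


def run_benchmark(config: RunConfig):
    """Execute the configured benchmark; returns (long_df, summary_df).

    Writes to ``config.out_dir``: ``masks/``, ``metrics_long.csv``,
    ``metrics_summary.csv``, ``metrics_pivot.csv`` and ``manifest.json``.
    Images without a truth mask are segmented but skipped in the metric
    tables (with a warning).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir:
        pairs = load_pairs(config.input_dir)
        if not pairs:
            raise FileNotFoundError(f"no images found in {config.input_dir}")
        datasets = [(len(pairs), pairs)]
    else:
        spec = PhantomSpec(**{**config.phantom, "seed": 0})
        sets = generate_benchmark_set(spec, config.counts, config.seed)
        datasets = [
            (
                count,
                [(f"phantom_{count}_{i:04d}", s.image, s.truth_mask)
                 for i, s in enumerate(samples)],
            )
            for count, samples in zip(config.counts, sets)
        ]

    models = _get_models(config)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EmptyROIWarning)
        for set_idx, (set_size, pairs) in enumerate(datasets):
            for img_idx, (name, img, truth) in enumerate(pairs):
                for m_idx, method in enumerate(config.methods):
                    seed = derive_seed(config.seed, set_idx, img_idx, m_idx)
                    t0 = time.perf_counter()
                    mask = segment_with_method(
                        img, method, config, seed, model=models.get(method)
                    )
                    elapsed = time.perf_counter() - t0
                    _save_mask(
                        mask, out / "masks" / f"set{set_size}" / f"{name}_{method}.png"
                    )
                    if truth is None:
                        warnings.warn(f"no truth mask for {name}; metrics skipped")
                        continue
                    rep = score(confusion(mask, truth), elapsed_seconds=elapsed)
                    rows.append(
                        {"set_size": set_size, "image": name, "method": method,
                         **rep.as_dict()}
                    )

    if not rows:
        raise RuntimeError("no image could be scored (no truth masks present)")
    long_df = pd.DataFrame(rows)
    summary = aggregate(long_df, group_keys=("method", "set_size"))
    pivot = (
        summary.melt(
            id_vars=["method", "set_size"],
            value_vars=[c for c in METRIC_COLUMNS if c in summary.columns],
            var_name="metric",
        )
        .pivot(index=["metric", "set_size"], columns="method", values="value")
        .reset_index()
    )

    fmt = lambda df: df.to_csv(index=False, float_format="%.6f")
    (out / "metrics_long.csv").write_text(fmt(long_df))
    (out / "metrics_summary.csv").write_text(fmt(summary))
    (out / "metrics_pivot.csv").write_text(fmt(pivot))
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return long_df, summary


def segment_one(
    img_path: Path | str,
    method: str,
    config: RunConfig,
    model: CNNMaskRefiner | None = None,
    out_path: Path | str | None = None,
):
    """Segment a single image file; returns (mask, report-or-None).

    If a ``<stem>_mask.png`` sidecar exists it is used as ground truth and
    a metric report is returned alongside the mask.
    """
    img_path = Path(img_path)
    try:
        img = np.asarray(Image.open(img_path))
    except Exception as exc:
        raise FormatError(f"cannot read image {img_path}: {exc}") from exc

    if method in ("fcm-cnn", "kmeans-cnn") and model is None:
        ckpt = config.cnn_checkpoints.get(method)
        if not ckpt:
            raise ValueError(f"method {method} requires a model checkpoint")
        model = CNNMaskRefiner.load(ckpt)

    seed = derive_seed(config.seed, 0)
    t0 = time.perf_counter()
    mask = segment_with_method(img, method, config, seed, model=model)
    elapsed = time.perf_counter() - t0

    if out_path is not None:
        _save_mask(mask, Path(out_path))

    truth_path = img_path.parent / f"{img_path.stem}_mask.png"
    report = None
    if truth_path.exists():
        truth = np.asarray(Image.open(truth_path)) > 127
        report = score(confusion(mask, truth), elapsed_seconds=elapsed)
    return mask, report
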