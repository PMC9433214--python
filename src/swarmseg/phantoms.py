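"""Synthetic phantom images with exact ground-truth masks.

Real medical modalities (MRI tumours, dermoscopic lesions, blood-smear
nuclei, lung CT) share a handful of difficulties that break naive intensity
clustering: bright compact foreground on a darker background, uneven
illumination, heavy acquisition noise and — for dermoscopy — dark hair
curves occluding the lesion.  A phantom reproduces exactly those features on
a canvas whose ground truth is known bit-for-bit, so every segmentation
method in this package can be validated without any external dataset.

A phantom is built in stages from three independent seeded RNG streams
(blobs, noise, hair), so e.g. the same seed with and without hair renders
the identical underlying scene:

1. elliptical blobs at ``blob_intensity_mean`` on a flat background —
   the truth mask records the blob interiors at this stage;
2. a linear left-to-right illumination ramp (fractional drop
   ``illumination_gradient``);
3. additive Gaussian noise with standard deviation ``noise_sigma``;
4. optional dark hair-like cubic Bezier curves, 1-3 px wide, drawn over
   the image only (never into the mask);
5. clipping to [0, 255] and rounding half-up to 8-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "PhantomSpecError",
    "MODALITY_PRESETS",
    "generate_phantom",
    "generate_benchmark_set",
    "save_sample",
    "load_sample",
    "load_pairs",
]

#: Intensity painted for hair curves (dark, like real dermoscopic hair).
HAIR_INTENSITY = 15.0


class PhantomSpecError(ValueError):
    """A phantom spec field violates its invariant; message names the field."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    Identical spec (including ``seed``) always renders a bit-identical
    sample.  Intensities are on the 8-bit scale.
    """

    width: int = 256
    height: int = 256
    n_blobs: int = 1
    blob_intensity_mean: float = 180.0
    background_intensity_mean: float = 60.0
    noise_sigma: float = 15.0
    illumination_gradient: float = 0.2
    hair_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 16:
            raise PhantomSpecError(f"width must be >= 16, got {self.width}")
        if self.height < 16:
            raise PhantomSpecError(f"height must be >= 16, got {self.height}")
        if self.n_blobs < 1:
            raise PhantomSpecError(f"n_blobs must be >= 1, got {self.n_blobs}")
        for field in ("blob_intensity_mean", "background_intensity_mean"):
            value = getattr(self, field)
            if not 0 <= value <= 255:
                raise PhantomSpecError(f"{field} must lie in [0, 255], got {value}")
        if self.blob_intensity_mean == self.background_intensity_mean:
            raise PhantomSpecError(
                "blob_intensity_mean must differ from background_intensity_mean"
            )
        if self.noise_sigma < 0:
            raise PhantomSpecError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not 0 <= self.illumination_gradient <= 1:
            raise PhantomSpecError(
                "illumination_gradient must lie in [0, 1], "
                f"got {self.illumination_gradient}"
            )
        if self.hair_count < 0:
            raise PhantomSpecError(f"hair_count must be >= 0, got {self.hair_count}")


@dataclass(frozen=True)
class PhantomSample:
    """A rendered phantom: 8-bit image, boolean truth mask, and its spec."""

    image: np.ndarray
    truth_mask: np.ndarray
    spec: PhantomSpec


# Preset difficulty profiles loosely evoking the four modalities.  The real
# datasets' intensity statistics are not published; these values are this
# package's own choices (see docs/methods.md) and claim no statistical match.
MODALITY_PRESETS: dict[str, dict] = {
    "skin": dict(
        blob_intensity_mean=150.0,
        background_intensity_mean=90.0,
        noise_sigma=10.0,
        illumination_gradient=0.25,
        hair_count=6,
    ),
    "mri": dict(
        blob_intensity_mean=200.0,
        background_intensity_mean=70.0,
        noise_sigma=20.0,
        illumination_gradient=0.15,
    ),
    "micro": dict(
        n_blobs=6,
        blob_intensity_mean=170.0,
        background_intensity_mean=220.0,
        noise_sigma=8.0,
        illumination_gradient=0.1,
    ),
    "ct": dict(
        blob_intensity_mean=190.0,
        background_intensity_mean=40.0,
        noise_sigma=25.0,
        illumination_gradient=0.1,
    ),
}


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _draw_ellipse_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Union of ``n_blobs`` random ellipses fully inside the frame."""
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    # Semi-axes sized so the foreground occupies a noticeable fraction of
    # the frame (~10-30% for one blob), as in lesion-centred crops.
    short = min(h, w)
    lo, hi = short / 8.0, short / 3.0
    for _ in range(spec.n_blobs):
        for _attempt in range(200):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            theta = rng.uniform(0.0, np.pi)
            cx = rng.uniform(0, w)
            cy = rng.uniform(0, h)
            # conservative in-frame test via the rotated bounding box
            ext_x = np.hypot(a * np.cos(theta), b * np.sin(theta))
            ext_y = np.hypot(a * np.sin(theta), b * np.cos(theta))
            if (
                cx - ext_x >= 1
                and cx + ext_x <= w - 2
                and cy - ext_y >= 1
                and cy + ext_y <= h - 2
            ):
                break
        ct, st = np.cos(theta), np.sin(theta)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        mask |= (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    return mask


def _draw_hairs(
    image: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> None:
    """Stamp dark cubic Bezier curves onto ``image`` in place."""
    h, w = spec.height, spec.width
    t = np.linspace(0.0, 1.0, 4 * (h + w))[:, None]
    for _ in range(spec.hair_count):
        pts = rng.uniform([0, 0], [h - 1, w - 1], size=(4, 2))
        width = int(rng.integers(1, 4))
        # cubic Bezier through the four control points
        curve = (
            (1 - t) ** 3 * pts[0]
            + 3 * (1 - t) ** 2 * t * pts[1]
            + 3 * (1 - t) * t**2 * pts[2]
            + t**3 * pts[3]
        )
        radius = max(width / 2.0, 0.5)
        r = int(np.ceil(radius))
        cy = np.round(curve[:, 0]).astype(int)
        cx = np.round(curve[:, 1]).astype(int)
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if dy * dy + dx * dx > radius * radius:
                    continue
                y = np.clip(cy + dy, 0, h - 1)
                x = np.clip(cx + dx, 0, w - 1)
                image[y, x] = HAIR_INTENSITY


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom deterministically from its spec.

    Returns
    -------
    PhantomSample
        ``image`` is uint8 (height, width); ``truth_mask`` is boolean and
        marks blob interiors before illumination/noise/hair corruption.
    """
    ss = np.random.SeedSequence([int(spec.seed)])
    rng_blobs, rng_noise, rng_hair = (np.random.default_rng(c) for c in ss.spawn(3))

    mask = _draw_ellipse_mask(spec, rng_blobs)
    image = np.full(
        (spec.height, spec.width), spec.background_intensity_mean, dtype=float
    )
    image[mask] = spec.blob_intensity_mean

    if spec.illumination_gradient > 0:
        ramp = 1.0 - spec.illumination_gradient * (
            np.arange(spec.width, dtype=float) / (spec.width - 1)
        )
        image *= ramp[None, :]
    if spec.noise_sigma > 0:
        image += rng_noise.normal(0.0, spec.noise_sigma, size=image.shape)
    if spec.hair_count > 0:
        _draw_hairs(image, spec, rng_hair)

    image = _round_half_up(np.clip(image, 0.0, 255.0)).astype(np.uint8)
    return PhantomSample(image=image, truth_mask=mask, spec=spec)


def derive_seed(master_seed: int, *counters: int) -> int:
    """Counter-based child seed: independent of iteration order, < 2**31."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, counters)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_benchmark_set(
    spec_template: PhantomSpec,
    counts: Sequence[int],
    seed: int,
) -> list[list[PhantomSample]]:
    """One phantom set per requested size, mirroring image-count sweeps.

    Per-sample seeds are derived from ``seed`` with a (set index, sample
    index) counter scheme, so samples vary in blob placement and noise draw
    while the whole collection is reproducible bit-exactly.
    """
    if len(counts) == 0:
        raise ValueError("counts must be non-empty")
    if any(c < 1 for c in counts):
        raise ValueError(f"every count must be >= 1, got {list(counts)}")
    sets: list[list[PhantomSample]] = []
    for set_idx, count in enumerate(counts):
        samples = [
            generate_phantom(
                dataclasses.replace(
                    spec_template, seed=derive_seed(seed, set_idx, sample_idx)
                )
            )
            for sample_idx in range(count)
        ]
        sets.append(samples)
    return sets


def save_sample(sample: PhantomSample, stem: Path | str) -> None:
    """Write ``<stem>.png``, ``<stem>_mask.png`` (0/255) and a spec sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(sample.image).save(stem.with_suffix(".png"))
    Image.fromarray((sample.truth_mask.astype(np.uint8)) * 255).save(
        stem.parent / f"{stem.name}_mask.png"
    )
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(dataclasses.asdict(sample.spec), fh, indent=2)


def load_sample(stem: Path | str) -> PhantomSample:
    """Inverse of :func:`save_sample`."""
    stem = Path(stem)
    image = np.asarray(Image.open(stem.with_suffix(".png")))
    mask = np.asarray(Image.open(stem.parent / f"{stem.name}_mask.png")) > 127
    with open(stem.with_suffix(".json")) as fh:
        spec = PhantomSpec(**json.load(fh))
    return PhantomSample(image=image, truth_mask=mask, spec=spec)


def load_pairs(directory: Path | str) -> list[tuple[str, np.ndarray, np.ndarray | None]]:
    """Load ``(name, image, mask-or-None)`` pairs from a directory.

    Any ``<stem>.png`` (or .tif/.tiff/.jpg/.jpeg) that is not itself a
    ``*_mask`` file is an image; its mask, if present, is ``<stem>_mask.png``.
    """
    directory = Path(directory)
    pairs = []
    exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in exts or path.stem.endswith("_mask"):
            continue
        image = np.asarray(Image.open(path))
        mask_path = directory / f"{path.stem}_mask.png"
        mask = np.asarray(Image.open(mask_path)) > 127 if mask_path.exists() else None
        pairs.append((path.stem, image, mask))
    return pairs
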