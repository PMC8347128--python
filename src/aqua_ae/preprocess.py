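"""Crop preprocessing: quality filter, enhancement, augmentation, squaring, resize.

The training pipeline expects every input as a 256×256×3 array in [0, 1]
with the subject's aspect ratio intact. Object crops of arbitrary shape are
therefore embedded centered in a zero-filled square of side ``max(H, W)``
before resizing (black padding), low-variance frames are dropped, and the
sample count is multiplied by rotating (every 45° by default) and shifting
each crop.

Enhancement applies, in order: a multiplicative brightness factor, contrast
scaling around the per-channel mean, and a 3×3 sharpening kernel
(correlation, zero-padded borders), clipping to [0, 1] after each step.
The default kernel has all eight neighbors at −1 and a center of 11; its
sum of 3 intentionally amplifies intensities (clipping handles overflow),
which brightens murky sources. A center-9 variant (sum 1) sharpens without
amplification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import transform as sktransform

__all__ = [
    "EnhanceConfig",
    "AugmentConfig",
    "square_pad",
    "resize",
    "enhance",
    "augment",
    "quality_filter",
    "preprocess_pipeline",
]


def sharpen_kernel(center: float) -> np.ndarray:
    """3×3 kernel with all eight neighbors −1 and the given center weight."""
    k = -np.ones((3, 3))
    k[1, 1] = center
    return k


@dataclass(frozen=True)
class EnhanceConfig:
    brightness_factor: float = 2.0
    contrast_factor: float = 0.6
    kernel: np.ndarray = field(default_factory=lambda: sharpen_kernel(11.0))

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=np.float64)
        if k.shape != (3, 3):
            raise ValueError(f"kernel must be 3x3, got {k.shape}")
        object.__setattr__(self, "kernel", k)


@dataclass(frozen=True)
class AugmentConfig:
    rotation_step_degrees: float = 45.0
    shifts: tuple[tuple[float, float], ...] = ()
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        step = self.rotation_step_degrees
        if step <= 0 or abs(360.0 / step - round(360.0 / step)) > 1e-9:
            raise ValueError(f"360 must be divisible by rotation step, got {step}")
        object.__setattr__(self, "shifts", tuple(tuple(s) for s in self.shifts))

    @property
    def n_rotations(self) -> int:
        return int(round(360.0 / self.rotation_step_degrees))


def square_pad(crop: np.ndarray) -> np.ndarray:
    """Embed a crop centered in a zero-filled square of side max(H, W).

    Preserves the subject's aspect ratio exactly; the offset on each axis is
    ``floor((S - dim) / 2)``.
    """
    crop = np.asarray(crop, dtype=np.float64)
    if crop.ndim != 3 or crop.shape[2] != 3:
        raise ValueError(f"expected HxWx3 crop, got shape {crop.shape}")
    h, w, _ = crop.shape
    if h == 0 or w == 0:
        raise ValueError("zero-area crop")
    s = max(h, w)
    out = np.zeros((s, s, 3), dtype=np.float64)
    y0 = (s - h) // 2
    x0 = (s - w) // 2
    out[y0 : y0 + h, x0 : x0 + w] = crop
    return out


def resize(img: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize of a square image to target×target, clipped to [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    if target < 1:
        raise ValueError(f"target must be >= 1, got {target}")
    if img.ndim != 3 or img.shape[0] != img.shape[1]:
        raise ValueError(f"expected a square HxWxC image, got shape {img.shape}")
    if img.shape[0] == target:
        return img.copy()
    out = sktransform.resize(
        img,
        (target, target, img.shape[2]),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def enhance(img: np.ndarray, cfg: EnhanceConfig | None = None) -> np.ndarray:
    """Brightness → contrast → 3×3 kernel, clipping to [0, 1] after each step.

    Brightness multiplies pixel values; contrast scales each channel around
    its mean; the kernel is applied as an unnormalized correlation with
    zero-padded borders.
    """
    if cfg is None:
        cfg = EnhanceConfig()
    img = np.asarray(img, dtype=np.float64)
    out = np.clip(img * cfg.brightness_factor, 0.0, 1.0)
    means = out.mean(axis=(0, 1), keepdims=True)
    out = np.clip((out - means) * cfg.contrast_factor + means, 0.0, 1.0)
    filtered = np.stack(
        [
            ndimage.correlate(out[..., c], cfg.kernel, mode="constant", cval=0.0)
            for c in range(out.shape[2])
        ],
        axis=-1,
    )
    return np.clip(filtered, 0.0, 1.0)


def _rotate(img: np.ndarray, angle: float, fill: float) -> np.ndarray:
    """Rotate about the center; 90° multiples are exact index permutations."""
    angle = angle % 360.0
    if angle == 0.0:
        return img.copy()
    if angle % 90.0 == 0.0:
        return np.ascontiguousarray(np.rot90(img, k=int(angle // 90), axes=(0, 1)))
    out = sktransform.rotate(
        img, angle, resize=False, order=1, mode="constant", cval=fill, preserve_range=True
    )
    return np.clip(out, 0.0, 1.0)


def _shift(img: np.ndarray, dx: float, dy: float, fill: float) -> np.ndarray:
    out = ndimage.shift(
        img, (dy, dx, 0.0), order=1, mode="constant", cval=fill, prefilter=False
    )
    return np.clip(out, 0.0, 1.0)


def augment(img: np.ndarray, cfg: AugmentConfig | None = None) -> list[np.ndarray]:
    """All rotations of the crop and of each shifted variant.

    Returns ``(1 + len(shifts)) * (360 / step)`` images: every rotation of
    the unshifted crop plus every rotation of each shift. Requires a square
    input so rotation keeps the frame; exposed corners are zero-filled.
    """
    if cfg is None:
        cfg = AugmentConfig()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[0] != img.shape[1]:
        raise ValueError(f"augment requires a square image, got shape {img.shape}")
    variants = [img] + [_shift(img, dx, dy, cfg.fill_value) for dx, dy in cfg.shifts]
    out: list[np.ndarray] = []
    for variant in variants:
        for i in range(cfg.n_rotations):
            out.append(_rotate(variant, i * cfg.rotation_step_degrees, cfg.fill_value))
    return out


def quality_filter(
    imgs: list[np.ndarray], tau: float = 0.02
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Split images into (kept, dropped) by a variance proxy for quality.

    An image is dropped when its maximum per-channel standard deviation is
    below ``tau`` — near-constant frames carry no trainable contour signal.
    Order is preserved in both lists.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    kept: list[np.ndarray] = []
    dropped: list[np.ndarray] = []
    for img in imgs:
        arr = np.asarray(img, dtype=np.float64)
        score = arr.std(axis=(0, 1)).max() if arr.ndim == 3 else arr.std()
        (kept if score >= tau else dropped).append(img)
    return kept, dropped


@dataclass(frozen=True)
class PipelineConfig:
    target: int = 256
    tau: float = 0.02
    enhance: EnhanceConfig | None = None  # None = no enhancement pass
    augment: AugmentConfig = field(default_factory=AugmentConfig)


def preprocess_pipeline(
    src_dir: str | Path, out_dir: str | Path, cfg: PipelineConfig | None = None
) -> list[dict]:
    """Run filter → enhance → square-pad → augment → resize → save over a directory.

    Reads every PNG in ``src_dir`` (sorted by name), writes the processed
    target×target outputs to ``out_dir`` and returns the manifest: one record
    per output with its source file, the applied operations, and the output
    path. The manifest is also written as ``manifest.json`` in ``out_dir``.
    Squaring precedes augmentation so rotations act on a square frame.
    """
    if cfg is None:
        cfg = PipelineConfig()
    src_dir = Path(src_dir)
    out_dir = Path(out_dir)
    paths = sorted(src_dir.glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG images found in {src_dir}")
    imgs = [np.asarray(Image.open(p).convert("RGB"), dtype=np.float64) / 255.0 for p in paths]
    kept_pairs = [
        (p, img)
        for p, img in zip(paths, imgs)
        if np.asarray(img).std(axis=(0, 1)).max() >= cfg.tau
    ]
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    counter = 0
    for src_path, img in kept_pairs:
        if cfg.enhance is not None:
            img = enhance(img, cfg.enhance)
        img = square_pad(img)
        for j, aug in enumerate(augment(img, cfg.augment)):
            final = resize(aug, cfg.target)
            out_path = out_dir / f"proc_{counter:06d}.png"
            arr8 = np.clip(np.rint(final * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr8, mode="RGB").save(out_path)
            manifest.append(
                {
                    "source": src_path.name,
                    "ops": {
                        "enhanced": cfg.enhance is not None,
                        "augment_index": j,
                        "rotation_step": cfg.augment.rotation_step_degrees,
                        "n_shifts": len(cfg.augment.shifts),
                        "target": cfg.target,
                        "tau": cfg.tau,
                    },
                    "output": out_path.name,
                }
            )
            counter += 1
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
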