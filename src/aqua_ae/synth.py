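"""Synthetic low-contrast aquatic scenes with ground-truth fish boxes.

Aquarium monitoring footage is murky: light enters from one side and falls
off across the compartment, reflections and fixtures clutter the
background, and the fish differ from their surroundings by only a small
intensity offset. This module emulates those properties so every
downstream stage (preprocessing, autoencoder training, difference-image
denoising) is testable without real footage.

Scenes are deterministic functions of :class:`SceneParams` (including the
seed): the same parameters produce bit-identical frames on any platform
(PCG64 generator, fixed drawing order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SceneParams",
    "BBox",
    "PlacementError",
    "make_background",
    "compose_scene",
    "make_dataset",
    "save_scene",
    "load_scene",
]

# murk base color: dim blue-green water column
_BASE_COLOR = np.array([0.16, 0.30, 0.34])
# illumination amplitude at gradient_strength = 1 (additive, centered)
_GRADIENT_AMPLITUDE = 0.4
# clutter: up to this many shapes at clutter_density = 1
_MAX_CLUTTER = 12
_PLACEMENT_RETRIES = 50


class PlacementError(RuntimeError):
    """Raised when non-overlapping fish placement fails after bounded retries."""


@dataclass(frozen=True)
class SceneParams:
    """Controls for one synthetic scene.

    contrast_delta is the foreground-background intensity offset in [0, 1];
    noise_sigma the additive Gaussian noise std on the [0, 1] scale;
    gradient_strength the left-to-right illumination falloff in [0, 1]
    (brightest at column 0); clutter_density in [0, 1] scales the number of
    low-alpha background shapes standing in for reflections and fixtures.
    """

    height: int = 64
    width: int = 64
    n_fish: int = 3
    contrast_delta: float = 0.1
    noise_sigma: float = 0.05
    gradient_strength: float = 0.3
    clutter_density: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError(f"scene dimensions must be positive, got {self.height}x{self.width}")
        if self.n_fish < 0:
            raise ValueError("n_fish must be >= 0")
        if not 0.0 <= self.contrast_delta <= 1.0:
            raise ValueError("contrast_delta must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.gradient_strength <= 1.0:
            raise ValueError("gradient_strength must lie in [0, 1]")
        if not 0.0 <= self.clutter_density <= 1.0:
            raise ValueError("clutter_density must lie in [0, 1]")


@dataclass(frozen=True)
class BBox:
    """Half-open pixel box [x0, x1) × [y0, y1), 0-based."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {self}")

    def overlaps(self, other: "BBox") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )

    def as_list(self) -> list[int]:
        return [self.x0, self.y0, self.x1, self.y1]


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def make_background(params: SceneParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Murk color + horizontal illumination gradient + clutter + noise.

    With all variation sources off (noise_sigma = 0, clutter_density = 0,
    gradient_strength = 0) the result is a constant-color frame.
    """
    if rng is None:
        rng = _rng(params.seed)
    h, w = params.height, params.width
    img = np.broadcast_to(_BASE_COLOR, (h, w, 3)).astype(np.float64).copy()

    if params.gradient_strength > 0:
        # brightest at column 0, fading rightward; zero-mean so the overall
        # brightness does not depend on gradient_strength
        ramp = np.linspace(0.5, -0.5, w) * _GRADIENT_AMPLITUDE * params.gradient_strength
        img += ramp[None, :, None]

    n_clutter = int(round(params.clutter_density * _MAX_CLUTTER))
    for _ in range(n_clutter):
        img = _add_clutter_shape(img, rng)

    if params.noise_sigma > 0:
        img += rng.normal(0.0, params.noise_sigma, size=img.shape)

    return np.clip(img, 0.0, 1.0)


def _add_clutter_shape(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Blend one low-alpha rectangle or ellipse into the background.

    Rectangles mimic fixtures (a metal bar), ellipses mimic reflections and
    compartments seen through the water.
    """
    h, w, _ = img.shape
    kind = rng.integers(0, 2)
    alpha = rng.uniform(0.1, 0.3)
    tint = rng.uniform(-0.15, 0.15, size=3)
    if kind == 0:  # bar
        horizontal = rng.integers(0, 2) == 0
        thickness = max(1, int(rng.uniform(0.02, 0.08) * (h if horizontal else w)))
        if horizontal:
            y = int(rng.integers(0, max(1, h - thickness)))
            region = (slice(y, y + thickness), slice(None))
        else:
            x = int(rng.integers(0, max(1, w - thickness)))
            region = (slice(None), slice(x, x + thickness))
        img[region] = (1 - alpha) * img[region] + alpha * np.clip(img[region] + tint, 0, 1)
    else:  # reflection blob
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        ry = rng.uniform(0.05, 0.25) * h
        rx = rng.uniform(0.05, 0.25) * w
        yy, xx = np.mgrid[0:h, 0:w]
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        img[mask] = (1 - alpha) * img[mask] + alpha * np.clip(img[mask] + tint, 0, 1)
    return img


def _fish_mask(
    h: int, w: int, cx: float, cy: float, a: float, b: float, theta: float
) -> np.ndarray:
    """Fusiform silhouette: body ellipse plus a smaller tail ellipse."""
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st  # along-body coordinate
    v = -dx * st + dy * ct
    body = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    # tail behind the body along -u
    tu = u + 0.95 * a
    tail = (tu / (0.45 * a)) ** 2 + (v / (0.55 * b)) ** 2 <= 1.0
    return body | tail


def compose_scene(
    params: SceneParams,
) -> tuple[np.ndarray, list[BBox]]:
    """Background plus ``n_fish`` low-contrast fusiform shapes.

    Each fish is an offset of ``contrast_delta`` from the local background
    (sign drawn per fish), with a slight per-channel tint. Boxes are the
    exact extent of each fish's silhouette, so every foreground pixel lies
    inside its reported box. Fish are placed without box overlap; if a
    non-overlapping position cannot be found after bounded retries a
    :class:`PlacementError` is raised.
    """
    rng = _rng(params.seed)
    img = make_background(params, rng)
    h, w = params.height, params.width
    boxes: list[BBox] = []
    side = min(h, w)
    for _ in range(params.n_fish):
        placed = False
        for _attempt in range(_PLACEMENT_RETRIES):
            a = rng.uniform(0.10, 0.16) * side  # body half-length
            b = a * rng.uniform(0.35, 0.5)  # body half-width
            theta = rng.uniform(0, 2 * np.pi)
            margin = 1.6 * a
            if 2 * margin >= min(h, w):
                continue
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            mask = _fish_mask(h, w, cx, cy, a, b, theta)
            if not mask.any():
                continue
            ys, xs = np.nonzero(mask)
            box = BBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
            if any(box.overlaps(other) for other in boxes):
                continue
            sign = 1.0 if rng.integers(0, 2) == 0 else -1.0
            tint = rng.uniform(-0.2, 0.2, size=3) * params.contrast_delta
            offset = sign * params.contrast_delta + tint
            img[mask] = np.clip(img[mask] + offset, 0.0, 1.0)
            boxes.append(box)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place fish {len(boxes) + 1}/{params.n_fish} in a "
                f"{h}x{w} frame after {_PLACEMENT_RETRIES} retries"
            )
    return img, boxes


def make_dataset(
    n_scenes: int, params: SceneParams
) -> tuple[list[np.ndarray], list[list[BBox]]]:
    """Generate ``n_scenes`` scenes with per-scene seeds ``seed + index``.

    Per-item seed derivation keeps any subset reproducible independently.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    frames: list[np.ndarray] = []
    box_lists: list[list[BBox]] = []
    for i in range(n_scenes):
        img, boxes = compose_scene(replace(params, seed=params.seed + i))
        frames.append(img)
        box_lists.append(boxes)
    return frames, box_lists


def save_scene(
    out_dir: str | Path, index: int, img: np.ndarray, boxes: list[BBox], params: SceneParams
) -> Path:
    """Write one frame as 8-bit PNG plus a JSON sidecar with its boxes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    png_path = out_dir / f"scene_{index:05d}.png"
    arr8 = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr8, mode="RGB").save(png_path)
    sidecar = {
        "boxes": [b.as_list() for b in boxes],
        "seed": params.seed,
        "params": asdict(params),
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return png_path


def load_scene(png_path: str | Path) -> tuple[np.ndarray, list[BBox]]:
    """Read a frame and its sidecar boxes back (values rescaled to [0, 1])."""
    png_path = Path(png_path)
    img = np.asarray(Image.open(png_path).convert("RGB"), dtype=np.float64) / 255.0
    sidecar_path = png_path.with_suffix(".json")
    boxes: list[BBox] = []
    if sidecar_path.exists():
        data = json.loads(sidecar_path.read_text())
        boxes = [BBox(*b) for b in data.get("boxes", [])]
    return img, boxes
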