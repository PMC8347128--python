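"""Difference-image denoising and Sobel treatment for subject observation.

A trained autoencoder smooths away exactly what it could not learn —
transient foreground subjects against a learned murky background. The
standardized difference image (DIFF) between a frame and its
reconstruction therefore reveals the subjects while suppressing the
static background; applying Sobel gradient magnitude to DIFF (DIFF2)
further sharpens the subject contours. Caregivers can watch DIFF2 panels
instead of the raw low-contrast footage.

The retrain recipe is compositional: train a model on source frames, emit
the DIFF dataset with :func:`observe`, optionally train a second model on
those DIFF images, and Sobel-treat its output. Every stage reuses the same
fit/observe machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from aqua_ae.metrics import benchmark, image_diff, standardize
from aqua_ae.models import Autoencoder

__all__ = ["DiffPanel", "difference_image", "sobel_treatment", "observe", "save_panel"]

# Rec. 601 luma weights for the RGB -> luminance collapse before Sobel
_LUMA = np.array([0.299, 0.587, 0.114])
_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


@dataclass(frozen=True)
class DiffPanel:
    """One observation panel: source, reconstruction, DIFF, DIFF2.

    All four share spatial dimensions; ``benchmark_value`` is the
    visual-contrast benchmark between source and reconstruction.
    """

    source: np.ndarray
    reconstructed: np.ndarray
    diff: np.ndarray
    diff2: np.ndarray
    benchmark_value: float


def difference_image(src: np.ndarray, model: Autoencoder) -> np.ndarray:
    """Standardized difference between a frame and its reconstruction.

    The result lies in [0, 1]; a perfectly reconstructed frame gives an
    all-zero difference.
    """
    src = np.asarray(src, dtype=np.float64)
    if src.shape != model.input_shape:
        raise ValueError(f"frame shape {src.shape} does not match model {model.input_shape}")
    return image_diff(src, model.reconstruct(src))


def sobel_treatment(img: np.ndarray) -> np.ndarray:
    """Gradient-magnitude edge image of an RGB frame, standardized to [0, 1].

    The frame is collapsed to luminance, correlated with the horizontal and
    vertical 3×3 Sobel operators (replicate-edge borders, so a constant
    frame has zero gradient everywhere), and the magnitude
    ``sqrt(gx² + gy²)`` is min-max standardized. The single channel is
    replicated to RGB so panels can be displayed uniformly.
    """
    img = np.asarray(img, dtype=np.float64)
    luma = img @ _LUMA if img.ndim == 3 else img
    gx = ndimage.correlate(luma, _SOBEL_X, mode="nearest")
    gy = ndimage.correlate(luma, _SOBEL_Y, mode="nearest")
    mag = np.sqrt(gx**2 + gy**2)
    if mag.max() == mag.min():
        out = np.zeros_like(mag)
    else:
        out = standardize(mag)
    return np.repeat(out[..., None], 3, axis=-1)


def observe(
    frames: list[np.ndarray] | np.ndarray,
    model: Autoencoder,
    diff_model: Autoencoder | None = None,
) -> list[DiffPanel]:
    """Build one :class:`DiffPanel` per frame with a trained model.

    By default DIFF2 is the Sobel treatment of DIFF directly. When
    ``diff_model`` is given (a second autoencoder retrained on DIFF images),
    DIFF2 is the Sobel treatment of that model's reconstruction of DIFF —
    the alternative observation path in which the second model smooths the
    difference image before edge extraction.
    """
    panels: list[DiffPanel] = []
    for frame in frames:
        frame = np.asarray(frame, dtype=np.float64)
        recon = model.reconstruct(frame)
        diff = image_diff(frame, recon)
        diff2_src = diff if diff_model is None else diff_model.reconstruct(diff)
        panels.append(
            DiffPanel(
                source=frame,
                reconstructed=recon,
                diff=diff,
                diff2=sobel_treatment(diff2_src),
                benchmark_value=benchmark(frame, recon),
            )
        )
    return panels


def save_panel(panel: DiffPanel, path: str | Path) -> Path:
    """Write a panel as a side-by-side strip: source | reconstructed | DIFF | DIFF2."""
    strip = np.concatenate(
        [panel.source, panel.reconstructed, panel.diff, panel.diff2], axis=1
    )
    arr8 = np.clip(np.rint(strip * 255.0), 0, 255).astype(np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr8, mode="RGB").save(path)
    return path
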