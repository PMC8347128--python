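"""Reference desk-scale experiments on the synthetic fixture conditions.

These functions define the package's standard verification experiments at
desk scale — 64×64 frames, a few hundred images, minutes on one CPU — so
the same procedures can be run from the test suite, the acceptance script,
or interactively. The scene parameters are the generator defaults (the
study conditions); only the seed varies.
"""

from __future__ import annotations

import numpy as np

from aqua_ae.denoise import observe
from aqua_ae.models import ModelSpec, build_autoencoder
from aqua_ae.synth import SceneParams, make_dataset
from aqua_ae.train import TrainConfig, evaluate, fit

__all__ = [
    "fixture_scenes",
    "training_descent_experiment",
    "trained_vs_untrained_experiment",
    "salience_experiment",
]

FIXTURE_SIDE = 64
FIXTURE_N = 200
CNN_SPEC = ModelSpec("cnn", (32, 16), input_side=FIXTURE_SIDE)


def fixture_scenes(n: int, seed: int, n_fish: int = 3):
    """Default-condition scenes at fixture scale; returns (frames, box lists)."""
    params = SceneParams(height=FIXTURE_SIDE, width=FIXTURE_SIDE, n_fish=n_fish, seed=seed)
    frames, boxes = make_dataset(n, params)
    return np.stack(frames), boxes


def training_descent_experiment(seed: int, epochs: int = 12, n: int = FIXTURE_N) -> dict:
    """Train the 32-16 CNN on the fixture and report the validation-loss drop.

    Returns the epoch-1 and best validation losses and their ratio; a ratio
    below 0.5 means the loss at least halved within the trained epochs.
    """
    data, _ = fixture_scenes(n, seed=seed + 10)
    model = build_autoencoder(CNN_SPEC)
    results = fit(model, data, TrainConfig(epochs=epochs, batch_size=8, seed=seed))
    epoch1 = results.val_loss[0]
    best = min(results.val_loss)
    return {
        "epoch1_val_loss": epoch1,
        "best_val_loss": best,
        "val_loss_ratio": best / epoch1,
        "epochs_run": len(results.val_loss),
        "n_images": n,
        "model": model,
        "results": results,
    }


def trained_vs_untrained_experiment(
    seed: int, n_seeds: int = 10, epochs: int = 3, n: int = FIXTURE_N
) -> dict:
    """Paired comparison: does brief training beat a fresh seeded model?

    For each of ``n_seeds`` seeds, a 32-16 CNN is trained for a few epochs on
    the fixture and its mean reconstruction benchmark on the held-out 20% is
    compared with that of an untrained model drawn from the same seed.
    Returns the fraction of seeds where the trained model wins.
    """
    data, _ = fixture_scenes(n, seed=seed + 10)
    split = int(round(0.8 * n))
    train, test = data[:split], data[split:]
    wins = 0
    trained_means, untrained_means = [], []
    for k in range(n_seeds):
        s = seed + 100 + k
        trained = build_autoencoder(CNN_SPEC)
        fit(trained, train, TrainConfig(epochs=epochs, batch_size=8, seed=s, patience=epochs))
        untrained = build_autoencoder(CNN_SPEC).initialize(s)
        t_mean = evaluate(trained, test).mean
        u_mean = evaluate(untrained, test).mean
        trained_means.append(t_mean)
        untrained_means.append(u_mean)
        wins += t_mean < u_mean
    return {
        "fraction_improved": wins / n_seeds,
        "n_seeds": n_seeds,
        "trained_mean_benchmark": float(np.mean(trained_means)),
        "untrained_mean_benchmark": float(np.mean(untrained_means)),
    }


def salience_experiment(
    seed: int, n_train: int = 100, n_observe: int = 20, epochs: int = 6
) -> dict:
    """DIFF2 foreground salience with a background-trained model.

    A 32-16 CNN is trained on background-only frames (no fish) so its
    reconstruction of a fish scene approximates the background; the
    standardized difference then carries the fish, and its Sobel treatment
    (DIFF2) is measured inside vs outside the ground-truth boxes. Returns
    the mean-intensity ratio inside/outside.
    """
    bg, _ = fixture_scenes(n_train, seed=seed + 500, n_fish=0)
    model = build_autoencoder(CNN_SPEC)
    fit(model, bg, TrainConfig(epochs=epochs, batch_size=8, seed=seed + 2))
    frames, box_lists = fixture_scenes(n_observe, seed=seed + 900)
    inside, outside = [], []
    for panel, boxes in zip(observe(frames, model), box_lists):
        mask = np.zeros(panel.diff2.shape[:2], dtype=bool)
        for b in boxes:
            mask[b.y0 : b.y1, b.x0 : b.x1] = True
        lum = panel.diff2[..., 0]
        inside.append(lum[mask].mean())
        outside.append(lum[~mask].mean())
    ratio = float(np.mean(inside) / np.mean(outside))
    return {
        "inside_mean": float(np.mean(inside)),
        "outside_mean": float(np.mean(outside)),
        "salience_ratio": ratio,
        "n_observe": n_observe,
    }
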