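"""Symmetric MLP and CNN autoencoders built from declarative specs.

A :class:`ModelSpec` is a dash-separated list of stage widths, e.g.
``"256-64"`` for an MLP (dense units, ending at the latent length) or
``"256-128-64"`` for a CNN (conv filters per block). Builders produce a
:class:`Autoencoder` whose decoder mirrors the encoder stages in reverse:

* MLP — flatten → dense stages (ReLU) → latent → mirrored dense stages →
  output dense back to side²·3 with sigmoid. Every dense layer has a bias,
  so a layer of ``n_in → n_out`` holds ``n_in·n_out + n_out`` parameters.
* CNN — per stage a 3×3 same-padding convolution (ReLU) followed by 2×2
  max pooling; the latent is the final pooled tensor. The decoder mirrors
  with stride-1 3×3 transposed convolutions and 2× up-sampling, and the
  output head is a 3×3 convolution to 3 channels with sigmoid (for a
  256-filter final stage: 9·256·3 + 3 = 6915 parameters).

Parameter counts are structural — derived from shapes, available before
any weight is allocated — so even a hundred-million-parameter spec can be
summarised instantly. Weights follow lazily via ``initialize(seed)``
(uniform, scaled by fan-in, PCG64-seeded, bit-reproducible).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from aqua_ae._layers import (
    Layer,
    Flatten,
    Reshape,
    Dense,
    Conv2D,
    ConvTranspose2D,
    MaxPool2D,
    UpSampling2D,
)

__all__ = ["ModelSpec", "Autoencoder", "parse_spec", "build_mlp", "build_cnn", "count_params"]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative architecture descriptor.

    ``stages`` are encoder widths in encoder order; the last entry is the
    latent width (MLP) or the latent channel count (CNN).
    """

    family: str  # "mlp" | "cnn"
    stages: tuple[int, ...]
    input_side: int = 256
    channels: int = 3

    def __post_init__(self) -> None:
        family = self.family.lower()
        if family not in ("mlp", "cnn"):
            raise ValueError(f"family must be 'mlp' or 'cnn', got {self.family!r}")
        object.__setattr__(self, "family", family)
        stages = tuple(int(s) for s in self.stages)
        if not stages or any(s <= 0 for s in stages):
            raise ValueError(f"stages must be non-empty positive integers, got {stages}")
        object.__setattr__(self, "stages", stages)
        if self.input_side < 1:
            raise ValueError("input_side must be >= 1")
        if family == "cnn":
            if self.input_side % (2 ** len(stages)) != 0:
                raise ValueError(
                    f"input_side {self.input_side} not divisible by 2^{len(stages)}"
                )

    @property
    def latent_shape(self) -> tuple[int, ...]:
        if self.family == "mlp":
            return (self.stages[-1],)
        side = self.input_side // (2 ** len(self.stages))
        return (side, side, self.stages[-1])

    @property
    def text(self) -> str:
        return "-".join(str(s) for s in self.stages)


def parse_spec(
    text: str, family: str, input_side: int = 256, channels: int = 3
) -> ModelSpec:
    """Parse a dash-separated width list like ``"256-128-64"`` into a spec."""
    tokens = text.strip().split("-")
    try:
        stages = tuple(int(t) for t in tokens)
    except ValueError as exc:
        raise ValueError(f"non-integer stage token in {text!r}") from exc
    return ModelSpec(family=family, stages=stages, input_side=input_side, channels=channels)


@dataclass(frozen=True)
class _SummaryRow:
    id: str
    name: str
    type: str
    output_shape: tuple[int, ...]
    activation: str
    params: int


class Autoencoder:
    """A symmetric encoder/decoder network over [0, 1] RGB images.

    Built by :func:`build_mlp` or :func:`build_cnn`. ``encode``/``decode``/
    ``reconstruct`` accept a single H×W×3 image or an (N, H, W, 3) batch.
    ``fit`` delegates to :func:`aqua_ae.train.fit` and returns a
    :class:`~aqua_ae.train.TrainingResults`.
    """

    def __init__(
        self,
        spec: ModelSpec,
        layers: list[Layer],
        encoder_len: int,
        summary_rows: list[_SummaryRow],
    ):
        self.spec = spec
        self.layers = layers
        self.encoder_len = encoder_len  # layers[:encoder_len] form the encoder
        self._summary_rows = summary_rows
        self.initialized = False

    # ----- structure -----
    @property
    def input_shape(self) -> tuple[int, int, int]:
        return (self.spec.input_side, self.spec.input_side, self.spec.channels)

    @property
    def latent_shape(self) -> tuple[int, ...]:
        return self.spec.latent_shape

    @property
    def param_count(self) -> int:
        return sum(layer.param_count for layer in self.layers)

    def layer_table(self) -> list[_SummaryRow]:
        return list(self._summary_rows)

    def summary(self) -> str:
        """Layer summary table: id, name, type, output shape, activation, params."""
        lines = [
            f"{self.spec.family.upper()} autoencoder '{self.spec.text}' "
            f"(input {self.input_shape}, latent {self.latent_shape})",
            f"{'Id':<10}{'Layer':<18}{'Type':<18}{'Output Shape':<22}"
            f"{'Activation':<12}{'Param #':>12}",
        ]
        for row in self._summary_rows:
            shape = "(None, " + ", ".join(f"{d:,}" for d in row.output_shape) + ")"
            lines.append(
                f"{row.id:<10}{row.name:<18}{row.type:<18}{shape:<22}"
                f"{row.activation:<12}{row.params:>12,}"
            )
        lines.append(f"Total params: {self.param_count:,}")
        return "\n".join(lines)

    # ----- weights -----
    def initialize(self, seed: int = 0) -> "Autoencoder":
        rng = np.random.Generator(np.random.PCG64(seed))
        for layer in self.layers:
            layer.initialize(rng)
        self.initialized = True
        return self

    def _require_initialized(self) -> None:
        if not self.initialized:
            raise RuntimeError("model weights not initialized; call initialize(seed) first")

    # ----- inference -----
    def _as_batch(self, x: np.ndarray, expect: tuple[int, ...]) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=np.float64)
        if x.shape == expect:
            return x[None], True
        if x.ndim == len(expect) + 1 and x.shape[1:] == expect:
            return x, False
        raise ValueError(f"expected shape {expect} or (N, *{expect}), got {x.shape}")

    def encode(self, img: np.ndarray) -> np.ndarray:
        self._require_initialized()
        x, single = self._as_batch(img, self.input_shape)
        for layer in self.layers[: self.encoder_len]:
            x = layer.forward(x)
        return x[0] if single else x

    def decode(self, latent: np.ndarray) -> np.ndarray:
        self._require_initialized()
        x, single = self._as_batch(latent, self.latent_shape)
        for layer in self.layers[self.encoder_len :]:
            x = layer.forward(x)
        return x[0] if single else x

    def reconstruct(self, img: np.ndarray) -> np.ndarray:
        self._require_initialized()
        x, single = self._as_batch(img, self.input_shape)
        for layer in self.layers:
            x = layer.forward(x)
        return x[0] if single else x

    # training entry point (statsmodels-style: model.fit() -> results)
    def fit(self, data: np.ndarray, config=None, val_data: np.ndarray | None = None):
        from aqua_ae.train import fit as _fit

        return _fit(self, data, config, val_data=val_data)

    # ----- persistence -----
    def get_weights(self) -> list[np.ndarray]:
        self._require_initialized()
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        self._require_initialized()
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError(f"expected {len(flat)} arrays, got {len(weights)}")
        for p, w in zip(flat, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w

    def save(self, path: str | Path) -> Path:
        """Single-file checkpoint: named weight arrays plus the spec as JSON."""
        self._require_initialized()
        path = Path(path)
        arrays = {}
        for li, layer in enumerate(self.layers):
            for pi, p in enumerate(layer.params):
                arrays[f"layer{li:03d}_param{pi}"] = p
        buf = io.BytesIO()
        np.savez(buf, spec=np.frombuffer(json.dumps(asdict(self.spec)).encode(), dtype=np.uint8),
                 **arrays)
        path.write_bytes(buf.getvalue())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Autoencoder":
        with np.load(Path(path)) as data:
            spec_dict = json.loads(bytes(data["spec"]).decode())
            spec = ModelSpec(**{k: tuple(v) if k == "stages" else v for k, v in spec_dict.items()})
            model = build_autoencoder(spec).initialize(seed=0)
            names = sorted(k for k in data.files if k != "spec")
            model.set_weights([data[k] for k in names])
        return model


def build_mlp(spec: ModelSpec) -> Autoencoder:
    """Dense symmetric autoencoder per the declarative spec."""
    if spec.family != "mlp":
        raise ValueError(f"build_mlp requires an MLP spec, got family {spec.family!r}")
    n_input = spec.input_side * spec.input_side * spec.channels
    layers: list[Layer] = [Flatten(name="input")]
    rows = [_SummaryRow("IN", "input", "Input Layer", (n_input,), "ReLU", 0)]
    prev = n_input
    for i, width in enumerate(spec.stages):
        is_latent = i == len(spec.stages) - 1
        name = "latent" if is_latent else f"encoded_{width}"
        layer = Dense(prev, width, activation="relu", name=name)
        layers.append(layer)
        rows.append(
            _SummaryRow("L" if is_latent else f"EN{width}", name, "Dense", (width,),
                        "ReLU", layer.param_count)
        )
        prev = width
    for width in reversed(spec.stages[:-1]):
        layer = Dense(prev, width, activation="relu", name=f"decoded_{width}")
        layers.append(layer)
        rows.append(
            _SummaryRow(f"DE{width}", f"decoded_{width}", "Dense", (width,), "ReLU",
                        layer.param_count)
        )
        prev = width
    out = Dense(prev, n_input, activation="sigmoid", name="output")
    layers.append(out)
    layers.append(Reshape(target=(spec.input_side, spec.input_side, spec.channels)))
    rows.append(_SummaryRow("OUT", "output", "Dense", (n_input,), "Sigmoid", out.param_count))
    encoder_len = 1 + len(spec.stages)  # flatten + encoder denses
    return Autoencoder(spec, layers, encoder_len, rows)


def build_cnn(spec: ModelSpec) -> Autoencoder:
    """Convolutional symmetric autoencoder: [conv → maxpool] blocks mirrored
    by [transposed conv → up-sampling] blocks and a 3×3 sigmoid output conv."""
    if spec.family != "cnn":
        raise ValueError(f"build_cnn requires a CNN spec, got family {spec.family!r}")
    side = spec.input_side
    layers: list[Layer] = []
    rows = [_SummaryRow("IN", "input", "Input Layer", (side, side, spec.channels), "ReLU", 0)]
    prev_c = spec.channels
    cur = side
    for i, filters in enumerate(spec.stages):
        conv = Conv2D(prev_c, filters, activation="relu", name=f"Conv2D_{filters}")
        layers.append(conv)
        rows.append(
            _SummaryRow(f"CN_{filters}", conv.name, "Conv2D", (cur, cur, filters), "ReLU",
                        conv.param_count)
        )
        pool = MaxPool2D(name=f"MaxPooling_{filters}")
        layers.append(pool)
        cur //= 2
        is_latent = i == len(spec.stages) - 1
        rows.append(
            _SummaryRow("L" if is_latent else f"MP_{filters}",
                        "latent" if is_latent else pool.name,
                        "MaxPooling2D", (cur, cur, filters), "ReLU", 0)
        )
        prev_c = filters
    encoder_len = len(layers)
    for filters in reversed(spec.stages):
        tconv = ConvTranspose2D(prev_c, filters, activation="relu", name=f"Conv2DT_{filters}")
        layers.append(tconv)
        rows.append(
            _SummaryRow(f"CND_{filters}", tconv.name, "Conv2DTranspose",
                        (cur, cur, filters), "ReLU", tconv.param_count)
        )
        up = UpSampling2D(name=f"UpSampling2D_{filters}")
        layers.append(up)
        cur *= 2
        rows.append(
            _SummaryRow(f"US_{filters}", up.name, "UpSampling2D", (cur, cur, filters),
                        "ReLU", 0)
        )
        prev_c = filters
    out = Conv2D(prev_c, spec.channels, activation="sigmoid", name="output")
    layers.append(out)
    rows.append(
        _SummaryRow("OUT", "output", "Conv2D", (cur, cur, spec.channels), "Sigmoid",
                    out.param_count)
    )
    return Autoencoder(spec, layers, encoder_len, rows)


def build_autoencoder(spec: ModelSpec) -> Autoencoder:
    """Dispatch on the spec family."""
    return build_mlp(spec) if spec.family == "mlp" else build_cnn(spec)


def count_params(model: Autoencoder) -> int:
    """Total trainable scalars (weights + biases), exact."""
    return model.param_count
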