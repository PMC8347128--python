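"""Architecture fidelity: spec parsing, parameter accounting, shapes, persistence."""

import numpy as np
import pytest

from aqua_ae.models import (
    Autoencoder,
    ModelSpec,
    build_autoencoder,
    build_cnn,
    build_mlp,
    count_params,
    parse_spec,
)

# Per-layer parameter counts of the published baseline architectures.
MLP_BASELINE_PARAMS = {
    "IN": 0,
    "EN256": 50_331_904,
    "EN128": 32_896,
    "L": 8_256,
    "DE128": 8_320,
    "DE256": 33_024,
    "OUT": 50_528_256,
}
CNN_BASELINE_PARAMS = {
    "IN": 0,
    "CN_256": 7_168,
    "MP_256": 0,
    "CN_128": 295_040,
    "MP_128": 0,
    "CN_64": 73_792,
    "L": 0,
    "CND_64": 36_928,
    "US_64": 0,
    "CND_128": 73_856,
    "US_128": 0,
    "CND_256": 295_168,
    "US_256": 0,
    "OUT": 6_915,
}
CNN_BASELINE_SHAPES = {
    "IN": (256, 256, 3),
    "CN_256": (256, 256, 256),
    "MP_256": (128, 128, 256),
    "CN_128": (128, 128, 128),
    "MP_128": (64, 64, 128),
    "CN_64": (64, 64, 64),
    "L": (32, 32, 64),
    "CND_64": (32, 32, 64),
    "US_64": (64, 64, 64),
    "CND_128": (64, 64, 128),
    "US_128": (128, 128, 128),
    "CND_256": (128, 128, 256),
    "US_256": (256, 256, 256),
    "OUT": (256, 256, 3),
}


class TestParseSpec:
    def test_mlp_spec_and_latent(self):
        spec = parse_spec("256-64", "mlp")
        assert spec.stages == (256, 64) and spec.latent_shape == (64,)

    def test_cnn_latent_shape_halves_per_stage(self):
        assert parse_spec("64-32-16", "cnn", 256).latent_shape == (32, 32, 16)
        assert parse_spec("512-256-128-64-32", "cnn", 256).latent_shape == (8, 8, 32)

    @pytest.mark.parametrize("bad", ["256-abc", "0-64", "-64", ""])
    def test_malformed_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_spec(bad, "mlp")

    def test_cnn_divisibility_enforced(self):
        with pytest.raises(ValueError):
            parse_spec("8-8-8", "cnn", input_side=28)


class TestParameterAccounting:
    def test_mlp_baseline_matches_published_layer_counts(self):
        model = build_mlp(parse_spec("256-128-64", "mlp", 256))
        got = {row.id: row.params for row in model.layer_table()}
        assert got == MLP_BASELINE_PARAMS
        assert model.param_count == sum(MLP_BASELINE_PARAMS.values())

    def test_cnn_baseline_matches_published_layer_counts_and_shapes(self):
        model = build_cnn(parse_spec("256-128-64", "cnn", 256))
        got = {row.id: row.params for row in model.layer_table()}
        shapes = {row.id: row.output_shape for row in model.layer_table()}
        assert got == CNN_BASELINE_PARAMS
        assert shapes == CNN_BASELINE_SHAPES

    def test_dense_closed_form_tiny_model(self):
        # side 2, channels 3 -> 12 inputs; encoder 12->1 (13), decoder 1->12 (24)
        model = build_mlp(ModelSpec("mlp", (1,), input_side=2))
        assert model.param_count == 37

    def test_conv_closed_form_tiny_model(self):
        model = build_cnn(ModelSpec("cnn", (4,), input_side=4))
        first_conv = model.layer_table()[1]
        assert first_conv.params == 3 * 3 * 3 * 4 + 4 == 112

    def test_count_params_of_empty_model_is_zero(self):
        empty = Autoencoder(ModelSpec("mlp", (1,), input_side=2), [], 0, [])
        assert count_params(empty) == 0

    def test_structural_count_needs_no_allocation(self):
        model = build_mlp(parse_spec("256-128-64", "mlp", 256))
        assert not model.initialized
        assert model.param_count == 100_942_656


class TestSymmetry:
    @pytest.mark.parametrize(
        "family,text",
        [
            ("mlp", "64-32-16"),
            ("mlp", "128-64-32"),
            ("mlp", "256-64"),
            ("cnn", "64-32-16"),
            ("cnn", "128-64-32"),
            ("cnn", "256-128-64-32"),
            ("cnn", "512-256-128-64-32"),
        ],
    )
    def test_roundtrip_shape_for_published_spec_grid(self, family, text):
        """decode(encode(x)) has the input shape for every published spec."""
        side = 32
        model = build_autoencoder(parse_spec(text, family, input_side=side)).initialize(0)
        x = np.random.default_rng(0).uniform(size=(side, side, 3))
        z = model.encode(x)
        assert z.shape == model.latent_shape
        y = model.decode(z)
        assert y.shape == x.shape
        assert y.min() >= 0.0 and y.max() <= 1.0  # sigmoid head

    def test_decoder_mirrors_encoder_stages(self):
        model = build_cnn(parse_spec("16-8-4", "cnn", 32))
        enc = [r.id for r in model.layer_table() if r.id.startswith("CN_")]
        dec = [r.id for r in model.layer_table() if r.id.startswith("CND_")]
        assert [i.split("_")[1] for i in dec] == [i.split("_")[1] for i in enc][::-1]


class TestInference:
    def test_zero_weight_decoder_outputs_half(self):
        model = build_cnn(ModelSpec("cnn", (4,), input_side=8)).initialize(0)
        for layer in model.layers:
            for p in layer.params:
                p[...] = 0.0
        out = model.decode(np.zeros(model.latent_shape))
        np.testing.assert_allclose(out, 0.5)  # sigmoid(0)

    def test_zero_weights_give_zero_latent(self):
        model = build_cnn(ModelSpec("cnn", (4,), input_side=8)).initialize(0)
        for layer in model.layers:
            for p in layer.params:
                p[...] = 0.0
        z = model.encode(np.random.default_rng(1).uniform(size=(8, 8, 3)))
        assert not z.any()

    def test_encode_is_deterministic(self):
        model = build_cnn(ModelSpec("cnn", (8, 4), input_side=16)).initialize(5)
        x = np.random.default_rng(2).uniform(size=(16, 16, 3))
        np.testing.assert_array_equal(model.encode(x), model.encode(x))

    def test_shape_mismatch_rejected(self):
        model = build_mlp(ModelSpec("mlp", (4,), input_side=8)).initialize(0)
        with pytest.raises(ValueError):
            model.encode(np.zeros((4, 4, 3)))
        with pytest.raises(ValueError):
            model.decode(np.zeros(7))

    def test_uninitialized_model_refuses_inference(self):
        model = build_mlp(ModelSpec("mlp", (4,), input_side=8))
        with pytest.raises(RuntimeError):
            model.encode(np.zeros((8, 8, 3)))


class TestCheckpoint:
    def test_save_load_roundtrip_is_byte_identical(self, tmp_path):
        model = build_cnn(ModelSpec("cnn", (8, 4), input_side=16)).initialize(9)
        x = np.random.default_rng(3).uniform(size=(16, 16, 3))
        before = model.reconstruct(x)
        path = model.save(tmp_path / "model.npz")
        loaded = Autoencoder.load(path)
        assert loaded.spec == model.spec
        for a, b in zip(model.get_weights(), loaded.get_weights()):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(loaded.reconstruct(x), before)

    def test_summary_mentions_every_layer_and_total(self):
        model = build_cnn(parse_spec("256-128-64", "cnn", 256))
        text = model.summary()
        assert "Conv2DTranspose" in text and "latent" in text
        assert "788,867" in text  # total of the published per-layer counts
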