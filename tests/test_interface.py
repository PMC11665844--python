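"""Configuration loading/validation, paired PNG/NIfTI I/O, and CLI smoke
coverage."""

import numpy as np
import pytest
import yaml
from PIL import Image

from ddanet import io as dio
from ddanet.cli import main as cli_main
from ddanet.config import RunConfig, load_config, save_config
from ddanet.errors import ConfigurationError, DimensionError, ImageFormatError
from ddanet.phantom import PhantomConfig, SlicePair, generate_dataset, generate_slice


class TestRunConfig:
    def test_minimal_config_applies_protocol_defaults(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text("data_dir: d\noutput_dir: o\n")
        cfg = load_config(path)
        assert cfg.train.learning_rate == pytest.approx(1e-4)
        assert cfg.train.batch_size == 4
        assert cfg.train.max_epochs == 150
        assert cfg.train.optimizer == "adam"
        assert cfg.loss.alpha == 1.0 and cfg.loss.beta == 1.0
        assert cfg.model.encoder_depth == 34

    def test_invalid_value_error_names_field(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text("loss:\n  alpha: -1\n")
        with pytest.raises(ConfigurationError, match="alpha"):
            load_config(path)

    def test_unknown_key_is_named(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text("train:\n  learning_rte: 0.1\n")
        with pytest.raises(ConfigurationError, match="learning_rte"):
            load_config(path)
        path.write_text("grandient: 1\n")
        with pytest.raises(ConfigurationError, match="grandient"):
            load_config(path)

    def test_round_trip_yields_equal_config(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text(
            "threshold: 0.4\n"
            "model:\n  stage_channels: [8, 8, 16, 32, 64]\n"
            "  decoder_channels: [32, 32, 16, 16, 8]\n  channel_reduction: 4\n"
            "train:\n  max_epochs: 3\n  seed: 11\n"
            "phantom:\n  size: 64\n")
        cfg = load_config(path)
        out = tmp_path / "echo.yaml"
        save_config(cfg, out)
        assert load_config(out) == cfg

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_config(tmp_path / "absent.yaml")

    def test_unparseable_yaml_raises(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("{: [")
        with pytest.raises(ConfigurationError, match="parse"):
            load_config(path)


class TestSliceIO:
    def test_png_round_trip_mask_exact_image_quantised(self, tmp_path):
        pair = generate_slice(PhantomConfig(size=64, seed=2),
                              np.random.default_rng(0), "rt-test")
        dio.write_slice_pair(pair, tmp_path)
        loaded = dio.read_slice_pair(tmp_path / "rt-test.png",
                                     tmp_path / "rt-test_mask.png")
        np.testing.assert_array_equal(loaded.mask, pair.mask)
        assert np.abs(loaded.image - pair.image).max() <= 1.0 / 255.0

    def test_round_trip_is_idempotent_after_first_quantisation(self, tmp_path):
        pair = generate_slice(PhantomConfig(size=64, seed=4),
                              np.random.default_rng(1), "idem")
        dio.write_slice_pair(pair, tmp_path)
        first = dio.read_slice_pair(tmp_path / "idem.png", tmp_path / "idem_mask.png")
        dio.write_slice_pair(first, tmp_path)
        second = dio.read_slice_pair(tmp_path / "idem.png", tmp_path / "idem_mask.png")
        assert np.abs(second.image - first.image).max() <= 1e-6
        np.testing.assert_array_equal(second.mask, first.mask)

    def test_intermediate_mask_values_binarise_above_127(self, tmp_path):
        Image.fromarray(np.full((8, 8), 100, dtype=np.uint8), "L").save(tmp_path / "img.png")
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[0, 0], mask[0, 1], mask[0, 2] = 127, 128, 255
        Image.fromarray(mask, "L").save(tmp_path / "img_mask.png")
        pair = dio.read_slice_pair(tmp_path / "img.png", tmp_path / "img_mask.png")
        assert pair.mask[0, 0] == 0 and pair.mask[0, 1] == 1 and pair.mask[0, 2] == 1

    def test_dimension_mismatch_and_rgb_rejected(self, tmp_path):
        Image.fromarray(np.zeros((8, 8), dtype=np.uint8), "L").save(tmp_path / "a.png")
        Image.fromarray(np.zeros((9, 8), dtype=np.uint8), "L").save(tmp_path / "b.png")
        with pytest.raises(DimensionError, match="dimensions differ"):
            dio.read_slice_pair(tmp_path / "a.png", tmp_path / "b.png")
        rgb = np.zeros((8, 8, 3), dtype=np.uint8)
        Image.fromarray(rgb, "RGB").save(tmp_path / "rgb.png")
        with pytest.raises(ImageFormatError, match="grayscale"):
            dio.read_slice_pair(tmp_path / "rgb.png", tmp_path / "a.png")

    def test_nifti_single_slice_is_minmax_scaled(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        data = np.random.default_rng(3).integers(-100, 400, (32, 32)).astype(np.float32)
        img = nib.Nifti1Image(data[..., None], affine=np.eye(4))
        nib.save(img, tmp_path / "slice.nii")
        loaded = dio.read_image(tmp_path / "slice.nii")
        assert loaded.shape == (32, 32)
        assert loaded.min() == 0.0 and loaded.max() == 1.0

    def test_probability_map_written_as_16bit(self, tmp_path):
        prob = np.random.default_rng(4).random((16, 16))
        path = dio.write_probability_map(prob, tmp_path / "p.png")
        back = np.asarray(Image.open(path), dtype=np.float64) / 65535.0
        assert np.abs(back - prob).max() <= 1.0 / 65535.0

    def test_dataset_write_read_with_manifest(self, tmp_path):
        pairs = generate_dataset(PhantomConfig(size=64, seed=6), 3)
        manifest = dio.write_dataset(pairs, tmp_path, seed=6)
        assert manifest.exists()
        loaded = dio.read_dataset(tmp_path)
        assert [p.slice_id for p in loaded] == sorted(p.slice_id for p in pairs)
        for orig in pairs:
            match = next(p for p in loaded if p.slice_id == orig.slice_id)
            np.testing.assert_array_equal(match.mask, orig.mask)


class TestCLI:
    def test_generate_split_train_predict_summarize_pipeline(self, tmp_path, capsys):
        data = tmp_path / "data"
        run = tmp_path / "run"
        assert cli_main(["generate", "--out", str(data), "--n", "6",
                         "--size", "64", "--seed", "7"]) == 0
        assert (data / "manifest.csv").exists()
        assert cli_main(["split", "--data", str(data), "--folds", "3",
                         "--seed", "1", "--out", str(tmp_path / "folds.json")]) == 0
        assert (tmp_path / "folds.json").exists()

        cfg = {"train": {"max_epochs": 1, "batch_size": 2, "augment_train": False},
               "model": {"stage_channels": [8, 8, 16, 32, 64],
                         "decoder_channels": [32, 32, 16, 16, 8],
                         "channel_reduction": 4}}
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        assert cli_main(["train", "--data", str(data), "--out", str(run),
                         "--config", str(cfg_path), "--seed", "2"]) == 0
        assert (run / "best.npz").exists() and (run / "train_log.csv").exists()

        out = tmp_path / "pred"
        image = next(p for p in sorted(data.glob("*.png"))
                     if not p.stem.endswith("_mask"))
        assert cli_main(["predict", "--checkpoint", str(run / "best.npz"),
                         "--out", str(out), str(image)]) == 0
        assert list(out.glob("*_prob.png"))

        assert cli_main(["evaluate", "--checkpoint", str(run / "best.npz"),
                         "--data", str(data),
                         "--out", str(tmp_path / "metrics.csv")]) == 0
        assert (tmp_path / "metrics.csv").exists()

        assert cli_main(["summarize", "--small"]) == 0
        printed = capsys.readouterr().out
        assert "total parameters" in printed

    def test_predict_rejects_indivisible_image(self, tmp_path, capsys):
        from ddanet.network import DDANet, ModelConfig, save_checkpoint
        ckpt = save_checkpoint(DDANet(ModelConfig.small(), seed=0), tmp_path / "m")
        Image.fromarray(np.zeros((50, 50), dtype=np.uint8), "L").save(tmp_path / "bad.png")
        rc = cli_main(["predict", "--checkpoint", str(ckpt),
                       "--out", str(tmp_path / "o"), str(tmp_path / "bad.png")])
        assert rc == 1
        assert "32" in capsys.readouterr().err

    def test_unknown_subcommand_exits_2(self):
        with pytest.raises(SystemExit) as exc:
            cli_main(["frobnicate"])
        assert exc.value.code == 2

    def test_summarize_count_matches_library(self, capsys):
        from ddanet.network import DDANet, ModelConfig, count_parameters
        assert cli_main(["summarize", "--small"]) == 0
        printed = capsys.readouterr().out
        expected = count_parameters(DDANet(ModelConfig.small(), seed=0))
        assert f"{expected:,d}" in printed
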