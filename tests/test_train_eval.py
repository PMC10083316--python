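"""Training pipeline: loss descent, determinism, checkpoint round-trips,
manifest evaluation, prediction output, the ablation runner and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from bafnet import (
    LeafGenConfig,
    ModelConfig,
    TrainConfig,
    evaluate,
    generate_dataset,
    load_checkpoint,
    predict,
    run_ablation,
    save_checkpoint,
    train,
)
from bafnet.blocks import SwinStageConfig
from bafnet.cli import leafgen, main
from bafnet.network import BAFNet
from bafnet.nn import Tensor, no_grad


@pytest.fixture(scope="module")
def leaf_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("leaves")
    cfg = LeafGenConfig(image_size=32, seed=0)
    generate_dataset(8, cfg, out, fractions=(0.5, 0.25, 0.25))
    return out


def tiny_model_cfg():
    return ModelConfig(base_channels=4, image_size=32,
                       swin=SwinStageConfig(window_size=8))


def tiny_train_cfg(**kw):
    kw.setdefault("batch_size", 2)
    kw.setdefault("epochs", 2)
    kw.setdefault("iters_per_epoch", 3)
    kw.setdefault("seed", 0)
    return TrainConfig(**kw)


def test_train_descends_and_logs(leaf_dir, tmp_path):
    ckpt, history = train(tiny_model_cfg(), tiny_train_cfg(),
                          leaf_dir / "manifest.csv", tmp_path)
    assert ckpt.exists() and (tmp_path / "history.jsonl").exists()
    assert len(history) == 2
    assert {"epoch", "train_loss", "val_loss", "val_miou"} <= set(history[0])
    assert history[-1]["train_loss"] < history[0]["train_loss"] * 1.5


def test_same_seed_identical_histories(leaf_dir, tmp_path):
    h1 = train(tiny_model_cfg(), tiny_train_cfg(), leaf_dir / "manifest.csv",
               tmp_path / "a")[1]
    h2 = train(tiny_model_cfg(), tiny_train_cfg(), leaf_dir / "manifest.csv",
               tmp_path / "b")[1]
    assert h1 == h2


def test_checkpoint_round_trip(tmp_path):
    model = BAFNet(tiny_model_cfg(), seed=5)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    back = load_checkpoint(path)
    assert back.cfg == model.cfg
    x = Tensor(np.random.default_rng(0).random((1, 3, 32, 32),
                                               dtype=np.float32))
    model.eval()
    back.eval()
    with no_grad():
        np.testing.assert_array_equal(model(x).numpy(), back(x).numpy())


def test_checkpoint_version_guard(tmp_path):
    import json

    meta = {"version": "other", "config": {}}
    np.savez(tmp_path / "bad.npz",
             __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))
    with pytest.raises(ValueError):
        load_checkpoint(tmp_path / "bad.npz")


def test_evaluate_table_format(leaf_dir, tmp_path):
    ckpt, _ = train(tiny_model_cfg(), tiny_train_cfg(),
                    leaf_dir / "manifest.csv", tmp_path)
    table = evaluate(ckpt, leaf_dir / "manifest.csv", split="test")
    assert list(table.columns) == ["PA", "PR", "PP", "PS", "IoU", "F1"]
    assert "mean" in table.index
    assert ((table >= 0) & (table <= 100)).all().all()
    with pytest.raises(ValueError):
        evaluate(ckpt, leaf_dir / "manifest.csv", split="nope")


def test_truth_as_prediction_scores_100(leaf_dir):
    """Feeding ground truth as the prediction gives 100.00 everywhere."""
    from bafnet.data_io import load_mask, read_manifest
    from bafnet.metrics import aggregate, evaluate_pair

    manifest = read_manifest(leaf_dir / "manifest.csv")
    reports = [
        evaluate_pair(load_mask(row["mask_path"])[0],
                      load_mask(row["mask_path"])[0])
        for _, row in manifest.iterrows()
    ]
    assert all(v == 100.0 for v in aggregate(reports).as_percent().values())


def test_predict_writes_mask(leaf_dir, tmp_path):
    model = BAFNet(tiny_model_cfg(), seed=0)
    ckpt = tmp_path / "m.npz"
    save_checkpoint(model, ckpt)
    manifest = pd.read_csv(leaf_dir / "manifest.csv")
    image_path = manifest.loc[0, "image_path"]
    out = tmp_path / "pred.png"
    mask = predict(ckpt, image_path, out)
    assert out.exists()
    assert mask.shape == (32, 32) and set(np.unique(mask)) <= {0, 1}
    with pytest.raises(OSError):
        predict(ckpt, tmp_path / "missing.png", tmp_path / "x.png")


def test_run_ablation_structure(leaf_dir, tmp_path):
    cfg = tiny_train_cfg(epochs=1, iters_per_epoch=2)
    table = run_ablation(leaf_dir / "manifest.csv", cfg, base_channels=4,
                         image_size=32, out_dir=tmp_path)
    assert len(table) == 4
    assert list(table["model"]) == ["SU-Net", "SU-Net-MSFF",
                                    "SU-Net-MSFF-FSFF", "BAF-Net"]
    flags = table[["MSFF", "FSFF", "BAF"]].to_numpy()
    assert (flags == [[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]]).all()
    params = table["n_params"].to_numpy()
    assert (np.diff(params) > 0).all()


def test_cli_leafgen_and_train_eval_predict(tmp_path):
    runner = CliRunner()
    data = tmp_path / "data"
    res = runner.invoke(leafgen, ["--n", "6", "--size", "32", "--seed", "1",
                                  "--out", str(data)])
    assert res.exit_code == 0, res.output
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(
        "model:\n  base_channels: 4\n  image_size: 32\n"
        "train:\n  epochs: 1\n  iters_per_epoch: 2\n  batch_size: 2\n"
    )
    run = tmp_path / "run"
    res = runner.invoke(main, ["train", "--config", str(cfg), "--data",
                               str(data / "manifest.csv"), "--out", str(run),
                               "--seed", "0"])
    assert res.exit_code == 0, res.output
    res = runner.invoke(main, ["eval", "--checkpoint",
                               str(run / "checkpoint.npz"), "--data",
                               str(data / "manifest.csv"), "--split", "train"])
    assert res.exit_code == 0, res.output
    assert "IoU" in res.output
    img = pd.read_csv(data / "manifest.csv").loc[0, "image_path"]
    res = runner.invoke(main, ["predict", "--checkpoint",
                               str(run / "checkpoint.npz"), "--image", img,
                               "--out", str(tmp_path / "pred.png")])
    assert res.exit_code == 0, res.output
    assert (tmp_path / "pred.png").exists()


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainConfig(lr=0.0)
    with pytest.raises(ValueError):
        TrainConfig(device="gpu")
    cfg = TrainConfig()
    assert (cfg.batch_size, cfg.epochs, cfg.iters_per_epoch, cfg.lr) == (
        4, 60, 350, 0.01
    )
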