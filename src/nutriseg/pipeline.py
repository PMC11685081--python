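"""End-to-end orchestration: split -> segment -> mask -> regress -> evaluate,
plus the 2x2 input-type x SE ablation grid.

Every random process (scene generation, splitting, weight init, batch
shuffling, augmentation) derives from the single run seed.  After each
regression epoch the model is evaluated on the test set; the reported result
is the best (lowest mean PMAE) snapshot, ties resolved toward the earliest
epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .dataset_io import (
    DishRecord, apply_mask, read_image, read_mask, read_metadata, split_dataset,
)
from .metrics import EvalReport, evaluate
from .regression import (
    RegNetConfig, RegTrainConfig, build_regressor, predict_nutrients, train_regressor,
)
from .segmentation import (
    SegNetConfig, SegTrainConfig, build_unet, evaluate_segmentation, predict_mask,
    train_segmenter,
)
from .synthetic import SceneConfig, generate_dishes

__all__ = ["RunConfig", "RunResult", "load_config", "load_dishes",
           "run_end_to_end", "run_ablation"]

INPUT_MODES = ("original", "segmented-gt", "segmented-predicted")


@dataclass(frozen=True)
class RunConfig:
    """One end-to-end experiment.

    data_dir None means dishes are generated in memory from `scene` with
    n_dishes scenes.  input_mode selects what the regressor sees: raw images,
    images masked by ground truth, or images masked by the trained UNet.
    """

    data_dir: str | None = None
    n_dishes: int = 400
    scene: SceneConfig = field(default_factory=SceneConfig)
    train_fraction: float = 0.8
    split_multiple: int | None = 8
    seed: int = 42
    input_mode: str = "segmented-predicted"
    se_enabled: bool = True
    seg_net: SegNetConfig = field(default_factory=SegNetConfig)
    seg_train: SegTrainConfig = field(default_factory=lambda: SegTrainConfig(epochs=50))
    reg_net: RegNetConfig = field(default_factory=RegNetConfig)
    reg_train: RegTrainConfig = field(default_factory=lambda: RegTrainConfig(epochs=300, batch_size=8))
    out_dir: str | None = None

    def __post_init__(self):
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}, got {self.input_mode!r}")
        if self.reg_train.batch_size < 1 or self.seg_train.batch_size < 1:
            raise ValueError("batch sizes must be >= 1")


@dataclass
class RunResult:
    config: RunConfig
    segmentation: dict[str, float] | None
    report: EvalReport          # metrics at the top-1 epoch
    best_epoch: int
    log: list[dict]             # per-epoch loss / lr / mean-PMAE trace
    seg_loss_trace: list[float] | None


# ------------------------------------------------------------------- config IO

_DEFAULTS = {
    "data_dir": None, "n_dishes": 400, "train_fraction": 0.8, "split_multiple": 8,
    "seed": 42, "input_mode": "segmented-predicted", "se_enabled": True,
    "seg_epochs": 50, "reg_epochs": 300, "batch_size": 8, "lr0_seg": 1e-3,
    "lr0_reg": 1e-4, "lr_decay": 0.99, "backbone": "small", "image_size": 128,
    "label_noise_cv": 0.0, "out_dir": None,
}


def load_config(path: str | Path | None) -> RunConfig:
    """Build a RunConfig from a YAML file; missing keys take defaults,
    unknown keys are rejected."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; known: {sorted(_DEFAULTS)}")
    cfg = {**_DEFAULTS, **raw}
    if cfg["batch_size"] < 1:
        raise ValueError("batch_size must be >= 1")
    if cfg["seg_epochs"] < 1 or cfg["reg_epochs"] < 1:
        raise ValueError("epoch counts must be >= 1")
    size = int(cfg["image_size"])
    seed = int(cfg["seed"])
    return RunConfig(
        data_dir=cfg["data_dir"],
        n_dishes=int(cfg["n_dishes"]),
        scene=SceneConfig(image_size=(size, size), seed=seed,
                          label_noise_cv=float(cfg["label_noise_cv"])),
        train_fraction=float(cfg["train_fraction"]),
        split_multiple=cfg["split_multiple"],
        seed=seed,
        input_mode=cfg["input_mode"],
        se_enabled=bool(cfg["se_enabled"]),
        seg_train=SegTrainConfig(epochs=int(cfg["seg_epochs"]), lr0=float(cfg["lr0_seg"]),
                                 lr_decay=float(cfg["lr_decay"]),
                                 batch_size=int(cfg["batch_size"]), seed=seed),
        reg_net=RegNetConfig(backbone=cfg["backbone"]),
        reg_train=RegTrainConfig(epochs=int(cfg["reg_epochs"]), lr0=float(cfg["lr0_reg"]),
                                 lr_decay=float(cfg["lr_decay"]),
                                 batch_size=int(cfg["batch_size"]), seed=seed),
        out_dir=cfg["out_dir"],
    )


def save_config_yaml(config: RunConfig, path: str | Path) -> None:
    cfg = {
        "data_dir": config.data_dir, "n_dishes": config.n_dishes,
        "train_fraction": config.train_fraction, "split_multiple": config.split_multiple,
        "seed": config.seed, "input_mode": config.input_mode, "se_enabled": config.se_enabled,
        "seg_epochs": config.seg_train.epochs, "reg_epochs": config.reg_train.epochs,
        "batch_size": config.reg_train.batch_size, "lr0_seg": config.seg_train.lr0,
        "lr0_reg": config.reg_train.lr0, "lr_decay": config.reg_train.lr_decay,
        "backbone": config.reg_net.backbone, "image_size": config.scene.image_size[0],
        "label_noise_cv": config.scene.label_noise_cv, "out_dir": config.out_dir,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


# --------------------------------------------------------------------- loading

def load_dishes(data_dir: str | Path) -> list[DishRecord]:
    """Load a generated-dataset directory (images/, masks/, metadata.csv)."""
    root = Path(data_dir)
    records = []
    for dish_id, label in read_metadata(root / "metadata.csv"):
        image = read_image(root / "images" / f"{dish_id}.png")
        mask_path = root / "masks" / f"{dish_id}.png"
        mask = read_mask(mask_path) if mask_path.exists() else None
        records.append(DishRecord(dish_id=dish_id, image=image, label=label, mask=mask))
    return records


def _obtain_dishes(config: RunConfig) -> list[DishRecord]:
    if config.data_dir is not None:
        return load_dishes(config.data_dir)
    scene = replace(config.scene, seed=config.seed)
    return [d.record for d in generate_dishes(scene, config.n_dishes)]


# ------------------------------------------------------------------ end to end

def run_end_to_end(config: RunConfig, verbose: bool = False) -> RunResult:
    dishes = _obtain_dishes(config)
    by_id = {d.dish_id: d for d in dishes}
    split = split_dataset(sorted(by_id), config.train_fraction, seed=config.seed,
                          round_to_multiple=config.split_multiple)
    train = [by_id[i] for i in split.train_ids]
    test = [by_id[i] for i in split.test_ids]

    seg_scores = None
    seg_trace = None
    if config.input_mode == "segmented-predicted":
        unet = build_unet(config.seg_net, seed=config.seed)
        seg_trace = train_segmenter(unet, train, config.seg_train)
        seg_scores = evaluate_segmentation(unet, test)
        def food_view(rec: DishRecord) -> np.ndarray:
            return apply_mask(rec.image, predict_mask(unet, rec.image))
    elif config.input_mode == "segmented-gt":
        def food_view(rec: DishRecord) -> np.ndarray:
            if rec.mask is None:
                raise ValueError(f"dish {rec.dish_id!r} lacks a ground-truth mask")
            return apply_mask(rec.image, rec.mask)
    else:  # original
        def food_view(rec: DishRecord) -> np.ndarray:
            return rec.image

    train_imgs = [food_view(r) for r in train]
    test_imgs = [food_view(r) for r in test]
    train_y = np.stack([r.label.as_array() for r in train])
    test_y = np.stack([r.label.as_array() for r in test])

    reg_cfg = replace(config.reg_net, se_enabled=config.se_enabled)
    model = build_regressor(reg_cfg, seed=config.seed)

    snapshots: list[tuple[float, int, np.ndarray]] = []

    def eval_hook(m) -> float:
        pred = predict_nutrients(m, test_imgs)
        rep = evaluate(pred, test_y)
        snapshots.append((rep.mean_pmae, len(snapshots), pred))
        return rep.mean_pmae

    reg_train = replace(config.reg_train, seed=config.seed)
    log = train_regressor(model, train_imgs, train_y, reg_train, eval_fn=eval_hook)
    if verbose:
        for entry in log:
            print(f"epoch {entry['epoch']:>3}  loss {entry['loss']:.4f}  "
                  f"lr {entry['lr']:.2e}  test mean PMAE {entry['eval']:.2f}%")

    # top-1: lowest mean PMAE, earliest epoch on ties
    best_pmae, best_epoch, best_pred = min(snapshots, key=lambda t: (t[0], t[1]))
    report = evaluate(best_pred, test_y, segmentation=seg_scores)

    result = RunResult(config=config, segmentation=seg_scores, report=report,
                       best_epoch=best_epoch, log=log, seg_loss_trace=seg_trace)
    if config.out_dir:
        _write_run(result, Path(config.out_dir))
    return result


def _write_run(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "report.csv")
    result.report.export_scatter(out / "scatter")
    machine = {
        "best_epoch": result.best_epoch,
        "mean_pmae": result.report.mean_pmae,
        "segmentation": result.segmentation,
        "log": result.log,
        "seg_loss_trace": result.seg_loss_trace,
        "seed": result.config.seed,
        "input_mode": result.config.input_mode,
        "se_enabled": result.config.se_enabled,
    }
    (out / "run.json").write_text(json.dumps(machine, indent=2))
    (out / "report.txt").write_text(result.report.to_text() + "\n")


# -------------------------------------------------------------------- ablation

def run_ablation(config: RunConfig, segmented_mode: str = "segmented-gt",
                 verbose: bool = False) -> list[dict]:
    """The 2x2 grid {original, segmented} x {SE, no-SE} with a shared split.

    Returns four rows with per-nutrient PMAE and mean PMAE, ordered as
    (original, SE), (original, no-SE), (segmented, SE), (segmented, no-SE).
    """
    rows = []
    for input_mode in ("original", segmented_mode):
        for se_enabled in (True, False):
            cfg = replace(config, input_mode=input_mode, se_enabled=se_enabled,
                          out_dir=None)
            res = run_end_to_end(cfg, verbose=verbose)
            row = {
                "input": "original" if input_mode == "original" else "segmented",
                "se": se_enabled,
                "mean_pmae": res.report.mean_pmae,
            }
            for nutrient, metrics_ in res.report.per_nutrient.items():
                row[f"pmae_{nutrient}"] = metrics_["pmae"]
            rows.append(row)
    return rows
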