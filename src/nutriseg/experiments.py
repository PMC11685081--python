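"""Desk-scale study recipes: self-contained experiments that train the
pipeline on built-in synthetic scenes and report its headline quantities.

These are deliberately small (64x64 scenes, a 2-stage UNet, the small CNN
backbone) so each runs in minutes on one CPU core.  They are qualitative
analogues of the full-scale study — segmentation recovery, nutrient
recovery, the segmented-vs-original input ablation — not reproductions of
its absolute numbers, which require the external dish dataset and far larger
models.
"""

from __future__ import annotations

import numpy as np

from .dataset_io import apply_mask
from .metrics import evaluate
from .pipeline import RunConfig, run_end_to_end
from .regression import (
    RegNetConfig, RegTrainConfig, build_regressor, color_area_features,
    predict_nutrients, train_regressor,
)
from .segmentation import (
    SegNetConfig, SegTrainConfig, build_unet, evaluate_segmentation, train_segmenter,
)
from .synthetic import DEFAULT_PALETTE, SceneConfig, generate_dishes

__all__ = [
    "segmentation_recovery", "nutrient_recovery", "linear_readout_floor",
    "ablation_direction", "pipeline_determinism",
]

_IMAGE_SIZE = (64, 64)


def segmentation_recovery(seed: int = 42, n_train: int = 300, n_test: int = 40,
                          epochs: int = 14) -> dict[str, float]:
    """Train a tiny UNet (2 stages, base 8) on noiseless scenes; held-out
    overlap metrics (fractions in [0, 1])."""
    scenes = generate_dishes(SceneConfig(image_size=_IMAGE_SIZE, seed=seed),
                             n_train + n_test)
    records = [d.record for d in scenes]
    train, test = records[:n_train], records[n_train:]
    net = build_unet(SegNetConfig(n_stages=2, base_channels=8), seed=seed)
    trace = train_segmenter(net, train,
                            SegTrainConfig(epochs=epochs, lr0=2e-3, seed=seed, batch_size=8))
    scores = evaluate_segmentation(net, test)
    scores["final_loss"] = trace[-1]
    scores["n_train"] = n_train
    scores["n_test"] = n_test
    return scores


def nutrient_recovery(seed: int = 42, n: int = 500, epochs: int = 40) -> dict[str, float]:
    """Train the small CNN + SE regressor on ground-truth-masked noiseless
    dishes; held-out per-nutrient and mean PMAE (percent)."""
    records = [d.record for d in generate_dishes(SceneConfig(image_size=_IMAGE_SIZE, seed=seed), n)]
    n_train = int(n * 0.8)
    train, test = records[:n_train], records[n_train:]
    train_imgs = [apply_mask(r.image, r.mask) for r in train]
    test_imgs = [apply_mask(r.image, r.mask) for r in test]
    train_y = np.stack([r.label.as_array() for r in train])
    test_y = np.stack([r.label.as_array() for r in test])
    model = build_regressor(RegNetConfig(backbone="small", se_enabled=True), seed=seed)
    train_regressor(model, train_imgs, train_y,
                    RegTrainConfig(epochs=epochs, lr0=1e-3, batch_size=8, seed=seed))
    report = evaluate(predict_nutrients(model, test_imgs), test_y)
    out = {f"pmae_{k}": v["pmae"] for k, v in report.per_nutrient.items()}
    out["mean_pmae"] = report.mean_pmae
    out["n_train"] = n_train
    out["n_test"] = n - n_train
    return out


def linear_readout_floor(seed: int = 42, n: int = 200) -> dict[str, float]:
    """Least squares from per-ingredient color areas to labels: the error
    floor a learned regressor is bounded by on noiseless scenes."""
    records = [d.record for d in generate_dishes(SceneConfig(image_size=_IMAGE_SIZE, seed=seed), n)]
    X = np.stack([color_area_features(apply_mask(r.image, r.mask), DEFAULT_PALETTE)
                  for r in records])
    Y = np.stack([r.label.as_array() for r in records])
    n_train = int(n * 0.8)
    Xtr = np.hstack([X[:n_train], np.ones((n_train, 1))])
    Xte = np.hstack([X[n_train:], np.ones((n - n_train, 1))])
    W, *_ = np.linalg.lstsq(Xtr, Y[:n_train], rcond=None)
    report = evaluate(np.maximum(Xte @ W, 0), Y[n_train:])
    return {"mean_pmae": report.mean_pmae, "n": n}


def _ablation_run_config(seed: int, input_mode: str, n_dishes: int, epochs: int) -> RunConfig:
    return RunConfig(
        n_dishes=n_dishes,
        scene=SceneConfig(image_size=_IMAGE_SIZE, n_distractors=(2, 5), seed=seed),
        seed=seed,
        input_mode=input_mode,
        se_enabled=True,
        reg_net=RegNetConfig(backbone="small"),
        reg_train=RegTrainConfig(epochs=epochs, lr0=1e-3, batch_size=8, seed=seed),
    )


def ablation_direction(seeds=(1, 2, 3), n_dishes: int = 200,
                       epochs: int = 15) -> dict[str, float]:
    """Segmented-input vs whole-image training on distractor-laden scenes.

    Returns per-mode median mean PMAE over the seeds and their difference
    (positive = masking helps, the direction the full-scale ablation shows).
    """
    results = {"original": [], "segmented": []}
    for seed in seeds:
        for mode, key in (("original", "original"), ("segmented-gt", "segmented")):
            res = run_end_to_end(_ablation_run_config(seed, mode, n_dishes, epochs))
            results[key].append(res.report.mean_pmae)
    med_orig = float(np.median(results["original"]))
    med_seg = float(np.median(results["segmented"]))
    return {
        "median_original_mean_pmae": med_orig,
        "median_segmented_mean_pmae": med_seg,
        "improvement": med_orig - med_seg,
        "n_seeds": len(seeds),
        "n_dishes": n_dishes,
    }


def pipeline_determinism(seed: int = 42, n_dishes: int = 80) -> dict[str, object]:
    """Run the full segment-then-regress pipeline twice with one seed and
    compare the metric traces element for element."""
    def make_config():
        return RunConfig(
            n_dishes=n_dishes,
            scene=SceneConfig(image_size=_IMAGE_SIZE, seed=seed),
            seed=seed,
            input_mode="segmented-predicted",
            seg_net=SegNetConfig(n_stages=2, base_channels=8),
            seg_train=SegTrainConfig(epochs=4, lr0=2e-3, batch_size=8, seed=seed),
            reg_net=RegNetConfig(backbone="tiny", head_dims=(32,)),
            reg_train=RegTrainConfig(epochs=6, lr0=1e-3, batch_size=8, seed=seed),
        )

    a = run_end_to_end(make_config())
    b = run_end_to_end(make_config())
    trace_a = [e["loss"] for e in a.log] + [e["eval"] for e in a.log] + a.seg_loss_trace
    trace_b = [e["loss"] for e in b.log] + [e["eval"] for e in b.log] + b.seg_loss_trace
    return {
        "identical": trace_a == trace_b,
        "mean_pmae": a.report.mean_pmae,
        "n_dishes": n_dishes,
    }
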