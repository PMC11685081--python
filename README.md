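# nutriseg

Estimating the nutrient content of a plated meal from a single top-view
photograph — for dietary-assessment research and nutrition-tracking tools —
with a *segment-first, regress-second* pipeline:

1. **Food segmentation.** A UNet (symmetric encoder–decoder with skip
   connections) separates food pixels from plate, table and clutter.
2. **Foreground masking.** Every pixel outside the predicted food region is
   set to zero, so the downstream regressor never sees the background.
3. **Nutrient regression.** A convolutional backbone extracts features from
   the masked image, a Squeeze-and-Excitation (SE) block recalibrates the
   feature channels, and three fully connected layers predict the
   five-component nutrient label *y = (mass g, calories kcal, fat g, carb g,
   protein g)*.

Because mass and calories are roughly an order of magnitude larger than the
macronutrients in grams, training uses a **sum-normalized multi-task loss**:
for each nutrient *m*,

    l_m = Σᵢ |ŷᵢ^m − yᵢ^m| / Σᵢ yᵢ^m,      L = Σ_m l_m

Each subtask loss is scale-free, so no nutrient dominates the gradient.
Evaluation uses the matching scale-free metric **PMAE** (percentage mean
absolute error), `PMAE = 100 · MAE / mean(y)`; algebraically `l_m ≡
PMAE/100` on the same data. Segmentation quality is scored with Dice,
Jaccard, precision and recall; the regression report adds MAE/MSE/RMSE/R²
per nutrient and the unweighted mean PMAE over the five nutrients, with the
best (lowest mean PMAE) per-epoch test snapshot reported as the run's result.

The package ships a **synthetic plated-food scene generator** (plate,
irregular multi-ingredient food blobs with per-ingredient nutrient
densities, food-colored off-plate distractors, exact ground-truth masks and
labels) so the entire pipeline trains, evaluates and ablates with no
external data. All networks run on a compact NumPy autodiff engine
(`nutriseg.nn`) — no GPU or deep-learning framework required.

## Worked example

Train the full pipeline on 200 synthetic 64×64 dishes (160 train / 40 test,
split in multiples of 8), with a 2-stage UNet and the small CNN backbone:

```python
from nutriseg.pipeline import RunConfig, run_end_to_end
from nutriseg.synthetic import SceneConfig
from nutriseg.segmentation import SegNetConfig, SegTrainConfig
from nutriseg.regression import RegNetConfig, RegTrainConfig

config = RunConfig(
    n_dishes=200,
    scene=SceneConfig(image_size=(64, 64), seed=42),
    seed=42,
    input_mode="segmented-predicted",
    seg_net=SegNetConfig(n_stages=2, base_channels=8),
    seg_train=SegTrainConfig(epochs=10, lr0=2e-3),
    reg_net=RegNetConfig(backbone="small"),
    reg_train=RegTrainConfig(epochs=20, lr0=1e-3, batch_size=8),
)
result = run_end_to_end(config)
print(result.report.to_text())
print(f"top-1 epoch: {result.best_epoch}")
```

Output (about 3 minutes on one CPU core):

```
Nutrient       PMAE (%)         MAE         MSE        RMSE          R2
mass              23.56        3.93       33.01        5.75        0.35
calories          38.20        9.33      226.42       15.05        0.17
fat               50.76        0.45        0.51        0.72        0.47
carb              37.36        0.69        0.85        0.92        0.78
protein           53.84        1.13        4.01        2.00        0.09
Mean PMAE (%): 40.74
Segmentation: dice=92.27%  jaccard=85.98%  precision=89.88%  recall=95.47%
top-1 epoch: 19
```

Reading it: the UNet recovers 92% Dice overlap with the true food masks
after 10 epochs; the regressor, trained for only 20 epochs on 160 dishes,
predicts mass within 23.6% and calories within 38.2% of the truth on
held-out dishes (mean PMAE 40.7%). More data and epochs tighten this
substantially — the 500-dish, 40-epoch experiment in
`nutriseg.experiments.nutrient_recovery` reaches a mean PMAE near 12%.

The same pipeline is available from the shell:

```bash
nutriseg gen --n 200 --out scratch/ds --seed 42 --size 64
nutriseg run --out scratch/run --seed 42
nutriseg ablate            # {original, segmented} × {SE, no-SE} grid
```

## Layout

- `nutriseg/dataset_io.py` — metadata CSV, image/mask PNG I/O, masking, splits
- `nutriseg/synthetic.py` — plated-food scene generator with exact labels
- `nutriseg/segmentation.py` — UNet, training, Dice/Jaccard/precision/recall
- `nutriseg/regression.py` — SE block, backbone + FC heads, augmentation
- `nutriseg/metrics.py` — normalized multi-task loss, PMAE, evaluation reports
- `nutriseg/pipeline.py` — end-to-end runs and the 2×2 ablation grid
- `nutriseg/experiments.py` — desk-scale study recipes
- `nutriseg/nn/` — NumPy autodiff tensors, layers, Adam + lr decay
- `docs/methods.md` — models, assumptions, parameter choices, limitations
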