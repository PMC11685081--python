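"""Synthetic plated-food scene generator with ground-truth masks and labels.

Each scene is a plate (ellipse) on a textured, cluttered background with a
few irregular ingredient blobs on the plate and optional food-colored
distractor objects off the plate.  The ground-truth mask is the union of
ingredient pixels only.  Nutrient labels are deterministic linear functions
of per-ingredient pixel areas — mass per pixel times area, scaled by each
ingredient's caloric density and macro fractions — optionally perturbed by
truncated multiplicative Gaussian noise.

Default densities are chosen so that mass and calories come out roughly an
order of magnitude larger than fat, carbohydrate and protein, reproducing
the magnitude asymmetry that motivates the sum-normalized multi-task loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import polygon as _polygon

from .dataset_io import (
    DishRecord, NutrientLabel, write_image, write_mask, write_metadata,
)

__all__ = [
    "IngredientSpec", "SceneConfig", "SyntheticDish", "DEFAULT_PALETTE",
    "sample_scene", "nutrient_oracle", "generate_dataset", "area_fraction",
]


@dataclass(frozen=True)
class IngredientSpec:
    """Appearance and nutrient density of one synthetic ingredient.

    density packs (mass g/pixel, kcal/g, fat g/g, carb g/g, protein g/g).
    """

    name: str
    color: tuple[int, int, int]
    texture_jitter: float
    density: tuple[float, float, float, float, float]

    def __post_init__(self):
        if self.density[0] <= 0:
            raise ValueError(f"{self.name}: mass-per-pixel must be > 0")
        if any(d < 0 for d in self.density):
            raise ValueError(f"{self.name}: density components must be >= 0")


# A fixed palette: distinct hues, with per-gram densities loosely modeled on
# everyday foods so that labels span realistic magnitudes.
DEFAULT_PALETTE: tuple[IngredientSpec, ...] = (
    IngredientSpec("rice",      (235, 229, 214), 6.0, (0.030, 1.3, 0.003, 0.28, 0.027)),
    IngredientSpec("chicken",   (202, 160, 110), 8.0, (0.035, 1.9, 0.075, 0.000, 0.270)),
    IngredientSpec("broccoli",  (58, 130, 62),   9.0, (0.025, 0.35, 0.004, 0.070, 0.028)),
    IngredientSpec("carrot",    (230, 126, 34),  7.0, (0.026, 0.41, 0.002, 0.096, 0.009)),
    IngredientSpec("beef",      (128, 64, 48),   8.0, (0.038, 2.5, 0.150, 0.000, 0.260)),
    IngredientSpec("salmon",    (245, 130, 120), 7.0, (0.034, 2.1, 0.130, 0.000, 0.200)),
    IngredientSpec("egg",       (250, 220, 90),  6.0, (0.030, 1.55, 0.110, 0.011, 0.130)),
    IngredientSpec("potato",    (222, 200, 140), 6.0, (0.032, 0.87, 0.001, 0.200, 0.021)),
    IngredientSpec("tomato",    (214, 40, 40),   8.0, (0.028, 0.18, 0.002, 0.039, 0.009)),
    IngredientSpec("pasta",     (240, 210, 160), 6.0, (0.031, 1.6, 0.009, 0.310, 0.058)),
    IngredientSpec("beans",     (90, 60, 120),   8.0, (0.029, 1.3, 0.005, 0.240, 0.090)),
    IngredientSpec("spinach",   (36, 90, 40),    9.0, (0.022, 0.23, 0.004, 0.036, 0.029)),
)


@dataclass(frozen=True)
class SceneConfig:
    """Generation parameters; defaults mirror real top-view dish statistics
    (food typically covering 5-30% of the frame)."""

    image_size: tuple[int, int] = (128, 128)
    n_ingredients: tuple[int, int] = (1, 4)
    target_area_fraction: tuple[float, float] = (0.05, 0.30)
    n_distractors: tuple[int, int] = (0, 3)
    label_noise_cv: float = 0.0
    seed: int = 0
    palette: tuple[IngredientSpec, ...] = DEFAULT_PALETTE

    def __post_init__(self):
        lo, hi = self.target_area_fraction
        if not (0.0 < lo <= hi < 0.6):
            raise ValueError("target_area_fraction must lie within (0, 0.6)")
        if self.label_noise_cv < 0:
            raise ValueError("label_noise_cv must be >= 0")


@dataclass
class SyntheticDish:
    """A generated dish plus the provenance needed to recompute its label."""

    record: DishRecord
    ingredient_names: tuple[str, ...]
    pixel_areas: tuple[int, ...]
    noise_draws: np.ndarray  # multiplicative factors, one per nutrient


def nutrient_oracle(areas, specs: list[IngredientSpec] | tuple[IngredientSpec, ...]) -> NutrientLabel:
    """Exact nutrient label from per-ingredient pixel areas.

    mass = sum_k a_k * mpp_k;   calories = sum_k a_k * mpp_k * kcal_per_g_k;
    fat / carb / protein analogously through their per-gram fractions.
    """
    areas = np.asarray(areas, dtype=np.float64)
    if len(areas) != len(specs):
        raise ValueError(f"{len(areas)} areas but {len(specs)} ingredient specs")
    if (areas < 0).any():
        raise ValueError("pixel areas must be non-negative")
    mass = cal = fat = carb = protein = 0.0
    for a, spec in zip(areas, specs):
        mpp, kcal_g, fat_g, carb_g, prot_g = spec.density
        grams = a * mpp
        mass += grams
        cal += grams * kcal_g
        fat += grams * fat_g
        carb += grams * carb_g
        protein += grams * prot_g
    return NutrientLabel(mass=mass, calories=cal, fat=fat, carb=carb, protein=protein)


def area_fraction(mask: np.ndarray) -> float:
    """Foreground pixels over total pixels."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    return float(mask.sum()) / mask.size


# ------------------------------------------------------------------ geometry

def _star_blob(rng: np.random.Generator, cy: float, cx: float, radius: float,
               shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a random star-convex blob with a smoothed irregular boundary."""
    n_pts = 24
    theta = np.linspace(0.0, 2 * np.pi, n_pts, endpoint=False)
    # smooth radial perturbation from a few random harmonics
    r = np.ones(n_pts)
    for harmonic in (2, 3, 5):
        amp = rng.uniform(0.05, 0.22)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.sin(harmonic * theta + phase)
    r = np.clip(r, 0.35, 1.6) * radius
    rr, cc = _polygon(cy + r * np.sin(theta), cx + r * np.cos(theta), shape=shape)
    blob = np.zeros(shape, dtype=bool)
    blob[rr, cc] = True
    return blob


def _ellipse_mask(shape: tuple[int, int], cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def sample_scene(config: SceneConfig, rng: np.random.Generator,
                 max_retries: int = 20) -> SyntheticDish:
    """Draw one plated-food scene.

    The scene is resampled (up to ``max_retries``) until the realized food
    area fraction falls inside the configured range; blob placement makes
    small overshoot possible on any single draw.
    """
    H, W = config.image_size
    for _ in range(max_retries):
        dish = _sample_once(config, rng, H, W)
        frac = area_fraction(dish.record.mask)
        lo, hi = config.target_area_fraction
        if lo * 0.5 <= frac <= hi * 1.2:  # resampling tolerance
            return dish
    raise RuntimeError(
        f"could not realize a food area fraction in {config.target_area_fraction} "
        f"for image size {config.image_size} after {max_retries} attempts"
    )


def _sample_once(config: SceneConfig, rng: np.random.Generator, H: int, W: int) -> SyntheticDish:
    # background: dark tabletop texture
    base = rng.uniform(25, 70)
    image = np.clip(
        base + rng.normal(0, 9, size=(H, W, 1)) + rng.uniform(-12, 12, size=(1, 1, 3)),
        0, 255,
    ).astype(np.float64) * np.ones((1, 1, 3))
    image = image[:, :, :3]

    # plate: light ellipse roughly centered
    cy = H / 2 + rng.uniform(-0.05, 0.05) * H
    cx = W / 2 + rng.uniform(-0.05, 0.05) * W
    ry = rng.uniform(0.30, 0.40) * H
    rx = rng.uniform(0.30, 0.40) * W
    plate = _ellipse_mask((H, W), cy, cx, ry, rx)
    plate_tone = rng.uniform(195, 240)
    image[plate] = plate_tone + rng.normal(0, 4, size=(int(plate.sum()), 3))

    # ingredients: star blobs inside the plate, one palette entry each
    k = int(rng.integers(config.n_ingredients[0], config.n_ingredients[1] + 1))
    target = rng.uniform(*config.target_area_fraction) * H * W
    chosen = rng.choice(len(config.palette), size=k, replace=False)
    specs = [config.palette[i] for i in chosen]
    per_blob = target / k
    mask = np.zeros((H, W), dtype=np.uint8)
    areas: list[int] = []
    for spec in specs:
        radius = np.sqrt(per_blob / np.pi)
        bcy = cy + rng.uniform(-0.45, 0.45) * ry
        bcx = cx + rng.uniform(-0.45, 0.45) * rx
        blob = _star_blob(rng, bcy, bcx, radius, (H, W)) & plate & (mask == 0)
        areas.append(int(blob.sum()))
        color = np.array(spec.color, dtype=np.float64)
        jitter = rng.normal(0, spec.texture_jitter, size=(int(blob.sum()), 3))
        image[blob] = np.clip(color + jitter, 0, 255)
        mask[blob] = 1

    # distractors: food-colored blobs strictly off the plate, not in the mask
    nd = int(rng.integers(config.n_distractors[0], config.n_distractors[1] + 1))
    for _ in range(nd):
        spec = config.palette[int(rng.integers(len(config.palette)))]
        radius = np.sqrt(rng.uniform(0.2, 1.0) * per_blob / np.pi)
        dcy, dcx = rng.uniform(0, H), rng.uniform(0, W)
        blob = _star_blob(rng, dcy, dcx, radius, (H, W)) & ~plate
        color = np.array(spec.color, dtype=np.float64)
        jitter = rng.normal(0, spec.texture_jitter, size=(int(blob.sum()), 3))
        image[blob] = np.clip(color + jitter, 0, 255)

    clean = nutrient_oracle(areas, specs).as_array()
    if config.label_noise_cv > 0:
        noise = 1.0 + rng.normal(0.0, config.label_noise_cv, size=5)
        noise = np.maximum(noise, 0.0)  # truncate so labels stay >= 0
    else:
        noise = np.ones(5)
    label = NutrientLabel.from_array(clean * noise)

    record = DishRecord(
        dish_id="", image=np.clip(image, 0, 255).astype(np.uint8), label=label, mask=mask,
    )
    return SyntheticDish(
        record=record,
        ingredient_names=tuple(s.name for s in specs),
        pixel_areas=tuple(areas),
        noise_draws=noise,
    )


def generate_dishes(config: SceneConfig, n: int) -> list[SyntheticDish]:
    """Generate n dishes with ids synth_000000..; deterministic in config.seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    dishes = []
    for i in range(n):
        dish = sample_scene(config, rng)
        dish.record.dish_id = f"synth_{i:06d}"
        dishes.append(dish)
    return dishes


def generate_dataset(config: SceneConfig, n: int, out_dir: str | Path) -> Path:
    """Write n dishes to disk: images/, masks/ and metadata.csv.

    The layout round-trips through the dataset_io readers; returns out_dir.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    records = []
    for dish in generate_dishes(config, n):
        rec = dish.record
        write_image(rec.image, out / "images" / f"{rec.dish_id}.png")
        write_mask(rec.mask, out / "masks" / f"{rec.dish_id}.png")
        records.append((rec.dish_id, rec.label))
    write_metadata(records, out / "metadata.csv")
    return out
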