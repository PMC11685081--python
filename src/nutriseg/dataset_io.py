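"""Dish metadata, image and mask I/O, foreground masking, and train/test splits.

Metadata lives in a plain CSV whose rows follow the record layout
``[image_name, calories, mass, fat, carb, protein]``; an optional header row is
auto-detected.  Masks persist as single-channel 8-bit PNGs with background 0
and foreground 255, loaded to {0, 1} rasters.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "NutrientLabel", "DishRecord", "DatasetSplit", "NUTRIENTS",
    "read_metadata", "write_metadata", "read_mask", "write_mask",
    "read_image", "write_image", "apply_mask", "split_dataset",
]

#: Canonical nutrient order used for model outputs and evaluation reports.
NUTRIENTS = ("mass", "calories", "fat", "carb", "protein")

#: Field order after the id column in the metadata file.
_CSV_FIELDS = ("calories", "mass", "fat", "carb", "protein")


class MetadataError(ValueError):
    """Raised for malformed or inconsistent metadata files."""


@dataclass(frozen=True)
class NutrientLabel:
    """Five-component nutrient target for one dish.

    mass and fat/carb/protein are in grams, calories in kcal.  All components
    must be finite and non-negative.
    """

    mass: float
    calories: float
    fat: float
    carb: float
    protein: float

    def __post_init__(self):
        for name in NUTRIENTS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"nutrient '{name}' must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        """Values in canonical NUTRIENTS order (mass, calories, fat, carb, protein)."""
        return np.array([getattr(self, n) for n in NUTRIENTS], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "NutrientLabel":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (5,):
            raise ValueError(f"expected 5 components, got shape {arr.shape}")
        return cls(**dict(zip(NUTRIENTS, arr.tolist())))


@dataclass
class DishRecord:
    """One dish: image, optional binary food mask, nutrient label."""

    dish_id: str
    image: np.ndarray  # H x W x 3 uint8
    label: NutrientLabel
    mask: np.ndarray | None = None  # H x W in {0,1}, or None

    def __post_init__(self):
        if self.mask is not None and self.mask.shape != self.image.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image {self.image.shape[:2]}"
            )


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int = field(default=0)


# --------------------------------------------------------------------- metadata

def read_metadata(path: str | Path) -> list[tuple[str, NutrientLabel]]:
    """Read dish metadata rows ``id, calories, mass, fat, carb, protein``.

    A header line is auto-detected (non-numeric second field).  Duplicate ids
    and negative nutrients are rejected; malformed lines raise MetadataError
    naming the line number.
    """
    path = Path(path)
    records: list[tuple[str, NutrientLabel]] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 6:
                raise MetadataError(f"{path}:{lineno}: expected 6 fields, got {len(row)}")
            dish_id = row[0].strip()
            if lineno == 1:
                # header auto-detection: a non-numeric second field
                try:
                    float(row[1])
                except ValueError:
                    continue
            try:
                values = [float(c) for c in row[1:]]
            except ValueError:
                raise MetadataError(f"{path}:{lineno}: non-numeric nutrient field") from None
            if any(v < 0 for v in values):
                raise MetadataError(f"{path}:{lineno}: negative nutrient value")
            if dish_id in seen:
                raise MetadataError(f"{path}:{lineno}: duplicate dish id {dish_id!r}")
            seen.add(dish_id)
            kwargs = dict(zip(_CSV_FIELDS, values))
            records.append((dish_id, NutrientLabel(**kwargs)))
    return records


def write_metadata(records: list[tuple[str, NutrientLabel]], path: str | Path,
                   header: bool = True) -> None:
    """Write metadata re-readable by :func:`read_metadata` (inverse mapping)."""
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise MetadataError("duplicate dish ids in records")
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        if header:
            w.writerow(("image_name",) + _CSV_FIELDS)
        for dish_id, label in records:
            w.writerow([dish_id] + [repr(getattr(label, f)) for f in _CSV_FIELDS])


# ------------------------------------------------------------------------ masks

def read_mask(path: str | Path) -> np.ndarray:
    """Load a single-channel 0/255 PNG as a {0,1} uint8 raster.

    Intermediate gray values (antialiased exports) are thresholded at 128
    with a warning.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.mode not in ("L", "1", "I", "I;16"):
            raise OSError(f"{path}: expected a single-channel mask image, got mode {im.mode!r}")
        arr = np.asarray(im.convert("L"))
    strict = np.isin(arr, (0, 255)).all()
    if not strict:
        warnings.warn(f"{path}: mask has values strictly between 0 and 255; thresholding at 128",
                      stacklevel=2)
    return (arr >= 128).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Persist a {0,1} raster as 0/255 single-channel PNG (inverse of read_mask)."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be a 2-D array with values in {0, 1}")
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(Path(path))


def read_image(path: str | Path) -> np.ndarray:
    with Image.open(Path(path)) as im:
        return np.asarray(im.convert("RGB"))


def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(Path(path))


# -------------------------------------------------------------------- transforms

def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every pixel outside the food region; the input is not modified."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if mask.shape != image.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image {image.shape[:2]}")
    return image * mask[..., None].astype(image.dtype)


# ------------------------------------------------------------------------ splits

def split_dataset(ids, train_fraction: float = 0.8, seed: int = 42,
                  round_to_multiple: int | None = 8) -> DatasetSplit:
    """Shuffle ids and split into train/test.

    When ``round_to_multiple`` is set, the train size is the multiple nearest
    to ``train_fraction * n`` (ties toward the larger training set) and the
    total must itself allow both halves to be non-empty multiples — matching
    the convention of splitting 3,224 dishes into 2,576 train / 648 test.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("dish ids must be unique")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(ids)
    target = train_fraction * n
    if round_to_multiple is not None:
        m = int(round_to_multiple)
        if n < 2 * m:
            raise ValueError(f"need at least {2 * m} ids to split in multiples of {m}, got {n}")
        if n % m:
            raise ValueError(f"total id count {n} is not a multiple of {m}")
        lo = int(np.floor(target / m)) * m
        hi = lo + m
        # nearest multiple; tie -> larger training set
        n_train = hi if (hi - target) <= (target - lo) else lo
        n_train = min(max(n_train, m), n - m)
    else:
        n_train = int(round(target))
        n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    return DatasetSplit(tuple(shuffled[:n_train]), tuple(shuffled[n_train:]), seed=seed)
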