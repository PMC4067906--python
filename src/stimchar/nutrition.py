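"""Per-image nutrition metadata and the caloric-density median split.

Each food image carries energy density (kcal/100 g), macronutrients
(g/100 g), the mass of the depicted portion, and an item count, plus
categorical labels (food class, sweet/savory, whole/processed).  The
module derives per-portion totals, splits food images into high vs. low
caloric density at the median, and exposes the Pearson-correlation
cross-validation used when two coders independently estimate the same
metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: Column order of the nutrition CSV interchange format.
NUTRITION_CSV_COLUMNS = [
    "image_id",
    "is_food",
    "category",
    "sweet_savory",
    "processing",
    "kcal_per_100g",
    "protein_per_100g",
    "carb_per_100g",
    "fat_per_100g",
    "portion_grams",
    "item_count",
    "total_kcal",
]

FOOD_CATEGORIES = (
    "fruit",
    "vegetable",
    "chocolate",
    "meat",
    "fish",
    "nuts",
    "beverage",
    "other",
)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class NutrientRecord:
    """Nutrition metadata for one image.

    Nutrient fields are per 100 g; ``portion_grams`` is the mass of the
    depicted portion; ``item_count`` the number of displayed items
    (e.g. three apples).  Missing values are ``None``/NaN, never zero.
    """

    image_id: str
    kcal_per_100g: float | None = None
    protein_per_100g: float | None = None
    carb_per_100g: float | None = None
    fat_per_100g: float | None = None
    portion_grams: float | None = None
    item_count: int = 1
    is_food: bool = True
    category: str = "other"
    sweet_savory: str = "unclassifiable"
    processing: str = "unclassifiable"

    def __post_init__(self) -> None:
        for field in (
            "kcal_per_100g",
            "protein_per_100g",
            "carb_per_100g",
            "fat_per_100g",
            "portion_grams",
        ):
            v = getattr(self, field)
            if v is not None and not _is_missing(v) and v < 0:
                raise ValueError(f"{field} must be >= 0, got {v}")
        for field in ("protein_per_100g", "carb_per_100g", "fat_per_100g"):
            v = getattr(self, field)
            if v is not None and not _is_missing(v) and v > 100:
                raise ValueError(f"{field} exceeds 100 g per 100 g: {v}")
        if self.is_food and self.item_count < 1:
            raise ValueError("item_count must be >= 1 for food images")


@dataclass(frozen=True)
class PortionTotals:
    """Absolute amounts for the depicted portion; ``available`` is False
    when the portion mass is unknown (totals are then NaN, not zero)."""

    total_kcal: float
    total_protein_g: float
    total_carb_g: float
    total_fat_g: float
    available: bool = True


def portion_total(record: NutrientRecord) -> PortionTotals:
    """Scale per-100 g values to the depicted portion.

    A missing portion mass yields NaN totals flagged unavailable; a
    zero or negative mass is a data error and raises.
    """
    g = record.portion_grams
    if _is_missing(g):
        nan = float("nan")
        return PortionTotals(nan, nan, nan, nan, available=False)
    if g <= 0:
        raise ValueError(
            f"portion_grams must be > 0, got {g} for {record.image_id}"
        )

    def scale(per100: float | None) -> float:
        return float("nan") if _is_missing(per100) else per100 * g / 100.0

    return PortionTotals(
        total_kcal=scale(record.kcal_per_100g),
        total_protein_g=scale(record.protein_per_100g),
        total_carb_g=scale(record.carb_per_100g),
        total_fat_g=scale(record.fat_per_100g),
        available=True,
    )


@dataclass(frozen=True)
class CalorieSplit:
    """High/low caloric-density assignment for a set of food images."""

    median_density: float
    labels: dict[str, str]  # image_id -> "high" | "low"

    def group(self, label: str) -> list[str]:
        return [i for i, lab in self.labels.items() if lab == label]


def median_split(records: Iterable[NutrientRecord]) -> CalorieSplit:
    """Split food images at the median caloric density (kcal/100 g).

    Densities at or below the median are labeled ``low``, above it
    ``high`` — a deterministic tie rule so reruns reproduce the same
    split.  Non-food records and records with missing density are
    excluded (the exclusion count is logged).
    """
    usable: list[tuple[str, float]] = []
    skipped = 0
    for rec in records:
        if not rec.is_food or _is_missing(rec.kcal_per_100g):
            skipped += 1
            continue
        usable.append((rec.image_id, float(rec.kcal_per_100g)))
    if skipped:
        log.info("median_split: excluded %d records (non-food or missing "
                 "density)", skipped)
    if len(usable) < 2:
        raise ValueError(
            f"median split needs >= 2 food records with density, "
            f"got {len(usable)}"
        )
    densities = np.array([d for _, d in usable])
    med = float(np.median(densities))
    labels = {
        image_id: ("low" if d <= med else "high") for image_id, d in usable
    }
    if np.all(densities == densities[0]):
        log.warning("median_split: all densities equal; every image is 'low'")
    return CalorieSplit(median_density=med, labels=labels)


def coder_agreement(
    coder_a: Sequence[float], coder_b: Sequence[float]
) -> float:
    """Pearson correlation between two coders' estimates of the same
    items — the cross-validation statistic for double-coded metadata."""
    a = np.asarray(coder_a, dtype=np.float64)
    b = np.asarray(coder_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("coder vectors must be 1D and of equal length")
    if a.size < 3:
        raise ValueError(f"need >= 3 paired estimates, got {a.size}")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def records_to_frame(records: Iterable[NutrientRecord]) -> pd.DataFrame:
    """Serialize records to the nutrition CSV schema (adds total_kcal)."""
    rows = []
    for rec in records:
        totals = portion_total(rec) if rec.is_food else None
        rows.append(
            {
                "image_id": rec.image_id,
                "is_food": rec.is_food,
                "category": rec.category,
                "sweet_savory": rec.sweet_savory,
                "processing": rec.processing,
                "kcal_per_100g": rec.kcal_per_100g,
                "protein_per_100g": rec.protein_per_100g,
                "carb_per_100g": rec.carb_per_100g,
                "fat_per_100g": rec.fat_per_100g,
                "portion_grams": rec.portion_grams,
                "item_count": rec.item_count,
                "total_kcal": totals.total_kcal if totals else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=NUTRITION_CSV_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[NutrientRecord]:
    """Parse a nutrition CSV frame back into records."""
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            NutrientRecord(
                image_id=str(row.image_id),
                kcal_per_100g=_opt(row.kcal_per_100g),
                protein_per_100g=_opt(row.protein_per_100g),
                carb_per_100g=_opt(row.carb_per_100g),
                fat_per_100g=_opt(row.fat_per_100g),
                portion_grams=_opt(row.portion_grams),
                item_count=int(row.item_count),
                is_food=bool(row.is_food),
                category=str(row.category),
                sweet_savory=str(row.sweet_savory),
                processing=str(row.processing),
            )
        )
    return records


def _opt(x) -> float | None:
    return None if pd.isna(x) else float(x)
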