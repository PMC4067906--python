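"""Deterministic synthetic data: stimulus images, nutrition tables,
and simulated rating surveys with known generative truth.

The generators emulate the conventions of standardized stimulus
databases — single objects on a white 600 × 450 canvas, a nutrition
table with per-100 g and per-portion values, and an online survey in
which each participant rates a random subset of food and non-food
images on 1–100 visual-analog scales plus two dichotomous items.

Every generator is a pure function of its spec (including the seed),
and returns analytic ground truth computed from the spec parameters —
not measured from the generated artifact — so downstream metrics can be
verified against closed-form values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image

from stimchar.imageio_mask import GRAY_WEIGHTS
from stimchar.nutrition import FOOD_CATEGORIES, NutrientRecord

DEFAULT_CANVAS = (600, 450)  # (width, height), the database standard

#: Atwater energy factors, kcal per gram.
ATWATER = {"protein": 4.0, "carb": 4.0, "fat": 9.0}


def _gray_of(color: tuple[int, int, int]) -> float:
    return float(np.dot(GRAY_WEIGHTS, color))


class SpecError(ValueError):
    """Raised when a generator spec is inconsistent (e.g. object too big)."""


@dataclass(frozen=True)
class ObjectSpec:
    """Parametric description of one synthetic stimulus image.

    ``shape`` is one of ``square``, ``disk``, ``checkerboard``,
    ``grating``, ``composite``.  ``side_or_radius`` is the square/
    checkerboard side or the disk radius in pixels; ``texture_cells``
    the checkerboard grid order; ``grating_cycles`` the number of full
    sinusoid periods across the image width.  ``position`` is the
    top-left corner for squares and the center for disks (``None`` =
    centered).
    """

    shape: str = "square"
    fill_color: tuple[int, int, int] = (0, 0, 0)
    secondary_color: tuple[int, int, int] = (90, 90, 90)
    side_or_radius: int = 100
    texture_cells: int = 1
    grating_cycles: int = 8
    grating_amplitude: float = 100.0
    position: tuple[int, int] | None = None
    canvas: tuple[int, int] = DEFAULT_CANVAS
    seed: int = 0


@dataclass(frozen=True)
class ImageTruth:
    """Analytic ground truth for one generated image.

    ``object_pixels`` is the exact boolean object raster (None for
    gratings, which fill the frame); ``gray_mean``/``gray_sd`` are the
    closed-form luminance statistics over the object pixels.
    """

    object_pixels: np.ndarray | None
    size_fraction: float | None
    gray_mean: float | None
    gray_sd: float | None
    grating_cycles: int | None
    spec: ObjectSpec


def _blank(canvas: tuple[int, int]) -> np.ndarray:
    w, h = canvas
    return np.full((h, w, 3), 255, dtype=np.uint8)


def _square_origin(spec: ObjectSpec, side: int) -> tuple[int, int]:
    w, h = spec.canvas
    if spec.position is not None:
        x0, y0 = spec.position
    else:
        x0, y0 = (w - side) // 2, (h - side) // 2
    if x0 < 0 or y0 < 0 or x0 + side > w or y0 + side > h:
        raise SpecError(
            f"object of side {side} at ({x0}, {y0}) exceeds canvas {spec.canvas}"
        )
    return x0, y0


def _mixture_stats(
    populations: list[tuple[int, float]]
) -> tuple[float, float]:
    """Mean and population SD of a pixel population given as
    (count, gray value) components."""
    counts = np.array([c for c, _ in populations], dtype=np.float64)
    values = np.array([v for _, v in populations], dtype=np.float64)
    total = counts.sum()
    mean = float((counts * values).sum() / total)
    var = float((counts * (values - mean) ** 2).sum() / total)
    return mean, float(np.sqrt(var))


def generate_image(spec: ObjectSpec) -> tuple[np.ndarray, ImageTruth]:
    """Render the spec onto a white canvas and derive its ground truth.

    Deterministic: the same spec always yields byte-identical pixels.
    """
    w, h = spec.canvas
    if w < 1 or h < 1:
        raise SpecError(f"canvas must be positive, got {spec.canvas}")
    img = _blank(spec.canvas)
    total = w * h

    if spec.shape == "square":
        s = spec.side_or_radius
        x0, y0 = _square_origin(spec, s)
        img[y0 : y0 + s, x0 : x0 + s] = spec.fill_color
        mask = np.zeros((h, w), dtype=bool)
        mask[y0 : y0 + s, x0 : x0 + s] = True
        g = _gray_of(spec.fill_color)
        truth = ImageTruth(mask, s * s / total, g, 0.0, None, spec)

    elif spec.shape == "disk":
        r = spec.side_or_radius
        cx, cy = spec.position if spec.position is not None else (w // 2, h // 2)
        if cx - r < 0 or cy - r < 0 or cx + r >= w or cy + r >= h:
            raise SpecError(
                f"disk of radius {r} at ({cx}, {cy}) exceeds canvas {spec.canvas}"
            )
        yy, xx = np.ogrid[:h, :w]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        img[mask] = spec.fill_color
        g = _gray_of(spec.fill_color)
        truth = ImageTruth(mask, mask.sum() / total, g, 0.0, None, spec)

    elif spec.shape == "checkerboard":
        n = spec.texture_cells
        if n < 1:
            raise SpecError("texture_cells must be >= 1")
        cell = spec.side_or_radius // n
        if cell < 1:
            raise SpecError(
                f"side {spec.side_or_radius} too small for {n} cells"
            )
        side = cell * n
        x0, y0 = _square_origin(spec, side)
        mask = np.zeros((h, w), dtype=bool)
        mask[y0 : y0 + side, x0 : x0 + side] = True
        ii = (np.arange(side) // cell)[:, None]
        jj = (np.arange(side) // cell)[None, :]
        primary = (ii + jj) % 2 == 0
        block = np.where(
            primary[..., None],
            np.array(spec.fill_color, dtype=np.uint8),
            np.array(spec.secondary_color, dtype=np.uint8),
        ).astype(np.uint8)
        img[y0 : y0 + side, x0 : x0 + side] = block
        n_primary_cells = (n * n + 1) // 2
        n_secondary_cells = n * n - n_primary_cells
        g1, g2 = _gray_of(spec.fill_color), _gray_of(spec.secondary_color)
        mean, sd = _mixture_stats(
            [
                (n_primary_cells * cell * cell, g1),
                (n_secondary_cells * cell * cell, g2),
            ]
        )
        truth = ImageTruth(mask, side * side / total, mean, sd, None, spec)

    elif spec.shape == "grating":
        k = spec.grating_cycles
        if not 1 <= k <= w // 2:
            raise SpecError(
                f"grating_cycles must be in [1, {w // 2}], got {k}"
            )
        x = np.arange(w)
        profile = 127.5 + spec.grating_amplitude * np.sin(2 * np.pi * k * x / w)
        row = np.clip(np.rint(profile), 0, 255).astype(np.uint8)
        img[:] = np.repeat(row[None, :, None], 3, axis=2)
        truth = ImageTruth(None, None, None, None, k, spec)

    elif spec.shape == "composite":
        # A square and a disk side by side, both sized from side_or_radius.
        s = spec.side_or_radius
        r = max(1, s // 2)
        x0, y0 = w // 4 - s // 2, (h - s) // 2
        cx, cy = 3 * w // 4, h // 2
        if x0 < 0 or y0 < 0 or x0 + s > w or cx + r >= w or cy + r >= h:
            raise SpecError(
                f"composite of size {s} exceeds canvas {spec.canvas}"
            )
        mask = np.zeros((h, w), dtype=bool)
        mask[y0 : y0 + s, x0 : x0 + s] = True
        img[y0 : y0 + s, x0 : x0 + s] = spec.fill_color
        yy, xx = np.ogrid[:h, :w]
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        mask |= disk
        img[disk] = spec.secondary_color
        g1, g2 = _gray_of(spec.fill_color), _gray_of(spec.secondary_color)
        mean, sd = _mixture_stats([(s * s, g1), (int(disk.sum()), g2)])
        truth = ImageTruth(mask, mask.sum() / total, mean, sd, None, spec)

    else:
        raise SpecError(f"unknown shape {spec.shape!r}")

    return img, truth


def write_image(
    img: np.ndarray, path: str | Path, jpeg_quality: int = 95
) -> Path:
    """Write an RGB array to disk; format follows the file suffix.

    PNG (lossless, the default for fixtures, so mask recovery is exact)
    or JPEG (lossy, for threshold-robustness exercises).
    """
    path = Path(path)
    im = Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB")
    if path.suffix.lower() in (".jpg", ".jpeg"):
        # 4:4:4 sampling: chroma subsampling would smear color edges far
        # beyond the DCT quantization error.
        im.save(path, quality=jpeg_quality, subsampling=0)
    else:
        im.save(path)
    return path


# --------------------------------------------------------------------------
# Nutrition tables
# --------------------------------------------------------------------------

#: Food-class proportions used by the nutrition generator, mirroring a
#: typical western food-image pool (fruits, vegetables, chocolate, meat,
#: fish, nuts, beverages, mixed/other).
FOOD_CATEGORY_P = {
    "fruit": 0.133,
    "vegetable": 0.207,
    "chocolate": 0.114,
    "meat": 0.111,
    "fish": 0.0228,
    "nuts": 0.0176,
    "beverage": 0.0158,
    "other": 0.3788,
}
SWEET_SAVORY_P = {"sweet": 0.428, "savory": 0.388, "unclassifiable": 0.184}
PROCESSING_P = {"processed": 0.320, "whole": 0.667, "unclassifiable": 0.013}


def generate_nutrition(
    n_items: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_nonfood: int = 0,
) -> list[NutrientRecord]:
    """Generate an internally consistent nutrition table.

    Macronutrients are drawn uniformly (protein 0–25, carbohydrate
    0–70, fat 0–35 g/100 g); energy density follows the Atwater factors
    (4/4/9 kcal per g) plus Gaussian noise of SD ``noise_sd`` kcal,
    floored at 0.  Categories are assigned with the pool proportions in
    :data:`FOOD_CATEGORY_P`.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    cats = list(FOOD_CATEGORY_P)
    cat_p = np.array([FOOD_CATEGORY_P[c] for c in cats])
    cat_p = cat_p / cat_p.sum()
    sweet_levels = list(SWEET_SAVORY_P)
    sweet_p = np.array(list(SWEET_SAVORY_P.values()))
    proc_levels = list(PROCESSING_P)
    proc_p = np.array(list(PROCESSING_P.values()))
    for i in range(n_items):
        protein = rng.uniform(0, 25)
        carb = rng.uniform(0, 70)
        fat = rng.uniform(0, 35)
        kcal = (
            ATWATER["protein"] * protein
            + ATWATER["carb"] * carb
            + ATWATER["fat"] * fat
        )
        if noise_sd > 0:
            kcal += rng.normal(0, noise_sd)
        records.append(
            NutrientRecord(
                image_id=f"food_{i + 1:04d}",
                kcal_per_100g=max(0.0, float(kcal)),
                protein_per_100g=float(protein),
                carb_per_100g=float(carb),
                fat_per_100g=float(fat),
                portion_grams=float(np.round(rng.uniform(20, 400), 1)),
                item_count=int(min(12, 1 + rng.geometric(0.5))),
                is_food=True,
                category=str(rng.choice(cats, p=cat_p)),
                sweet_savory=str(rng.choice(sweet_levels, p=sweet_p)),
                processing=str(rng.choice(proc_levels, p=proc_p)),
            )
        )
    for i in range(n_nonfood):
        records.append(
            NutrientRecord(
                image_id=f"nonfood_{i + 1:04d}",
                is_food=False,
                category="other",
            )
        )
    return records


# --------------------------------------------------------------------------
# Simulated rating surveys
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSpec:
    """One recruitment sample: size, per-rater image quotas, and
    demographic composition (proportions; ages in years, BMI kg/m²)."""

    name: str
    n_participants: int
    n_nonfood_per_rater: int
    n_food_per_rater: int
    completion: float = 0.8
    male_p: float = 0.25
    vegetarian_p: float = 0.15
    vegan_p: float = 0.03
    dieting_p: float = 0.12
    age_mean: float = 28.0
    age_sd: float = 10.0
    age_min: float = 11.0
    age_max: float = 77.0
    bmi_mean: float = 23.5
    bmi_sd: float = 4.5


def default_samples() -> tuple[SampleSpec, ...]:
    """The four-sample recruitment structure the survey design mirrors:
    a distance-teaching university sample, a general German-speaking
    sample, a US crowdworker sample, and a small adolescent sample."""
    return (
        SampleSpec("unihagen", 638, 40, 80, completion=0.898, male_p=0.172,
                   vegetarian_p=0.196, vegan_p=0.027, dieting_p=0.099,
                   age_mean=32.8, age_sd=10.07, age_min=17, age_max=73,
                   bmi_mean=23.4, bmi_sd=4.68),
        SampleSpec("german_speaking", 831, 25, 40, completion=0.776,
                   male_p=0.167, vegetarian_p=0.202, vegan_p=0.039,
                   dieting_p=0.103, age_mean=24.7, age_sd=5.46, age_min=18,
                   age_max=65, bmi_mean=22.5, bmi_sd=3.70),
        SampleSpec("us", 496, 17, 35, completion=0.696, male_p=0.363,
                   vegetarian_p=0.054, vegan_p=0.022, dieting_p=0.238,
                   age_mean=35.9, age_sd=13.41, age_min=18, age_max=77,
                   bmi_mean=27.3, bmi_sd=7.29),
        SampleSpec("children_youth", 23, 5, 35, completion=0.783,
                   male_p=0.609, vegetarian_p=0.043, vegan_p=0.0,
                   dieting_p=0.043, age_mean=13.9, age_sd=1.56, age_min=11,
                   age_max=18, bmi_mean=18.7, bmi_sd=2.77),
    )


#: Default per-image latent mean priors (mu, between-image SD) and the
#: within-image rating SD, on the 1–100 VAS scale.
DEFAULT_LATENT_PRIORS = {
    "complexity_vas": (50.0, 12.0),
    "valence_vas": (55.0, 12.0),
    "arousal_vas": (34.0, 12.0),
    "palatability_vas": (58.0, 12.0),
    "desire_vas": (34.0, 12.0),
}
DEFAULT_WITHIN_SD = 18.0


@dataclass(frozen=True)
class SurveySpec:
    """Design of one simulated normative survey.

    Each participant in each sample rates a uniform random subset of
    the food pool and of the non-food pool (quota per sample); VAS
    responses are latent image means plus subgroup effects plus normal
    noise, rounded and clamped to integers in [1, 100].  Injected
    effects: a male shift on desire to eat, a vegetarian/vegan shift on
    meat palatability and desire, and a linear hunger slope on desire.
    """

    samples: tuple[SampleSpec, ...] = field(default_factory=default_samples)
    n_food_images: int = 568
    n_nonfood_images: int = 315
    latent_priors: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_PRIORS)
    )
    within_sd: float = DEFAULT_WITHIN_SD
    meat_p: float = 0.111
    male_desire_shift: float = 8.3
    vegetarian_meat_palatability_shift: float = -36.5
    vegetarian_meat_desire_shift: float = -23.8
    hunger_desire_slope: float = 0.4
    hunger_mean: float = 28.5
    hunger_sd: float = 25.4
    familiarity_p_range: tuple[float, float] = (0.85, 1.0)
    recognizability_p_range: tuple[float, float] = (0.85, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.n_food_per_rater > self.n_food_images:
                raise ValueError(
                    f"sample {s.name!r}: food quota exceeds pool size"
                )
            if s.n_nonfood_per_rater > self.n_nonfood_images:
                raise ValueError(
                    f"sample {s.name!r}: non-food quota exceeds pool size"
                )
            if not 0 <= s.completion <= 1:
                raise ValueError("completion must be a probability")


@dataclass(frozen=True)
class SurveyData:
    """Simulated survey output plus the generative truth that made it."""

    ratings: pd.DataFrame
    profiles: pd.DataFrame
    truth: dict


def _clip_round_vas(values: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(values), 1, 100).astype(np.int64)


def simulate_survey(spec: SurveySpec) -> SurveyData:
    """Simulate the survey and return ratings, profiles, and truth.

    The truth dict holds the per-image latent means (DataFrame), the
    per-image meat flags, and the injected effect sizes, so recovery
    tests can compare estimates against what generated the data.
    """
    rng = np.random.default_rng(spec.seed)

    food_ids = [f"food_{i + 1:04d}" for i in range(spec.n_food_images)]
    nonfood_ids = [f"nonfood_{i + 1:04d}" for i in range(spec.n_nonfood_images)]
    all_ids = food_ids + nonfood_ids
    is_food = np.array([True] * len(food_ids) + [False] * len(nonfood_ids))
    is_meat = np.zeros(len(all_ids), dtype=bool)
    is_meat[: len(food_ids)] = rng.random(len(food_ids)) < spec.meat_p

    latents = {}
    for scale, (mu, sd) in spec.latent_priors.items():
        vals = np.clip(rng.normal(mu, sd, size=len(all_ids)), 1, 100)
        if scale in ("palatability_vas", "desire_vas"):
            vals[~is_food] = np.nan
        latents[scale] = vals
    p_familiar = rng.uniform(*spec.familiarity_p_range, size=len(all_ids))
    p_recognizable = rng.uniform(
        *spec.recognizability_p_range, size=len(all_ids)
    )

    profile_rows = []
    rating_chunks: list[dict[str, np.ndarray]] = []
    pid = 0
    for sample in spec.samples:
        for _ in range(sample.n_participants):
            pid += 1
            participant_id = f"p{pid:05d}"
            male = rng.random() < sample.male_p
            u = rng.random()
            if u < sample.vegan_p:
                diet = "vegan"
            elif u < sample.vegan_p + sample.vegetarian_p:
                diet = "vegetarian"
            else:
                diet = "omnivore"
            age = float(
                np.clip(
                    rng.normal(sample.age_mean, sample.age_sd),
                    sample.age_min,
                    sample.age_max,
                )
            )
            bmi = float(
                max(12.0, rng.normal(sample.bmi_mean, sample.bmi_sd))
            )
            hunger_latent = float(
                np.clip(rng.normal(spec.hunger_mean, spec.hunger_sd), 1, 100)
            )
            hunger_pre = int(
                np.clip(np.rint(hunger_latent + rng.normal(0, 4)), 1, 100)
            )
            hunger_post = int(
                np.clip(np.rint(hunger_latent + rng.normal(0, 4)), 1, 100)
            )
            completed = rng.random() < sample.completion
            frac = 1.0 if completed else rng.uniform(0.05, 0.95)
            kf = int(np.rint(frac * sample.n_food_per_rater))
            kn = int(np.rint(frac * sample.n_nonfood_per_rater))

            profile_rows.append(
                {
                    "participant_id": participant_id,
                    "sample": sample.name,
                    "age": round(age, 1),
                    "gender": "male" if male else "female",
                    "bmi": round(bmi, 1),
                    "diet_style": diet,
                    "currently_dieting": bool(rng.random() < sample.dieting_p),
                    "hunger_pre": hunger_pre,
                    "hunger_post": hunger_post,
                }
            )

            food_sel = (
                rng.choice(len(food_ids), size=kf, replace=False)
                if kf
                else np.empty(0, dtype=np.intp)
            )
            nonfood_sel = (
                len(food_ids)
                + rng.choice(len(nonfood_ids), size=kn, replace=False)
                if kn
                else np.empty(0, dtype=np.intp)
            )
            sel = np.concatenate([food_sel, nonfood_sel]).astype(np.intp)
            if sel.size == 0:
                continue
            m = sel.size
            hunger_avg = (hunger_pre + hunger_post) / 2.0
            veg = diet in ("vegetarian", "vegan")
            chunk: dict[str, np.ndarray] = {
                "participant_id": np.repeat(participant_id, m),
                "image_id": np.array(all_ids, dtype=object)[sel],
                "familiarity": rng.random(m) < p_familiar[sel],
                "recognizability": rng.random(m) < p_recognizable[sel],
            }
            for scale in (
                "complexity_vas",
                "valence_vas",
                "arousal_vas",
                "palatability_vas",
                "desire_vas",
            ):
                base = latents[scale][sel].copy()
                if scale == "desire_vas":
                    if male:
                        base += spec.male_desire_shift
                    base += spec.hunger_desire_slope * (
                        hunger_avg - spec.hunger_mean
                    )
                    if veg:
                        base += np.where(
                            is_meat[sel], spec.vegetarian_meat_desire_shift, 0.0
                        )
                elif scale == "palatability_vas" and veg:
                    base += np.where(
                        is_meat[sel],
                        spec.vegetarian_meat_palatability_shift,
                        0.0,
                    )
                if spec.within_sd > 0:
                    base = base + rng.normal(0, spec.within_sd, size=m)
                applicable = ~np.isnan(latents[scale][sel])
                out = np.full(m, np.nan)
                out[applicable] = _clip_round_vas(base[applicable])
                chunk[scale] = out
            rating_chunks.append(chunk)

    ratings = pd.DataFrame(
        {
            col: np.concatenate([c[col] for c in rating_chunks])
            for col in rating_chunks[0]
        }
    )
    profiles = pd.DataFrame(profile_rows)
    truth = {
        "latent_means": pd.DataFrame(latents, index=all_ids),
        "is_food": pd.Series(is_food, index=all_ids),
        "is_meat": pd.Series(is_meat, index=all_ids),
        "effects": {
            "male_desire_shift": spec.male_desire_shift,
            "vegetarian_meat_palatability_shift":
                spec.vegetarian_meat_palatability_shift,
            "vegetarian_meat_desire_shift": spec.vegetarian_meat_desire_shift,
            "hunger_desire_slope": spec.hunger_desire_slope,
        },
        "spec": spec,
    }
    return SurveyData(ratings=ratings, profiles=profiles, truth=truth)
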