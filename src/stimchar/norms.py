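"""Normative-rating aggregation, subgroup splits, and category contrasts.

Input is a tidy ratings table (one row per participant × image) plus a
participant table with demographics and eating-habit covariates.  The
module filters raters by the completeness rule, aggregates per-image
norms (mean/SD/n per VAS scale, percent-yes per dichotomous item),
optionally stratified by participant subgroups (gender, diet style,
sample), and runs paired category contrasts across image groups with
both Cohen's d conventions.

Expected ratings columns::

    participant_id, image_id, familiarity, recognizability,
    complexity_vas, valence_vas, arousal_vas, palatability_vas, desire_vas

VAS values are integers 1–100; palatability and desire apply to food
images only and are missing (NaN) for non-food rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

VAS_SCALES = (
    "complexity_vas",
    "valence_vas",
    "arousal_vas",
    "palatability_vas",
    "desire_vas",
)
FOOD_ONLY_SCALES = ("palatability_vas", "desire_vas")
DICHOTOMOUS_ITEMS = ("familiarity", "recognizability")

RATING_COLUMNS = ("participant_id", "image_id") + DICHOTOMOUS_ITEMS + VAS_SCALES

#: Column order of the norms CSV interchange format.
NORMS_CSV_COLUMNS = ["image_id", "subgroup", "scale", "mean", "sd", "n"]


def infer_food_images(ratings: pd.DataFrame) -> pd.Series:
    """Flag each image as food iff any rater gave it a food-only rating."""
    return ratings.groupby("image_id")["palatability_vas"].apply(
        lambda s: s.notna().any()
    )


def filter_participants(
    ratings: pd.DataFrame,
    min_food_images: int = 3,
    is_food: Mapping[str, bool] | pd.Series | None = None,
) -> pd.DataFrame:
    """Keep participants with complete ratings on enough food images.

    A food rating is complete when both dichotomous items and all five
    VAS scales are present.  ``is_food`` maps image_id to food status;
    if omitted it is inferred from the presence of food-only scales.
    """
    if min_food_images < 0:
        raise ValueError("min_food_images must be >= 0")
    if min_food_images == 0:
        return ratings
    if is_food is None:
        is_food = infer_food_images(ratings)
    food_flag = ratings["image_id"].map(pd.Series(is_food)).fillna(False)
    food_rows = ratings[food_flag.astype(bool)]
    complete = food_rows[list(DICHOTOMOUS_ITEMS + VAS_SCALES)].notna().all(
        axis=1
    )
    counts = food_rows.loc[complete].groupby("participant_id").size()
    keep = set(counts[counts >= min_food_images].index)
    dropped = ratings["participant_id"].nunique() - len(keep)
    if dropped:
        log.info("filter_participants: dropped %d of %d raters",
                 dropped, ratings["participant_id"].nunique())
    return ratings[ratings["participant_id"].isin(keep)]


def _aggregate_block(ratings: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    rows = []
    grouped = ratings.groupby("image_id")
    for scale in VAS_SCALES:
        agg = grouped[scale].agg(["mean", "std", "count"])
        agg = agg[agg["count"] > 0]
        for image_id, r in agg.iterrows():
            rows.append(
                (image_id, subgroup, scale, r["mean"], r["std"], int(r["count"]))
            )
    for item in DICHOTOMOUS_ITEMS:
        agg = grouped[item].agg(
            pct=lambda s: 100.0 * s.dropna().astype(float).mean()
            if s.notna().any() else np.nan,
            count=lambda s: s.notna().sum(),
        )
        agg = agg[agg["count"] > 0]
        for image_id, r in agg.iterrows():
            rows.append(
                (image_id, subgroup, item, r["pct"], np.nan, int(r["count"]))
            )
    return pd.DataFrame(rows, columns=NORMS_CSV_COLUMNS)


def aggregate(
    ratings: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
    subgroup_factors: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-image norms: mean/SD/n per VAS scale, percent-yes per
    dichotomous item, overall and per requested subgroup level.

    The ``subgroup`` column is ``"all"`` for the overall block and
    ``"factor=level"`` for stratified blocks.  Participants lacking a
    subgroup value are dropped from that stratification only.
    """
    blocks = [_aggregate_block(ratings, "all")]
    if subgroup_factors:
        if profiles is None:
            raise ValueError("subgroup aggregation requires a profiles table")
        for factor in subgroup_factors:
            if factor not in profiles.columns:
                raise ValueError(
                    f"subgroup factor {factor!r} absent from profiles"
                )
            fac = profiles.set_index("participant_id")[factor]
            n_missing = int(fac.isna().sum())
            if n_missing:
                log.info("aggregate: %d participants lack %r; dropped from "
                         "that stratification", n_missing, factor)
            for level in sorted(fac.dropna().unique(), key=str):
                members = set(fac[fac == level].index)
                sub = ratings[ratings["participant_id"].isin(members)]
                if len(sub):
                    blocks.append(
                        _aggregate_block(sub, f"{factor}={level}")
                    )
    out = pd.concat(blocks, ignore_index=True)
    return out.sort_values(
        ["subgroup", "image_id", "scale"], kind="stable"
    ).reset_index(drop=True)


@dataclass(frozen=True)
class ContrastResult:
    """Paired category contrast over participants.

    Per participant, ratings are averaged within each image group; the
    paired t-test compares those two per-participant means.  Both
    Cohen's d conventions are reported: ``d_z`` (mean difference over
    the SD of differences, the quantity ``t/sqrt(n)``) and ``d_av``
    (mean difference over the average of the two group SDs).
    """

    label_a: str
    label_b: str
    t: float
    df: int
    p: float
    d_z: float
    d_av: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_participants: int


def category_contrast(
    ratings: pd.DataFrame,
    image_labels: Mapping[str, str] | pd.Series,
    scale: str,
) -> ContrastResult:
    """Paired t-test comparing two image groups on one rating scale.

    Only participants who rated at least one image in *both* groups
    contribute; df = number of such participants minus 1.
    """
    if scale not in VAS_SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    labels = pd.Series(image_labels)
    levels = sorted(labels.dropna().unique(), key=str)
    if len(levels) != 2:
        raise ValueError(
            f"image_labels must have exactly 2 levels, got {levels}"
        )
    lab_a, lab_b = str(levels[0]), str(levels[1])
    df_ = ratings.assign(_label=ratings["image_id"].map(labels))
    df_ = df_.dropna(subset=["_label", scale])
    per = df_.pivot_table(
        index="participant_id", columns="_label", values=scale, aggfunc="mean"
    )
    if lab_a not in per.columns or lab_b not in per.columns:
        raise ValueError("no ratings in one of the label groups")
    per = per.dropna(subset=[lab_a, lab_b])
    n = len(per)
    if n < 2:
        raise ValueError(
            "paired contrast needs >= 2 participants rating both groups"
        )
    a = per[lab_a].to_numpy(dtype=np.float64)
    b = per[lab_b].to_numpy(dtype=np.float64)
    diff = a - b
    sd_diff = diff.std(ddof=1)
    res = stats.ttest_rel(a, b)
    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    d_z = diff.mean() / sd_diff if sd_diff > 0 else 0.0
    mean_sd = (sd_a + sd_b) / 2
    d_av = diff.mean() / mean_sd if mean_sd > 0 else 0.0
    return ContrastResult(
        label_a=lab_a,
        label_b=lab_b,
        t=float(res.statistic) if sd_diff > 0 else 0.0,
        df=n - 1,
        p=float(res.pvalue) if sd_diff > 0 else 1.0,
        d_z=float(d_z),
        d_av=float(d_av),
        mean_a=float(a.mean()),
        sd_a=float(sd_a),
        mean_b=float(b.mean()),
        sd_b=float(sd_b),
        n_participants=n,
    )


class CorrelationResult(NamedTuple):
    r: float
    n: int
    p: float


def covariate_correlation(
    ratings: pd.DataFrame,
    profiles: pd.DataFrame,
    covariate: str,
    scale: str,
    image_subset: Sequence[str] | None = None,
) -> CorrelationResult:
    """Correlate a participant covariate (hunger, BMI, age, ...) with
    per-participant mean ratings on an image subset."""
    if covariate not in profiles.columns:
        raise ValueError(f"covariate {covariate!r} absent from profiles")
    sub = ratings
    if image_subset is not None:
        sub = sub[sub["image_id"].isin(set(image_subset))]
    per = sub.dropna(subset=[scale]).groupby("participant_id")[scale].mean()
    cov = profiles.set_index("participant_id")[covariate]
    joined = pd.concat([per.rename("rating"), cov.rename("cov")], axis=1)
    joined = joined.dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 participants with covariate and ratings")
    if joined["cov"].nunique() == 1:
        raise ValueError("correlation undefined for constant covariate")
    res = stats.pearsonr(joined["cov"], joined["rating"])
    return CorrelationResult(
        r=float(res.statistic), n=len(joined), p=float(res.pvalue)
    )


class HungerAverage(NamedTuple):
    value: float
    single_source: bool


def hunger_average(
    hunger_pre: float | None, hunger_post: float | None
) -> HungerAverage:
    """Mean of pre- and post-survey hunger; falls back to whichever is
    present (flagged), NaN when both are missing."""
    pre_missing = hunger_pre is None or pd.isna(hunger_pre)
    post_missing = hunger_post is None or pd.isna(hunger_post)
    if pre_missing and post_missing:
        return HungerAverage(float("nan"), False)
    if pre_missing:
        return HungerAverage(float(hunger_post), True)
    if post_missing:
        return HungerAverage(float(hunger_pre), True)
    return HungerAverage((float(hunger_pre) + float(hunger_post)) / 2.0, False)


def with_hunger(profiles: pd.DataFrame) -> pd.DataFrame:
    """Return profiles with a ``hunger`` column averaging pre and post."""
    out = profiles.copy()
    out["hunger"] = [
        hunger_average(pre, post).value
        for pre, post in zip(out["hunger_pre"], out["hunger_post"])
    ]
    return out
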