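"""Matched stimulus-set selection.

When two stimulus conditions (e.g. high- vs. low-calorie images) are
compared, incidental differences in physical features (brightness,
size, green contribution, total calories ...) confound the contrast.
This module selects equal-size subsets per condition that minimize the
maximum absolute standardized mean difference (SMD) across a chosen
feature list — the max-over-features objective guarantees no single
feature stays badly unbalanced.

Algorithm: small two-condition instances are solved exactly by
enumerating all subset pairs; larger ones use seeded random initial
subsets followed by steepest-descent swap hill-climbing (replace one
selected image with an unselected one of the same condition, or swap
simultaneously in both conditions, whenever that lowers the objective),
restarted a few times; deterministic given the spec seed.  SMDs are
standardized by the pooled SD of the full candidate pool so the
denominator is stable across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchSpec:
    """Configuration of one matching run.

    ``features`` is either a list of metric column names (unit weights)
    or a mapping name -> positive weight; ``max_std_diff`` is the
    balance tolerance in pooled-SD units the caller wants to reach.
    """

    group_label_field: str
    features: Sequence[str] | Mapping[str, float]
    subset_size: int
    max_std_diff: float = 0.25
    seed: int = 0
    n_restarts: int = 8
    max_iterations: int = 10_000

    def feature_weights(self) -> dict[str, float]:
        if isinstance(self.features, Mapping):
            weights = dict(self.features)
        else:
            weights = {name: 1.0 for name in self.features}
        if not weights:
            raise ValueError("at least one feature is required")
        for name, w in weights.items():
            if w <= 0:
                raise ValueError(f"weight for {name!r} must be > 0, got {w}")
        return weights

    def __post_init__(self) -> None:
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        if self.max_std_diff <= 0:
            raise ValueError("max_std_diff must be > 0")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of a matching run."""

    selected: dict[str, list[str]]  # condition -> image_ids
    std_diffs: dict[str, float]  # feature -> max |SMD| across pairs
    objective: float  # max over features of |SMD| (weighted)
    tolerance_met: bool
    excluded_features: list[str] = field(default_factory=list)


def _objective(Z: np.ndarray, groups: list[np.ndarray]) -> float:
    means = np.stack([Z[g].mean(axis=0) for g in groups])
    worst = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            worst = max(worst, float(np.abs(means[i] - means[j]).max()))
    return worst


#: Skip the simultaneous two-condition swap scan when the number of
#: (swap-in-a, swap-in-b) pairs exceeds this — the single-swap scan
#: alone keeps large problems tractable.
_PAIR_SCAN_LIMIT = 4_000_000


def _swap_deltas(
    Z: np.ndarray, group: np.ndarray, outside: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All single-swap mean changes for one condition.

    Returns (deltas, positions, candidates): replacing the member at
    ``positions[i]`` with ``candidates[i]`` changes the group mean by
    ``deltas[i]``.
    """
    k = len(group)
    pos = np.repeat(np.arange(k), len(outside))
    cand = np.tile(outside, k)
    deltas = (Z[cand] - Z[group][pos]) / k
    return deltas, pos, cand


def _pairwise_obj(means: np.ndarray) -> float:
    worst = 0.0
    for i in range(len(means)):
        for j in range(i + 1, len(means)):
            worst = max(worst, float(np.abs(means[i] - means[j]).max()))
    return worst


def _descend(
    Z: np.ndarray,
    groups: list[np.ndarray],
    condition_idx: dict[str, np.ndarray],
    conditions: list[str],
    max_iterations: int,
) -> tuple[list[np.ndarray], float]:
    """Steepest-descent swap hill-climbing from the given start.

    The neighborhood is all single swaps (replace one selected image
    with an unselected one of the same condition) and, for two
    conditions, all simultaneous swap pairs — the pair moves escape the
    plateaus that trap single swaps under a max-type objective.
    """
    means = np.stack([Z[g].mean(axis=0) for g in groups])
    obj = _pairwise_obj(means)
    two = len(groups) == 2
    for _ in range(max_iterations):
        best_move = None
        best_obj = obj
        per_group = []
        for gi, c in enumerate(conditions):
            outside = np.setdiff1d(condition_idx[c], groups[gi])
            if len(outside) == 0:
                per_group.append(None)
                continue
            deltas, pos, cand = _swap_deltas(Z, groups[gi], outside)
            per_group.append((deltas, pos, cand))
            shifted = means[gi] + deltas  # (n_moves, F)
            worst = np.zeros(len(deltas))
            for gj in range(len(groups)):
                if gj == gi:
                    continue
                worst = np.maximum(
                    worst, np.abs(shifted - means[gj]).max(axis=1)
                )
            const = 0.0
            for gj in range(len(groups)):
                for gk in range(gj + 1, len(groups)):
                    if gi in (gj, gk):
                        continue
                    const = max(
                        const, float(np.abs(means[gj] - means[gk]).max())
                    )
            worst = np.maximum(worst, const)
            best_i = int(np.argmin(worst))
            if worst[best_i] < best_obj - 1e-12:
                best_obj = float(worst[best_i])
                best_move = [(gi, int(pos[best_i]), int(cand[best_i]))]
        if (
            two
            and per_group[0] is not None
            and per_group[1] is not None
            and len(per_group[0][0]) * len(per_group[1][0])
            <= _PAIR_SCAN_LIMIT
        ):
            d_a, pos_a, cand_a = per_group[0]
            d_b, pos_b, cand_b = per_group[1]
            gap = means[0] - means[1]
            # |(ma + da) - (mb + db)| for every (da, db) pair
            pairwise = np.abs(
                gap[None, None, :] + d_a[:, None, :] - d_b[None, :, :]
            ).max(axis=2)
            ia, ib = np.unravel_index(np.argmin(pairwise), pairwise.shape)
            if pairwise[ia, ib] < best_obj - 1e-12:
                best_obj = float(pairwise[ia, ib])
                best_move = [
                    (0, int(pos_a[ia]), int(cand_a[ia])),
                    (1, int(pos_b[ib]), int(cand_b[ib])),
                ]
        if best_move is None:
            break
        for gi, pos, cand in best_move:
            groups[gi][pos] = cand
        means = np.stack([Z[g].mean(axis=0) for g in groups])
        obj = _pairwise_obj(means)
    return groups, obj


#: Enumerate two-condition instances exactly while the number of
#: (subset-of-a, subset-of-b) pairs stays below this bound; local
#: search takes over beyond it.
_EXACT_PAIR_LIMIT = 1_000_000


def _exact_two_condition(
    Z: np.ndarray, idx: list[np.ndarray], k: int
) -> tuple[list[np.ndarray], float] | None:
    """Exhaustive search over all subset pairs for two conditions.

    Returns None when the instance is too large to enumerate; the
    caller then falls back to the seeded swap heuristic.
    """
    from itertools import combinations
    from math import comb

    n_pairs = comb(len(idx[0]), k) * comb(len(idx[1]), k)
    if n_pairs > _EXACT_PAIR_LIMIT:
        return None
    combos = [
        np.array(list(combinations(range(len(ix)), k)), dtype=np.intp)
        for ix in idx
    ]
    means = [Z[ix][cb].mean(axis=1) for ix, cb in zip(idx, combos)]
    worst = np.zeros((len(means[0]), len(means[1])))
    for f in range(Z.shape[1]):  # feature-wise to cap peak memory
        np.maximum(
            worst,
            np.abs(means[0][:, None, f] - means[1][None, :, f]),
            out=worst,
        )
    ia, ib = np.unravel_index(np.argmin(worst), worst.shape)
    groups = [idx[0][combos[0][ia]], idx[1][combos[1][ib]]]
    return groups, float(worst[ia, ib])


def match(candidates: pd.DataFrame, spec: MatchSpec) -> MatchResult:
    """Select matched subsets of ``spec.subset_size`` images per
    condition, minimizing the maximum absolute SMD across features.

    ``candidates`` needs an ``image_id`` column, the condition column
    named by ``spec.group_label_field``, and every feature column.
    Constant features carry no balance information and are excluded
    with a warning.
    """
    weights = spec.feature_weights()
    for col in ("image_id", spec.group_label_field, *weights):
        if col not in candidates.columns:
            raise ValueError(f"candidates table lacks column {col!r}")
    pool = candidates.dropna(subset=list(weights)).reset_index(drop=True)

    kept, excluded, scaled_cols = [], [], []
    for name, w in weights.items():
        values = pool[name].to_numpy(dtype=np.float64)
        sd = values.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            log.warning("match: feature %r is constant; excluded", name)
            excluded.append(name)
            continue
        kept.append(name)
        scaled_cols.append(w * values / sd)
    if not kept:
        raise ValueError("all features constant; nothing to match on")
    Z = np.column_stack(scaled_cols)

    labels = pool[spec.group_label_field].astype(str)
    conditions = sorted(labels.unique())
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions to match")
    condition_idx = {
        c: np.flatnonzero((labels == c).to_numpy()) for c in conditions
    }
    for c, idx in condition_idx.items():
        if len(idx) < spec.subset_size:
            raise ValueError(
                f"condition {c!r} has {len(idx)} candidates, fewer than "
                f"subset_size={spec.subset_size}"
            )

    best_groups: list[np.ndarray] | None = None
    best_obj = np.inf
    if len(conditions) == 2:
        exact = _exact_two_condition(
            Z, [condition_idx[c] for c in conditions], spec.subset_size
        )
        if exact is not None:
            best_groups, best_obj = exact

    rng = np.random.default_rng(spec.seed)
    for _ in range(0 if best_groups is not None else max(1, spec.n_restarts)):
        groups = [
            rng.choice(condition_idx[c], size=spec.subset_size, replace=False)
            for c in conditions
        ]
        groups, obj = _descend(
            Z, groups, condition_idx, conditions, spec.max_iterations
        )
        if obj < best_obj:
            best_obj = obj
            best_groups = [g.copy() for g in groups]

    assert best_groups is not None
    means = np.stack([Z[g].mean(axis=0) for g in best_groups])
    std_diffs = {}
    for k, name in enumerate(kept):
        worst = 0.0
        for i in range(len(conditions)):
            for j in range(i + 1, len(conditions)):
                worst = max(worst, abs(float(means[i, k] - means[j, k])))
        std_diffs[name] = worst / weights[name]  # back to pooled-SD units
    selected = {
        c: sorted(pool.loc[g, "image_id"].astype(str))
        for c, g in zip(conditions, best_groups)
    }
    return MatchResult(
        selected=selected,
        std_diffs=std_diffs,
        objective=float(best_obj),
        tolerance_met=bool(best_obj <= spec.max_std_diff),
        excluded_features=excluded,
    )
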