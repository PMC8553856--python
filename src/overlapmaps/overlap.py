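"""Between-city pattern similarity for unique / two-shared / three-shared
trials, and the repulsion difference score.

A trial's sharing class is the number of cities that contain all of its
peripheral stores (the center store belongs to every city and is ignored
throughout this module, as is the city-overlap bookkeeping generally).
Between-city pairs combine correct, uncensored trials presented in runs of
different cities, under condition-specific matching rules:

* ``unique``       — both trials attributable to exactly one city and their
  peripheral store sets disjoint (the clean, unrelated-content baseline);
* ``two_shared``   — identical peripheral store sets attributable to the
  same two cities;
* ``three_shared`` — identical peripheral store sets present in all cities.

Because every run probes a single city, between-city pairs are automatically
cross-run, which avoids within-run temporal autocorrelation.  Cross-task
pairs (spatial x temporal) are included by default to maximize pair counts.

The repulsion score is three_shared_z - unique_z: ~0 indicates pattern
separation (orthogonalized codes), negative values indicate repulsion
(differentiation beyond orthogonalization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CENTER, EnvironmentModel
from .mps import SimilarityResult
from .simulate import PatternSet
from .stats import fisher_z
from .tsnr import PERCENTILE_LEVELS, TSNRMask, masks_all_levels

OVERLAP_CONDITIONS = ("unique", "two_shared", "three_shared")


@dataclass(frozen=True)
class PairRule:
    condition: str
    within_task_only: bool = False

    def __post_init__(self) -> None:
        if self.condition not in OVERLAP_CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


def _trial_keys(meta: pd.DataFrame, env: EnvironmentModel) -> pd.DataFrame:
    """Per-trial peripheral store set, sharing level and store bitmask."""
    stores_arr = meta[["store_top", "store_bl", "store_br"]].to_numpy(int)
    cities = meta["city"].to_numpy(int)
    tasks = meta["task"].to_numpy()
    usable = meta["correct"].to_numpy(bool) & ~meta["censored"].to_numpy(bool)
    level_cache: dict[frozenset[int], str] = {}
    rows = []
    for i in range(len(meta)):
        stores = frozenset(int(s) for s in stores_arr[i]) - {CENTER}
        if stores not in level_cache:
            level_cache[stores] = env.classify_sharing(stores).level
        mask = 0
        for s in stores:
            mask |= 1 << s
        rows.append(
            {
                "trial": i,
                "city": cities[i],
                "task": tasks[i],
                "stores": stores,
                "mask": mask,
                "level": level_cache[stores],
                "usable": bool(usable[i]),
            }
        )
    return pd.DataFrame(rows)


def enumerate_pairs(
    meta: pd.DataFrame,
    env: EnvironmentModel,
    rule: PairRule,
) -> list[tuple[int, int]]:
    """All (i, j) trial-index pairs satisfying the rule, i < j."""
    keys = _trial_keys(meta, env)
    keys = keys[keys["usable"]]
    out: list[tuple[int, int]] = []

    if rule.condition == "unique":
        sub = keys[keys["level"] == "unique"]
        recs = list(sub.itertuples())
        for a in range(len(recs)):
            for b in range(a + 1, len(recs)):
                ra, rb = recs[a], recs[b]
                if ra.city == rb.city:
                    continue
                if ra.mask & rb.mask:
                    continue  # overlapping stores: not a clean baseline pair
                if rule.within_task_only and ra.task != rb.task:
                    continue
                out.append((min(ra.trial, rb.trial), max(ra.trial, rb.trial)))
        return sorted(out)

    level = rule.condition
    sub = keys[keys["level"] == level]
    for _, grp in sub.groupby("stores"):
        recs = list(grp.itertuples())
        for a in range(len(recs)):
            for b in range(a + 1, len(recs)):
                ra, rb = recs[a], recs[b]
                if ra.city == rb.city:
                    continue
                if rule.within_task_only and ra.task != rb.task:
                    continue
                out.append((min(ra.trial, rb.trial), max(ra.trial, rb.trial)))
    return sorted(out)


def _pairwise_r(
    patterns: np.ndarray, pairs: Sequence[tuple[int, int]], voxel_idx: np.ndarray | None
) -> np.ndarray:
    X = patterns if voxel_idx is None else patterns[:, voxel_idx]
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.einsum("ij,ij->i", Xc[i], Xc[j]) / (norms[i] * norms[j])
    return r


def between_city_ps(
    patterns: PatternSet,
    env: EnvironmentModel,
    rule: PairRule,
    tsnr_mask: TSNRMask | None = None,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> SimilarityResult:
    """Mean Fisher-z Pearson r over all pairs satisfying the rule."""
    if pairs is None:
        pairs = enumerate_pairs(patterns.meta, env, rule)
    if not pairs:
        raise ValueError(f"no qualifying pairs for condition {rule.condition!r}")
    voxel_idx = tsnr_mask.kept_voxels if tsnr_mask is not None else None
    r = _pairwise_r(patterns.patterns, pairs, voxel_idx)
    ok = ~np.isnan(r)
    if not ok.any():
        raise ValueError(f"all pairs degenerate for condition {rule.condition!r}")
    z = fisher_z(r[ok])
    return SimilarityResult(
        rule.condition,
        float(np.mean(z)),
        int(ok.sum()),
        patterns.roi_name,
        tsnr_mask.percentile_level if tsnr_mask is not None else None,
        n_dropped=int((~ok).sum()),
    )


def between_city_ps_across_tsnr(
    patterns: PatternSet,
    env: EnvironmentModel,
    within_task_only: bool = False,
    levels: Sequence[int] = PERCENTILE_LEVELS,
) -> dict[str, float]:
    """Mean z per condition, averaged across the eight tSNR levels."""
    masks = masks_all_levels(patterns.voxel_tsnr, patterns.roi_name)
    out: dict[str, list[float]] = {c: [] for c in OVERLAP_CONDITIONS}
    for cond in OVERLAP_CONDITIONS:
        rule = PairRule(cond, within_task_only)
        pairs = enumerate_pairs(patterns.meta, env, rule)
        for lvl in levels:
            out[cond].append(between_city_ps(patterns, env, rule, masks[lvl], pairs).z)
    return {c: float(np.mean(v)) for c, v in out.items()}


def pairlevel_z(
    patterns: PatternSet,
    env: EnvironmentModel,
    rule: PairRule,
    tsnr_mask: TSNRMask | None = None,
) -> np.ndarray:
    """Fisher-z values of every qualifying pair (for paired/two-sample tests)."""
    pairs = enumerate_pairs(patterns.meta, env, rule)
    if not pairs:
        raise ValueError(f"no qualifying pairs for condition {rule.condition!r}")
    voxel_idx = tsnr_mask.kept_voxels if tsnr_mask is not None else None
    r = _pairwise_r(patterns.patterns, pairs, voxel_idx)
    return fisher_z(r[~np.isnan(r)])


def repulsion_score(unique_z: float, three_shared_z: float) -> float:
    """three_shared - unique: negative => repulsion, ~0 => separation."""
    return three_shared_z - unique_z


def subsample_pairs(
    pairs_by_condition: Mapping[str, Sequence[tuple[int, int]]],
    rng: np.random.Generator,
) -> dict[str, list[tuple[int, int]]]:
    """Equal-pair-count control: subsample every condition to the minimum."""
    n_min = min(len(p) for p in pairs_by_condition.values())
    out = {}
    for cond, pairs in pairs_by_condition.items():
        idx = rng.choice(len(pairs), size=n_min, replace=False)
        out[cond] = [pairs[k] for k in np.sort(idx)]
    return out
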