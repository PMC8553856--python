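"""Store templates and the holistic-retrieval pattern-similarity conditions.

A store template is the mean single-trial t pattern across the six localizer
repetitions of that store; it probes whether the store's memory trace is
reinstated during retrieval trials that do not display it.  Three conditions
are formed from template-trial Pearson correlations (Fisher-z transformed,
averaged within condition):

* ``unique_within``  — unique store s of city c  x  correct, uncensored
  trials of c that do not contain s;
* ``unique_between`` — unique store s of city c  x  correct, uncensored
  trials of the other cities;
* ``shared_within``  — shared store s  x  correct, uncensored trials of the
  cities sharing s that do not contain s.

Holistic, environment-specific retrieval predicts
unique_within > unique_between and unique_within > shared_within.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import EnvironmentModel, LOCALIZER_STORES
from .simulate import PatternSet
from .stats import fisher_z
from .tsnr import PERCENTILE_LEVELS, TSNRMask, masks_all_levels

CONDITIONS = ("unique_within", "shared_within", "unique_between")


@dataclass
class StoreTemplate:
    store_id: int
    pattern: np.ndarray
    n_repetitions_used: int


@dataclass(frozen=True)
class SimilarityResult:
    condition: str
    z: float
    n_pairs: int
    roi_name: str = "roi"
    tsnr_level: int | None = None
    n_dropped: int = 0  # zero-variance pairs excluded


def build_store_templates(
    localizer: PatternSet,
    stores: Sequence[int] = LOCALIZER_STORES,
    use_censored: bool = True,
) -> dict[int, StoreTemplate]:
    """Average each old store's localizer repetitions into a template."""
    meta = localizer.meta
    if "old_store" not in meta.columns:
        raise ValueError("localizer metadata must carry an 'old_store' column")
    out = {}
    for s in stores:
        m = (meta["old_store"] == s).to_numpy()
        if not use_censored:
            m &= ~meta["censored"].to_numpy(bool)
        if not m.any():
            raise ValueError(f"store {s} has no usable localizer repetitions")
        out[s] = StoreTemplate(s, localizer.patterns[m].mean(axis=0), int(m.sum()))
    return out


def holistic_pairs(
    template_stores: Iterable[int],
    meta: pd.DataFrame,
    env: EnvironmentModel,
) -> pd.DataFrame:
    """Enumerate (store, trial, condition) pairs for the three conditions.

    Trials must be retrieval trials; incorrect or censored trials never pair.
    Returns a frame with columns store, trial (positional index), condition.
    """
    usable = meta["correct"].to_numpy(bool) & ~meta["censored"].to_numpy(bool)
    trial_city = meta["city"].to_numpy()
    stores_arr = meta[["store_top", "store_bl", "store_br"]].to_numpy(int)
    in_triad = {i: set(stores_arr[i]) for i in range(len(meta))}
    rows = []
    for s in template_stores:
        cities = env.cities_containing(s)
        unique = len(cities) == 1
        for i in np.flatnonzero(usable):
            c = int(trial_city[i])
            contains = s in in_triad[i]
            if unique:
                if c in cities and not contains:
                    rows.append((s, i, "unique_within"))
                elif c not in cities:
                    rows.append((s, i, "unique_between"))
            else:
                if c in cities and not contains:
                    rows.append((s, i, "shared_within"))
    return pd.DataFrame(rows, columns=["store", "trial", "condition"])


def _pair_correlations(
    templates: Mapping[int, StoreTemplate],
    retrieval: PatternSet,
    pairs: pd.DataFrame,
    voxel_idx: np.ndarray | None,
) -> np.ndarray:
    """Pearson r for every (template, trial) pair on the kept voxels.

    Zero-variance patterns yield NaN (callers drop and count them).
    """
    stores = sorted(templates)
    T = np.stack([templates[s].pattern for s in stores])
    X = retrieval.patterns
    if voxel_idx is not None:
        T = T[:, voxel_idx]
        X = X[:, voxel_idx]
    Tc = T - T.mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(Tc, axis=1)
    xn = np.linalg.norm(Xc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Tc @ Xc.T) / np.outer(tn, xn)
    R[:, xn == 0] = np.nan
    R[tn == 0, :] = np.nan
    srow = {s: k for k, s in enumerate(stores)}
    return R[[srow[s] for s in pairs["store"]], pairs["trial"].to_numpy()]


def holistic_ps(
    templates: Mapping[int, StoreTemplate],
    retrieval: PatternSet,
    env: EnvironmentModel,
    tsnr_mask: TSNRMask | None = None,
    pairs: pd.DataFrame | None = None,
) -> dict[str, SimilarityResult]:
    """Fisher-z mean similarity per holistic condition at one tSNR level."""
    if pairs is None:
        pairs = holistic_pairs(templates.keys(), retrieval.meta, env)
    voxel_idx = tsnr_mask.kept_voxels if tsnr_mask is not None else None
    r = _pair_correlations(templates, retrieval, pairs, voxel_idx)
    z = fisher_z(np.where(np.isnan(r), 0.0, r))
    out = {}
    for cond in (c for c in CONDITIONS if (pairs["condition"] == c).any()):
        m = (pairs["condition"] == cond).to_numpy()
        ok = m & ~np.isnan(r)
        if not ok.any():
            raise ValueError(f"condition {cond!r} has only degenerate pairs")
        out[cond] = SimilarityResult(
            cond,
            float(np.asarray(z)[ok].mean()),
            int(ok.sum()),
            retrieval.roi_name,
            tsnr_mask.percentile_level if tsnr_mask is not None else None,
            n_dropped=int((m & np.isnan(r)).sum()),
        )
    return out


def holistic_ps_across_tsnr(
    templates: Mapping[int, StoreTemplate],
    retrieval: PatternSet,
    env: EnvironmentModel,
    levels: Sequence[int] = PERCENTILE_LEVELS,
) -> dict[str, float]:
    """Grand mean z per condition across the eight tSNR percentile levels."""
    masks = masks_all_levels(retrieval.voxel_tsnr, retrieval.roi_name)
    pairs = holistic_pairs(templates.keys(), retrieval.meta, env)
    acc: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    for lvl in levels:
        res = holistic_ps(templates, retrieval, env, masks[lvl], pairs)
        for c in CONDITIONS:
            acc[c].append(res[c].z)
    return {c: float(np.mean(v)) for c, v in acc.items()}


def balanced_pairs(
    pairs: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Subsample every condition to the smallest condition's pair count."""
    n_min = pairs.groupby("condition").size().min()
    keep = []
    for _, grp in pairs.groupby("condition"):
        idx = rng.choice(len(grp), size=n_min, replace=False)
        keep.append(grp.iloc[np.sort(idx)])
    return pd.concat(keep, ignore_index=True)


def similarity_table(results: Mapping[str, SimilarityResult], subject: str | int = 0) -> pd.DataFrame:
    """Tidy TSV-ready table: subject, roi, tsnr_level, condition, z, n_pairs."""
    return pd.DataFrame(
        [
            {
                "subject": subject,
                "roi": r.roi_name,
                "tsnr_level": r.tsnr_level,
                "condition": r.condition,
                "z": r.z,
                "n_pairs": r.n_pairs,
            }
            for r in results.values()
        ]
    )
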