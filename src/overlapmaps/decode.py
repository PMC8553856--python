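"""Decoding analyses: cross-environment generalization and city identity.

* ``svr_leave_one_city_out`` — linear support-vector regression of the
  spatial-distance index, trained on two cities and tested on the third;
  accuracy is the Fisher-z Spearman correlation between actual and predicted
  distances (chance level 0).  Distances are first trimmed to a uniform
  frequency distribution (iteratively removing trials from the over-full
  bin until a Kolmogorov-Smirnov test against the discrete uniform is
  nonsignificant), so the decoder cannot exploit base-rate structure.
* ``svm_interval_leave_one_city_out`` — 3-class linear SVM for the temporal
  interval (16/24/32 s) with class balancing (chance 1/3).
* ``svm_city`` — 3-class linear SVM (C = 1) on the 12 run-level patterns
  under leave-three-runs-out cross-validation: every one-run-per-city
  held-out combination (4^3 = 64) is evaluated and averaged (chance 33.33%).
* ``same_location_mps`` — between-city similarity of trials occupying the
  same layout slots vs different slots, matched on the number of differing
  store identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVC, SVR

from .design import CENTER, EnvironmentModel
from .mps import SimilarityResult
from .simulate import PatternSet
from .stats import fisher_z
from .tsnr import TSNRMask


@dataclass
class DecodeResult:
    scheme: str
    per_city: dict[int, float]
    overall: float
    chance: float
    n_folds: int
    extra: dict = field(default_factory=dict)


class UniformityError(RuntimeError):
    """Raised when a distance bin empties before the KS test passes."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


def _discrete_uniform_cdf(bins: np.ndarray):
    bins = np.sort(bins)

    def cdf(x):
        x = np.atleast_1d(x)
        return np.searchsorted(bins, x, side="right") / len(bins)

    return cdf


def ks_uniformity(values: np.ndarray, bins: np.ndarray) -> tuple[float, float]:
    """KS statistic and p of values against the discrete uniform over bins."""
    res = sps.kstest(values, _discrete_uniform_cdf(bins))
    return float(res.statistic), float(res.pvalue)


def enforce_uniform_distance(
    distances: np.ndarray,
    rng: np.random.Generator,
    alpha: float = 0.05,
    decimals: int = 9,
    bins: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of a trial subset whose distance frequencies are uniform.

    While the KS test against the discrete uniform over the distance bins
    rejects (p <= alpha), one randomly chosen trial is removed from the
    currently over-represented bin (ties broken toward the shortest
    distance, which is the bin that over-fills under this design).  ``bins``
    defaults to the observed distance values; pass the design's full
    distance set to also penalize unobserved distances.
    """
    d = np.round(np.asarray(distances, float), decimals)
    bins = np.unique(d) if bins is None else np.round(np.asarray(bins, float), decimals)
    keep = np.arange(len(d))
    while True:
        stat, p = ks_uniformity(d[keep], bins)
        if p > alpha:
            return np.sort(keep)
        counts = {b: int(np.sum(d[keep] == b)) for b in bins}
        # over-full bin; ties -> smallest distance
        target = min(counts, key=lambda b: (-counts[b], b))
        members = keep[d[keep] == target]
        if len(members) <= 1:
            raise UniformityError(
                "distance bin exhausted before reaching uniformity",
                {"counts": counts, "ks_stat": stat, "p": p, "bin": float(target)},
            )
        drop = members[rng.integers(len(members))]
        keep = keep[keep != drop]


def _spatial_subset(patterns: PatternSet) -> tuple[np.ndarray, pd.DataFrame]:
    meta = patterns.meta
    m = (
        (meta["task"] == "spatial").to_numpy()
        & meta["correct"].to_numpy(bool)
        & ~meta["censored"].to_numpy(bool)
    )
    return patterns.patterns[m], meta[m].reset_index(drop=True)


def svr_leave_one_city_out(
    patterns: PatternSet,
    env: EnvironmentModel,
    rng_seed: int,
    C: float = 1.0,
    epsilon: float = 0.1,
    standardize: bool = False,
    tsnr_mask: TSNRMask | None = None,
    alpha: float = 0.05,
) -> DecodeResult:
    """Leave-one-city-out SVR of the spatial-distance index (chance z = 0)."""
    rng = np.random.default_rng(rng_seed)
    X, meta = _spatial_subset(patterns)
    if tsnr_mask is not None:
        X = X[:, tsnr_mask.kept_voxels]
    keep = enforce_uniform_distance(meta["distance_index"].to_numpy(), rng, alpha)
    X, meta = X[keep], meta.iloc[keep].reset_index(drop=True)
    if standardize:
        X = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)

    y = meta["distance_index"].to_numpy(float)
    city = meta["city"].to_numpy(int)
    per_city: dict[int, float] = {}
    for held in sorted(env.cities):
        test = city == held
        if test.sum() < 3:
            raise ValueError(f"held-out city {held} has fewer than 3 trials")
        model = SVR(kernel="linear", C=C, epsilon=epsilon)
        model.fit(X[~test], y[~test])
        pred = model.predict(X[test])
        rho = sps.spearmanr(y[test], pred).statistic
        per_city[held] = fisher_z(0.0 if np.isnan(rho) else rho)
    overall = float(np.mean(list(per_city.values())))
    return DecodeResult("svr_distance", per_city, overall, 0.0, len(per_city),
                        extra={"n_trials": len(y)})


def _balance_classes(
    labels: np.ndarray,
    idx: np.ndarray,
    rng: np.random.Generator,
    expected: np.ndarray | None = None,
) -> np.ndarray:
    """Subsample ``idx`` so each label occurs equally often."""
    classes, counts = np.unique(labels[idx], return_counts=True)
    if expected is not None and set(classes) != set(expected):
        missing = sorted(set(expected) - set(classes))
        raise ValueError(f"class(es) {missing} empty in this fold")
    n = counts.min()
    keep = []
    for cl in classes:
        members = idx[labels[idx] == cl]
        keep.append(rng.choice(members, size=n, replace=False))
    return np.sort(np.concatenate(keep))


def svm_interval_leave_one_city_out(
    patterns: PatternSet,
    rng_seed: int,
    C: float = 1.0,
    tsnr_mask: TSNRMask | None = None,
) -> DecodeResult:
    """Leave-one-city-out 3-class SVM for temporal interval (chance 1/3)."""
    rng = np.random.default_rng(rng_seed)
    meta = patterns.meta
    m = (
        (meta["task"] == "temporal").to_numpy()
        & meta["correct"].to_numpy(bool)
        & ~meta["censored"].to_numpy(bool)
    )
    X = patterns.patterns[m]
    if tsnr_mask is not None:
        X = X[:, tsnr_mask.kept_voxels]
    sub = meta[m].reset_index(drop=True)
    y = sub["interval_index"].to_numpy(int)
    city = sub["city"].to_numpy(int)

    expected = np.unique(y)
    per_city: dict[int, float] = {}
    for held in sorted(np.unique(city)):
        train = _balance_classes(y, np.flatnonzero(city != held), rng, expected)
        test = _balance_classes(y, np.flatnonzero(city == held), rng, expected)
        model = SVC(kernel="linear", C=C)
        model.fit(X[train], y[train])
        per_city[int(held)] = float(np.mean(model.predict(X[test]) == y[test]))
    overall = float(np.mean(list(per_city.values())))
    return DecodeResult("svm_interval", per_city, overall, 1.0 / 3.0, len(per_city))


def svm_city(
    run_patterns: np.ndarray,
    run_cities: np.ndarray,
    C: float = 1.0,
    expected_cities: tuple[int, ...] = (1, 2, 3),
) -> DecodeResult:
    """City classification of run-level patterns, leave-three-runs-out.

    Every combination holding out exactly one run per city is evaluated (all
    4^3 = 64 with the standard 4-runs-per-city design) and accuracies are
    averaged; this enumeration is deterministic.
    """
    X = np.asarray(run_patterns, float)
    labels = np.asarray(run_cities, int)
    cities = sorted(expected_cities)
    runs_by_city = {c: np.flatnonzero(labels == c) for c in cities}
    for c, runs in runs_by_city.items():
        if len(runs) == 0:
            raise ValueError(f"missing run maps for city {c}")

    correct = {c: [] for c in cities}
    n_folds = 0
    for held in product(*(runs_by_city[c] for c in cities)):
        test = np.array(held)
        train = np.setdiff1d(np.arange(len(labels)), test)
        model = SVC(kernel="linear", C=C, decision_function_shape="ovo")
        model.fit(X[train], labels[train])
        pred = model.predict(X[test])
        for c, p in zip(cities, pred):
            correct[c].append(float(p == c))
        n_folds += 1
    per_city = {c: float(np.mean(v)) for c, v in correct.items()}
    overall = float(np.mean([v for vs in correct.values() for v in vs]))
    return DecodeResult("svm_city", per_city, overall, 1.0 / 3.0, n_folds)


# ---------------------------------------------------------------------------
# same-location vs different-location MPS
# ---------------------------------------------------------------------------

def _slot_key(row: pd.Series, env: EnvironmentModel) -> frozenset[int]:
    slots = set()
    for k in ("store_top", "store_bl", "store_br"):
        s = int(row[k])
        if s != CENTER:
            slots.add(env.slot_of(s))
    return frozenset(slots)


def same_location_pairs(
    meta: pd.DataFrame, env: EnvironmentModel
) -> pd.DataFrame:
    """Between-city trial pairs labeled same/different location + store diff count.

    Same-location pairs occupy identical layout slot sets in different
    cities; different-location pairs occupy different slot sets.  ``n_diff``
    counts differing peripheral store identities, the matching variable.
    """
    usable = np.flatnonzero(
        meta["correct"].to_numpy(bool) & ~meta["censored"].to_numpy(bool)
    )
    info = []
    for i in usable:
        row = meta.iloc[i]
        stores = frozenset(
            int(row[k]) for k in ("store_top", "store_bl", "store_br")
        ) - {CENTER}
        info.append((i, int(row["city"]), _slot_key(row, env), stores))
    rows = []
    for a in range(len(info)):
        for b in range(a + 1, len(info)):
            ia, ca, ka, sa = info[a]
            ib, cb, kb, sb = info[b]
            if ca == cb or len(ka) != len(kb):
                continue
            n_diff = len(sa - sb)
            rows.append(
                {
                    "i": ia,
                    "j": ib,
                    "location": "same" if ka == kb else "different",
                    "n_stores": len(sa),  # spatial (3) vs temporal (2) geometry
                    "n_diff": n_diff,
                }
            )
    return pd.DataFrame(rows)


def same_location_mps(
    patterns: PatternSet,
    env: EnvironmentModel,
    tsnr_mask: TSNRMask | None = None,
) -> tuple[dict[str, SimilarityResult], float, list[tuple[int, int]]]:
    """Same- vs matched different-location between-city similarity.

    The different-location mean is reweighted so its distribution over
    store-difference counts matches the same-location pair set; strata with
    no matched different-location pair are dropped (returned for logging).
    Returns ({'same_location', 'different_location'}, contrast, dropped strata).
    """
    pairs = same_location_pairs(patterns.meta, env)
    if pairs.empty or not (pairs["location"] == "same").any():
        raise ValueError("no same-location between-city pairs available")
    voxel_idx = tsnr_mask.kept_voxels if tsnr_mask is not None else None
    X = patterns.patterns if voxel_idx is None else patterns.patterns[:, voxel_idx]
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    i = pairs["i"].to_numpy()
    j = pairs["j"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.einsum("ij,ij->i", Xc[i], Xc[j]) / (norms[i] * norms[j])
    z = fisher_z(np.where(np.isnan(r), 0.0, r))
    pairs = pairs.assign(z=np.asarray(z), bad=np.isnan(r))
    pairs = pairs[~pairs["bad"]]

    same = pairs[pairs["location"] == "same"]
    diff = pairs[pairs["location"] == "different"]
    strata = same.groupby(["n_stores", "n_diff"]).size()
    dropped: list[tuple[int, int]] = []
    z_same_parts, z_diff_parts, weights = [], [], []
    for (n_stores, n_diff), n_same in strata.items():
        d = diff[(diff["n_diff"] == n_diff) & (diff["n_stores"] == n_stores)]
        if d.empty:
            dropped.append((int(n_stores), int(n_diff)))
            continue
        s = same[(same["n_diff"] == n_diff) & (same["n_stores"] == n_stores)]
        z_same_parts.append(s["z"].mean())
        z_diff_parts.append(d["z"].mean())
        weights.append(n_same)
    if not weights:
        raise ValueError("no matched different-location pairs in any stratum")
    w = np.asarray(weights, float) / np.sum(weights)
    z_same = float(np.dot(w, z_same_parts))
    z_diff = float(np.dot(w, z_diff_parts))
    results = {
        "same_location": SimilarityResult(
            "same_location", z_same, int(same.shape[0]), patterns.roi_name,
            tsnr_mask.percentile_level if tsnr_mask else None,
        ),
        "different_location": SimilarityResult(
            "different_location", z_diff, int(diff.shape[0]), patterns.roi_name,
            tsnr_mask.percentile_level if tsnr_mask else None,
        ),
    }
    return results, z_same - z_diff, dropped
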