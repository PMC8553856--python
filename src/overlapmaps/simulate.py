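"""Synthetic single-trial voxel patterns with planted, recoverable effects.

The generator realizes each representational hypothesis the analyses test as
an explicit latent construction at "neuron" level, then mixes neurons into
voxels through a nonnegative pooling matrix:

* ``eta_holistic`` — trials of a city incidentally reinstate that city's
  *unpresented* unique stores (holistic retrieval).
* ``rho_shared``  — a store shared between k cities has one latent code per
  city; their pairwise Pearson correlation is imposed *exactly* at
  ``rho_shared`` through a Gram-matrix factorization (>0 shared code,
  0 pattern separation, <0 repulsion).
* ``beta_schema`` — a voxel subset carries a linear code for the spatial
  distance index, common to all cities (spatial schema).
* ``gamma_city``  — an additive city-identity code.
* ``beta_slot``   — an additive code per occupied layout slot, common to all
  cities (same-location signal).
* ``kappa_interval`` — an additive code per temporal-interval category,
  shared across cities or (optionally) city-specific.

Trial noise is i.i.d. Gaussian per voxel with a standard deviation scaled
inversely to that voxel's temporal SNR, so low-tSNR voxels are genuinely
noisier and the tSNR percentile filter is consequential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .design import CENTER, EnvironmentModel, FILLER_STORES, triad_from_row


@dataclass
class EffectSpec:
    """Latent effect strengths planted in the synthetic patterns."""

    eta_holistic: float = 0.0
    rho_shared: float | Mapping[int, float] = 0.0  # scalar, or {n_cities: rho}
    beta_schema: float = 0.0  # pattern units per length unit of distance index
    gamma_city: float = 0.0
    beta_slot: float = 0.0
    kappa_interval: float = 0.0
    interval_code_shared: bool = True
    # the center store appears in every temporal trial of every city, so its
    # identity code is a task-common component; default 0 keeps the null
    # calibration of the between-city contrasts exact.
    center_amplitude: float = 0.0
    sigma_noise: float = 1.0  # per-trial voxel noise SD at the reference tSNR
    tsnr_median: float = 40.0  # lognormal tSNR profile across voxels
    tsnr_sigma: float = 0.3

    def __post_init__(self) -> None:
        for name in ("eta_holistic", "beta_schema", "gamma_city", "beta_slot",
                     "kappa_interval", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for k, rho in self._rho_items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"rho_shared must lie in [-1, 1], got {rho}")
            # a k-city equicorrelation matrix is PSD iff rho >= -1/(k-1)
            if k > 1 and rho < -1.0 / (k - 1) - 1e-12:
                raise ValueError(
                    f"rho_shared={rho} is not achievable for a store shared by "
                    f"{k} cities (requires rho >= {-1.0 / (k - 1):.3f})"
                )

    def _rho_items(self):
        if isinstance(self.rho_shared, Mapping):
            return [(int(k), float(v)) for k, v in self.rho_shared.items()]
        return [(2, float(self.rho_shared)), (3, float(self.rho_shared))]

    def rho_for(self, n_cities: int) -> float:
        if isinstance(self.rho_shared, Mapping):
            return float(self.rho_shared[n_cities])
        return float(self.rho_shared)

    @classmethod
    def from_yaml(cls, path) -> "EffectSpec":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class NeuronToVoxelMap:
    """Nonnegative pooling of latent neurons into voxels."""

    weights: np.ndarray  # (n_neurons, n_voxels)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.ndim != 2 or np.any(w < 0):
            raise ValueError("weights must be a nonnegative 2-D matrix")
        if np.any(w.sum(axis=0) <= 0):
            raise ValueError("every voxel must pool at least one neuron")
        self.weights = w

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[1]


@dataclass
class PatternSet:
    """Trials-by-voxels t-statistic patterns plus aligned trial metadata."""

    patterns: np.ndarray  # (n_trials, n_voxels)
    meta: pd.DataFrame
    voxel_tsnr: np.ndarray
    roi_name: str = "roi"

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, float)
        self.voxel_tsnr = np.asarray(self.voxel_tsnr, float)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be 2-D (trials x voxels)")
        if len(self.meta) != self.patterns.shape[0]:
            raise ValueError("meta rows must align 1:1 with pattern rows")
        if self.voxel_tsnr.shape != (self.patterns.shape[1],):
            raise ValueError("voxel_tsnr length must equal n_voxels")
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("patterns contain non-finite entries")

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]


@dataclass
class StoreCodes:
    """Latent neuron-level codes for stores and auxiliary signals."""

    by_store_city: dict[tuple[int, int], np.ndarray]
    city_codes: dict[int, np.ndarray]
    schema_direction: np.ndarray
    slot_codes: dict[int, np.ndarray]
    interval_codes: dict[tuple[int, int | None], np.ndarray]  # (interval, city|None)
    center_code: np.ndarray
    filler_codes: dict[int, np.ndarray]
    n_neurons: int

    def localizer_code(self, store: int) -> np.ndarray:
        """A store's city-independent code: the mean of its per-city codes."""
        vs = [v for (s, _c), v in self.by_store_city.items() if s == store]
        if not vs:
            raise KeyError(f"no codes for store {store}")
        return np.mean(vs, axis=0)


def rng_for(seed: int, *labels: int) -> np.random.Generator:
    """Named substream: all randomness flows from one root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(labels)))


def _zero_mean_orthonormal(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """m orthonormal n-vectors, each exactly orthogonal to the constant vector.

    Zero mean + orthonormality make sample Pearson correlations between any
    linear combinations equal their construction Gram matrix exactly.
    """
    if m >= n:
        raise ValueError("need n_neurons > number of latent directions")
    g = rng.standard_normal((n, m + 1))
    g[:, 0] = 1.0  # absorb the constant direction first
    q, _ = np.linalg.qr(g)
    return q[:, 1:]


def _equicorr_factor(k: int, rho: float) -> np.ndarray:
    """A with A @ A.T == the k x k equicorrelation matrix (eigen square root)."""
    gram = np.full((k, k), rho)
    np.fill_diagonal(gram, 1.0)
    w, v = np.linalg.eigh(gram)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def make_store_codes(
    env: EnvironmentModel,
    effect: EffectSpec,
    rng_seed: int,
    n_neurons: int = 200,
) -> StoreCodes:
    """Draw latent codes: one vector per (store, city), exact cross-city rho.

    Distinct stores (and all auxiliary codes) occupy mutually orthogonal
    directions; within a shared store, the per-city vectors have pairwise
    Pearson correlation exactly ``rho_shared``.
    """
    rng = rng_for(rng_seed, 0)
    stores = sorted(env.all_stores - {CENTER})
    share = {s: sorted(env.cities_containing(s)) for s in stores}
    intervals = (16, 24, 32)

    n_dirs = sum(len(cs) for cs in share.values())  # per-store-city directions
    n_aux = 1 + len(env.cities) + 1 + env.n_slots  # center + city + schema + slots
    n_interval = len(intervals) * (1 if effect.interval_code_shared else len(env.cities))
    basis = _zero_mean_orthonormal(n_neurons, n_dirs + n_aux + n_interval, rng)
    basis = basis * math.sqrt(n_neurons)  # unit per-neuron variance
    cols = iter(range(basis.shape[1]))

    by_store_city: dict[tuple[int, int], np.ndarray] = {}
    for s in stores:
        cities = share[s]
        block = np.column_stack([basis[:, next(cols)] for _ in cities])
        if len(cities) == 1:
            vecs = block
        else:
            A = _equicorr_factor(len(cities), effect.rho_for(len(cities)))
            vecs = block @ A.T
        for j, c in enumerate(cities):
            by_store_city[(s, c)] = vecs[:, j]

    center_code = basis[:, next(cols)]
    city_codes = {c: basis[:, next(cols)] for c in sorted(env.cities)}
    schema_direction = basis[:, next(cols)]
    slot_codes = {slot: basis[:, next(cols)] for slot in range(env.n_slots)}
    interval_codes: dict[tuple[int, int | None], np.ndarray] = {}
    if effect.interval_code_shared:
        for t in intervals:
            interval_codes[(t, None)] = basis[:, next(cols)]
    else:
        for c in sorted(env.cities):
            for t in intervals:
                interval_codes[(t, c)] = basis[:, next(cols)]

    filler_rng = rng_for(rng_seed, 1)
    filler_codes = {
        f: _demean(filler_rng.standard_normal(n_neurons)) for f in FILLER_STORES
    }
    return StoreCodes(
        by_store_city=by_store_city,
        city_codes=city_codes,
        schema_direction=schema_direction,
        slot_codes=slot_codes,
        interval_codes=interval_codes,
        center_code=center_code,
        filler_codes=filler_codes,
        n_neurons=n_neurons,
    )


def _demean(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def make_neuron_to_voxel_map(
    n_neurons: int,
    n_voxels: int,
    rng_seed: int,
    pool_size: int = 12,
) -> NeuronToVoxelMap:
    """Each voxel pools ``pool_size`` random neurons with gamma weights."""
    rng = rng_for(rng_seed, 2)
    w = np.zeros((n_neurons, n_voxels))
    for v in range(n_voxels):
        idx = rng.choice(n_neurons, size=pool_size, replace=False)
        weights = rng.gamma(shape=1.0, size=pool_size)
        w[idx, v] = weights / np.linalg.norm(weights)
    return NeuronToVoxelMap(w)


def draw_voxel_tsnr(n_voxels: int, effect: EffectSpec, rng: np.random.Generator) -> np.ndarray:
    return effect.tsnr_median * np.exp(rng.normal(0.0, effect.tsnr_sigma, n_voxels))


def neuron_signal_for_trial(
    row: pd.Series,
    codes: StoreCodes,
    effect: EffectSpec,
    env: EnvironmentModel,
) -> np.ndarray:
    """Deterministic neuron-level signal for one trial row of a schedule."""
    s = np.zeros(codes.n_neurons)
    if row["task"] == "localizer":
        for key in ("store_top", "store_bl", "store_br"):
            sid = int(row[key])
            if sid in codes.filler_codes:
                s += codes.filler_codes[sid]
            elif sid == CENTER:
                s += codes.center_code
            else:
                s += codes.localizer_code(sid)
        return s

    city = int(row["city"])
    triad = triad_from_row(row)
    for sid in triad.stores:
        if sid == CENTER:
            s += effect.center_amplitude * codes.center_code
        else:
            s += codes.by_store_city[(sid, city)]
    if effect.eta_holistic > 0:
        for sid in env.cities[city]:
            if sid not in triad.stores and len(env.cities_containing(sid)) == 1:
                s += effect.eta_holistic * codes.by_store_city[(sid, city)]
    if effect.gamma_city > 0:
        s += effect.gamma_city * codes.city_codes[city]
    if effect.beta_slot > 0:
        for sid in triad.peripheral_stores:
            s += effect.beta_slot * codes.slot_codes[env.slot_of(sid)]
    if effect.beta_schema > 0 and row["task"] == "spatial":
        s += effect.beta_schema * float(row["distance_index"]) * codes.schema_direction
    if effect.kappa_interval > 0 and row["task"] == "temporal":
        key = (int(row["interval_index"]), None if effect.interval_code_shared else city)
        s += effect.kappa_interval * codes.interval_codes[key]
    return s


def simulate_trial_patterns(
    schedule: pd.DataFrame,
    codes: StoreCodes,
    mapping: NeuronToVoxelMap,
    effect: EffectSpec,
    rng_seed: int,
    env: EnvironmentModel,
    roi_name: str = "roi",
) -> PatternSet:
    """Compose planted signals + tSNR-scaled noise into a trials x voxels set."""
    if mapping.n_neurons != codes.n_neurons:
        raise ValueError("neuron count mismatch between codes and mapping")
    rng = rng_for(rng_seed, 3)
    signal = np.stack(
        [
            neuron_signal_for_trial(row, codes, effect, env)
            for row in schedule.to_dict("records")
        ]
    )
    vox = signal @ mapping.weights
    tsnr = draw_voxel_tsnr(mapping.n_voxels, effect, rng)
    noise_sd = effect.sigma_noise * (effect.tsnr_median / tsnr)
    vox = vox + rng.standard_normal(vox.shape) * noise_sd
    return PatternSet(vox, schedule.reset_index(drop=True), tsnr, roi_name)


def simulate_roi_patterns(
    schedule: pd.DataFrame,
    effects: Mapping[str, EffectSpec],
    rng_seed: int,
    env: EnvironmentModel,
    n_neurons: int = 200,
    n_voxels: int = 100,
) -> dict[str, PatternSet]:
    """Independent codes, mixing and noise per ROI (one EffectSpec each)."""
    out = {}
    for i, (roi, effect) in enumerate(effects.items()):
        codes = make_store_codes(env, effect, rng_seed + 7919 * (i + 1) % 2**31, n_neurons)
        mapping = make_neuron_to_voxel_map(n_neurons, n_voxels, rng_seed + 104729 * (i + 1) % 2**31)
        out[roi] = simulate_trial_patterns(
            schedule, codes, mapping, effect, rng_seed + 1299709 * (i + 1) % 2**31, env, roi
        )
    return out


def simulate_run_patterns(
    patterns: PatternSet,
    remembered_only: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Run-level patterns: per-run mean of (remembered) trial patterns.

    Returns (run_patterns, run_cities) sorted by run index.  A pattern-level
    shortcut for the run-GLM estimates used by the city classifier.
    """
    meta = patterns.meta
    keep = np.ones(len(meta), bool)
    if remembered_only:
        keep &= meta["correct"].to_numpy(bool) & ~meta["censored"].to_numpy(bool)
    runs = sorted(meta["run"].unique())
    maps, cities = [], []
    for r in runs:
        idx = keep & (meta["run"] == r).to_numpy()
        if not idx.any():
            raise ValueError(f"run {r} has no remembered trials")
        maps.append(patterns.patterns[idx].mean(axis=0))
        cities.append(int(meta.loc[idx, "city"].iloc[0]))
    return np.stack(maps), np.asarray(cities)


def simulate_null_run_patterns(
    n_voxels: int,
    rng_seed: int,
    runs_per_city: int = 4,
    cities: tuple[int, ...] = (1, 2, 3),
) -> tuple[np.ndarray, np.ndarray]:
    """Pure-noise run-level patterns carrying no city information."""
    rng = rng_for(rng_seed, 4)
    labels = np.repeat(cities, runs_per_city)
    order = rng.permutation(len(labels))
    return rng.standard_normal((len(labels), n_voxels)), labels[order]


# ---------------------------------------------------------------------------
# BOLD time-series simulation
# ---------------------------------------------------------------------------

TR_S = 2.59  # repetition time of the acquisition sequence


def simulate_bold(
    schedule_run: pd.DataFrame,
    patterns: np.ndarray,
    rng_seed: int,
    tr: float = TR_S,
    ar_coef: float = 0.3,
    noise_sd: float = 1.0,
    fd_spike_prob: float = 0.0,
    fd_spike_mm: float = 1.0,
    hrf_model: str = "spm",
    pad_s: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """HRF-convolved trial responses + AR(1) noise for one run.

    ``patterns`` is (n_trials, n_voxels): each trial's response amplitude per
    voxel.  Returns (bold (n_scans, n_voxels), frame_times, fd_trace).
    The framewise-displacement trace has i.i.d. spikes of ``fd_spike_mm`` mm
    with probability ``fd_spike_prob`` per frame (censor threshold: 0.5 mm).
    """
    from .glm import trial_design  # deferred: avoids an import cycle

    rng = rng_for(rng_seed, 5)
    onsets = schedule_run["onset"].to_numpy(float)
    durations = schedule_run["duration"].to_numpy(float)
    n_scans = int(math.ceil((onsets[-1] + durations[-1] + pad_s) / tr))
    frame_times = np.arange(n_scans) * tr
    X = trial_design(onsets, durations, frame_times, hrf_model=hrf_model)
    clean = X @ patterns

    w = rng.standard_normal(clean.shape) * noise_sd * math.sqrt(1.0 - ar_coef**2)
    noise = np.empty_like(w)
    noise[0] = rng.standard_normal(clean.shape[1]) * noise_sd
    for t in range(1, len(w)):
        noise[t] = ar_coef * noise[t - 1] + w[t]

    fd = np.where(rng.random(n_scans) < fd_spike_prob, fd_spike_mm, 0.05)
    return clean + noise, frame_times, fd


def censored_trials_from_fd(
    schedule_run: pd.DataFrame,
    frame_times: np.ndarray,
    fd: np.ndarray,
    threshold_mm: float = 0.5,
) -> np.ndarray:
    """True where any frame within a trial's modeled response exceeds FD 0.5 mm."""
    flags = []
    for _, row in schedule_run.iterrows():
        on, off = row["onset"], row["onset"] + row["duration"]
        in_trial = (frame_times >= on) & (frame_times < off)
        flags.append(bool(np.any(fd[in_trial] > threshold_mm)))
    return np.asarray(flags)
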