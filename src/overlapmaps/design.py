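"""Experimental design model: cities, stores, triads and trial schedules.

Three virtual cities share a single circular layout: six peripheral stores on
a circle plus one center store ("Camera Store") common to all cities.  City
identity is carried only by *which* store occupies each peripheral slot:

* City 1 = stores {1, 2, 3, 4, 5, 6}
* City 2 = stores {1, 2, 3, 5, 6, 7}   (store 7 replaces store 4)
* City 3 = stores {1, 3, 5, 7, 8, 9}   (stores 8, 9 replace stores 2, 6)

so cities 1-2 overlap in 5 stores, 2-3 in 4 and 1-3 in 3, and a store keeps
the same physical slot in every city it belongs to.  Travel duration from the
center is 8 s for stores {3, 5, 6, 9} and 16 s for {1, 2, 4, 7, 8}.

Everything downstream (synthetic data, pattern-similarity labeling, decoding
folds) derives its labels from this module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CENTER = 0  #: store id of the central "Camera Store"

#: peripheral slot index (0..5 around the circle) per store id
DEFAULT_SLOTS: dict[int, int] = {1: 0, 2: 1, 3: 2, 4: 3, 5: 4, 6: 5, 7: 3, 8: 1, 9: 5}

#: travel duration (s) from the center store
DEFAULT_DURATIONS: dict[int, int] = {3: 8, 5: 8, 6: 8, 9: 8, 1: 16, 2: 16, 4: 16, 7: 16, 8: 16}

DEFAULT_CITIES: dict[int, frozenset[int]] = {
    1: frozenset({1, 2, 3, 4, 5, 6}),
    2: frozenset({1, 2, 3, 5, 6, 7}),
    3: frozenset({1, 3, 5, 7, 8, 9}),
}

#: slow event-related trial timing (seconds)
TRIAL_DURATION_S = 18.13
STIMULUS_S = 9.0
BASELINE_S = 7.77
N_RETRIEVAL_RUNS = 12
TRIALS_PER_RUN = 15
LOCALIZER_RUNS = 2
LOCALIZER_TRIALS_PER_RUN = 18
#: stores probed in the localizer ("old" stores with templates)
LOCALIZER_STORES = (2, 4, 6, 7, 8, 9)
#: ids used for unstudied filler stores shown only in the localizer
FILLER_STORES = tuple(range(101, 125))

EQUALITY_TOL = 1e-9


@dataclass(frozen=True)
class Store:
    """A store and its physical slot on the circular layout."""

    id: int
    angle: float  # radians; NaN-free, CENTER uses 0.0
    radius: float
    duration_s: int | None  # travel time from center; None for CENTER

    @property
    def xy(self) -> tuple[float, float]:
        return (self.radius * math.cos(self.angle), self.radius * math.sin(self.angle))


@dataclass(frozen=True)
class SharingClass:
    """How many cities a store or triad can be attributed to."""

    level: str  # 'unique' | 'two_shared' | 'three_shared'
    attributable_cities: frozenset[int]


@dataclass(frozen=True)
class Triad:
    """One probe display: a top store and two bottom stores from one city."""

    top: int
    bottom_left: int
    bottom_right: int
    task: str  # 'spatial' | 'temporal'
    city: int

    def __post_init__(self) -> None:
        if len({self.top, self.bottom_left, self.bottom_right}) != 3:
            raise ValueError(f"triad stores must be distinct: {self}")
        if self.task not in ("spatial", "temporal"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == "temporal" and self.top != CENTER:
            raise ValueError("temporal triads must have the center store on top")

    @property
    def stores(self) -> frozenset[int]:
        return frozenset({self.top, self.bottom_left, self.bottom_right})

    @property
    def peripheral_stores(self) -> frozenset[int]:
        return self.stores - {CENTER}


LEVEL_BY_COUNT = {1: "unique", 2: "two_shared", 3: "three_shared"}


@dataclass(frozen=True)
class EnvironmentModel:
    """The three city store-sets plus shared coordinates and durations."""

    cities: Mapping[int, frozenset[int]]
    slots: Mapping[int, int]
    durations: Mapping[int, int]
    radius: float = 1.0
    n_slots: int = 6

    def __post_init__(self) -> None:
        for cid, stores in self.cities.items():
            if len(stores) != self.n_slots:
                raise ValueError(f"city {cid} must have {self.n_slots} peripheral stores")
            if CENTER in stores:
                raise ValueError("city sets list peripheral stores only")
            used = [self.slots[s] for s in stores]
            if len(set(used)) != self.n_slots:
                raise ValueError(f"city {cid} has duplicate slot assignments")
        for s, d in self.durations.items():
            if d not in (8, 16):
                raise ValueError(f"store {s}: duration must be 8 or 16 s, got {d}")
        cache = {CENTER: np.zeros(2)}
        for s in self.slots:
            a = 2.0 * math.pi * self.slots[s] / self.n_slots
            cache[s] = np.array([self.radius * math.cos(a), self.radius * math.sin(a)])
        object.__setattr__(self, "_coords", cache)

    # -- geometry -----------------------------------------------------------
    def store(self, store_id: int) -> Store:
        if store_id == CENTER:
            return Store(CENTER, 0.0, 0.0, None)
        if store_id not in self.slots:
            raise KeyError(f"unknown store id {store_id}")
        angle = 2.0 * math.pi * self.slots[store_id] / self.n_slots
        return Store(store_id, angle, self.radius, self.durations[store_id])

    def coords(self, store_id: int) -> np.ndarray:
        try:
            return self._coords[store_id]
        except KeyError:
            raise KeyError(f"unknown store id {store_id}") from None

    def slot_of(self, store_id: int) -> int | None:
        """Peripheral slot index, or None for the center store."""
        if store_id == CENTER:
            return None
        if store_id not in self.slots:
            raise KeyError(f"unknown store id {store_id}")
        return self.slots[store_id]

    # -- membership ---------------------------------------------------------
    @property
    def all_stores(self) -> frozenset[int]:
        out: set[int] = {CENTER}
        for stores in self.cities.values():
            out |= stores
        return frozenset(out)

    def cities_containing(self, store_id: int) -> frozenset[int]:
        if store_id == CENTER:
            return frozenset(self.cities)
        if store_id not in self.slots:
            raise KeyError(f"unknown store id {store_id}")
        return frozenset(c for c, stores in self.cities.items() if store_id in stores)

    def overlap(self, city_a: int, city_b: int) -> frozenset[int]:
        """Peripheral stores common to two cities (center excluded)."""
        return self.cities[city_a] & self.cities[city_b]

    def classify_sharing(self, stores: int | Iterable[int]) -> SharingClass:
        """Attribute a store or a triad's store set to the cities containing it.

        A triad is attributable to a city iff every member store belongs to it.
        The center store belongs to every city and so never restricts the set.
        """
        if isinstance(stores, int):
            stores = [stores]
        cities: frozenset[int] | None = None
        for s in stores:
            cs = self.cities_containing(s)
            cities = cs if cities is None else cities & cs
        if cities is None or not cities:
            raise ValueError("store set is not attributable to any city")
        return SharingClass(LEVEL_BY_COUNT[len(cities)], cities)

    # -- serialization ------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "cities": {str(c): sorted(s) for c, s in self.cities.items()},
            "slots": {str(k): v for k, v in self.slots.items()},
            "durations": {str(k): v for k, v in self.durations.items()},
            "radius": self.radius,
            "n_slots": self.n_slots,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EnvironmentModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            cities={int(k): frozenset(v) for k, v in d["cities"].items()},
            slots={int(k): v for k, v in d["slots"].items()},
            durations={int(k): v for k, v in d["durations"].items()},
            radius=d["radius"],
            n_slots=d["n_slots"],
        )


def build_environment(config: Mapping | None = None) -> EnvironmentModel:
    """Build the (default) three-city environment model.

    ``config`` may override ``cities``, ``slots``, ``durations``, ``radius``;
    invalid definitions (wrong store count, duplicate slots) are rejected.
    """
    config = dict(config or {})
    return EnvironmentModel(
        cities={int(k): frozenset(v) for k, v in config.get("cities", DEFAULT_CITIES).items()},
        slots=dict(config.get("slots", DEFAULT_SLOTS)),
        durations=dict(config.get("durations", DEFAULT_DURATIONS)),
        radius=float(config.get("radius", 1.0)),
    )


# ---------------------------------------------------------------------------
# distance / interval indices
# ---------------------------------------------------------------------------

def spatial_distance_index(triad: Triad, env: EnvironmentModel) -> float:
    """Sum of the two top-to-bottom Euclidean distances of a spatial triad."""
    if triad.task != "spatial":
        raise ValueError("spatial_distance_index requires a spatial triad")
    top = env.coords(triad.top)
    d1 = float(np.linalg.norm(top - env.coords(triad.bottom_left)))
    d2 = float(np.linalg.norm(top - env.coords(triad.bottom_right)))
    return d1 + d2


def temporal_interval_index(triad: Triad, env: EnvironmentModel) -> int:
    """Sum of the travel durations of the two bottom stores (top = center)."""
    if triad.task != "temporal" or triad.top != CENTER:
        raise ValueError("temporal_interval_index requires a center-topped temporal triad")
    return env.durations[triad.bottom_left] + env.durations[triad.bottom_right]


def triad_equality(triad: Triad, env: EnvironmentModel) -> str:
    """'equal' when the two comparison legs tie (within 1e-9), else 'unequal'."""
    if triad.task == "spatial":
        top = env.coords(triad.top)
        d1 = float(np.linalg.norm(top - env.coords(triad.bottom_left)))
        d2 = float(np.linalg.norm(top - env.coords(triad.bottom_right)))
        return "equal" if abs(d1 - d2) <= EQUALITY_TOL else "unequal"
    d1 = env.durations[triad.bottom_left]
    d2 = env.durations[triad.bottom_right]
    return "equal" if d1 == d2 else "unequal"


def enumerate_spatial_triads(env: EnvironmentModel, city: int) -> list[Triad]:
    """All ordered-top spatial triads of a city (bottom pair unordered)."""
    stores = sorted(env.cities[city])
    out = []
    for top in stores:
        rest = [s for s in stores if s != top]
        for i in range(len(rest)):
            for j in range(i + 1, len(rest)):
                out.append(Triad(top, rest[i], rest[j], "spatial", city))
    return out


def enumerate_temporal_triads(env: EnvironmentModel, city: int) -> list[Triad]:
    stores = sorted(env.cities[city])
    return [
        Triad(CENTER, stores[i], stores[j], "temporal", city)
        for i in range(len(stores))
        for j in range(i + 1, len(stores))
    ]


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

#: triads guaranteed to recur across cities so that the between-city
#: pattern-similarity conditions always have matched pairs.  Values are
#: (top, bottom_left, bottom_right) store tuples; keys are city ids.
_SPATIAL_ANCHORS: dict[int, list[tuple[int, int, int]]] = {
    # {1,3,5}: the only store set present in all three cities (equal triad);
    # {2,3,6}: shared by cities 1-2 only; {3,5,7}: shared by cities 2-3 only;
    # last entry per city: a store set unique to that city, pairwise disjoint
    # across cities so the unique-trial between-city baseline has legal pairs.
    1: [(1, 3, 5), (3, 2, 6), (4, 1, 5)],
    2: [(1, 3, 5), (3, 2, 6), (7, 3, 5), (7, 2, 6)],
    3: [(1, 3, 5), (7, 3, 5), (3, 8, 9)],
}


def _run_city_order(rng: np.random.Generator) -> list[int]:
    """Six-run city order: two blocks of a 1-2-3 permutation, no immediate repeat."""
    first = list(rng.permutation([1, 2, 3]))
    while True:
        second = list(rng.permutation([1, 2, 3]))
        if second[0] != first[-1]:
            return first + second


def _spatial_pools(env: EnvironmentModel, city: int) -> tuple[list[Triad], list[Triad]]:
    pool = enumerate_spatial_triads(env, city)
    eq = [t for t in pool if triad_equality(t, env) == "equal"]
    uneq = [t for t in pool if triad_equality(t, env) == "unequal"]
    return eq, uneq


def _sample_spatial_run(
    env: EnvironmentModel,
    city: int,
    rng: np.random.Generator,
    pools: tuple[list[Triad], list[Triad]] | None = None,
) -> list[Triad]:
    """15 spatial triads: 6 equal + 9 unequal, anchors included, no repeats."""
    eq, uneq = pools if pools is not None else _spatial_pools(env, city)

    chosen: list[Triad] = []
    for top, bl, br in _SPATIAL_ANCHORS[city]:
        chosen.append(Triad(top, bl, br, "spatial", city))
    n_eq = sum(triad_equality(t, env) == "equal" for t in chosen)
    n_uneq = len(chosen) - n_eq

    def fill(source: list[Triad], need: int) -> list[Triad]:
        taken_sets = {(t.top, t.stores) for t in chosen}
        avail = [t for t in source if (t.top, t.stores) not in taken_sets]
        idx = rng.choice(len(avail), size=need, replace=False)
        return [avail[i] for i in idx]

    chosen += fill(eq, 6 - n_eq)
    chosen += fill(uneq, 9 - n_uneq)
    # randomize left/right and presentation order
    out = []
    for t in chosen:
        if rng.random() < 0.5:
            t = replace(t, bottom_left=t.bottom_right, bottom_right=t.bottom_left)
        out.append(t)
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def _sample_temporal_run(
    env: EnvironmentModel, city: int, rng: np.random.Generator
) -> list[Triad]:
    """All 15 bottom-store pairs of the city, shuffled (6 equal + 9 unequal)."""
    pool = enumerate_temporal_triads(env, city)
    out = []
    for t in pool:
        if rng.random() < 0.5:
            t = replace(t, bottom_left=t.bottom_right, bottom_right=t.bottom_left)
        out.append(t)
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def _trials_to_frame(
    triads: Sequence[Triad],
    env: EnvironmentModel,
    run: int,
    rng: np.random.Generator,
    accuracy: float,
    censor_prob: float,
) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(triads):
        sharing = env.classify_sharing(t.stores)
        rows.append(
            {
                "onset": round(i * TRIAL_DURATION_S, 4),
                "duration": STIMULUS_S,
                "trial_type": t.task,
                "run": run,
                "city": t.city,
                "task": t.task,
                "store_top": t.top,
                "store_bl": t.bottom_left,
                "store_br": t.bottom_right,
                "equality": triad_equality(t, env),
                "sharing_level": sharing.level,
                "distance_index": spatial_distance_index(t, env)
                if t.task == "spatial"
                else np.nan,
                "interval_index": temporal_interval_index(t, env)
                if t.task == "temporal"
                else np.nan,
                "correct": bool(rng.random() < accuracy),
                "censored": bool(rng.random() < censor_prob),
            }
        )
    return pd.DataFrame(rows)


def generate_retrieval_schedule(
    env: EnvironmentModel,
    rng_seed: int,
    accuracy: float = 0.9,
    censor_prob: float = 0.05,
    spatial_first: bool | None = None,
) -> pd.DataFrame:
    """Generate the 12-run (180-trial) retrieval schedule.

    Six consecutive runs per task (two per city), 15 trials per run; the city
    order never repeats a city back-to-back and visits every city before any
    repeat.  Per task, 60% of trials are 'unequal' and 40% 'equal'
    comparisons.  ``accuracy`` and ``censor_prob`` control the simulated
    correctness and motion-censoring flags.
    """
    rng = np.random.default_rng(rng_seed)
    if spatial_first is None:
        spatial_first = bool(rng.random() < 0.5)
    tasks = ["spatial"] * 6 + ["temporal"] * 6 if spatial_first else ["temporal"] * 6 + ["spatial"] * 6
    cities = _run_city_order(rng) + _run_city_order(rng)

    pools = {c: _spatial_pools(env, c) for c in env.cities}
    frames = []
    for run_idx, (task, city) in enumerate(zip(tasks, cities), start=1):
        if task == "spatial":
            triads = _sample_spatial_run(env, city, rng, pools[city])
        else:
            triads = _sample_temporal_run(env, city, rng)
        frames.append(_trials_to_frame(triads, env, run_idx, rng, accuracy, censor_prob))
    return pd.concat(frames, ignore_index=True)


def generate_localizer_schedule(
    env: EnvironmentModel,
    rng_seed: int,
    censor_prob: float = 0.0,
) -> pd.DataFrame:
    """Generate the 2-run x 18-trial localizer (vowel-counting) schedule.

    Each of the six studied stores appears three times per run, once in each
    triad position, flanked by unstudied filler stores; repetitions of the
    same store are 2 to 12 trials apart.
    """
    rng = np.random.default_rng(rng_seed)
    frames = []
    for run in (1, 2):
        order = _localizer_order(rng)
        positions = {s: list(rng.permutation(["top", "bl", "br"])) for s in LOCALIZER_STORES}
        rows = []
        for i, store in enumerate(order):
            pos = positions[store].pop()
            fillers = rng.choice(FILLER_STORES, size=2, replace=False)
            slots = {"top": None, "bl": None, "br": None}
            slots[pos] = store
            fill_iter = iter(fillers)
            for key in slots:
                if slots[key] is None:
                    slots[key] = int(next(fill_iter))
            rows.append(
                {
                    "onset": round(i * TRIAL_DURATION_S, 4),
                    "duration": STIMULUS_S,
                    "trial_type": "localizer",
                    "run": run,
                    "city": np.nan,
                    "task": "localizer",
                    "store_top": slots["top"],
                    "store_bl": slots["bl"],
                    "store_br": slots["br"],
                    "old_store": store,
                    "position": pos,
                    "equality": "n/a",
                    "correct": True,
                    "censored": bool(rng.random() < censor_prob),
                }
            )
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def _localizer_order(rng: np.random.Generator, max_tries: int = 10_000) -> list[int]:
    """Order of 18 old-store occurrences with inter-repetition gaps in [2, 12]."""
    base = list(LOCALIZER_STORES) * 3
    for _ in range(max_tries):
        order = [base[i] for i in rng.permutation(len(base))]
        last: dict[int, int] = {}
        ok = True
        for i, s in enumerate(order):
            if s in last and not (2 <= i - last[s] <= 12):
                ok = False
                break
            last[s] = i
        if ok:
            return order
    raise RuntimeError("could not satisfy localizer spacing constraints")


# ---------------------------------------------------------------------------
# events i/o
# ---------------------------------------------------------------------------

def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def triad_from_row(row: Mapping) -> Triad:
    return Triad(
        int(row["store_top"]),
        int(row["store_bl"]),
        int(row["store_br"]),
        str(row["task"]),
        int(row["city"]),
    )
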