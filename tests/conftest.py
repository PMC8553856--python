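import numpy as np
import pandas as pd
import pytest

from overlapmaps import build_environment
from overlapmaps.design import generate_localizer_schedule, generate_retrieval_schedule
from overlapmaps.simulate import EffectSpec
from overlapmaps.workflows import simulate_subject


@pytest.fixture(scope="session")
def env():
    return build_environment()


@pytest.fixture(scope="session")
def schedule(env):
    return generate_retrieval_schedule(env, rng_seed=11)


@pytest.fixture(scope="session")
def localizer(env):
    return generate_localizer_schedule(env, rng_seed=12)


@pytest.fixture(scope="session")
def null_subject(env):
    """A synthetic subject with every effect strength at zero."""
    return simulate_subject(EffectSpec(), rng_seed=21, env=env)


@pytest.fixture(scope="session")
def holistic_subject(env):
    """Holistic reinstatement planted; shared stores pattern-separated."""
    return simulate_subject(
        EffectSpec(eta_holistic=0.5, gamma_city=0.5), rng_seed=22, env=env
    )


@pytest.fixture(scope="session")
def repulsion_subject(env):
    return simulate_subject(
        EffectSpec(eta_holistic=0.5, rho_shared=-0.3, gamma_city=0.5),
        rng_seed=23,
        env=env,
    )


def toy_overlap_meta() -> pd.DataFrame:
    """Hand-written 20-trial metadata for brute-force pair-rule checks."""
    rows = [
        # city, task, (top, bl, br), correct, censored
        (1, "spatial", (1, 4, 5), True, False),   # unique city 1
        (1, "spatial", (4, 2, 6), True, False),   # unique city 1
        (1, "spatial", (1, 3, 5), True, False),   # three-shared
        (1, "spatial", (3, 2, 6), True, False),   # two-shared (1,2)
        (1, "temporal", (0, 3, 5), True, False),  # three-shared temporal
        (1, "temporal", (0, 2, 4), True, False),  # unique city 1 temporal
        (2, "spatial", (7, 2, 6), True, False),   # unique city 2
        (2, "spatial", (1, 3, 5), True, False),   # three-shared
        (2, "spatial", (3, 2, 6), True, False),   # two-shared (1,2)
        (2, "spatial", (5, 1, 3), True, False),   # three-shared, other top
        (2, "temporal", (0, 3, 5), True, False),  # three-shared temporal
        (2, "temporal", (0, 2, 7), True, False),  # unique city 2 temporal
        (3, "spatial", (3, 8, 9), True, False),   # unique city 3
        (3, "spatial", (1, 3, 5), True, False),   # three-shared
        (3, "spatial", (7, 3, 5), True, False),   # two-shared (2,3)
        (3, "temporal", (0, 3, 5), True, False),  # three-shared temporal
        (3, "temporal", (0, 8, 9), True, False),  # unique city 3 temporal
        (3, "spatial", (1, 3, 5), False, False),  # incorrect: never pairs
        (1, "spatial", (1, 3, 5), True, True),    # censored: never pairs
        (2, "spatial", (7, 2, 6), True, False),   # unique city 2 (duplicate set)
    ]
    return pd.DataFrame(
        [
            {
                "run": i + 1,
                "city": c,
                "task": task,
                "store_top": t[0],
                "store_bl": t[1],
                "store_br": t[2],
                "correct": corr,
                "censored": cen,
            }
            for i, (c, task, t, corr, cen) in enumerate(rows)
        ]
    )
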