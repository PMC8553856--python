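"""Subject-level convenience pipelines over the synthetic generator.

A "synthetic subject" is one draw of the full design: a retrieval schedule,
a localizer schedule, latent store codes at the requested effect strengths,
and trials-by-voxels patterns per ROI.  The helpers here run the standard
analyses end-to-end on such subjects so that recovery sweeps, the analysis
drivers and the acceptance checks share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import EnvironmentModel, build_environment, generate_localizer_schedule, generate_retrieval_schedule
from .decode import DecodeResult, svm_city, svr_leave_one_city_out
from .mps import build_store_templates, holistic_ps_across_tsnr
from .overlap import PairRule, between_city_ps_across_tsnr, pairlevel_z, repulsion_score
from .simulate import (
    EffectSpec,
    PatternSet,
    make_neuron_to_voxel_map,
    make_store_codes,
    simulate_run_patterns,
    simulate_trial_patterns,
)


@dataclass
class SyntheticSubject:
    env: EnvironmentModel
    retrieval: PatternSet
    localizer: PatternSet
    effect: EffectSpec


def simulate_subject(
    effect: EffectSpec,
    rng_seed: int,
    env: EnvironmentModel | None = None,
    n_neurons: int = 200,
    n_voxels: int = 100,
    roi_name: str = "roi",
    accuracy: float = 0.9,
    censor_prob: float = 0.05,
) -> SyntheticSubject:
    """One synthetic subject: shared codes drive retrieval and localizer."""
    env = env or build_environment()
    schedule = generate_retrieval_schedule(env, rng_seed, accuracy, censor_prob)
    localizer = generate_localizer_schedule(env, rng_seed + 1)
    codes = make_store_codes(env, effect, rng_seed, n_neurons)
    mapping = make_neuron_to_voxel_map(n_neurons, n_voxels, rng_seed)
    retr = simulate_trial_patterns(schedule, codes, mapping, effect, rng_seed, env, roi_name)
    loc = simulate_trial_patterns(localizer, codes, mapping, effect, rng_seed + 2, env, roi_name)
    return SyntheticSubject(env, retr, loc, effect)


def holistic_scores(subject: SyntheticSubject) -> dict[str, float]:
    """Mean z per holistic condition, averaged across the 8 tSNR levels."""
    templates = build_store_templates(subject.localizer)
    return holistic_ps_across_tsnr(templates, subject.retrieval, subject.env)


def overlap_scores(subject: SyntheticSubject) -> dict[str, float]:
    """Between-city condition means plus the repulsion difference score."""
    z = between_city_ps_across_tsnr(subject.retrieval, subject.env)
    z["repulsion_score"] = repulsion_score(z["unique"], z["three_shared"])
    return z


def overlap_pair_test(subject: SyntheticSubject) -> float:
    """Within-subject Welch t p-value: three_shared vs unique pair z values."""
    from scipy import stats as sps

    zu = pairlevel_z(subject.retrieval, subject.env, PairRule("unique"))
    zs = pairlevel_z(subject.retrieval, subject.env, PairRule("three_shared"))
    return float(sps.ttest_ind(zs, zu, equal_var=False).pvalue)


def schema_svr(subject: SyntheticSubject, rng_seed: int) -> DecodeResult:
    return svr_leave_one_city_out(subject.retrieval, subject.env, rng_seed)


def city_classification(subject: SyntheticSubject) -> DecodeResult:
    maps, cities = simulate_run_patterns(subject.retrieval)
    return svm_city(maps, cities)


def null_city_accuracy(
    n_replicates: int,
    rng_seed: int,
    n_voxels: int = 30,
) -> np.ndarray:
    """Null calibration: city SVM accuracy on pure-noise run patterns.

    Returns the per-replicate mean accuracies (fraction correct); their grand
    mean estimates the classifier's empirical chance level.
    """
    from .simulate import simulate_null_run_patterns

    accs = np.empty(n_replicates)
    for k in range(n_replicates):
        maps, cities = simulate_null_run_patterns(n_voxels, rng_seed + k)
        accs[k] = svm_city(maps, cities).overall
    return accs
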