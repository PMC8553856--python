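"""Synthetic generator: exact correlation construction, planted signals,
BOLD simulation, and qualitative neuron-to-voxel fidelity."""

import numpy as np
import pandas as pd
import pytest

from overlapmaps.design import CENTER, Triad, spatial_distance_index
from overlapmaps.simulate import (
    EffectSpec,
    NeuronToVoxelMap,
    PatternSet,
    censored_trials_from_fd,
    make_neuron_to_voxel_map,
    make_store_codes,
    neuron_signal_for_trial,
    simulate_bold,
    simulate_trial_patterns,
)
from overlapmaps.workflows import simulate_subject, holistic_scores, overlap_scores


class TestEffectSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rho_shared": 1.5},
            {"rho_shared": -0.8},  # unreachable for a three-city store
            {"sigma_noise": -1.0},
            {"eta_holistic": -0.1},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EffectSpec(**kwargs)

    def test_per_level_rho(self):
        spec = EffectSpec(rho_shared={2: -0.5, 3: -0.3})
        assert spec.rho_for(2) == -0.5
        assert spec.rho_for(3) == -0.3

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "effect.yaml"
        p.write_text("eta_holistic: 0.5\nsigma_noise: 0.8\n")
        spec = EffectSpec.from_yaml(p)
        assert spec.eta_holistic == 0.5
        assert spec.sigma_noise == 0.8


class TestStoreCodes:
    @pytest.mark.parametrize("rho", [1.0, 0.0, -0.3])
    def test_cross_city_correlation_exact(self, env, rho):
        codes = make_store_codes(env, EffectSpec(rho_shared=rho), rng_seed=4)
        for store in (1, 3, 5):  # three-city stores
            vs = [codes.by_store_city[(store, c)] for c in (1, 2, 3)]
            r = np.corrcoef(np.stack(vs))
            off = r[np.triu_indices(3, 1)]
            assert off == pytest.approx(rho, abs=1e-9)
        for store in (2, 6, 7):  # two-city stores
            cities = sorted(env.cities_containing(store))
            r = np.corrcoef(
                codes.by_store_city[(store, cities[0])],
                codes.by_store_city[(store, cities[1])],
            )[0, 1]
            assert r == pytest.approx(rho, abs=1e-9)

    def test_rho_one_gives_identical_vectors(self, env):
        codes = make_store_codes(env, EffectSpec(rho_shared=1.0), rng_seed=4)
        assert np.allclose(codes.by_store_city[(1, 1)], codes.by_store_city[(1, 3)])

    def test_distinct_stores_orthogonal(self, env):
        codes = make_store_codes(env, EffectSpec(), rng_seed=4)
        a = codes.by_store_city[(1, 1)]
        b = codes.by_store_city[(4, 1)]
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_determinism(self, env):
        c1 = make_store_codes(env, EffectSpec(), rng_seed=9)
        c2 = make_store_codes(env, EffectSpec(), rng_seed=9)
        assert np.array_equal(c1.by_store_city[(1, 1)], c2.by_store_city[(1, 1)])


class TestNeuronToVoxelMap:
    def test_every_voxel_pools_a_neuron(self):
        m = make_neuron_to_voxel_map(50, 20, rng_seed=1, pool_size=5)
        assert (np.count_nonzero(m.weights, axis=0) == 5).all()

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            NeuronToVoxelMap(np.array([[1.0, -0.5], [0.2, 0.3]]))

    def test_empty_voxel_rejected(self):
        with pytest.raises(ValueError):
            NeuronToVoxelMap(np.array([[1.0, 0.0], [0.2, 0.0]]))


class TestTrialPatterns:
    def _noiseless(self, env, effect, seed=3):
        from overlapmaps.design import generate_retrieval_schedule

        sched = generate_retrieval_schedule(env, seed, censor_prob=0.0)
        codes = make_store_codes(env, effect, seed)
        mapping = make_neuron_to_voxel_map(200, 60, seed)
        return sched, simulate_trial_patterns(sched, codes, mapping, effect, seed, env)

    def test_identical_store_sets_give_identical_patterns(self, env):
        effect = EffectSpec(sigma_noise=0.0)
        sched, ps = self._noiseless(env, effect)
        # temporal runs enumerate all bottom pairs, so each city's two
        # temporal runs repeat every store set
        key = sched.apply(
            lambda r: (r["city"], frozenset({r["store_top"], r["store_bl"], r["store_br"]})),
            axis=1,
        )
        dup = key[key.duplicated(keep=False)]
        some = dup.unique()[0]
        idx = np.flatnonzero(key == some)
        assert np.allclose(ps.patterns[idx[0]], ps.patterns[idx[1]])

    def test_schema_projection_proportional_to_distance(self, env):
        effect = EffectSpec(beta_schema=0.7, sigma_noise=0.0)
        codes = make_store_codes(env, effect, 5)
        d = codes.schema_direction
        t = Triad(1, 2, 6, "spatial", 1)
        row = {
            "task": "spatial",
            "city": 1,
            "store_top": 1,
            "store_bl": 2,
            "store_br": 6,
            "distance_index": spatial_distance_index(t, env),
        }
        s = neuron_signal_for_trial(pd.Series(row), codes, effect, env)
        proj = s @ d / (d @ d)
        assert proj == pytest.approx(0.7 * row["distance_index"], abs=1e-9)

    def test_patterns_align_with_meta_and_are_finite(self, null_subject):
        ps = null_subject.retrieval
        assert ps.patterns.shape == (len(ps.meta), ps.n_voxels)
        assert np.isfinite(ps.patterns).all()
        assert len(ps.voxel_tsnr) == ps.n_voxels

    def test_misaligned_meta_rejected(self, null_subject):
        ps = null_subject.retrieval
        with pytest.raises(ValueError):
            PatternSet(ps.patterns[:-1], ps.meta, ps.voxel_tsnr)

    def test_determinism(self, env):
        a = simulate_subject(EffectSpec(), rng_seed=31, env=env)
        b = simulate_subject(EffectSpec(), rng_seed=31, env=env)
        assert np.array_equal(a.retrieval.patterns, b.retrieval.patterns)


class TestEndToEndRecovery:
    def test_holistic_contrast_positive_when_planted(self, env):
        diffs_on, diffs_off = [], []
        for seed in range(10):
            on = simulate_subject(EffectSpec(eta_holistic=0.5), rng_seed=100 + seed, env=env)
            off = simulate_subject(EffectSpec(), rng_seed=100 + seed, env=env)
            zs_on = holistic_scores(on)
            zs_off = holistic_scores(off)
            diffs_on.append(zs_on["unique_within"] - zs_on["unique_between"])
            diffs_off.append(zs_off["unique_within"] - zs_off["unique_between"])
        assert np.mean(diffs_on) > 0.05
        assert abs(np.mean(diffs_off)) < 0.02

    def test_neuron_to_voxel_fidelity_of_separation_vs_repulsion(self, env):
        """Voxel-level similarity preserves the sign of neuron-level codes."""
        means = {}
        for rho in (0.0, -0.3):
            scores = [
                overlap_scores(
                    simulate_subject(
                        EffectSpec(rho_shared=rho, gamma_city=0.5), rng_seed=200 + s, env=env
                    )
                )["repulsion_score"]
                for s in range(10)
            ]
            means[rho] = np.mean(scores)
        assert means[-0.3] < -0.05   # repulsion detectable at voxel level
        assert abs(means[0.0]) < 0.05  # separation stays near zero

    def test_monotonicity_in_planted_strength(self, env):
        """Mean holistic contrast grows along an effect-strength grid."""
        grid = [0.0, 0.25, 0.5, 1.0]
        means = []
        for eta in grid:
            vals = []
            for seed in range(6):
                s = simulate_subject(EffectSpec(eta_holistic=eta), rng_seed=300 + seed, env=env)
                z = holistic_scores(s)
                vals.append(z["unique_within"] - z["unique_between"])
            means.append(np.mean(vals))
        assert all(b > a - 0.01 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]


class TestBold:
    def _run1(self, env, schedule):
        return schedule[schedule["run"] == 1].reset_index(drop=True)

    def test_noiseless_single_trial_peak(self, env, schedule):
        run = self._run1(env, schedule).iloc[[0]].reset_index(drop=True)
        amp = np.array([[2.0]])
        bold, ft, _ = simulate_bold(run, amp, rng_seed=1, noise_sd=0.0)
        peak_t = ft[np.argmax(bold[:, 0])]
        onset = run["onset"].iloc[0]
        assert onset + 4 < peak_t < onset + 14  # HRF lag after a 9 s boxcar
        bold2, _, _ = simulate_bold(run, 2 * amp, rng_seed=1, noise_sd=0.0)
        assert np.allclose(bold2, 2 * bold)

    def test_no_spikes_no_censoring(self, env, schedule):
        run = self._run1(env, schedule)
        amps = np.zeros((len(run), 2))
        _, ft, fd = simulate_bold(run, amps, rng_seed=2, noise_sd=0.0, fd_spike_prob=0.0)
        assert not censored_trials_from_fd(run, ft, fd).any()

    def test_censoring_matches_binomial_expectation(self, env, schedule):
        run = self._run1(env, schedule)
        amps = np.zeros((len(run), 1))
        p = 0.05
        fracs = []
        for seed in range(60):
            _, ft, fd = simulate_bold(run, amps, rng_seed=seed, noise_sd=0.0, fd_spike_prob=p)
            fracs.append(censored_trials_from_fd(run, ft, fd).mean())
        # frames per 9 s trial at TR 2.59 s: 3 or 4 -> expected censor fraction
        n_frames = [((ft >= r["onset"]) & (ft < r["onset"] + r["duration"])).sum()
                    for _, r in run.iterrows()]
        expected = np.mean([1 - (1 - p) ** k for k in n_frames])
        assert np.mean(fracs) == pytest.approx(expected, abs=0.03)
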