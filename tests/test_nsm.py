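import itertools

import numpy as np
import pytest

import naivesampling as ns
from naivesampling import (
    DecileProfile,
    ExemplarMemory,
    MatrixTrial,
    SamplingScheme,
    draw_sample,
    eager_running_estimates,
    encode,
    estimate_descriptives,
    retrieval_weights,
    simulate_identification,
    simulate_participant,
    simulate_production,
    simulate_sampling_task,
)

UNIFORM = SamplingScheme()


class TestEncode:
    def test_lossless_storage(self, exposure_set):
        mem = encode(exposure_set)
        assert mem.size == 120
        assert np.array_equal(mem.encoding_index, np.arange(1, 121))
        assert np.array_equal(mem.decode(), exposure_set.values)

    def test_partial_exposure(self, exposure_set):
        mem = encode(exposure_set.values[:60])
        assert mem.size == 60

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ExemplarMemory(np.array([], dtype=int))


class TestDrawSample:
    def test_exhaustive_sample_returns_everything(self, exposure_set):
        mem = encode(exposure_set)
        for policy in ("uniform", "recency", "primacy"):
            scheme = SamplingScheme(policy=policy, decay=0.9, k=mem.size)
            got = draw_sample(mem, scheme, seed=0)
            assert sorted(got) == sorted(mem.values)

    def test_oversized_sample_rejected(self):
        mem = encode([10, 20, 30])
        with pytest.raises(ValueError):
            draw_sample(mem, SamplingScheme(k=4), seed=0)

    def test_recency_weights_enumeration_oracle(self):
        # decay .5 over positions 1..3: unnormalized (.25, .5, 1) -> (1/7, 2/7, 4/7)
        w = retrieval_weights(3, SamplingScheme(policy="recency", decay=0.5))
        assert np.allclose(w / w.sum(), [1 / 7, 2 / 7, 4 / 7])
        w = retrieval_weights(3, SamplingScheme(policy="primacy", decay=0.5))
        assert np.allclose(w / w.sum(), [4 / 7, 2 / 7, 1 / 7])

    def test_recency_monte_carlo_matches_enumeration(self, rng):
        mem = encode([100, 200, 300])
        scheme = SamplingScheme(policy="recency", decay=0.5, k=1)
        n = 30000
        draws = np.array([draw_sample(mem, scheme, rng, k=1)[0] for _ in range(n)])
        freqs = np.array([(draws == v).mean() for v in (100, 200, 300)])
        exact = np.array([1 / 7, 2 / 7, 4 / 7])
        tol = 4 * np.sqrt(exact * (1 - exact) / n)
        assert np.all(np.abs(freqs - exact) < tol)

    def test_uniform_inclusion_probabilities(self, rng):
        mem = encode([100, 200, 300, 400])
        n = 20000
        draws = np.array([draw_sample(mem, UNIFORM, rng, k=1)[0] for _ in range(n)])
        freqs = np.array([(draws == v).mean() for v in (100, 200, 300, 400)])
        tol = 4 * np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(freqs - 0.25) < tol)

    def test_decay_one_is_uniform_for_all_policies(self):
        for policy in ("recency", "primacy"):
            w = retrieval_weights(5, SamplingScheme(policy=policy, decay=1.0))
            assert np.allclose(w, 1.0)

    def test_invalid_scheme_parameters(self):
        with pytest.raises(ValueError):
            SamplingScheme(policy="middle")
        with pytest.raises(ValueError):
            SamplingScheme(decay=0.0)
        with pytest.raises(ValueError):
            SamplingScheme(k=0)


class TestDescriptives:
    def test_worked_example(self):
        est = estimate_descriptives([4, 8, 12])
        assert est.mean == 8.0
        assert est.median == 8.0
        assert est.mad == pytest.approx(8 / 3)

    def test_singleton(self):
        est = estimate_descriptives([42])
        assert est.mean == est.median == 42.0
        assert est.mad == 0.0

    def test_even_size_median_midpoint(self):
        assert estimate_descriptives([1, 2, 3, 10]).median == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_descriptives([])


class TestSimulateProduction:
    def test_law_of_large_numbers(self, exposure_set, rng):
        mem = encode(exposure_set)
        counts = simulate_production(mem, UNIFORM, n_pools=1000, seed=rng)
        assert counts.sum() == 120
        assert np.all(np.abs(counts - 12) <= 2)

    def test_full_information_limit_is_exact(self, exposure_set):
        mem = encode(exposure_set)
        scheme = SamplingScheme(k=mem.size)
        counts = simulate_production(mem, scheme, n_pools=1, seed=0)
        assert counts.tolist() == [12] * 10

    def test_seeded_determinism(self, exposure_set):
        mem = encode(exposure_set)
        a = simulate_production(mem, UNIFORM, seed=33)
        b = simulate_production(mem, UNIFORM, seed=33)
        assert np.array_equal(a, b)


class TestSimulateIdentification:
    def test_self_match_under_exhaustive_sampling(self, prototypes):
        # memory realizing a prototype's profile exactly; full-memory sample
        target = prototypes[3]  # most peaked unimodal
        counts = target.profile.counts(120)
        values = np.concatenate(
            [np.full(c, d * 100 + 50) for d, c in enumerate(counts)])
        mem = encode(values)
        choice = simulate_identification(mem, SamplingScheme(k=mem.size),
                                         prototypes, n_pools=1, seed=0)
        assert choice == 4

    def test_uniform_memory_large_pools_prefers_uniform(self, exposure_set, prototypes, rng):
        mem = encode(exposure_set)
        choices = [simulate_identification(mem, UNIFORM, prototypes,
                                           n_pools=200, seed=rng)
                   for _ in range(40)]
        assert np.mean([c == 1 for c in choices]) > 0.5

    def test_small_samples_distort_shape(self, exposure_set, prototypes, rng):
        mem = encode(exposure_set)
        small = [simulate_identification(mem, UNIFORM, prototypes, n_pools=1, seed=rng)
                 for _ in range(300)]
        large = [simulate_identification(mem, UNIFORM, prototypes, n_pools=200, seed=rng)
                 for _ in range(300)]
        nonuniform_small = np.mean([c != 1 for c in small])
        nonuniform_large = np.mean([c != 1 for c in large])
        assert nonuniform_small > nonuniform_large


class TestSimulateSamplingTask:
    def test_greedy_is_single_swap_optimal_for_uniform_target(self, exposure_set, matrices):
        mem = encode(exposure_set)
        scheme = SamplingScheme(k=mem.size)  # remembered profile exactly uniform
        matrix = matrices[0]
        sel = simulate_sampling_task(mem, scheme, matrix, n_pools=1, seed=1)
        assert len(sel) == 10
        target = np.full(10, 0.1)
        prof = DecileProfile.from_values(sel).bins
        base = np.linalg.norm(prof - target)
        counts = np.bincount(ns.decile_of(sel) - 1, minlength=10)
        # no swap of a selected value for an unselected one may improve the fit
        for out_v in sel:
            for in_v in matrix.values:
                if in_v in sel:
                    continue
                c = counts.copy()
                c[(out_v - 1) // 100] -= 1
                c[(in_v - 1) // 100] += 1
                assert np.linalg.norm(c / 10 - target) >= base - 1e-9

    def test_near_uniform_selection_covers_most_deciles(self, exposure_set, matrices):
        mem = encode(exposure_set)
        sel = simulate_sampling_task(mem, SamplingScheme(k=mem.size), matrices[1],
                                     n_pools=1, seed=2)
        occupied = np.count_nonzero(np.bincount(ns.decile_of(sel) - 1, minlength=10))
        assert occupied >= 8

    def test_concentrated_memory_selects_centrally(self, matrices):
        mem = encode(np.arange(401, 601, 5))  # all exemplars in deciles 5-6
        sel = simulate_sampling_task(mem, SamplingScheme(k=mem.size), matrices[0],
                                     n_pools=1, seed=3)
        deciles = ns.decile_of(sel)
        # matrix holds only 3 values in each central decile; greedy takes all 6
        assert np.sum((deciles == 5) | (deciles == 6)) == 6

    def test_provenance_invisible_to_selection(self):
        # same decile layout, different values and provenance -> same profile
        values_a = np.concatenate([np.arange(d * 100 + 1, d * 100 + 4) for d in range(10)])
        values_b = values_a + 90  # still 3 per decile, different integers
        old = MatrixTrial(values=values_a, provenance="old", trial_index=1)
        new = MatrixTrial(values=values_b, provenance="new", trial_index=2)
        mem = encode(np.arange(1, 1001, 25)[:40])
        scheme = SamplingScheme(k=40)
        sel_old = simulate_sampling_task(mem, scheme, old, n_pools=1, seed=4)
        sel_new = simulate_sampling_task(mem, scheme, new, n_pools=1, seed=4)
        prof_old = np.bincount(ns.decile_of(sel_old) - 1, minlength=10)
        prof_new = np.bincount(ns.decile_of(sel_new) - 1, minlength=10)
        assert np.array_equal(prof_old, prof_new)


class TestEagerEstimates:
    def test_constant_sequence(self):
        m, v = eager_running_estimates([7, 7, 7, 7], learning_rate=0.2)
        assert np.allclose(m, 7.0) and np.allclose(v, 0.0)

    def test_harmonic_endpoint_is_exact_mean(self):
        m, _ = eager_running_estimates([4, 8, 12])
        assert m[-1] == pytest.approx(8.0, abs=1e-12)

    def test_fixed_rate_tracks_recent_half(self, halves):
        e_a, e_b = halves
        seq = ns.order_by_condition(e_a, e_b, "U-B", seed=5)
        _, v = eager_running_estimates(seq, learning_rate=0.1)
        var_first = np.var(seq.values[:60].astype(float))
        var_second = np.var(seq.values[60:].astype(float))
        assert abs(v[-1] - var_second) < abs(v[-1] - var_first)

    def test_learning_rate_validation(self):
        with pytest.raises(ValueError):
            eager_running_estimates([1, 2], learning_rate=0.0)
        with pytest.raises(ValueError):
            eager_running_estimates([1, 2], learning_rate=1.5)
        with pytest.raises(ValueError):
            eager_running_estimates([], learning_rate=0.5)


class TestSimulateParticipant:
    def test_full_record(self, exposure_set, prototypes, matrices):
        mem = encode(exposure_set)
        rec = simulate_participant(mem, UNIFORM, seed=11, prototypes=prototypes,
                                   matrices=matrices, condition="UN")
        assert rec.production.sum() == 120
        assert 1 <= rec.identification <= 7
        assert len(rec.sample_selections) == 8
        for idx, sel in rec.sample_selections.items():
            matrix = next(m for m in matrices if m.trial_index == idx)
            assert set(sel).issubset(set(matrix.values))
            assert rec.sample_provenance[idx] == matrix.provenance
        for est in (rec.est_mean, rec.est_median, rec.est_mad):
            assert np.isfinite(est)

    def test_reproducible_given_seed(self, exposure_set, prototypes, matrices):
        mem = encode(exposure_set)
        kwargs = dict(prototypes=prototypes, matrices=matrices)
        a = simulate_participant(mem, UNIFORM, seed=12, **kwargs)
        b = simulate_participant(mem, UNIFORM, seed=12, **kwargs)
        assert np.array_equal(a.production, b.production)
        assert a.identification == b.identification
        assert a.est_mad == b.est_mad

    def test_k_jitter_stays_in_stm_range(self, exposure_set, rng):
        scheme = SamplingScheme(k_jitter=True)
        ks = [scheme.resolve_k(rng) for _ in range(200)]
        assert set(ks) <= set(range(2, 7)) and len(set(ks)) > 1


class TestDispersionBias:
    def test_sample_mad_underestimates_population_mad(self, rng):
        # exact enumeration of all C(10, 4) samples of a 10-exemplar memory
        values = np.array([13, 88, 152, 260, 341, 450, 589, 666, 787, 940])
        pop_mad = np.mean(np.abs(values - values.mean()))
        sample_mads = [estimate_descriptives(np.array(combo)).mad
                       for combo in itertools.combinations(values, 4)]
        assert np.mean(sample_mads) < pop_mad
        # Monte-Carlo through the retrieval path agrees with the enumeration
        mem = encode(values)
        mc = np.mean([estimate_descriptives(draw_sample(mem, UNIFORM, rng)).mad
                      for _ in range(4000)])
        se = np.std(sample_mads) / np.sqrt(4000)
        assert abs(mc - np.mean(sample_mads)) < 4 * se


class TestSchemeRecovery:
    def test_retrieval_policy_identifiable_from_condition_means(self, halves):
        # uniform vs recency (decay .5) separated by the B-U minus U-B gap in
        # final-test production SI at n = 16 per group
        from test_acceptance import production_si_by_condition

        e_a, e_b = halves
        correct = 0
        cases = []
        for rep in range(12):
            cases.append((SamplingScheme(k=4), "uniform", 700 + rep))
            cases.append((SamplingScheme(policy="recency", decay=0.5, k=4),
                          "recency", 800 + rep))
        for scheme, truth, seed in cases:
            table = production_si_by_condition(e_a, e_b, scheme, n_per_condition=16,
                                               seed=seed, conditions=("U-B", "B-U"))
            gap = (table[table["condition"] == "B-U"]["si"].mean()
                   - table[table["condition"] == "U-B"]["si"].mean())
            guess = "recency" if gap > 0.2 else "uniform"
            correct += guess == truth
        assert correct >= 0.9 * len(cases)
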