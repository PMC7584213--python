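"""Synthetic-data generator: trees, histories, records, bootstrap."""

import collections

import numpy as np
import pytest
import scipy.stats

import karyorate as kr
from karyorate.simulate import SimulationConfig, _gillespie_branch


class TestYuleTrees:
    def test_two_tips_is_a_cherry_at_target_height(self, rng):
        tree = kr.simulate_yule_tree(2, 1.0, rng, height_target=40.0)
        assert tree.n_tips == 2
        assert tree.height == pytest.approx(40.0)
        assert tree.is_ultrametric()

    def test_binary_rooted_node_count(self, rng):
        tree = kr.simulate_yule_tree(500, 1.0, rng)
        assert tree.n_nodes == 2 * 500 - 1  # 499 internal nodes

    def test_fixed_seed_gives_identical_newick(self):
        a = kr.simulate_yule_tree(30, 1.0, np.random.default_rng(8), height_target=10.0)
        b = kr.simulate_yule_tree(30, 1.0, np.random.default_rng(8), height_target=10.0)
        assert a.to_newick() == b.to_newick()

    def test_terminal_branches_are_positive(self, rng):
        tree = kr.simulate_yule_tree(100, 1.0, rng, height_target=100.0)
        assert tree.brlen[: tree.n_tips].min() > 0

    def test_too_few_tips_rejected(self, rng):
        with pytest.raises(ValueError):
            kr.simulate_yule_tree(1, 1.0, rng)


class TestHistory:
    def test_zero_rates_freeze_root_state(self, rng):
        tree = kr.simulate_yule_tree(20, 1.0, rng, height_target=100.0)
        space = kr.build_state_space(1, 30)
        params = kr.RateParameters(units="per_Myr")
        states, events = kr.simulate_history(tree, params, space, (12, kr.MONOCENTRIC), rng)
        assert events == []
        assert all(s == (12, kr.MONOCENTRIC) for s in states.values())

    def test_strong_one_way_switching_absorbs(self, rng):
        tree = kr.simulate_yule_tree(20, 1.0, rng, height_target=100.0)
        space = kr.build_state_space(1, 30)
        params = kr.RateParameters(q_MH=1.0, units="per_Myr")  # q_HM = 0
        states, _ = kr.simulate_history(tree, params, space, (12, kr.MONOCENTRIC), rng)
        for i in range(tree.n_tips):
            assert states[i][1] is kr.HOLOCENTRIC

    def test_fission_only_cherry_mean_increment(self, rng):
        """On a cherry of height t with fission-only rate r, the expected
        tip count is n0 + r*t (Poisson increments)."""
        n0, r, t, reps = 12, 0.05, 20.0, 2000
        tree = kr.Phylogeny.from_newick(f"(t1:{t},t2:{t});")
        space = kr.build_state_space(1, 120)
        params = kr.RateParameters(gamma_M=r, units="per_Myr")
        tips = []
        for _ in range(reps):
            states, _ = kr.simulate_history(tree, params, space, (n0, kr.MONOCENTRIC), rng)
            tips.extend([states[0][0], states[1][0]])
        mean = np.mean(tips)
        se = np.std(tips) / np.sqrt(len(tips))
        assert abs(mean - (n0 + r * t)) < 3 * se

    def test_states_never_leave_bounds(self, rng):
        space = kr.build_state_space(3, 9)
        tree = kr.simulate_yule_tree(30, 1.0, rng, height_target=300.0)
        params = kr.RateParameters(
            gamma_M=0.1, gamma_H=0.1, delta_M=0.1, delta_H=0.1,
            rho_M=0.02, rho_H=0.02, q_MH=0.02, q_HM=0.02, units="per_Myr",
        )
        states, events = kr.simulate_history(tree, params, space, (5, kr.MONOCENTRIC), rng)
        for n, _ in states.values():
            assert 3 <= n <= 9
        for ev in events:
            assert 3 <= ev.n_to <= 9

    def test_polyploidy_events_are_doublings(self, rng):
        space = kr.build_state_space(1, 80)
        tree = kr.simulate_yule_tree(40, 1.0, rng, height_target=200.0)
        params = kr.RateParameters(rho_M=0.01, units="per_Myr")
        _, events = kr.simulate_history(tree, params, space, (6, kr.MONOCENTRIC), rng)
        doublings = [ev for ev in events if ev.kind == "polyploidy"]
        assert doublings, "expected at least one doubling at this exposure"
        assert all(ev.n_to == 2 * ev.n_from for ev in doublings)

    def test_short_branch_frequencies_match_transition_probabilities(self, rng):
        """Forward simulation and the likelihood share one generator: over
        many short branches, empirical end-state frequencies match expm(Qt)
        within binomial error."""
        space = kr.build_state_space(1, 6)
        params = kr.RateParameters(
            gamma_M=0.4, delta_M=0.3, rho_M=0.2, q_MH=0.3, q_HM=0.1,
            gamma_H=0.2, delta_H=0.1, units="per_Myr",
        )
        Q = kr.build_rate_matrix(params, space)
        t, reps = 0.8, 4000
        start = (3, kr.MONOCENTRIC)
        row = kr.transition_probability_matrix(Q, t)[space.index_of(*start)]
        counts = collections.Counter()
        for _ in range(reps):
            end, _ = _gillespie_branch(start, t, params, space, rng, node=0)
            counts[space.index_of(*end)] += 1
        for idx, p in enumerate(row):
            if p < 0.005:
                continue
            se = np.sqrt(p * (1 - p) / reps)
            assert abs(counts[idx] / reps - p) < 4 * se


class TestRecords:
    def test_zero_jitter_duplicates_truth(self, rng):
        space = kr.build_state_space(1, 30)
        tips = {"a": (10, kr.MONOCENTRIC), "b": (12, kr.HOLOCENTRIC)}
        ds = kr.make_records(tips, 3, 0, rng, space)
        for taxon, (n, c) in tips.items():
            assert all(o.haploid_n == n and o.centromere is c for o in ds.records[taxon])

    def test_single_record_equals_tip_state(self, rng):
        space = kr.build_state_space(1, 30)
        tips = {"a": (10, kr.MONOCENTRIC)}
        ds = kr.make_records(tips, 1, 5, rng, space)
        assert len(ds.records["a"]) == 1
        assert ds.records["a"][0].haploid_n == 10

    def test_jitter_is_uniform(self, rng):
        space = kr.build_state_space(1, 100)
        tips = {"a": (50, kr.MONOCENTRIC)}
        ds = kr.make_records(tips, 10_001, 2, rng, space)
        deviations = [o.haploid_n - 50 for o in ds.records["a"][1:]]
        counts = collections.Counter(deviations)
        observed = [counts[d] for d in (-2, -1, 0, 1, 2)]
        chi2, p = scipy.stats.chisquare(observed)
        assert p > 0.01

    def test_centromere_never_jittered(self, rng):
        space = kr.build_state_space(1, 30)
        tips = {"a": (10, kr.HOLOCENTRIC)}
        ds = kr.make_records(tips, 50, 3, rng, space)
        assert all(o.centromere is kr.HOLOCENTRIC for o in ds.records["a"])


class TestPosteriorTreeEmulation:
    def test_zero_sd_gives_identical_copies(self, rng):
        tree = kr.simulate_yule_tree(20, 1.0, rng, height_target=50.0)
        copies = kr.emulate_posterior_trees(tree, 4, 0.0, rng)
        assert len(copies) == 4
        for c in copies:
            assert np.array_equal(c.brlen, tree.brlen)

    def test_jittered_trees_stay_ultrametric_same_height(self, rng):
        tree = kr.simulate_yule_tree(50, 1.0, rng, height_target=100.0)
        for c in kr.emulate_posterior_trees(tree, 20, 0.2, rng):
            assert c.is_ultrametric(rtol=1e-6)
            assert c.height == pytest.approx(100.0, rel=1e-9)

    def test_internal_branches_vary(self, rng):
        tree = kr.simulate_yule_tree(50, 1.0, rng, height_target=100.0)
        copies = kr.emulate_posterior_trees(tree, 30, 0.2, rng)
        one_internal = [c.brlen[c.n_tips + 2] for c in copies]
        assert np.std(one_internal) / np.mean(one_internal) > 0

    def test_total_length_not_systematically_inflated(self, rng):
        tree = kr.simulate_yule_tree(100, 1.0, rng, height_target=100.0)
        copies = kr.emulate_posterior_trees(tree, 30, 0.1, rng)
        ratios = [c.brlen.sum() / tree.brlen.sum() for c in copies]
        assert abs(np.mean(ratios) - 1.0) < 0.1


class TestBootstrap:
    def test_degenerate_inputs_give_identical_replicates(self, rng, tiny_trees):
        ds = kr.ChromosomeDataset.from_observations(
            [kr.TipObservation(f"t{i}", 5, kr.MONOCENTRIC) for i in range(1, 9)]
        )
        reps = kr.bootstrap_datasets(ds, tiny_trees[:1], 5, rng)
        first = reps[0]
        for boot, tree in reps:
            assert tree is first[1]
            assert boot.to_dataframe().equals(first[0].to_dataframe())

    def test_replicate_count(self, rng, tiny_dataset, tiny_trees):
        assert len(kr.bootstrap_datasets(tiny_dataset, tiny_trees, 1000, rng)) == 1000

    def test_fixed_seed_reproducible(self, tiny_dataset, tiny_trees):
        a = kr.bootstrap_datasets(tiny_dataset, tiny_trees, 10, np.random.default_rng(1))
        b = kr.bootstrap_datasets(tiny_dataset, tiny_trees, 10, np.random.default_rng(1))
        for (da, ta), (db, tb) in zip(a, b):
            assert ta.label == tb.label
            assert da.to_dataframe().equals(db.to_dataframe())


class TestSimulateDataset:
    def test_bundle_is_consistent(self):
        cfg = SimulationConfig(n_tips=30, n_posterior_trees=5, seed=3,
                               records_per_taxon=2, record_jitter=1)
        sim = kr.simulate_dataset(cfg)
        assert len(sim.trees) == 5
        assert len(sim.dataset) == 30
        # record centromere equals the simulated terminal state
        for taxon, (n, c) in sim.tip_states().items():
            assert all(o.centromere is c for o in sim.dataset.records[taxon])
        truth = sim.truth_dict()
        assert truth["n_tips"] == 30
        assert truth["event_counts"]["polyploidy"] == 0  # rho = 0 by default

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_tips=15, n_posterior_trees=2, seed=9)
        a, b = kr.simulate_dataset(cfg), kr.simulate_dataset(cfg)
        assert a.tree.to_newick() == b.tree.to_newick()
        assert a.dataset.to_dataframe().equals(b.dataset.to_dataframe())
        assert a.event_counts() == b.event_counts()
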