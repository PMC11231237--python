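import numpy as np
import pytest

from ssrpop.scenarios import (
    DEMES,
    MutationModel,
    build_reference_table,
    classify_scenario,
    default_scenarios,
    pod_error_rates,
    simulate_coalescent,
    summary_stat_names,
    summary_stats,
    _mutate_sizes,
    _simulate_tree,
)

SIZES4 = {d: 4 for d in DEMES}


class TestScenarios:
    def test_all_validate(self):
        for sc in default_scenarios():
            assert sc.validate()

    def test_scenario3_two_root_lineages_until_deepest(self):
        sc = next(s for s in default_scenarios() if s.id == 3)
        # before the deepest event two lineage pools remain
        pre = [ev for ev in sc.events if ev.time != "t5"]
        merged = {ev.source for ev in pre}
        alive = [d for d in DEMES if d not in merged]
        assert len(alive) == 2
        assert sc.events[-1].time == "t5"

    def test_prior_draw_respects_time_order(self):
        sc = next(s for s in default_scenarios() if s.id == 2)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            params = sc.draw_params(rng)
            ts = [params["t"][k] for k in sorted(params["t"])]
            assert all(a < b for a, b in zip(ts, ts[1:]))

    def test_admixture_only_in_scenario_4(self):
        kinds = {s.id: {e.kind for e in s.events} for s in default_scenarios()}
        assert "admix" in kinds[4]
        for sid in (1, 2, 3, 5):
            assert kinds[sid] == {"merge"}
        sc4 = next(s for s in default_scenarios() if s.id == 4)
        rng = np.random.default_rng(1)
        r = sc4.draw_params(rng)["r"]
        assert all(0.1 <= v <= 0.9 for v in r.values())


class TestCoalescent:
    def test_tmrca_two_lineages(self):
        """E[T2] = 2N generations for a single deme."""
        rng = np.random.default_rng(0)
        N = 500.0
        ts = [
            _simulate_tree(rng, {"MEX": 2}, {"MEX": N}, [])[1][-1]
            for _ in range(2000)
        ]
        assert np.mean(ts) == pytest.approx(2 * N, rel=0.05)

    def test_total_tree_length(self):
        """E[total length] = 4N * sum_{i=2..k} 1/(i-1) for k lineages."""
        rng = np.random.default_rng(1)
        N, k = 300.0, 6
        tot = []
        for _ in range(1500):
            parent, times, nl = _simulate_tree(rng, {"MEX": k}, {"MEX": N}, [])
            lengths = times[parent[: 2 * nl - 2]] - times[: 2 * nl - 2]
            tot.append(lengths.sum())
        expected = 4 * N * sum(1.0 / i for i in range(1, k))
        assert np.mean(tot) == pytest.approx(expected, rel=0.05)

    def test_smm_variance(self):
        """Var(allele size difference) tracks mu * total branch length."""
        rng = np.random.default_rng(2)
        mu, N = 5e-4, 500.0
        diffs, tot = [], []
        for _ in range(3000):
            parent, times, nl = _simulate_tree(rng, {"MEX": 2}, {"MEX": N}, [])
            sizes = _mutate_sizes(rng, parent, times, nl, mu, 0.0)
            diffs.append(sizes[0] - sizes[1])
            tot.append(2 * times[-1])
        assert np.var(diffs) == pytest.approx(mu * np.mean(tot), rel=0.1)

    def test_divergence_limits(self):
        """Deep split -> high theta; immediate split -> theta near 0."""
        sc = default_scenarios()[1]
        mm = MutationModel(mu_range=(5e-4, 5e-4))
        rng = np.random.default_rng(3)
        params = sc.draw_params(rng)
        mut = mm.draw(8, rng)
        names = summary_stat_names([d for d in DEMES])
        k = names.index("theta_PER-AM_PER-AND")

        deep = dict(params, t={t: v for t, v in params["t"].items()})
        deep["t"] = {"t1": 50.0, "t2": 100.0, "t3": 150.0, "t4": 60000.0,
                     "t5": 80000.0}
        deep["N"] = {d: 300.0 for d in DEMES}
        ds = simulate_coalescent(sc, deep, mut, {d: 6 for d in DEMES}, 8, seed=4)
        theta_deep = summary_stats(ds)[k]

        shallow = dict(deep)
        shallow["t"] = {"t1": 1.0, "t2": 2.0, "t3": 3.0, "t4": 10.0, "t5": 20.0}
        ds2 = simulate_coalescent(sc, shallow, mut, {d: 6 for d in DEMES}, 8, seed=5)
        theta_shallow = summary_stats(ds2)[k]
        assert theta_deep > 0.2
        assert abs(theta_shallow) < 0.1

    def test_duplicated_demes_near_zero_stats(self, rng):
        sc = default_scenarios(tight_priors=True)[0]
        params = sc.draw_params(rng)
        mut = MutationModel().draw(6, rng)
        ds = simulate_coalescent(sc, params, mut, SIZES4, 6, seed=6)
        # duplicate one deme's samples as a fake second deme
        import ssrpop.genotypes as G
        si = ds.samples_of("MEX")
        calls = np.concatenate([ds.calls[si], ds.calls[si]])
        dup = G.GenotypeDataset(
            [f"a{i}" for i in range(len(si))] + [f"b{i}" for i in range(len(si))],
            ds.locus_names, calls, ["A"] * len(si) + ["B"] * len(si))
        names = summary_stat_names(["A", "B"])
        ss = summary_stats(dup)
        # the unbiased estimator is <= 0 for literally duplicated samples
        assert ss[names.index("theta_A_B")] < 0.02
        assert ss[names.index("dmu2_A_B")] == pytest.approx(0.0, abs=1e-12)
        assert ss[names.index("das_A_B")] == pytest.approx(0.0, abs=1e-12)


class TestReferenceTableAndRF:
    def test_table_shape_and_determinism(self):
        scns = default_scenarios(tight_priors=True)
        mm = MutationModel()
        ref1 = build_reference_table(scns, mm, 10, SIZES4, 5, seed=11)
        ref2 = build_reference_table(scns, mm, 10, SIZES4, 5, seed=11)
        assert ref1.stats.shape == (10, len(summary_stat_names(list(DEMES))))
        assert np.array_equal(ref1.scenario_ids, ref2.scenario_ids)
        assert np.allclose(ref1.stats, ref2.stats, equal_nan=True)
        assert set(ref1.scenario_ids) <= {1, 2, 3, 4, 5}

    def test_scenario_label_distribution(self):
        scns = default_scenarios(tight_priors=True)
        ref = build_reference_table(scns, MutationModel(), 300, SIZES4, 4,
                                    seed=12)
        counts = np.bincount(ref.scenario_ids, minlength=6)[1:]
        # multinomial around 60 per scenario
        assert (counts > 30).all() and (counts < 95).all()

    def test_min_rows_per_scenario_enforced(self):
        scns = default_scenarios(tight_priors=True)
        ref = build_reference_table(scns, MutationModel(), 60, SIZES4, 4,
                                    seed=13)
        with pytest.raises(ValueError):
            classify_scenario(ref, ref.stats[0], n_trees=10, seed=0)

    def test_training_row_classified_correctly(self):
        """A well-separated 2-scenario design classifies a training row."""
        scns = [s for s in default_scenarios(tight_priors=True) if s.id in (1, 2)]
        ref = build_reference_table(scns, MutationModel(), 400, SIZES4, 6,
                                    seed=14)
        row = int(np.flatnonzero(ref.scenario_ids == 2)[0])
        res = classify_scenario(ref, ref.stats[row], n_trees=100, seed=1)
        assert res.chosen == 2
        assert abs(sum(res.votes.values()) - 1.0) < 1e-9
        assert 0.0 <= res.posterior_prob <= 1.0

    def test_identical_scenarios_chance_votes(self):
        """Two copies of the same scenario: votes and posterior near 0.5."""
        sc = default_scenarios(tight_priors=True)[1]
        from dataclasses import replace
        twin = replace(sc, id=9)
        ref = build_reference_table([sc, twin], MutationModel(), 500, SIZES4,
                                    5, seed=15)
        obs_rng = np.random.default_rng(16)
        params = sc.draw_params(obs_rng)
        mut = MutationModel().draw(5, obs_rng)
        obs = summary_stats(simulate_coalescent(sc, params, mut, SIZES4, 5,
                                                seed=17))
        res = classify_scenario(ref, obs, n_trees=200, seed=2)
        assert res.votes[2] == pytest.approx(0.5, abs=0.12)
        assert res.oob_error == pytest.approx(0.5, abs=0.1)

    def test_column_order_invariance(self):
        """Scenario choice does not depend on summary-vector column order."""
        scns = [s for s in default_scenarios(tight_priors=True) if s.id in (1, 2)]
        ref = build_reference_table(scns, MutationModel(), 300, SIZES4, 5,
                                    seed=18)
        obs = ref.stats[5]
        res1 = classify_scenario(ref, obs, n_trees=100, seed=3)
        perm = np.random.default_rng(0).permutation(ref.stats.shape[1])
        from dataclasses import replace as drep
        ref2 = drep(ref, stats=ref.stats[:, perm],
                    stat_names=[ref.stat_names[i] for i in perm])
        res2 = classify_scenario(ref2, obs[perm], n_trees=100, seed=3)
        assert res1.chosen == res2.chosen

    def test_pod_error_rates_separated_pair(self):
        """Strongly separated scenarios: POD error rates are low."""
        scns = [s for s in default_scenarios(tight_priors=True) if s.id in (2, 3)]
        mm = MutationModel()
        ref = build_reference_table(scns, mm, 600, SIZES4, 6, seed=19)
        pods = pod_error_rates(ref, scns, mm, SIZES4, 6,
                               n_pods_per_scenario=40, n_trees=100, seed=20)
        assert pods["mean_error"] <= 0.15
        for sid in (2, 3):
            assert pods[sid]["type1"] <= 0.2
            assert pods[sid]["type2"] <= 0.2
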