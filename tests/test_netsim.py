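"""Network generation, perturbation, weighting, and count sampling."""

import numpy as np
import pytest
from scipy import stats

from prana.netsim import (
    AGE_CATEGORIES,
    ReferenceDistribution,
    ScenarioConfig,
    assign_partial_correlations,
    build_networks,
    generate_base_network,
    perturb_for_age,
    perturb_for_group,
    reference_from_negative_binomial,
    sample_expression,
    simulate_dataset,
    synthetic_reference_distribution,
)


class TestBaseNetwork:
    def test_symmetric_zero_diagonal(self):
        adj, hubs = generate_base_network(20, seed=3)
        assert np.array_equal(adj, adj.T)
        assert np.all(np.diag(adj) == 0)
        assert sorted(hubs.tolist()) == list(range(20))

    def test_seed_determinism(self):
        a1, _ = generate_base_network(20, seed=5)
        a2, _ = generate_base_network(20, seed=5)
        a3, _ = generate_base_network(20, seed=6)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, a3)

    def test_hub_heterogeneity(self):
        # hubs should clearly dominate: max degree >= 2 x median in >= 90%
        hits = 0
        for s in range(100):
            adj, _ = generate_base_network(20, seed=s)
            deg = adj.sum(axis=0)
            hits += np.max(deg) >= 2 * np.median(deg)
        assert hits >= 90

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            generate_base_network(4, seed=0)


class TestPerturbations:
    def test_hub_count_from_effect_size(self):
        adj, hubs = generate_base_network(20, seed=1)
        for effect, expected in ((0.10, 2), (0.05, 1), (0.20, 4)):
            pert = perturb_for_group(adj, hubs, effect)
            zeroed = np.flatnonzero(pert.sum(axis=0) == 0)
            removed = set(hubs[:expected].tolist())
            assert removed <= set(zeroed.tolist())

    def test_non_hub_edges_untouched(self):
        adj, hubs = generate_base_network(20, seed=2)
        pert = perturb_for_group(adj, hubs, 0.10)
        removed = set(hubs[:2].tolist())
        edges = lambda a: {(i, j) for i, j in zip(*np.nonzero(np.triu(a, 1)))}
        diff = edges(adj) - edges(pert)
        assert all(i in removed or j in removed for i, j in diff)
        assert all(
            i not in removed and j not in removed for i, j in edges(pert)
        )

    def test_scenario_one_identical_across_ages(self):
        adj, hubs = generate_base_network(20, seed=4)
        omega = perturb_for_age(adj, hubs, "I", 0.10)
        for z in (1, 2):
            for c in (2, 3):
                assert np.array_equal(omega[(z, c)], omega[(z, 1)])
        assert not np.array_equal(omega[(1, 1)], omega[(2, 1)])

    def test_scenario_two_cumulative_removals(self):
        adj, hubs = generate_base_network(20, seed=4)
        omega = perturb_for_age(adj, hubs, "II", 0.10)
        # per group: each later category removes one additional ranked hub
        for z in (1, 2):
            base_zeroed = 2 if z == 2 else 0
            for c in AGE_CATEGORIES:
                expected_removed = set(hubs[:base_zeroed].tolist()) if z == 2 else set()
                expected_removed |= set(hubs[2 : 2 + (c - 1)].tolist())
                degrees = omega[(z, c)].sum(axis=0)
                assert all(degrees[k] == 0 for k in expected_removed)
        # all six networks unique
        mats = [omega[(z, c)].tobytes() for z in (1, 2) for c in AGE_CATEGORIES]
        assert len(set(mats)) == 6

    def test_scenario_three_groups_share_networks(self):
        adj, hubs = generate_base_network(20, seed=4)
        omega = perturb_for_age(adj, hubs, "III")
        for c in AGE_CATEGORIES:
            assert np.array_equal(omega[(1, c)], omega[(2, c)])
        assert np.all(omega[(1, 2)].sum(axis=0)[hubs[:2]] == 0)
        assert np.all(omega[(1, 3)].sum(axis=0)[hubs[:4]] == 0)


class TestPartialCorrelations:
    def test_empty_adjacency_gives_identity(self):
        prec, pcor = assign_partial_correlations(np.zeros((6, 6), dtype=int), seed=0)
        assert np.array_equal(prec, np.eye(6))
        assert np.all(pcor == 0)

    def test_positive_definite_over_seeds(self):
        for s in range(100):
            adj, _ = generate_base_network(15, seed=s)
            prec, _ = assign_partial_correlations(adj, seed=s)
            assert np.linalg.eigvalsh(prec).min() > 0

    def test_support_matches_adjacency(self):
        adj, _ = generate_base_network(12, seed=9)
        _, pcor = assign_partial_correlations(adj, seed=9)
        assert np.array_equal(pcor != 0, adj == 1)

    def test_pcor_derived_from_precision(self):
        adj, _ = generate_base_network(10, seed=2)
        prec, pcor = assign_partial_correlations(adj, seed=2)
        d = np.sqrt(np.diag(prec))
        expected = -prec / np.outer(d, d)
        np.fill_diagonal(expected, 0)
        assert np.allclose(pcor[adj == 1], expected[adj == 1])


class TestReferenceDistribution:
    def test_quantile_extremes_and_integrality(self, rng):
        ref = synthetic_reference_distribution(3, seed=1, n_ref=500)
        for g in range(3):
            lo = ref.quantile(np.array(0.0), gene=g)
            hi = ref.quantile(np.array(1.0), gene=g)
            assert lo == ref._sorted[g, 0] and hi == ref._sorted[g, -1]
        assert np.all(ref._sorted >= 0)
        assert np.all(ref._sorted == np.floor(ref._sorted))

    def test_nb_moments(self):
        ref = reference_from_negative_binomial([100.0], [5.0], 10000, seed=7)
        sample = ref._sorted[0]
        assert abs(sample.mean() - 100) / 100 <= 0.10
        assert abs(sample.var() - 2100) / 2100 <= 0.10

    def test_minimum_reference_size(self):
        with pytest.raises(ValueError):
            synthetic_reference_distribution(3, seed=0, n_ref=50)


class TestSampleExpression:
    def test_dimensions_and_group_split(self):
        cfg = ScenarioConfig(p=10, n=40, scenario="I", seed=8)
        data = simulate_dataset(cfg)
        assert data.expr.values.shape == (40, 10)
        assert (data.z == 1).sum() == 20 and (data.z == 2).sum() == 20
        assert np.all(data.expr.values >= 0)
        assert np.all(data.expr.values == np.floor(data.expr.values))

    def test_marginals_follow_reference(self, rng):
        # inverse-CDF mapping preserves marginals: compare empirical CDFs
        cfg = ScenarioConfig(p=5, n=1000, scenario="I", effect_size=0.2, seed=3)
        ref = synthetic_reference_distribution(5, seed=99, n_ref=4000)
        nets = build_networks(cfg, rng)
        data = sample_expression(nets, cfg, rng, ref)
        for g in range(5):
            d = stats.ks_2samp(data.expr.values[:, g], ref._sorted[g]).statistic
            assert d <= 0.08

    def test_edge_induces_rank_correlation(self):
        # a strong group-1-only edge shows higher |spearman| in group 1
        hits = 0
        for s in range(60):
            rng = np.random.default_rng(1000 + s)
            cfg = ScenarioConfig(p=10, n=500, scenario="I", effect_size=0.10, seed=s)
            nets = build_networks(cfg, rng)
            o1, o2 = nets.omega[(1, 1)], nets.omega[(2, 1)]
            diff = (o1 == 1) & (o2 == 0)
            if not diff.any():
                continue
            j, k = np.argwhere(np.triu(diff, 1))[0]
            data = sample_expression(nets, cfg, rng)
            r1 = stats.spearmanr(data.expr.values[data.z == 1][:, [j, k]])[0]
            r2 = stats.spearmanr(data.expr.values[data.z == 2][:, [j, k]])[0]
            hits += abs(r1) > abs(r2)
        assert hits / 60 >= 0.9

    def test_scenario_three_age_confounding(self):
        cfg = ScenarioConfig(p=10, n=400, scenario="III", seed=5)
        data = simulate_dataset(cfg)
        # group 1 samples mostly the oldest category, group 2 the youngest
        assert data.age_category[data.z == 1].mean() > data.age_category[data.z == 2].mean()
        # drawn ages are consistent with the assigned category
        cuts = cfg.age_cuts
        cat = 1 + (data.age >= cuts[0]).astype(int) + (data.age > cuts[1]).astype(int)
        assert np.array_equal(cat, data.age_category)

    def test_fresh_network_each_replicate(self):
        cfg = ScenarioConfig(p=20, n=40, scenario="I", seed=0)
        hubs = [
            set(build_networks(cfg, np.random.default_rng(s)).hub_indices[:2].tolist())
            for s in range(10)
        ]
        assert len({frozenset(h) for h in hubs}) > 1

    def test_n_too_small(self):
        cfg = ScenarioConfig(p=10, n=6, scenario="I", seed=0)
        with pytest.raises(ValueError):
            simulate_dataset(cfg)
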