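"""Generators: in-degree laws, exact degree realization, structural regimes."""

import numpy as np
import pytest
from scipy import stats

from burstnet.graph import DirectedGraph
from burstnet.measures import (
    clustering_coefficient,
    length_to_self,
    motif_counts,
)
from burstnet.netgen import (
    InDegreeSpec,
    NetworkRecipe,
    assign_populations,
    excitatory_subgraph,
    generate_ff,
    generate_loopy,
    generate_random,
    generate_ws,
    sample_in_degrees,
)

from oracles import motif_census_oracle
from burstnet.measures import MOTIF_ORDER


# ---------------------------------------------------------------------------
# in-degree sampling
# ---------------------------------------------------------------------------
class TestInDegreeSampling:
    def test_binomial_moments_match_closed_form(self):
        # Bin(99, 0.2): mean 19.8, variance 15.84
        spec = InDegreeSpec("binomial", 0.2, 100)
        draws = np.concatenate(
            [sample_in_degrees(spec, seed) for seed in range(100)]
        )  # 10^4 draws
        assert abs(draws.mean() - 19.8) < 0.15
        assert abs(draws.var(ddof=1) - 15.84) < 0.8

    def test_binomial_degenerate_small_p_is_all_zero(self):
        spec = InDegreeSpec("binomial", 1e-12, 100)
        assert (sample_in_degrees(spec, 0) == 0).all()

    def test_powerlaw_exact_mean_matches_target(self):
        spec = InDegreeSpec("powerlaw", 0.2, 100)
        k, pmf = spec.pmf_support()
        exact_mean = float((k * pmf).sum())
        assert abs(exact_mean - spec.target_mean) / spec.target_mean < 0.01

    def test_powerlaw_sample_mean_within_five_percent(self):
        spec = InDegreeSpec("powerlaw", 0.2, 100)
        draws = np.concatenate([sample_in_degrees(spec, s) for s in range(100)])
        assert abs(draws.mean() - 19.8) / 19.8 < 0.05
        assert draws.min() >= spec.min_degree and draws.max() <= 99

    def test_powerlaw_infeasible_target_raises(self):
        spec = InDegreeSpec("powerlaw", 0.01, 100)  # target mean < min_degree
        with pytest.raises(ValueError, match="not attainable"):
            sample_in_degrees(spec, 0)

    def test_sampling_is_reproducible(self):
        spec = InDegreeSpec("powerlaw", 0.3, 100)
        assert (sample_in_degrees(spec, 7) == sample_in_degrees(spec, 7)).all()


# ---------------------------------------------------------------------------
# wiring schemes
# ---------------------------------------------------------------------------
ALL_GENERATORS = {
    "RN": lambda deg, seed: generate_random(deg, seed),
    "WS1": lambda deg, seed: generate_ws(deg, 1, 0.6, seed),
    "WS2": lambda deg, seed: generate_ws(deg, 2, 0.6, seed),
    "FF": lambda deg, seed: generate_ff(deg, 1.0, seed),
    "L4": lambda deg, seed: generate_loopy(deg, 4, 1.0, seed),
}


@pytest.mark.parametrize("name", ALL_GENERATORS)
def test_in_degree_preserved_exactly_and_diagonal_zero(name):
    spec = InDegreeSpec("binomial", 0.2, 100)
    deg = sample_in_degrees(spec, 3)
    g = ALL_GENERATORS[name](deg, 4)
    assert (g.in_degrees() == deg).all()
    assert not g.adjacency.diagonal().any()
    assert g.adjacency.dtype == bool


@pytest.mark.parametrize("name", ALL_GENERATORS)
def test_generators_deterministic_under_seed(name):
    deg = sample_in_degrees(InDegreeSpec("binomial", 0.2, 64), 1)
    a = ALL_GENERATORS[name](deg, 99).adjacency
    b = ALL_GENERATORS[name](deg, 99).adjacency
    assert (a == b).all()


class TestRandom:
    def test_zero_degrees_give_empty_graph(self):
        g = generate_random(np.zeros(10, dtype=int), 0)
        assert g.n_edges == 0

    def test_full_degrees_force_complete_graph(self):
        g = generate_random([4] * 5, 0)
        expected = ~np.eye(5, dtype=bool)
        assert (g.adjacency == expected).all()

    def test_out_degrees_approximately_binomial(self):
        # each node's out-degree aggregates ~Bin(n-1, k/(n-1)) choices
        spec = InDegreeSpec("binomial", 0.2, 100)
        outs = []
        for s in range(100):
            g = generate_random(sample_in_degrees(spec, s), 1000 + s)
            outs.append(g.out_degrees())
        outs = np.concatenate(outs)
        kbar = outs.mean()
        edges = np.arange(0, 100)
        probs = stats.binom.pmf(edges[:-1], 99, kbar / 99)
        # pool tails so expected counts are > 5
        obs, _ = np.histogram(outs, bins=np.r_[-0.5, np.arange(12.5, 28.5), 99.5])
        exp = np.r_[probs[:13].sum(), probs[13:28], probs[28:].sum()] * len(outs)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, len(obs) - 1)
        assert p > 0.01


class TestWattsStrogatz:
    def test_strength_one_ring_wires_nearest_neighbours(self):
        g = generate_ws([4] * 100, 1, 1.0, 0)
        for i in range(100):
            expected = {(i - 2) % 100, (i - 1) % 100, (i + 1) % 100, (i + 2) % 100}
            assert set(np.flatnonzero(g.adjacency[:, i])) == expected

    def test_locally_connected_network_has_high_clustering(self):
        spec = InDegreeSpec("binomial", 0.2, 100)
        cc_lcn = np.mean([
            clustering_coefficient(generate_ws(sample_in_degrees(spec, s), 1, 1.0, s))
            for s in range(5)
        ])
        cc_rn = np.mean([
            clustering_coefficient(generate_random(sample_in_degrees(spec, s), s))
            for s in range(5)
        ])
        assert cc_lcn > 2 * cc_rn

    def test_torus_requires_square_node_count(self):
        with pytest.raises(ValueError, match="square"):
            generate_ws([2] * 10, 2, 1.0, 0)

    def test_clustering_monotone_in_rewiring(self):
        # ensemble-mean CC non-increasing in p_rw = 1 - strength (1 sigma slack)
        spec = InDegreeSpec("binomial", 0.2, 100)
        means, sds = [], []
        for strength in (1.0, 0.75, 0.5, 0.25, 0.0):
            ccs = [
                clustering_coefficient(
                    generate_ws(sample_in_degrees(spec, 10 + r), 1, strength, 20 + r)
                )
                for r in range(8)
            ]
            means.append(np.mean(ccs))
            sds.append(np.std(ccs))
        for a, b, sd in zip(means, means[1:], sds[1:]):
            assert b <= a + sd


class TestStrengthZeroIsRandom:
    """Strength 0 of every class must be statistically identical to RN."""

    @pytest.mark.parametrize("cls", ["WS1", "WS2", "FF", "L3"])
    def test_strength_zero_cc_matches_rn(self, cls):
        spec = InDegreeSpec("binomial", 0.2, 49)  # 7x7 torus for WS2
        gen = {
            "WS1": lambda d, s: generate_ws(d, 1, 0.0, s),
            "WS2": lambda d, s: generate_ws(d, 2, 0.0, s),
            "FF": lambda d, s: generate_ff(d, 0.0, s),
            "L3": lambda d, s: generate_loopy(d, 3, 0.0, s),
        }[cls]
        cc_a = [
            clustering_coefficient(gen(sample_in_degrees(spec, s), 100 + s))
            for s in range(40)
        ]
        cc_b = [
            clustering_coefficient(generate_random(sample_in_degrees(spec, 200 + s), 300 + s))
            for s in range(40)
        ]
        p = stats.mannwhitneyu(cc_a, cc_b, alternative="two-sided").pvalue
        assert p > 0.01


class TestFeedForward:
    def test_extreme_ff_maximizes_ff_motifs(self):
        spec = InDegreeSpec("binomial", 0.2, 100)
        def motmeans(gen):
            return np.mean([motif_counts(gen(s)) for s in range(6)], axis=0)
        ff = motmeans(lambda s: generate_ff(sample_in_degrees(spec, s), 1.0, 50 + s))
        rn = motmeans(lambda s: generate_random(sample_in_degrees(spec, s), 60 + s))
        # Mot5 (feed-forward loop) and Mot6 exceed the random ensemble
        assert ff[4] > rn[4]
        assert ff[5] > rn[5]

    def test_small_ff_census_matches_brute_force(self):
        deg = sample_in_degrees(InDegreeSpec("binomial", 0.3, 10), 5)
        g = generate_ff(deg, 1.0, 6)
        assert (
            motif_counts(g) == motif_census_oracle(g.adjacency.astype(int), MOTIF_ORDER)
        ).all()


class TestLoopy:
    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    def test_length_to_self_pulled_toward_promoted_length(self, k):
        spec = InDegreeSpec("binomial", 0.2, 100)
        lts_l = np.mean([
            length_to_self(generate_loopy(sample_in_degrees(spec, s), k, 1.0, 70 + s))
            for s in range(5)
        ])
        lts_rn = np.mean([
            length_to_self(generate_random(sample_in_degrees(spec, s), 80 + s))
            for s in range(5)
        ])
        assert abs(lts_l - k) < abs(lts_rn - k)

    def test_invalid_loop_length_rejected(self):
        with pytest.raises(ValueError):
            generate_loopy([2] * 10, 5, 1.0, 0)


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------
class TestPopulations:
    def test_inhibitory_count_and_determinism(self):
        g = generate_random(sample_in_degrees(InDegreeSpec("binomial", 0.2, 100), 0), 1)
        labelled = assign_populations(g, 0.2, 5)
        assert len(labelled.inhibitory_ids()) == 20
        assert len(labelled.excitatory_ids()) == 80
        again = assign_populations(g, 0.2, 5)
        assert (labelled.labels == again.labels).all()

    def test_zero_fraction_all_excitatory(self):
        g = generate_random([1] * 10, 0)
        labelled = assign_populations(g, 0.0, 0)
        assert len(labelled.inhibitory_ids()) == 0

    def test_relabeling_and_bad_fraction_rejected(self):
        g = assign_populations(generate_random([1] * 10, 0), 0.2, 0)
        with pytest.raises(ValueError):
            assign_populations(g, 0.2, 0)
        with pytest.raises(ValueError):
            assign_populations(generate_random([1] * 10, 0), 1.0, 0)

    def test_excitatory_subgraph_matches_manual_submatrix(self):
        adj = np.array([
            [0, 1, 1, 0, 0],
            [0, 0, 1, 1, 0],
            [1, 0, 0, 0, 1],
            [0, 1, 0, 0, 1],
            [1, 0, 0, 1, 0],
        ], dtype=bool)
        labels = np.array([0, 1, 0, 0, 1], dtype=np.int8)  # nodes 1, 4 inhibitory
        g = DirectedGraph(adj, labels=labels)
        sub = excitatory_subgraph(g)
        keep = [0, 2, 3]
        assert (sub.adjacency == adj[np.ix_(keep, keep)]).all()
        assert sub.n_edges <= g.n_edges
        assert list(sub.meta["parent_ids"]) == keep

    def test_subgraph_requires_labels(self):
        with pytest.raises(ValueError):
            excitatory_subgraph(generate_random([1] * 5, 0))


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------
class TestRecipes:
    def test_recipe_reproducible_and_seedable(self):
        spec = InDegreeSpec("binomial", 0.2, 49)
        r = NetworkRecipe("WS2", 0.5, spec, seed=11)
        assert (r.generate().adjacency == r.generate().adjacency).all()
        assert not (r.generate(1).adjacency == r.generate(2).adjacency).all()

    def test_lcn_classes_are_strength_one_ws(self):
        spec = InDegreeSpec("binomial", 0.2, 100)
        lcn = NetworkRecipe("LCN1", 1.0, spec).generate(3)
        ws = NetworkRecipe("WS1", 1.0, spec).generate(3)
        assert (lcn.adjacency == ws.adjacency).all()

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            NetworkRecipe("XX", 0.0, InDegreeSpec())
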