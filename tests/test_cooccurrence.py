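"""Cooccurrence stage: Spearman matrix, permutation null, edges, clusters."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mucinet.cooccurrence import (
    CooccurrenceModel,
    NullDistribution,
    call_edges,
    cluster_fast_greedy,
    degrader_subgraph,
    permutation_null,
    spearman_matrix,
)
from mucinet.tables import ValidationError, clr_transform


def _df(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols, index=[f"S{i}" for i in range(len(next(iter(cols.values()))))])


class TestSpearman:
    def test_identity_gives_one(self):
        df = _df({"x": [1.0, 2, 3, 4], "y": [1.0, 2, 3, 4]})
        assert spearman_matrix(df).at["x", "y"] == pytest.approx(1.0)

    def test_hand_evaluated_rank_formula(self):
        # x=[1,2,3], y=[3,1,2]: 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 36/24 = -0.5
        df = _df({"x": [1.0, 2, 3], "y": [3.0, 1, 2]})
        assert spearman_matrix(df).at["x", "y"] == pytest.approx(-0.5)

    def test_constant_vector_recorded_missing(self):
        df = _df({"x": [1.0, 2, 3], "y": [5.0, 5, 5]})
        rho = spearman_matrix(df)
        assert np.isnan(rho.at["x", "y"])
        assert np.isnan(rho.at["y", "y"])

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 5, size=(30, 6)).astype(float)  # many ties
        df = pd.DataFrame(x, columns=list("abcdef"))
        ours = spearman_matrix(df).to_numpy()
        ref = stats.spearmanr(x).statistic
        assert np.allclose(ours, ref, atol=1e-12)

    def test_min_present_samples_filters_species(self):
        counts = _df({"common": [1.0] * 6, "rare": [1.0, 0, 0, 0, 0, 0]})
        clrv = _df({"common": np.arange(6.0), "rare": np.arange(6.0)[::-1]})
        rho = spearman_matrix(clrv, min_present_samples=3, presence=counts)
        assert list(rho.columns) == ["common"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            spearman_matrix(_df({"x": [1.0, 2], "y": [2.0, 1]}))


class TestPermutationNull:
    def test_iid_noise_ci_symmetric_about_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(100, 10)))
        null = permutation_null(df, n_reps=300, seed=1)
        assert null.ci_lower < 0 < null.ci_upper
        assert abs(null.ci_lower + null.ci_upper) < 0.02

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(50, 8)))
        a = permutation_null(df, n_reps=200, seed=7)
        b = permutation_null(df, n_reps=200, seed=7)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)

    def test_too_few_reps_rejected(self):
        df = pd.DataFrame(np.random.default_rng(3).normal(size=(20, 4)))
        with pytest.raises(ValidationError, match="unstable"):
            permutation_null(df, n_reps=50)

    def test_null_rate_calibrated_on_independent_data(self):
        # fraction of true-null pairs flagged significant ~ 1 - ci_level
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.normal(size=(150, 30)))
        null = permutation_null(df, n_reps=400, ci_level=0.99, seed=5)
        rho = spearman_matrix(df)
        edges = call_edges(rho, null)
        rate = edges["significant"].mean()
        n_pairs = len(edges)
        mc = 3 * np.sqrt(0.01 * 0.99 / n_pairs)
        assert abs(rate - 0.01) < max(mc, 0.01)


class TestCallEdges:
    NULL = NullDistribution(-0.12, 0.12, 1000, 0.99, 10)

    def _rho(self, val):
        return pd.DataFrame(
            [[1.0, val], [val, 1.0]], index=["a", "b"], columns=["a", "b"]
        )

    def test_strong_positive_outside_ci_retained(self):
        e = call_edges(self._rho(0.5), self.NULL).iloc[0]
        assert e["significant"] and e["retained"]

    def test_negative_significant_not_retained(self):
        e = call_edges(self._rho(-0.6), self.NULL).iloc[0]
        assert e["significant"] and not e["retained"]

    def test_weak_positive_below_cutoff_not_retained(self):
        e = call_edges(self._rho(0.15), self.NULL).iloc[0]
        assert e["significant"] and not e["retained"]

    def test_inside_ci_not_significant(self):
        e = call_edges(self._rho(0.05), self.NULL).iloc[0]
        assert not e["significant"] and not e["retained"]

    def test_retained_implies_significant_and_above_cutoff(self, default_community):
        model = CooccurrenceModel(
            default_community.abundance,
            set(default_community.truth.degraders),
            n_reps=200,
        )
        res = model.fit(seed=9)
        ret = res.edges[res.edges["retained"]]
        assert ret["significant"].all()
        assert (ret["rho"] >= 0.2).all()


class TestSubgraphAndClusters:
    def _edges(self, pairs):
        return pd.DataFrame(
            [
                {"species_a": a, "species_b": b, "rho": 0.5,
                 "significant": True, "retained": True}
                for a, b in pairs
            ]
        )

    def test_first_neighbor_chain_semantics(self):
        # chain A(degrader)-B-C: C has no retained edge to a degrader, so the
        # network is {A, B} with the single edge A-B
        g = degrader_subgraph(self._edges([("A", "B"), ("B", "C")]), {"A"})
        assert set(g.nodes) == {"A", "B"}
        assert set(map(frozenset, g.edges)) == {frozenset({"A", "B"})}

    def test_isolated_degrader_retained_with_warning(self):
        with pytest.warns(UserWarning, match="no degrader has any retained edge"):
            g = degrader_subgraph(self._edges([("X", "Y")]), {"A"})
        assert set(g.nodes) == {"A"}

    def test_empty_degrader_set_rejected(self):
        with pytest.raises(ValidationError):
            degrader_subgraph(self._edges([]), set())

    def test_two_disconnected_cliques_two_clusters(self):
        g = nx.Graph()
        for clique in (["a", "b", "c"], ["x", "y", "z"]):
            g.add_edges_from(
                (u, v) for i, u in enumerate(clique) for v in clique[i + 1:]
            )
            for n in clique:
                g.nodes[n]["is_degrader"] = True
        clusters = cluster_fast_greedy(g)
        assert len(set(clusters.values())) == 2
        assert clusters["a"] == clusters["b"] == clusters["c"]

    def test_single_clique_one_cluster(self):
        g = nx.complete_graph(["a", "b", "c", "d"])
        assert set(cluster_fast_greedy(g).values()) == {1}

    def test_isolated_nodes_become_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        clusters = cluster_fast_greedy(g)
        assert sorted(clusters.values()) == [1, 2]

    def test_species_relabeling_permutes_edge_set(self, fixture_community):
        abund = fixture_community.abundance
        degraders = set(fixture_community.truth.degraders)
        res = CooccurrenceModel(abund, degraders, min_present_samples=0,
                                n_reps=150).fit(seed=3)
        mapping = {s: f"Z_{s}" for s in abund.species_ids}
        rc = abund.read_counts.rename(columns=mapping)
        ra = abund.rel_abundance.rename(columns=mapping)
        from mucinet.tables import AbundanceTable

        abund2 = AbundanceTable(rc, ra)
        res2 = CooccurrenceModel(
            abund2, {mapping[d] for d in degraders}, min_present_samples=0,
            n_reps=150,
        ).fit(seed=3)
        before = {
            frozenset((r["species_a"], r["species_b"]))
            for _, r in res.edges[res.edges["retained"]].iterrows()
        }
        after = {
            frozenset((a.removeprefix("Z_"), b.removeprefix("Z_")))
            for a, b in (
                (r["species_a"], r["species_b"])
                for _, r in res2.edges[res2.edges["retained"]].iterrows()
            )
        }
        assert before == after

    def test_partition_modularity_beats_trivial(self, default_community):
        res = CooccurrenceModel(
            default_community.abundance,
            set(default_community.truth.degraders),
            n_reps=200,
        ).fit(seed=13)
        g = res.network
        if g.number_of_edges():
            trivial = nx.algorithms.community.modularity(
                g, [set(g.nodes)], weight=None
            )
            assert res.modularity >= trivial

    def test_planted_blocks_recovered(self, default_community):
        from sklearn.metrics import adjusted_rand_score

        com = default_community
        res = CooccurrenceModel(
            com.abundance, set(com.truth.degraders), n_reps=300
        ).fit(seed=17)
        nodes = res.nodes_frame()
        truth = [com.truth.cluster_assignment[s] for s in nodes["species"]]
        assert adjusted_rand_score(truth, nodes["cluster"]) >= 0.8

    def test_per_pair_null_mode_runs(self, fixture_community):
        res = CooccurrenceModel(
            fixture_community.abundance,
            set(fixture_community.truth.degraders),
            min_present_samples=0,
            n_reps=150,
            null_mode="per_pair",
        ).fit(seed=2)
        assert {"significant", "retained"} <= set(res.edges.columns)
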