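"""Regression stage: contributions, OLS fits, RP edges, consensus, continuum."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_stratified
from mucinet.regression import (
    LmFit,
    RPEdge,
    TranscriptionModel,
    abundance_driven_fit,
    consensus,
    contributions,
    ecology_summary,
    response_predictor_fit,
)
from mucinet.tables import (
    UNCLASSIFIED,
    ClrMatrix,
    ConsistencyError,
    ValidationError,
    clr_transform,
)


def brute_force_ols(y, X):
    """Independent normal-equations + t/F-distribution OLS oracle."""
    y = np.asarray(y, float)
    X = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    n, p = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df_resid = n - p
    sigma2 = resid @ resid / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - resid @ resid / ss_tot
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - p)
    fstat = (r2 / (p - 1)) / ((1 - r2) / df_resid)
    fp = stats.f.sf(fstat, p - 1, df_resid)
    return beta, pvals, adj_r2, fp


class TestContributions:
    def test_share_arithmetic(self):
        t = make_stratified(
            [("S1", "3.2.1.18", "A", 5.0), ("S1", "3.2.1.18", UNCLASSIFIED, 15.0)]
        )
        c = contributions(t)
        a = c[c["species"] == "A"]["contribution"].iloc[0]
        assert a == pytest.approx(25.0)

    def test_single_transcriber_no_unclassified_gets_100(self):
        t = make_stratified([("S1", "3.2.1.18", "A", 7.0)])
        c = contributions(t)
        assert c["contribution"].iloc[0] == pytest.approx(100.0)

    def test_closure_per_sample_and_ec(self, fixture_community):
        mt = fixture_community.transcripts
        c = contributions(mt)
        sums = c.groupby(["sample", "ec"])["contribution"].sum()
        assert np.allclose(sums.to_numpy(), 100.0, atol=1e-6)

    def test_zero_total_samples_excluded(self):
        t = make_stratified(
            [("S1", "3.2.1.18", "A", 5.0)], samples=["S1", "S2"]
        )
        c = contributions(t)
        assert set(c["sample"]) == {"S1"}

    def test_stratum_exceeding_total_raises(self):
        t = make_stratified([("S1", "3.2.1.18", "A", 5.0)])
        t.totals.at["S1", "3.2.1.18"] = 5.0
        t.strata.loc[0, "cpm"] = 9.0  # corrupt after construction
        with pytest.raises(ConsistencyError):
            contributions(t)

    def test_classified_only_denominator_option(self):
        t = make_stratified(
            [("S1", "3.2.1.18", "A", 5.0), ("S1", "3.2.1.18", UNCLASSIFIED, 15.0)]
        )
        c = contributions(t, include_unclassified_denominator=False)
        a = c[c["species"] == "A"]["contribution"].iloc[0]
        assert a == pytest.approx(100.0)

    def test_fixture_contributions_match_generator_bookkeeping(
        self, fixture_community
    ):
        mt = fixture_community.transcripts
        c = contributions(mt).set_index(["sample", "ec", "species"])
        sub = mt.strata.sample(50, random_state=0)
        for _, r in sub.iterrows():
            tot = mt.community_total(r["sample"], r["ec"])
            expect = 100.0 * r["cpm"] / tot
            got = c.at[(r["sample"], r["ec"], r["species"]), "contribution"]
            assert got == pytest.approx(expect)


def _clr_from(df: pd.DataFrame) -> ClrMatrix:
    m = ClrMatrix.__new__(ClrMatrix)
    m.values = df
    m.pseudocount = 1.0
    return m


def _contrib_frame(samples, ec, species_values: dict) -> pd.DataFrame:
    rows = []
    for sp, vals in species_values.items():
        rows += [
            {"sample": s, "ec": ec, "species": sp, "contribution": v}
            for s, v in zip(samples, vals)
        ]
    return pd.DataFrame(rows)


class TestAbundanceDrivenFit:
    def test_perfect_linear_relation(self):
        samples = [f"S{i}" for i in range(10)]
        x = np.arange(10.0)
        contrib = _contrib_frame(samples, "3.2.1.18", {"A": 2 * x + 1})
        clr = _clr_from(pd.DataFrame({"A": x}, index=samples))
        fit = abundance_driven_fit(contrib, clr, "3.2.1.18", "A")
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.model_pvalue < 1e-12
        assert fit.params["A"] == pytest.approx(2.0)

    def test_null_relation_adj_r2_near_zero(self):
        rng = np.random.default_rng(10)
        samples = [f"S{i}" for i in range(200)]
        contrib = _contrib_frame(
            samples, "3.2.1.18", {"A": rng.uniform(0, 100, 200)}
        )
        clr = _clr_from(pd.DataFrame({"A": rng.normal(size=200)}, index=samples))
        fit = abundance_driven_fit(contrib, clr, "3.2.1.18", "A")
        assert abs(fit.adj_r2) < 0.05

    def test_adjusted_r2_may_be_negative(self):
        rng = np.random.default_rng(11)
        samples = [f"S{i}" for i in range(20)]
        contrib = _contrib_frame(samples, "3.2.1.18", {"A": rng.uniform(0, 1, 20)})
        clr = _clr_from(pd.DataFrame({"A": rng.normal(size=20)}, index=samples))
        fit = abundance_driven_fit(contrib, clr, "3.2.1.18", "A")
        assert fit.adj_r2 < 0.1  # typically slightly negative for pure noise

    def test_constant_predictor_flagged(self):
        samples = [f"S{i}" for i in range(12)]
        contrib = _contrib_frame(samples, "3.2.1.18", {"A": np.arange(12.0)})
        clr = _clr_from(pd.DataFrame({"A": np.ones(12)}, index=samples))
        fit = abundance_driven_fit(contrib, clr, "3.2.1.18", "A")
        assert fit.status == "constant_predictor"

    def test_too_few_observations_skipped(self):
        samples = [f"S{i}" for i in range(5)]
        contrib = _contrib_frame(samples, "3.2.1.18", {"A": np.arange(5.0)})
        clr = _clr_from(pd.DataFrame({"A": np.arange(5.0)}, index=samples))
        fit = abundance_driven_fit(contrib, clr, "3.2.1.18", "A", min_n_obs=10)
        assert fit.status == "too_few_obs"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for trial in range(5):
            n = int(rng.integers(15, 40))
            samples = [f"S{i}" for i in range(n)]
            x = rng.normal(size=n)
            y = 3 * x + rng.normal(size=n)
            contrib = _contrib_frame(samples, "3.2.1.18", {"A": y})
            clr = _clr_from(pd.DataFrame({"A": x}, index=samples))
            fit = abundance_driven_fit(contrib, clr, "3.2.1.18", "A")
            beta, pvals, adj_r2, fp = brute_force_ols(y, x[:, None])
            assert fit.params["A"] == pytest.approx(beta[1], abs=1e-8)
            assert fit.pvalues["A"] == pytest.approx(pvals[1], abs=1e-8)
            assert fit.adj_r2 == pytest.approx(adj_r2, abs=1e-8)
            assert fit.model_pvalue == pytest.approx(fp, abs=1e-8)


class TestResponsePredictorFit:
    def test_multivariate_matches_brute_force(self):
        rng = np.random.default_rng(13)
        n, samples = 60, [f"S{i}" for i in range(60)]
        X = pd.DataFrame(
            rng.normal(size=(n, 3)), columns=["A", "B", "C"], index=samples
        )
        y = 2 * X["B"].to_numpy() - 1.5 * X["C"].to_numpy() + rng.normal(size=n)
        contrib = _contrib_frame(samples, "3.2.1.18", {"A": y})
        edges, fits = response_predictor_fit(
            contrib, _clr_from(X), "3.2.1.18", ["A", "B", "C"]
        )
        fit = fits["A"]
        beta, pvals, adj_r2, _ = brute_force_ols(y, X[["B", "C"]].to_numpy())
        assert fit.params["B"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.params["C"] == pytest.approx(beta[2], abs=1e-8)
        assert fit.adj_r2 == pytest.approx(adj_r2, abs=1e-8)
        signs = {(e.predictor, e.response): e.sign for e in edges if e.response == "A"}
        assert signs[("B", "A")] == "positive"
        assert signs[("C", "A")] == "negative"

    def test_independent_transcribers_rarely_linked(self):
        rng = np.random.default_rng(14)
        n, samples = 300, [f"S{i}" for i in range(300)]
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["A", "B"], index=samples)
        contrib = _contrib_frame(
            samples,
            "3.2.1.18",
            {"A": rng.uniform(0, 100, n), "B": rng.uniform(0, 100, n)},
        )
        edges, _ = response_predictor_fit(contrib, _clr_from(X), "3.2.1.18", ["A", "B"])
        assert len(edges) <= 1  # chance hits at alpha=0.05 only

    def test_self_abundance_excluded_from_predictors(self):
        rng = np.random.default_rng(15)
        samples = [f"S{i}" for i in range(30)]
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["A", "B"], index=samples)
        contrib = _contrib_frame(
            samples, "3.2.1.18", {"A": rng.uniform(0, 1, 30), "B": rng.uniform(0, 1, 30)}
        )
        _, fits = response_predictor_fit(contrib, _clr_from(X), "3.2.1.18", ["A", "B"])
        assert fits["A"].predictors == ["B"]
        assert fits["B"].predictors == ["A"]

    def test_fewer_than_two_transcribers_rejected(self):
        with pytest.raises(ValidationError):
            response_predictor_fit(pd.DataFrame(), None, "3.2.1.18", ["A"])

    def test_self_edge_construction_rejected(self):
        with pytest.raises(ValidationError):
            RPEdge("3.2.1.18", "A", "A", -1.0, 0.01)


class TestConsensus:
    def _edge(self, ec, pred, resp, coef):
        return RPEdge(ec, pred, resp, coef, 0.01)

    def test_recurrent_negative_pair_labeled_always_negative(self):
        edges = {f"ec{i}": [self._edge(f"ec{i}", "A", "B", -1.0)] for i in range(4)}
        c = consensus(edges).iloc[0]
        assert c["label"] == "always_negative"
        assert c["n_negative"] == 4
        assert c["n_positive"] == 0

    def test_both_signs_labeled_mixed(self):
        edges = {
            "3.2.1.51": [self._edge("3.2.1.51", "A", "B", -1.0)],
            "3.2.1.22": [self._edge("3.2.1.22", "A", "B", +1.0)],
        }
        c = consensus(edges).iloc[0]
        assert c["label"] == "mixed"
        assert c["n_positive"] == 1 and c["n_negative"] == 1

    def test_empty_edge_sets_give_empty_consensus(self):
        assert len(consensus({})) == 0

    def test_mixed_iff_both_signs(self, default_community):
        from mucinet.tables import clr_transform

        com = default_community
        res = TranscriptionModel(
            com.transcripts, clr_transform(com.abundance), com.catalog
        ).fit()
        for _, row in res.consensus.iterrows():
            both = row["n_positive"] > 0 and row["n_negative"] > 0
            assert (row["label"] == "mixed") == both


class TestEcologySummary:
    def _fit(self, sp, ec, r2):
        return LmFit(sp, [sp], {sp: 1.0}, {sp: 0.001}, 0.001, r2, r2, 50, ec)

    def test_median_and_threshold_classification(self):
        fits = [self._fit("A", f"ec{i}", v) for i, v in enumerate([0.1, 0.3, 0.5])]
        summary, _ = ecology_summary(fits, [], {"A": 3})
        row = summary.set_index("species").loc["A"]
        assert row["median_adj_r2"] == pytest.approx(0.3)
        assert row["class"] == "competitive"

    def test_at_threshold_is_opportunistic(self):
        fits = [self._fit("A", "ec0", 0.2)]
        summary, _ = ecology_summary(fits, [], {"A": 1})
        assert summary.iloc[0]["class"] == "opportunistic"

    def test_no_negative_edges_gives_zero_inhibited(self):
        fits = [self._fit("A", f"ec{i}", 0.4) for i in range(3)]
        edges = [RPEdge("ec0", "A", "B", +2.0, 0.01)]
        summary, _ = ecology_summary(fits, edges, {"A": 3})
        row = summary.set_index("species").loc["A"]
        assert row["avg_inhibited"] == 0.0
        assert row["avg_facilitated"] == pytest.approx(1 / 3)

    def test_species_in_no_network_excluded_with_note(self):
        fits = [self._fit("A", "ec0", 0.4)]
        with pytest.warns(UserWarning, match="no EC network"):
            summary, _ = ecology_summary(fits, [], {})
        assert len(summary) == 0


class TestRecovery:
    def test_planted_suppression_edges_recovered(self, default_community):
        com = default_community
        res = TranscriptionModel(
            com.transcripts, clr_transform(com.abundance), com.catalog,
            species_subset=set(com.truth.degraders),
        ).fit()
        planted = {(p, r, e) for p, r, e, _ in com.truth.planted_edges}
        found = {
            (e.predictor, e.response, e.ec)
            for e in res.rp_edges
            if e.sign == "negative"
        }
        sensitivity = len(planted & found) / len(planted)
        assert sensitivity >= 0.8

    def test_planted_roles_recovered(self, default_community):
        com = default_community
        res = TranscriptionModel(
            com.transcripts, clr_transform(com.abundance), com.catalog
        ).fit()
        eco = res.ecology.set_index("species")
        for sp in eco.index:
            role = com.truth.role[sp]
            med = eco.at[sp, "median_adj_r2"]
            if role == "competitive":
                assert med > 0.2
            elif role == "opportunistic":
                assert med <= 0.2

    def test_continuum_trend_positive_and_significant(self, default_community):
        com = default_community
        res = TranscriptionModel(
            com.transcripts, clr_transform(com.abundance), com.catalog
        ).fit()
        assert len(res.ecology) >= 15
        t = res.trends["inhibited_vs_r2"]
        assert t.status == "ok"
        assert t.params["median_adj_r2"] > 0
        assert t.model_pvalue < 0.05
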