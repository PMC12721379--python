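"""Permutation-calibrated Spearman cooccurrence networks on clr abundances.

Pairwise Spearman correlations are computed between the clr-transformed
estimated read counts of all species present in enough samples. Significance
is calibrated against a permutation null: each species' values are shuffled
independently across samples (destroying cross-species association while
preserving marginals), all pairwise correlations of the shuffled data are
pooled over ``n_reps`` repetitions, and observed correlations outside the
central ``ci_level`` interval of that pooled null are significant. Negative
and weak (< ``min_rho``) correlations are then discarded, the network is
restricted to the degraders and their first neighbors, and communities are
found by greedy modularity maximisation (Clauset-Newman-Moore) on the
unweighted adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities, modularity
from scipy.stats import rankdata

from mucinet.tables import (
    ZERO_TOL,
    AbundanceTable,
    ClrMatrix,
    ValidationError,
    clr_transform,
)

__all__ = [
    "spearman_matrix",
    "permutation_null",
    "call_edges",
    "degrader_subgraph",
    "cluster_fast_greedy",
    "NullDistribution",
    "CooccurrenceModel",
    "CooccurrenceResults",
]


def _rank_columns(values: np.ndarray) -> np.ndarray:
    """Average ranks per column (Spearman's tie convention)."""
    return np.apply_along_axis(rankdata, 0, values)


def spearman_matrix(
    clr: ClrMatrix | pd.DataFrame, min_present_samples: int = 0,
    presence: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix between species columns.

    Species with fewer than ``min_present_samples`` nonzero-count samples
    (judged on ``presence``, a samples x species count/boolean frame) are
    dropped before correlating. Constant columns yield undefined
    correlations, recorded as NaN. Requires at least 3 samples.
    """
    df = clr.values if isinstance(clr, ClrMatrix) else clr
    if df.shape[0] < 3:
        raise ValidationError("need at least 3 samples for correlations")
    if min_present_samples and presence is not None:
        counts = (presence > ZERO_TOL).sum(axis=0)
        keep = [s for s in df.columns if counts.get(s, 0) >= min_present_samples]
        df = df[keep]
    x = df.to_numpy(float)
    ranks = _rank_columns(x)
    sd = ranks.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (ranks - ranks.mean(axis=0)) / np.where(constant, np.nan, sd)
        rho = (z.T @ z) / x.shape[0]
    rho[np.ix_(constant, constant)] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


@dataclass
class NullDistribution:
    """Pooled permutation null of pairwise Spearman correlations."""

    ci_lower: float
    ci_upper: float
    n_reps: int
    ci_level: float
    n_pairs: int
    seed: int | None = None
    pooled: np.ndarray | None = None  # optional, for diagnostics

    def __post_init__(self) -> None:
        if self.ci_lower > self.ci_upper:
            raise ValidationError("null CI bounds out of order")


def permutation_null(
    clr: ClrMatrix | pd.DataFrame,
    n_reps: int = 1000,
    ci_level: float = 0.99,
    seed: int | None = None,
    keep_pooled: bool = False,
) -> NullDistribution:
    """Null distribution of Spearman rho under independent species shuffles.

    Each repetition permutes every species' values independently across
    samples and computes all pairwise correlations; all ``n_reps x n_pairs``
    values are pooled into one global null whose central ``ci_level``
    interval defines the significance band. Since Spearman correlation
    depends only on ranks, shuffling raw counts and shuffling clr values are
    equivalent under this shuffling unit.
    """
    if n_reps < 100:
        raise ValidationError("n_reps < 100 gives unstable 99% tails")
    if not (0.0 < ci_level < 1.0):
        raise ValidationError("ci_level must be in (0, 1)")
    df = clr.values if isinstance(clr, ClrMatrix) else clr
    x = df.to_numpy(float)
    n, p = x.shape
    ranks = _rank_columns(x)
    sd = ranks.std(axis=0)
    ok = sd > 0
    z = (ranks[:, ok] - ranks[:, ok].mean(axis=0)) / sd[ok]
    p_ok = int(ok.sum())
    if p_ok < 2:
        raise ValidationError("fewer than 2 non-constant species")
    iu = np.triu_indices(p_ok, k=1)
    rng = np.random.default_rng(seed)
    pooled = np.empty(n_reps * len(iu[0]))
    for rep in range(n_reps):
        perm = np.argsort(rng.random((n, p_ok)), axis=0)
        zs = np.take_along_axis(z, perm, axis=0)
        corr = (zs.T @ zs) / n
        pooled[rep * len(iu[0]) : (rep + 1) * len(iu[0])] = corr[iu]
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(pooled, [alpha / 2.0, 1.0 - alpha / 2.0])
    return NullDistribution(
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_reps=n_reps,
        ci_level=ci_level,
        n_pairs=len(iu[0]),
        seed=seed,
        pooled=pooled if keep_pooled else None,
    )


def call_edges(
    rho: pd.DataFrame, null: NullDistribution, min_rho: float = 0.2
) -> pd.DataFrame:
    """Edge table from a correlation matrix and its permutation null.

    An edge is *significant* when its rho lies outside the null CI and
    *retained* when additionally positive and at least ``min_rho`` (negative
    and weak correlations are removed). Undefined correlations are skipped.
    """
    species = list(rho.index)
    rows = []
    vals = rho.to_numpy()
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            r = vals[i, j]
            if np.isnan(r):
                continue
            significant = bool(r < null.ci_lower or r > null.ci_upper)
            rows.append(
                {
                    "species_a": species[i],
                    "species_b": species[j],
                    "rho": float(r),
                    "significant": significant,
                    "retained": bool(significant and r >= min_rho),
                }
            )
    return pd.DataFrame(
        rows, columns=["species_a", "species_b", "rho", "significant", "retained"]
    )


def degrader_subgraph(edges: pd.DataFrame, degraders: set[str]) -> nx.Graph:
    """Network of degraders and their first neighbors.

    Nodes are the degraders plus every species sharing a retained edge with
    a degrader; edges are the retained edges among this node set. Degraders
    without edges remain as isolated nodes.
    """
    if not degraders:
        raise ValidationError("empty degrader set")
    retained = edges[edges["retained"]] if len(edges) else edges
    neighbors: set[str] = set()
    for _, row in retained.iterrows():
        a, b = row["species_a"], row["species_b"]
        if a in degraders:
            neighbors.add(b)
        if b in degraders:
            neighbors.add(a)
    nodes = set(degraders) | neighbors
    g = nx.Graph()
    for node in sorted(nodes):  # lexicographic insertion: deterministic tie-breaks
        g.add_node(node, is_degrader=node in degraders)
    for _, row in retained.iterrows():
        a, b = row["species_a"], row["species_b"]
        if a in nodes and b in nodes:
            g.add_edge(a, b, rho=row["rho"])
    if all(deg == 0 for n, deg in g.degree if g.nodes[n]["is_degrader"]):
        warnings.warn("no degrader has any retained edge", stacklevel=2)
    return g


def cluster_fast_greedy(g: nx.Graph) -> dict[str, int]:
    """Greedy-modularity communities of the unweighted network.

    Communities are computed on presence/absence of edges (weights ignored),
    isolated nodes become singleton clusters, and cluster ids (1-based) are
    assigned by decreasing size with the lexicographically smallest member
    breaking ties, so the labelling is reproducible.
    """
    if g.number_of_nodes() == 0:
        return {}
    if g.number_of_edges() == 0:
        comms = [{n} for n in g.nodes]
    else:
        comms = [set(c) for c in greedy_modularity_communities(g, weight=None)]
    comms.sort(key=lambda c: (-len(c), min(c)))
    return {node: i + 1 for i, c in enumerate(comms) for node in sorted(c)}


@dataclass
class CooccurrenceResults:
    """Fitted cooccurrence network: correlations, null, edges and clusters."""

    rho: pd.DataFrame
    null: NullDistribution
    edges: pd.DataFrame
    network: nx.Graph
    clusters: dict[str, int]
    min_rho: float

    def nodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": n,
                    "is_degrader": bool(self.network.nodes[n]["is_degrader"]),
                    "cluster": self.clusters.get(n, 0),
                }
                for n in sorted(self.network.nodes)
            ]
        )

    @property
    def modularity(self) -> float:
        if self.network.number_of_edges() == 0:
            return 0.0
        groups: dict[int, set[str]] = {}
        for node, c in self.clusters.items():
            groups.setdefault(c, set()).add(node)
        return float(modularity(self.network, groups.values(), weight=None))

    def summary(self) -> str:
        n_sig = int(self.edges["significant"].sum()) if len(self.edges) else 0
        n_ret = int(self.edges["retained"].sum()) if len(self.edges) else 0
        n_clusters = len(set(self.clusters.values()))
        return "\n".join(
            [
                "Cooccurrence network",
                "====================",
                f"species correlated:      {self.rho.shape[0]}",
                f"null CI ({self.null.ci_level:.0%}, {self.null.n_reps} reps): "
                f"[{self.null.ci_lower:+.4f}, {self.null.ci_upper:+.4f}]",
                f"significant edges:       {n_sig}",
                f"retained (rho >= {self.min_rho:.2g}): {n_ret}",
                f"network nodes / edges:   {self.network.number_of_nodes()} / "
                f"{self.network.number_of_edges()}",
                f"clusters (greedy modularity): {n_clusters}"
                f"  (Q = {self.modularity:.3f})",
            ]
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        self.nodes_frame().to_csv(outdir / "nodes.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "ci_lower": self.null.ci_lower,
                    "ci_upper": self.null.ci_upper,
                    "ci_level": self.null.ci_level,
                    "n_reps": self.null.n_reps,
                    "n_pairs": self.null.n_pairs,
                    "seed": self.null.seed,
                }
            ]
        ).to_csv(outdir / "null_summary.tsv", sep="\t", index=False)
        export = self.network.copy()
        for node, c in self.clusters.items():
            export.nodes[node]["cluster"] = int(c)
        nx.write_graphml(export, outdir / "network.graphml")


class CooccurrenceModel:
    """Permutation-calibrated cooccurrence network model.

    Parameters
    ----------
    abundance :
        Samples x species estimated read counts (+ relative abundances).
    degraders :
        Species to anchor the network on (typically the prevalent versatile
        call set of :class:`~mucinet.screen.DegraderScreen`).
    min_present_samples :
        Minimum nonzero-count samples for a species to enter the correlation
        universe (default 20, the sample size needed for robust network
        inference).
    n_reps, ci_level, min_rho :
        Permutation-null repetitions (default 1000), central interval
        (default 99%) and the minimum retained positive correlation
        (default 0.2).
    null_mode :
        ``"pooled"`` (default) pools all shuffled pair correlations into one
        global null; ``"per_pair"`` keeps a per-pair null (much coarser
        tails at the same ``n_reps``).
    """

    def __init__(
        self,
        abundance: AbundanceTable,
        degraders: set[str] | frozenset[str],
        min_present_samples: int = 20,
        pseudocount: float = 1.0,
        n_reps: int = 1000,
        ci_level: float = 0.99,
        min_rho: float = 0.2,
        null_mode: str = "pooled",
    ) -> None:
        if null_mode not in {"pooled", "per_pair"}:
            raise ValidationError(f"unknown null_mode {null_mode!r}")
        self.abundance = abundance
        self.degraders = set(degraders)
        self.min_present_samples = min_present_samples
        self.pseudocount = pseudocount
        self.n_reps = n_reps
        self.ci_level = ci_level
        self.min_rho = min_rho
        self.null_mode = null_mode

    def fit(self, seed: int | None = None) -> CooccurrenceResults:
        clr = clr_transform(self.abundance, pseudocount=self.pseudocount)
        rho = spearman_matrix(
            clr,
            min_present_samples=self.min_present_samples,
            presence=self.abundance.read_counts,
        )
        sub = clr.values[rho.columns]
        if self.null_mode == "pooled":
            null = permutation_null(sub, self.n_reps, self.ci_level, seed)
            edges = call_edges(rho, null, self.min_rho)
        else:
            null, edges = self._per_pair(sub, rho, seed)
        g = degrader_subgraph(edges, self.degraders & set(rho.columns))
        clusters = cluster_fast_greedy(g)
        return CooccurrenceResults(rho, null, edges, g, clusters, self.min_rho)

    def _per_pair(self, sub: pd.DataFrame, rho: pd.DataFrame, seed):
        """Per-pair permutation quantiles (coarse at 1000 reps)."""
        x = sub.to_numpy(float)
        n, p = x.shape
        ranks = _rank_columns(x)
        sd = ranks.std(axis=0)
        ok = sd > 0
        z = np.where(ok, (ranks - ranks.mean(axis=0)) / np.where(ok, sd, 1.0), np.nan)
        rng = np.random.default_rng(seed)
        alpha = 1.0 - self.ci_level
        acc = np.empty((self.n_reps, p, p))
        for rep in range(self.n_reps):
            perm = np.argsort(rng.random((n, p)), axis=0)
            zs = np.take_along_axis(z, perm, axis=0)
            acc[rep] = (zs.T @ zs) / n
        lo = np.quantile(acc, alpha / 2.0, axis=0)
        hi = np.quantile(acc, 1.0 - alpha / 2.0, axis=0)
        species = list(rho.index)
        rows = []
        vals = rho.to_numpy()
        for i in range(p):
            for j in range(i + 1, p):
                r = vals[i, j]
                if np.isnan(r):
                    continue
                significant = bool(r < lo[i, j] or r > hi[i, j])
                rows.append(
                    {
                        "species_a": species[i],
                        "species_b": species[j],
                        "rho": float(r),
                        "significant": significant,
                        "retained": bool(significant and r >= self.min_rho),
                    }
                )
        null = NullDistribution(
            ci_lower=float(np.nanmin(lo)),
            ci_upper=float(np.nanmax(hi)),
            n_reps=self.n_reps,
            ci_level=self.ci_level,
            n_pairs=p * (p - 1) // 2,
            seed=seed,
        )
        edges = pd.DataFrame(
            rows, columns=["species_a", "species_b", "rho", "significant", "retained"]
        )
        return null, edges
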