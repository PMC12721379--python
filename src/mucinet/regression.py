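"""Abundance-driven transcription and response-predictor regression networks.

Per-species transcription is first normalised to the share (%) of the
community total of its EC in each sample. Two families of ordinary least
squares models are then fitted over the samples where the EC is transcribed:

* **abundance-driven fits** — a species' contribution regressed on its own
  clr abundance; the adjusted R² is the "percentage of abundance-driven
  transcription" (it may be slightly negative for uninformative fits).
* **response-predictor fits** — for every response species, its contribution
  regressed jointly on the clr abundances of all *other* prevalent
  transcribers of the same EC; every coefficient with p < alpha becomes a
  directed, signed edge predictor -> response.

Edges are aggregated across ECs into a consensus network
(always-positive / always-negative / mixed) and summarised per species into
the competitive-opportunistic continuum: median adjusted R² versus the
average number of species a degrader inhibits (negative out-edges per
eligible network) or facilitates (positive out-edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from mucinet.tables import (
    UNCLASSIFIED,
    ZERO_TOL,
    ClrMatrix,
    ECCatalog,
    StratifiedFunctionTable,
    ConsistencyError,
    ValidationError,
    load_ec_catalog,
)
from mucinet.screen import transcription_prevalence

__all__ = [
    "contributions",
    "LmFit",
    "RPEdge",
    "abundance_driven_fit",
    "response_predictor_fit",
    "consensus",
    "ecology_summary",
    "TranscriptionModel",
    "TranscriptionResults",
]


def contributions(
    mt: StratifiedFunctionTable,
    ecs: list[str] | None = None,
    include_unclassified_denominator: bool = True,
) -> pd.DataFrame:
    """Per (sample, EC, species) % share of the EC's community transcription.

    Defined only for samples where the EC's community total is nonzero; the
    denominator includes the UNCLASSIFIED stratum by default (the community
    total), so per-(sample, EC) species shares sum to at most 100 with the
    unclassified share absorbing the remainder.
    """
    ecs = ecs if ecs is not None else mt.ec_ids
    sub = mt.strata[mt.strata["ec"].isin(ecs)].copy()
    if not include_unclassified_denominator:
        sub = sub[sub["species"] != UNCLASSIFIED].copy()
    if include_unclassified_denominator:
        denom = sub.apply(
            lambda r: mt.community_total(r["sample"], r["ec"]), axis=1
        ) if len(sub) else pd.Series(dtype=float)
    else:
        classified = (
            sub[sub["species"] != UNCLASSIFIED]
            .groupby(["sample", "ec"])["cpm"]
            .sum()
        )
        denom = sub.apply(
            lambda r: classified.get((r["sample"], r["ec"]), 0.0), axis=1
        ) if len(sub) else pd.Series(dtype=float)
    if len(sub):
        over = sub["cpm"] > denom + 1e-6
        if over.any():
            r = sub[over].iloc[0]
            raise ConsistencyError(
                f"stratum ({r['sample']}, {r['ec']}, {r['species']}) exceeds its total"
            )
        sub = sub[denom > ZERO_TOL]
        sub["contribution"] = 100.0 * sub["cpm"] / denom[denom > ZERO_TOL]
    else:
        sub["contribution"] = pd.Series(dtype=float)
    return sub[["sample", "ec", "species", "contribution"]].reset_index(drop=True)


@dataclass
class LmFit:
    """One OLS fit: coefficients, p-values, adjusted R² and bookkeeping."""

    response: str
    predictors: list[str]
    params: dict[str, float]
    pvalues: dict[str, float]
    model_pvalue: float
    adj_r2: float
    r2: float
    n_obs: int
    ec: str | None = None
    status: str = "ok"  # ok | constant_predictor | constant_response | too_few_obs
    condition_number: float = np.nan

    @property
    def significant(self) -> bool:
        return self.status == "ok" and self.model_pvalue < 0.05


@dataclass(frozen=True)
class RPEdge:
    """Directed, signed edge of a response-predictor network."""

    ec: str
    predictor: str
    response: str
    coefficient: float
    p_value: float

    def __post_init__(self) -> None:
        if self.predictor == self.response:
            raise ValidationError("self-edges are not allowed")

    @property
    def sign(self) -> str:
        return "positive" if self.coefficient > 0 else "negative"


def _ols(y: np.ndarray, X: pd.DataFrame, response: str, ec: str | None) -> LmFit:
    names = list(X.columns)
    if any(np.ptp(X[c].to_numpy()) == 0 for c in names):
        return LmFit(response, names, {}, {}, np.nan, np.nan, np.nan,
                     len(y), ec, status="constant_predictor")
    if np.ptp(y) == 0:
        return LmFit(response, names, {}, {}, np.nan, np.nan, np.nan,
                     len(y), ec, status="constant_response")
    design = sm.add_constant(X.to_numpy(float))
    fit = sm.OLS(y, design).fit()
    params = dict(zip(["intercept"] + names, map(float, fit.params)))
    pvals = dict(zip(["intercept"] + names, map(float, fit.pvalues)))
    return LmFit(
        response=response,
        predictors=names,
        params=params,
        pvalues=pvals,
        model_pvalue=float(fit.f_pvalue),
        adj_r2=float(fit.rsquared_adj),
        r2=float(fit.rsquared),
        n_obs=int(fit.nobs),
        ec=ec,
        condition_number=float(fit.condition_number),
    )


def _aligned(contrib: pd.DataFrame, clr: ClrMatrix, ec: str, species: str):
    """(samples, y) for one species' contribution to one EC, zeros filled.

    A species with no stratum row in a sample where the EC is transcribed
    contributed 0% there; those zeros are part of the response.
    """
    ec_rows = contrib[contrib["ec"] == ec]
    samples = sorted(ec_rows["sample"].unique())
    own = ec_rows[ec_rows["species"] == species].set_index("sample")["contribution"]
    y = own.reindex(samples).fillna(0.0).to_numpy(float)
    return samples, y


def abundance_driven_fit(
    contrib: pd.DataFrame,
    clr: ClrMatrix,
    ec: str,
    species: str,
    alpha: float = 0.05,
    min_n_obs: int = 10,
) -> LmFit:
    """OLS of a species' % contribution to an EC on its own clr abundance."""
    samples, y = _aligned(contrib, clr, ec, species)
    if len(samples) < min_n_obs:
        return LmFit(species, [species], {}, {}, np.nan, np.nan, np.nan,
                     len(samples), ec, status="too_few_obs")
    X = clr.values.loc[samples, [species]]
    return _ols(y, X, response=species, ec=ec)


def response_predictor_fit(
    contrib: pd.DataFrame,
    clr: ClrMatrix,
    ec: str,
    transcribers: list[str],
    alpha: float = 0.05,
) -> tuple[list[RPEdge], dict[str, LmFit]]:
    """Per-EC multivariate models: each transcriber's contribution on the
    clr abundances of all other transcribers; significant coefficients
    become directed edges."""
    transcribers = sorted(transcribers)
    if len(transcribers) < 2:
        raise ValidationError("need at least 2 prevalent transcribers")
    edges: list[RPEdge] = []
    fits: dict[str, LmFit] = {}
    for response in transcribers:
        predictors = [s for s in transcribers if s != response]
        samples, y = _aligned(contrib, clr, ec, response)
        if len(samples) <= len(predictors) + 1:
            fits[response] = LmFit(response, predictors, {}, {}, np.nan, np.nan,
                                   np.nan, len(samples), ec, status="too_few_obs")
            continue
        X = clr.values.loc[samples, predictors]
        fit = _ols(y, X, response=response, ec=ec)
        fits[response] = fit
        if fit.status != "ok":
            continue
        for pred in predictors:
            if fit.pvalues[pred] < alpha:
                edges.append(
                    RPEdge(ec, pred, response, fit.params[pred], fit.pvalues[pred])
                )
    return edges, fits


def consensus(edgesets: dict[str, list[RPEdge]] | list[list[RPEdge]]) -> pd.DataFrame:
    """Cross-EC consensus of directed edges.

    Groups (predictor, response) pairs over all per-EC networks and labels
    each ``always_positive``, ``always_negative`` or (iff both signs occur)
    ``mixed``; per-EC multiplicity is retained in ``ecs``.
    """
    if isinstance(edgesets, dict):
        all_edges = [e for edges in edgesets.values() for e in edges]
    else:
        all_edges = [e for edges in edgesets for e in edges]
    groups: dict[tuple[str, str], list[RPEdge]] = {}
    for e in all_edges:
        groups.setdefault((e.predictor, e.response), []).append(e)
    rows = []
    for (pred, resp), es in sorted(groups.items()):
        n_pos = sum(1 for e in es if e.sign == "positive")
        n_neg = sum(1 for e in es if e.sign == "negative")
        label = (
            "mixed" if n_pos > 0 and n_neg > 0
            else "always_positive" if n_pos else "always_negative"
        )
        rows.append(
            {
                "predictor": pred,
                "response": resp,
                "n_positive": n_pos,
                "n_negative": n_neg,
                "n_total": n_pos + n_neg,
                "label": label,
                "ecs": ";".join(sorted({e.ec for e in es})),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["predictor", "response", "n_positive", "n_negative",
                 "n_total", "label", "ecs"],
    )


def ecology_summary(
    fits: list[LmFit],
    edges: list[RPEdge],
    eligible_predictor: dict[str, int],
    competitive_threshold: float = 0.2,
) -> tuple[pd.DataFrame, dict[str, LmFit]]:
    """Competitive-opportunistic continuum per species, plus the two trends.

    ``median_adj_r2`` is the species' median abundance-driven adjusted R²
    across its ECs; ``avg_inhibited`` (``avg_facilitated``) is its number of
    negative (positive) out-edges divided by the number of EC networks in
    which it was an eligible predictor. Species above the threshold are
    classed competitive, at or below opportunistic. The returned trends are
    ``avg_inhibited ~ median_adj_r2`` and ``avg_facilitated ~ avg_inhibited``
    across species.
    """
    by_species: dict[str, list[float]] = {}
    for f in fits:
        if f.status == "ok":
            by_species.setdefault(f.response, []).append(f.adj_r2)
    rows = []
    skipped = []
    for sp in sorted(by_species):
        n_networks = eligible_predictor.get(sp, 0)
        if n_networks == 0:
            skipped.append(sp)
            continue
        n_neg = sum(1 for e in edges if e.predictor == sp and e.sign == "negative")
        n_pos = sum(1 for e in edges if e.predictor == sp and e.sign == "positive")
        med = float(np.median(by_species[sp]))
        rows.append(
            {
                "species": sp,
                "median_adj_r2": med,
                "n_ec_fits": len(by_species[sp]),
                "n_predictor_networks": n_networks,
                "avg_inhibited": n_neg / n_networks,
                "avg_facilitated": n_pos / n_networks,
                "class": "competitive" if med > competitive_threshold else "opportunistic",
            }
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} species in no EC network excluded from the continuum",
            stacklevel=2,
        )
    summary = pd.DataFrame(
        rows,
        columns=["species", "median_adj_r2", "n_ec_fits", "n_predictor_networks",
                 "avg_inhibited", "avg_facilitated", "class"],
    )
    trends: dict[str, LmFit] = {}
    for name, xcol, ycol in (
        ("inhibited_vs_r2", "median_adj_r2", "avg_inhibited"),
        ("facilitated_vs_inhibited", "avg_inhibited", "avg_facilitated"),
    ):
        if len(summary) >= 3 and np.ptp(summary[xcol].to_numpy()) > 0:
            trends[name] = _ols(
                summary[ycol].to_numpy(float), summary[[xcol]], response=ycol, ec=None
            )
        else:
            trends[name] = LmFit(ycol, [xcol], {}, {}, np.nan, np.nan, np.nan,
                                 len(summary), None, status="too_few_obs")
    return summary, trends


@dataclass
class TranscriptionResults:
    """Fitted transcription ecology: contributions, fits, edges, continuum."""

    contributions: pd.DataFrame
    prevalent_transcribers: dict[str, list[str]]
    abundance_fits: list[LmFit]
    rp_edges: list[RPEdge]
    rp_fits: dict[str, dict[str, LmFit]]
    consensus: pd.DataFrame
    ecology: pd.DataFrame
    trends: dict[str, LmFit]
    alpha: float
    competitive_threshold: float

    def abundance_fits_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ec": f.ec,
                "species": f.response,
                "adj_r2": f.adj_r2,
                "model_p": f.model_pvalue,
                "slope": f.params.get(f.response, np.nan),
                "n_obs": f.n_obs,
                "status": f.status,
            }
            for f in self.abundance_fits
        ]
        return pd.DataFrame(
            rows, columns=["ec", "species", "adj_r2", "model_p", "slope", "n_obs", "status"]
        )

    def rp_edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ec": e.ec,
                "predictor": e.predictor,
                "response": e.response,
                "coefficient": e.coefficient,
                "p_value": e.p_value,
                "sign": e.sign,
            }
            for e in self.rp_edges
        ]
        return pd.DataFrame(
            rows, columns=["ec", "predictor", "response", "coefficient", "p_value", "sign"]
        )

    def trends_frame(self) -> pd.DataFrame:
        rows = []
        for name, f in self.trends.items():
            slope_key = f.predictors[0] if f.predictors else None
            rows.append(
                {
                    "trend": name,
                    "slope": f.params.get(slope_key, np.nan),
                    "adj_r2": f.adj_r2,
                    "model_p": f.model_pvalue,
                    "n": f.n_obs,
                    "status": f.status,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        ok = [f for f in self.abundance_fits if f.status == "ok"]
        r2s = np.array([f.adj_r2 for f in ok]) if ok else np.array([np.nan])
        n_comp = int((self.ecology["class"] == "competitive").sum()) if len(self.ecology) else 0
        n_opp = len(self.ecology) - n_comp
        t = self.trends.get("inhibited_vs_r2")
        lines = [
            "Transcription ecology",
            "=====================",
            f"EC networks fitted:            {len(self.prevalent_transcribers)}",
            f"abundance-driven fits (ok):    {len(ok)}",
            f"adjusted R2 range / median:    "
            f"[{np.nanmin(r2s):+.2f}, {np.nanmax(r2s):+.2f}] / {np.nanmedian(r2s):.2f}",
            f"response-predictor edges:      {len(self.rp_edges)} "
            f"({sum(1 for e in self.rp_edges if e.sign == 'negative')} negative)",
            f"consensus pairs:               {len(self.consensus)} "
            f"({int((self.consensus['label'] == 'mixed').sum()) if len(self.consensus) else 0} mixed)",
            f"continuum classes:             {n_comp} competitive / {n_opp} opportunistic "
            f"(threshold {self.competitive_threshold})",
        ]
        if t is not None and t.status == "ok":
            lines.append(
                f"inhibited ~ median R2 trend:   slope "
                f"{t.params.get('median_adj_r2', np.nan):+.3f}, "
                f"p = {t.model_pvalue:.3g}, adj R2 = {t.adj_r2:.3f}"
            )
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.abundance_fits_frame().to_csv(
            outdir / "abundance_fits.tsv", sep="\t", index=False
        )
        self.rp_edges_frame().to_csv(outdir / "rp_edges.tsv", sep="\t", index=False)
        self.consensus.to_csv(outdir / "consensus_edges.tsv", sep="\t", index=False)
        self.ecology.to_csv(outdir / "ecology_summary.tsv", sep="\t", index=False)
        self.trends_frame().to_csv(outdir / "trend_fits.tsv", sep="\t", index=False)


class TranscriptionModel:
    """Per-EC regression model suite over a stratified transcript table.

    Parameters
    ----------
    transcripts :
        Species-stratified transcript table (cpm).
    clr :
        clr-transformed abundances on the same species namespace.
    catalog :
        EC catalog; only active catalog ECs are modelled.
    species_subset :
        Optional restriction of the transcriber universe (e.g. the prevalent
        versatile degraders from the screen); by default every per-EC
        prevalent transcriber enters.
    min_prevalence :
        Per-EC transcription prevalence for a species to enter that EC's
        models (default 0.10).
    alpha :
        Per-coefficient significance level for edges (default 0.05, no
        multiple-testing correction; set ``fdr=True`` for Benjamini-Hochberg
        within each EC network).
    """

    def __init__(
        self,
        transcripts: StratifiedFunctionTable,
        clr: ClrMatrix,
        catalog: ECCatalog | None = None,
        species_subset: set[str] | None = None,
        min_prevalence: float = 0.10,
        alpha: float = 0.05,
        competitive_threshold: float = 0.2,
        min_n_obs: int = 10,
        include_unclassified_denominator: bool = True,
        fdr: bool = False,
    ) -> None:
        self.transcripts = transcripts
        self.clr = clr
        self.catalog = catalog or load_ec_catalog()
        self.species_subset = species_subset
        self.min_prevalence = min_prevalence
        self.alpha = alpha
        self.competitive_threshold = competitive_threshold
        self.min_n_obs = min_n_obs
        self.include_unclassified_denominator = include_unclassified_denominator
        self.fdr = fdr

    def prevalent_by_ec(self) -> dict[str, list[str]]:
        prev = transcription_prevalence(self.transcripts, self.catalog.active_ecs)
        out: dict[str, list[str]] = {}
        for ec, grp in prev.groupby("ec"):
            keep = grp[grp["prevalence"] >= self.min_prevalence]["species"]
            species = sorted(set(keep) & set(self.clr.species_ids))
            if self.species_subset is not None:
                species = sorted(set(species) & set(self.species_subset))
            if species:
                out[ec] = species
        return out

    def fit(self) -> TranscriptionResults:
        by_ec = self.prevalent_by_ec()
        contrib = contributions(
            self.transcripts,
            list(by_ec),
            include_unclassified_denominator=self.include_unclassified_denominator,
        )
        abundance_fits: list[LmFit] = []
        rp_edges: list[RPEdge] = []
        rp_fits: dict[str, dict[str, LmFit]] = {}
        eligible: dict[str, int] = {}
        for ec, species in sorted(by_ec.items()):
            for sp in species:
                abundance_fits.append(
                    abundance_driven_fit(
                        contrib, self.clr, ec, sp, self.alpha, self.min_n_obs
                    )
                )
            if len(species) >= 2:
                edges, fits = response_predictor_fit(
                    contrib, self.clr, ec, species, self.alpha
                )
                if self.fdr:
                    edges = self._bh_filter(fits, species)
                rp_edges.extend(edges)
                rp_fits[ec] = fits
                for sp in species:
                    # a species is an eligible predictor wherever some other
                    # response model actually ran
                    if any(
                        f.status == "ok" for r, f in fits.items() if r != sp
                    ):
                        eligible[sp] = eligible.get(sp, 0) + 1
        cons = consensus({ec: [e for e in rp_edges if e.ec == ec] for ec in rp_fits})
        ecology, trends = ecology_summary(
            abundance_fits, rp_edges, eligible, self.competitive_threshold
        )
        return TranscriptionResults(
            contributions=contrib,
            prevalent_transcribers=by_ec,
            abundance_fits=abundance_fits,
            rp_edges=rp_edges,
            rp_fits=rp_fits,
            consensus=cons,
            ecology=ecology,
            trends=trends,
            alpha=self.alpha,
            competitive_threshold=self.competitive_threshold,
        )

    def _bh_filter(self, fits: dict[str, LmFit], species: list[str]) -> list[RPEdge]:
        """Benjamini-Hochberg over all coefficients of one EC network."""
        from statsmodels.stats.multitest import multipletests

        entries = []
        for resp, f in fits.items():
            if f.status != "ok":
                continue
            for pred in f.predictors:
                entries.append((f.ec, pred, resp, f.params[pred], f.pvalues[pred]))
        if not entries:
            return []
        reject, _, _, _ = multipletests(
            [e[4] for e in entries], alpha=self.alpha, method="fdr_bh"
        )
        return [
            RPEdge(*e) for e, keep in zip(entries, reject) if keep
        ]
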