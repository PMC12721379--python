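"""Screen for mucosal glycan degraders in stratified functional profiles.

The screen applies a filter cascade to the species-stratified transcript
table: species transcribing any catalog EC are *transcribers*; those whose
transcribed set is not confined to the galactosidases (widely available
galactose makes galactosidase-only transcription uninformative about the
mucin niche) and spans more than one EC are *versatile*; versatile species
with transcription prevalence >= ``min_prevalence`` for at least one EC
(prevalence measured against the samples where that EC is transcribed at
all) are *prevalent versatile* degraders. Encoders are called analogously
from the metagenome table.
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
    ECCatalog,
    StratifiedFunctionTable,
    ValidationError,
    load_ec_catalog,
)

__all__ = [
    "DegraderScreen",
    "DegraderScreenResults",
    "ec_prevalence",
    "transcription_prevalence",
    "gh_repertoire_comparison",
]


def ec_prevalence(
    table: StratifiedFunctionTable,
    catalog: ECCatalog,
    prevalence_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-EC detection prevalence and mean abundance across all samples.

    Prevalence is the fraction of samples whose community total for the EC
    is nonzero; an EC is flagged prevalent only under the strict
    ``prevalence > threshold`` rule (default 5%). Catalog ECs absent from
    the table are reported with prevalence 0. Also reports the number of
    species with any detectable stratum per EC.
    """
    if not len(table.sample_ids):
        raise ValidationError("empty functional table")
    n = len(table.sample_ids)
    rows = []
    det = table.strata[
        (table.strata["species"] != UNCLASSIFIED) & (table.strata["cpm"] > ZERO_TOL)
    ]
    for ec in catalog.ec_ids:
        if ec in table.totals.columns:
            tot = table.totals[ec]
            prev = float((tot > ZERO_TOL).sum()) / n
            mean_cpm = float(tot.mean())
        else:
            prev, mean_cpm = 0.0, 0.0
        n_species = det.loc[det["ec"] == ec, "species"].nunique()
        rows.append(
            {
                "ec": ec,
                "name": catalog.name_of(ec),
                "prevalence": prev,
                "mean_cpm": mean_cpm,
                "n_species": int(n_species),
                "prevalent": prev > prevalence_threshold,
            }
        )
    return pd.DataFrame(rows)


def transcription_prevalence(
    table: StratifiedFunctionTable, ecs: list[str] | None = None
) -> pd.DataFrame:
    """Per (EC, species) transcription prevalence.

    ``n_ec_samples`` counts samples where the EC's community total is
    nonzero (the denominator depends only on community totals, never on the
    focal species); ``n_species_samples`` counts those samples in which the
    species has a detectable stratum. ``prevalence`` is their ratio, NaN
    when the EC is never transcribed.
    """
    ecs = ecs if ecs is not None else table.ec_ids
    rows = []
    for ec in ecs:
        if ec in table.totals.columns:
            ec_on = table.totals[ec] > ZERO_TOL
        else:
            ec_on = pd.Series(False, index=table.sample_ids)
        n_ec = int(ec_on.sum())
        sub = table.strata[
            (table.strata["ec"] == ec)
            & (table.strata["species"] != UNCLASSIFIED)
            & (table.strata["cpm"] > ZERO_TOL)
        ]
        on_samples = set(ec_on.index[ec_on])
        counts = (
            sub[sub["sample"].isin(on_samples)].groupby("species")["sample"].nunique()
        )
        for sp, n_sp in counts.items():
            rows.append(
                {
                    "ec": ec,
                    "species": sp,
                    "n_ec_samples": n_ec,
                    "n_species_samples": int(n_sp),
                    "prevalence": n_sp / n_ec if n_ec else np.nan,
                }
            )
    return pd.DataFrame(
        rows, columns=["ec", "species", "n_ec_samples", "n_species_samples", "prevalence"]
    )


@dataclass
class DegraderScreenResults:
    """Call set produced by :meth:`DegraderScreen.fit`.

    The enforced chain is ``prevalent_versatile ⊆ versatile ⊆ transcribers``;
    encoders come from a different ome and are not required to contain the
    transcribers.
    """

    encoders: frozenset[str]
    transcribers: frozenset[str]
    versatile: frozenset[str]
    prevalent_versatile: frozenset[str]
    transcribed_ecs: dict[str, frozenset[str]]
    prevalence: pd.DataFrame
    ec_summary: pd.DataFrame
    mean_contribution: pd.DataFrame  # species x ec, % of EC community total
    min_prevalence: float

    def tier_of(self, species: str) -> str:
        if species in self.prevalent_versatile:
            return "prevalent_versatile"
        if species in self.versatile:
            return "versatile"
        if species in self.transcribers:
            return "transcriber"
        if species in self.encoders:
            return "encoder"
        return "none"

    def calls_frame(self) -> pd.DataFrame:
        species = sorted(self.encoders | self.transcribers)
        prev_best = (
            self.prevalence.groupby("species")["prevalence"].max()
            if len(self.prevalence)
            else pd.Series(dtype=float)
        )
        rows = [
            {
                "species": s,
                "tier": self.tier_of(s),
                "transcribed_ecs": ";".join(sorted(self.transcribed_ecs.get(s, ()))),
                "max_prevalence": round(float(prev_best.get(s, np.nan)), 6),
            }
            for s in species
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Mucosal glycan degrader screen",
            "==============================",
            f"encoders (any catalog EC in metagenome):      {len(self.encoders):5d}",
            f"transcribers (any catalog EC in transcripts): {len(self.transcribers):5d}",
            f"versatile (>1 EC, galactosidase-only removed):{len(self.versatile):5d}",
            f"prevalent versatile (prevalence >= "
            f"{self.min_prevalence:.0%} for >=1 EC):  {len(self.prevalent_versatile):5d}",
            "",
            "Per-EC detection (transcripts):",
            self.ec_summary.to_string(index=False, float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.calls_frame().to_csv(outdir / "degrader_calls.tsv", sep="\t", index=False)
        self.ec_summary.to_csv(outdir / "ec_summary.tsv", sep="\t", index=False)
        self.prevalence.to_csv(outdir / "prevalence.tsv", sep="\t", index=False)


class DegraderScreen:
    """Model object for the degrader filter cascade.

    Parameters
    ----------
    metagenome, transcripts :
        Species-stratified EC tables (gene copies and transcripts, cpm).
    catalog :
        EC catalog; defaults to the shipped mucin-degradation list.
    min_prevalence :
        Species-level transcription prevalence cutoff (inclusive, default
        0.10): keep species transcribing at least one EC in at least this
        fraction of the samples where that EC is transcribed.
    ec_prevalence_threshold :
        EC-level detection cutoff (strict, default 0.05).
    count_galactosidases_in_versatility :
        Whether the >1-EC versatility count includes the galactosidase ECs
        themselves (default True: a species transcribing beta-galactosidase
        plus a sialidase is versatile).
    """

    def __init__(
        self,
        metagenome: StratifiedFunctionTable | None,
        transcripts: StratifiedFunctionTable,
        catalog: ECCatalog | None = None,
        min_prevalence: float = 0.10,
        ec_prevalence_threshold: float = 0.05,
        count_galactosidases_in_versatility: bool = True,
    ) -> None:
        self.metagenome = metagenome
        self.transcripts = transcripts
        self.catalog = catalog or load_ec_catalog()
        if not (0.0 <= min_prevalence <= 1.0):
            raise ValidationError("min_prevalence must be in [0, 1]")
        self.min_prevalence = min_prevalence
        self.ec_prevalence_threshold = ec_prevalence_threshold
        self.count_galactosidases = count_galactosidases_in_versatility

    def fit(self) -> DegraderScreenResults:
        catalog = self.catalog
        active = [e for e in catalog.active_ecs]
        excluded = catalog.versatility_excluded_ecs

        def transcribed_sets(table: StratifiedFunctionTable) -> dict[str, frozenset[str]]:
            sub = table.strata[
                (table.strata["ec"].isin(active))
                & (table.strata["species"] != UNCLASSIFIED)
                & (table.strata["cpm"] > ZERO_TOL)
            ]
            return {
                sp: frozenset(g["ec"].unique()) for sp, g in sub.groupby("species")
            }

        mt_sets = transcribed_sets(self.transcripts)
        transcribers = frozenset(mt_sets)
        if not transcribers:
            warnings.warn("no species transcribe any catalog EC", stacklevel=2)
        encoders = (
            frozenset(transcribed_sets(self.metagenome))
            if self.metagenome is not None
            else frozenset()
        )

        # cascade: drop galactosidase-only transcribers, then single-EC ones
        not_gal_only = {
            s for s, ecs in mt_sets.items() if not ecs.issubset(excluded)
        }
        versatile = frozenset(
            s
            for s in not_gal_only
            if len(
                mt_sets[s] if self.count_galactosidases else mt_sets[s] - excluded
            )
            > 1
        )

        prevalence = transcription_prevalence(self.transcripts, active)
        keep = (
            prevalence[prevalence["prevalence"] >= self.min_prevalence]["species"]
            .unique()
            .tolist()
            if len(prevalence)
            else []
        )
        prevalent_versatile = versatile & frozenset(keep)

        summary = ec_prevalence(
            self.transcripts, catalog, self.ec_prevalence_threshold
        )
        mean_contrib = self._mean_contribution(active)
        return DegraderScreenResults(
            encoders=encoders,
            transcribers=transcribers,
            versatile=versatile,
            prevalent_versatile=frozenset(prevalent_versatile),
            transcribed_ecs=mt_sets,
            prevalence=prevalence,
            ec_summary=summary,
            mean_contribution=mean_contrib,
            min_prevalence=self.min_prevalence,
        )

    def _mean_contribution(self, active: list[str]) -> pd.DataFrame:
        """Species x EC mean % contribution over samples where the EC is on."""
        mt = self.transcripts
        frames = {}
        for ec in active:
            if ec not in mt.totals.columns:
                continue
            tot = mt.totals[ec]
            on = tot > ZERO_TOL
            if not on.any():
                continue
            mat = mt.stratum_matrix(ec).loc[on.index[on]]
            frames[ec] = (mat.div(tot[on], axis=0) * 100.0).mean(axis=0)
        if not frames:
            return pd.DataFrame()
        return pd.DataFrame(frames).fillna(0.0)


def gh_repertoire_comparison(
    mg: StratifiedFunctionTable,
    mt: StratifiedFunctionTable,
    catalog: ECCatalog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mucin-EC vs other-glycoside-hydrolase repertoire sizes per species.

    For every species with any catalog EC signal, counts the distinct
    catalog ECs and the distinct other GH-type ECs (EC class 3.2.1.- minus
    catalog members) in both the metagenome (encoded) and the transcript
    (transcribed) table, and fits the linear trend other ~ mucin for each
    ome. Returns ``(per_species, trends)``; a trend is flagged undefined
    when no other-GH ECs are present.
    """
    catalog = catalog or load_ec_catalog()
    cat_ecs = set(catalog.ec_ids)

    def counts(table: StratifiedFunctionTable) -> pd.DataFrame:
        pres = table.species_ec_presence()
        if pres.empty:
            return pd.DataFrame(columns=["n_mucin_ecs", "n_other_gh_ecs"])
        gh_cols = [c for c in pres.columns if c.startswith("3.2.1.")]
        mucin_cols = [c for c in pres.columns if c in cat_ecs]
        other_cols = [c for c in gh_cols if c not in cat_ecs]
        out = pd.DataFrame(
            {
                "n_mucin_ecs": pres[mucin_cols].sum(axis=1) if mucin_cols else 0,
                "n_other_gh_ecs": pres[other_cols].sum(axis=1) if other_cols else 0,
            }
        )
        return out[out["n_mucin_ecs"] > 0]

    enc = counts(mg).add_prefix("encoded_")
    tra = counts(mt).add_prefix("transcribed_")
    per_species = enc.join(tra, how="outer").fillna(0).astype(int)
    per_species.index.name = "species"

    trend_rows = []
    for ome, (xcol, ycol) in {
        "encoded": ("encoded_n_mucin_ecs", "encoded_n_other_gh_ecs"),
        "transcribed": ("transcribed_n_mucin_ecs", "transcribed_n_other_gh_ecs"),
    }.items():
        sub = per_species[per_species[xcol] > 0]
        x, y = sub[xcol].to_numpy(float), sub[ycol].to_numpy(float)
        if len(sub) < 3 or y.sum() == 0 or np.ptp(x) == 0:
            trend_rows.append(
                {"ome": ome, "slope": np.nan, "intercept": np.nan,
                 "adj_r2": np.nan, "p_value": np.nan, "n": len(sub), "defined": False}
            )
            continue
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        trend_rows.append(
            {
                "ome": ome,
                "slope": float(fit.params[1]),
                "intercept": float(fit.params[0]),
                "adj_r2": float(fit.rsquared_adj),
                "p_value": float(fit.f_pvalue),
                "n": int(fit.nobs),
                "defined": True,
            }
        )
    return per_species.reset_index(), pd.DataFrame(trend_rows)
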