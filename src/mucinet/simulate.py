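"""Synthetic stool-community generator with planted ecological structure.

The generator emulates the statistical shape of paired taxonomic and
species-stratified functional profiles without simulating reads:

* **abundances** — latent per-sample log-abundances drawn from a multivariate
  normal with block-diagonal correlation (``within_cluster_rho`` inside each
  of ``n_clusters`` blocks, zero outside), closed by softmax and multinomially
  sampled to ``total_reads_per_sample``. The blocks are the planted
  cooccurrence clusters.
* **transcription** — each mucin-degradation EC is transcribed by two guilds.
  *Competitive* species couple transcription to their own (clr) abundance:
  ``cpm = max(0, baseline + coupling_strength * (clr - mean clr) + noise)``.
  *Opportunistic* species transcribe at a baseline modulated by a logistic
  suppression term that decreases with the summed clr abundance of the
  competitive transcribers of the same EC (``suppression_strength`` sets the
  steepness); their transcription is thereby decoupled from their own
  abundance. Non-degraders transcribe nothing. A small unclassified stratum
  is added to every community total.
* **gene content** — degrader repertoires (plus encoder-only species and a
  proportional complement of non-catalog glycoside hydrolase ECs) appear in
  the metagenome table wherever the species is present.

By default an EC's competitive and opportunistic transcribers are placed in
different correlation blocks, so an opportunist's own abundance is
independent of the abundances that suppress it — the planted "decoupled"
regime is then identifiable rather than confounded with block correlation.

Everything is reproducible from ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, softmax

from mucinet.tables import (
    UNCLASSIFIED,
    AbundanceTable,
    ClrMatrix,
    ECCatalog,
    StratifiedFunctionTable,
    ValidationError,
    clr_transform,
    load_ec_catalog,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticCommunity",
    "simulate_abundances",
    "simulate_transcription",
    "simulate_gene_content",
    "simulate_community",
    "write_fixture_bundle",
]

ROLES = ("competitive", "opportunistic", "nondegrader")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic community.

    Defaults describe a desk-scale cohort: 300 samples, 40 species in four
    correlation blocks (within-block latent correlation 0.8), 100k estimated
    reads per sample, 10 competitive and 8 opportunistic degraders. Coupling
    (5 cpm per clr unit), suppression steepness (1 per clr unit) and noise
    (sd 2 cpm) are set so that the two transcription regimes are distinct but
    overlap realistically at the margins.
    """

    n_samples: int = 300
    n_species: int = 40
    n_clusters: int = 4
    within_cluster_rho: float = 0.8
    total_reads_per_sample: int = 100_000
    n_competitive: int | None = None  # default: 25% of n_species
    n_opportunistic: int | None = None  # default: 20% of n_species
    ec_repertoire: dict[str, tuple[str, ...]] | None = None
    roles: dict[str, str] | None = None
    coupling_strength: float = 5.0
    suppression_strength: float = 1.0
    noise_sd: float = 2.0
    baseline_cpm: float = 10.0
    unclassified_frac: float = 0.05
    latent_mu_sd: float = 1.5
    latent_sd: float = 1.0
    gh_slope: float = 2.0
    seed: int = 20240901

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_cluster_rho < 1.0):
            raise ValidationError("within_cluster_rho must be in [0, 1)")
        if self.n_clusters > self.n_species:
            raise ValidationError("n_clusters must not exceed n_species")
        if self.n_samples < 2 or self.n_species < 2:
            raise ValidationError("need at least 2 samples and 2 species")
        if self.noise_sd < 0 or self.unclassified_frac < 0:
            raise ValidationError("noise_sd and unclassified_frac must be >= 0")

    @property
    def eff_n_competitive(self) -> int:
        if self.n_competitive is not None:
            return self.n_competitive
        return max(1, round(0.25 * self.n_species))

    @property
    def eff_n_opportunistic(self) -> int:
        if self.n_opportunistic is not None:
            return self.n_opportunistic
        return max(1, round(0.20 * self.n_species))

    @property
    def species_ids(self) -> list[str]:
        return [f"Species{i:03d}" for i in range(1, self.n_species + 1)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"SAMPLE{i:04d}" for i in range(1, self.n_samples + 1)]

    def cluster_of(self) -> dict[str, int]:
        """Contiguous block assignment species -> cluster id (1-based)."""
        sp = self.species_ids
        return {
            s: (i * self.n_clusters) // self.n_species + 1 for i, s in enumerate(sp)
        }

    def resolve(self, catalog: ECCatalog | None = None):
        """Deterministic roles and EC repertoires implied by the config.

        User-supplied ``roles`` / ``ec_repertoire`` win; otherwise
        competitive species are drawn from the first half of the blocks and
        opportunists from the second half, each degrader gets 2-4 catalog
        ECs, and every EC is guaranteed at least one transcriber per guild.
        """
        catalog = catalog or load_ec_catalog()
        active = list(catalog.active_ecs)
        rng = np.random.default_rng([int(self.seed) % (2**31), 11])
        clusters = self.cluster_of()
        species = self.species_ids

        if self.roles is not None:
            roles = dict(self.roles)
            missing = set(species) - set(roles)
            if missing:
                raise ValidationError(f"roles missing for {sorted(missing)[:3]}...")
        else:
            half = {c for c in set(clusters.values()) if c <= self.n_clusters // 2}

            def interleave(pool_clusters: set[int]) -> list[str]:
                # round-robin over blocks so degraders span every block
                per_block = [
                    [s for s in species if clusters[s] == c]
                    for c in sorted(pool_clusters)
                ]
                out = []
                for i in range(max((len(b) for b in per_block), default=0)):
                    out.extend(b[i] for b in per_block if i < len(b))
                return out

            comp_pool = interleave(half)
            opp_pool = interleave(set(clusters.values()) - half)
            n_comp, n_opp = self.eff_n_competitive, self.eff_n_opportunistic
            if len(comp_pool) < n_comp or len(opp_pool) < n_opp:
                raise ValidationError("not enough species per block half for roles")
            comp = set(comp_pool[:n_comp])
            opp = set(opp_pool[:n_opp])
            roles = {
                s: "competitive" if s in comp else "opportunistic" if s in opp else "nondegrader"
                for s in species
            }
        bad = set(roles.values()) - set(ROLES)
        if bad:
            raise ValidationError(f"unknown role(s) {sorted(bad)}")

        if self.ec_repertoire is not None:
            repertoire = {s: tuple(v) for s, v in self.ec_repertoire.items()}
        else:
            repertoire = {}
            for s in species:
                if roles[s] == "nondegrader":
                    repertoire[s] = ()
                else:
                    k = int(rng.integers(2, 5))
                    repertoire[s] = tuple(
                        sorted(rng.choice(active, size=min(k, len(active)), replace=False))
                    )
            for guild in ("competitive", "opportunistic"):
                members = [s for s in species if roles[s] == guild]
                for ec in active:
                    if members and not any(ec in repertoire[s] for s in members):
                        s = members[int(rng.integers(len(members)))]
                        repertoire[s] = tuple(sorted(set(repertoire[s]) | {ec}))
        for s in species:
            if roles[s] in ("competitive", "opportunistic") and not repertoire.get(s):
                raise ValidationError(f"{roles[s]} species {s} has an empty EC repertoire")
        return roles, repertoire, clusters, catalog


@dataclass
class GroundTruth:
    """Planted structure: cluster labels, guild roles, and suppression edges."""

    cluster_assignment: dict[str, int]
    role: dict[str, str]
    repertoire: dict[str, tuple[str, ...]]
    planted_edges: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (predictor, response, ec, sign)

    def __post_init__(self) -> None:
        for pred, resp, ec, sign in self.planted_edges:
            if ec not in self.repertoire.get(resp, ()):
                raise ValidationError(
                    f"planted edge {pred}->{resp} references EC {ec} "
                    f"outside the response repertoire"
                )

    @property
    def degraders(self) -> list[str]:
        return sorted(s for s, r in self.role.items() if r != "nondegrader")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": s,
                "cluster": self.cluster_assignment[s],
                "role": self.role[s],
                "repertoire": ";".join(self.repertoire.get(s, ())),
            }
            for s in sorted(self.role)
        ]
        return pd.DataFrame(rows)


def _block_cholesky(config: GeneratorConfig) -> np.ndarray:
    """Cholesky factor of the block-diagonal latent correlation matrix."""
    p = config.n_species
    clusters = config.cluster_of()
    species = config.species_ids
    corr = np.eye(p)
    labels = np.array([clusters[s] for s in species])
    same = labels[:, None] == labels[None, :]
    corr[same] = config.within_cluster_rho
    np.fill_diagonal(corr, 1.0)
    return np.linalg.cholesky(corr)


def simulate_abundances(
    config: GeneratorConfig, catalog: ECCatalog | None = None
) -> tuple[AbundanceTable, GroundTruth]:
    """Draw the samples x species estimated-read-count table.

    Latent log-abundances are multivariate normal with the planted block
    correlation, softmax-closed per sample, then multinomially sampled to the
    configured sequencing depth (log-normal + multinomial overdispersion).
    """
    roles, repertoire, clusters, catalog = config.resolve(catalog)
    rng = np.random.default_rng([int(config.seed) % (2**31), 1])
    p, n = config.n_species, config.n_samples
    mu = rng.normal(0.0, config.latent_mu_sd, size=p)
    L = _block_cholesky(config)
    eps = rng.standard_normal(size=(n, p))
    z = mu + config.latent_sd * (eps @ L.T)
    probs = softmax(z, axis=1)
    counts = rng.multinomial(config.total_reads_per_sample, probs)
    rc = pd.DataFrame(
        counts.astype(float), index=config.sample_ids, columns=config.species_ids
    )
    ra = rc.div(rc.sum(axis=1), axis=0) * 100.0
    truth = GroundTruth(clusters, roles, repertoire)
    return AbundanceTable(rc, ra), truth


def simulate_transcription(
    abund: AbundanceTable,
    config: GeneratorConfig,
    catalog: ECCatalog | None = None,
) -> tuple[StratifiedFunctionTable, GroundTruth]:
    """Emit the species-stratified transcript table (cpm) for the community.

    Implements the two planted regimes (abundance-coupled competitive,
    competitor-suppressed opportunistic) described in the module docstring
    and records every (competitive predictor -> opportunist response, EC)
    pair as a planted negative edge.
    """
    roles, repertoire, clusters, catalog = config.resolve(catalog)
    rng = np.random.default_rng([int(config.seed) % (2**31), 2])
    clr = clr_transform(abund).values
    samples = abund.sample_ids
    active = list(catalog.active_ecs)

    records: list[tuple[str, str, str, float]] = []
    planted: list[tuple[str, str, str, str]] = []
    totals = pd.DataFrame(0.0, index=samples, columns=active)

    for ec in active:
        comp = [s for s in abund.species_ids
                if roles.get(s) == "competitive" and ec in repertoire.get(s, ())]
        opp = [s for s in abund.species_ids
               if roles.get(s) == "opportunistic" and ec in repertoire.get(s, ())]
        ec_cpm = pd.DataFrame(0.0, index=samples, columns=comp + opp)
        for s in comp:
            centered = clr[s] - clr[s].mean()
            noise = rng.normal(0.0, config.noise_sd, size=len(samples))
            ec_cpm[s] = np.maximum(
                0.0, config.baseline_cpm + config.coupling_strength * centered.to_numpy() + noise
            )
        if comp:
            comp_sum = clr[comp].sum(axis=1).to_numpy()
            comp_sum = comp_sum - np.median(comp_sum)
        else:
            comp_sum = np.zeros(len(samples))
        for s in opp:
            gate = expit(-config.suppression_strength * comp_sum)
            noise = rng.normal(0.0, config.noise_sd, size=len(samples))
            ec_cpm[s] = np.maximum(0.0, 2.0 * config.baseline_cpm * gate + noise)
            for pred in comp:
                planted.append((pred, s, ec, "negative"))
        stratum_sum = ec_cpm.sum(axis=1).to_numpy()
        uncl = np.where(
            stratum_sum > 0,
            stratum_sum
            * config.unclassified_frac
            / max(1e-12, 1.0 - config.unclassified_frac)
            * rng.uniform(0.8, 1.2, size=len(samples)),
            0.0,
        )
        totals[ec] = stratum_sum + uncl
        for s in ec_cpm.columns:
            col = ec_cpm[s].to_numpy()
            for i, sample in enumerate(samples):
                if col[i] > 0:
                    records.append((sample, ec, s, float(col[i])))
        for i, sample in enumerate(samples):
            if uncl[i] > 0:
                records.append((sample, ec, UNCLASSIFIED, float(uncl[i])))

    strata = pd.DataFrame(records, columns=["sample", "ec", "species", "cpm"])
    truth = GroundTruth(clusters, roles, repertoire, planted)
    return StratifiedFunctionTable(strata, totals), truth


#: non-catalog glycoside-hydrolase EC ids available to the repertoire sampler
_OTHER_GH_POOL = [f"3.2.1.{i}" for i in range(1, 160)]


def simulate_gene_content(
    abund: AbundanceTable,
    config: GeneratorConfig,
    catalog: ECCatalog | None = None,
) -> tuple[StratifiedFunctionTable, StratifiedFunctionTable]:
    """Metagenome (gene) table and transcribed other-GH complement.

    Returns ``(mg, mt_other_gh)``: the gene table carries every degrader's
    mucin repertoire plus encoder-only ECs on about half of the
    non-degraders, together with a complement of non-catalog glycoside
    hydrolase ECs whose count is proportional (slope ``gh_slope``) to the
    mucin repertoire size; the second table holds the transcribed ~70% subset
    of that complement, to be concatenated onto the transcript table when a
    repertoire comparison across all GH enzymes is wanted.
    """
    roles, repertoire, clusters, catalog = config.resolve(catalog)
    rng = np.random.default_rng([int(config.seed) % (2**31), 3])
    samples = abund.sample_ids
    pool = [e for e in _OTHER_GH_POOL if e not in set(catalog.ec_ids)]

    encoded: dict[str, set[str]] = {}
    transcribed_other: dict[str, set[str]] = {}
    active = list(catalog.active_ecs)
    for s in abund.species_ids:
        ecs = set(repertoire.get(s, ()))
        if roles[s] == "nondegrader" and rng.random() < 0.5:
            ecs |= set(rng.choice(active, size=int(rng.integers(1, 3)), replace=False))
        n_other = max(0, int(round(config.gh_slope * len(ecs) + rng.normal(0.0, 0.7))))
        others = set(rng.choice(pool, size=min(n_other, len(pool)), replace=False))
        encoded[s] = ecs | others
        n_tr = int(np.ceil(0.7 * len(others)))
        transcribed_other[s] = set(
            rng.choice(sorted(others), size=n_tr, replace=False)
        ) if n_tr else set()

    present = abund.read_counts > 0
    rel = abund.rel_abundance

    def build(assignment: Mapping[str, set[str]]) -> StratifiedFunctionTable:
        records = []
        ec_ids = sorted({e for v in assignment.values() for e in v})
        totals = pd.DataFrame(0.0, index=samples, columns=ec_ids)
        for s, ecs in assignment.items():
            mask = present[s].to_numpy()
            vals = rel[s].to_numpy() * 10.0
            for ec in ecs:
                for i, sample in enumerate(samples):
                    if mask[i] and vals[i] > 0:
                        records.append((sample, ec, s, float(vals[i])))
        strata = pd.DataFrame(records, columns=["sample", "ec", "species", "cpm"])
        if len(strata):
            sums = strata.groupby(["sample", "ec"])["cpm"].sum().unstack(fill_value=0.0)
            totals.loc[sums.index, sums.columns] = sums.to_numpy()
        totals *= 1.0 + config.unclassified_frac
        return StratifiedFunctionTable(strata, totals)

    return build(encoded), build(transcribed_other)


@dataclass
class SyntheticCommunity:
    """Bundle of everything the generator produced for one config."""

    config: GeneratorConfig
    abundance: AbundanceTable
    metagenome: StratifiedFunctionTable
    transcripts: StratifiedFunctionTable
    truth: GroundTruth
    catalog: ECCatalog


def simulate_community(
    config: GeneratorConfig | None = None,
    catalog: ECCatalog | None = None,
    with_other_gh: bool = False,
) -> SyntheticCommunity:
    """Run the full generator: abundances, gene content and transcription."""
    config = config or GeneratorConfig()
    catalog = catalog or load_ec_catalog()
    abund, truth_a = simulate_abundances(config, catalog)
    mt, truth = simulate_transcription(abund, config, catalog)
    mg, mt_gh = simulate_gene_content(abund, config, catalog)
    if with_other_gh and len(mt_gh.strata):
        strata = pd.concat([mt.strata, mt_gh.strata], ignore_index=True)
        totals = mt.totals.join(mt_gh.totals, how="outer").fillna(0.0)
        totals = totals.reindex(mt.sample_ids)
        mt = StratifiedFunctionTable(strata, totals)
    return SyntheticCommunity(config, abund, mg, mt, truth, catalog)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(
    config: GeneratorConfig, outdir: str | Path, catalog: ECCatalog | None = None
) -> dict:
    """Write a self-contained fixture bundle and return its manifest.

    Layout: ``profiles/<sample>.tsv`` per-sample taxonomic profiles,
    ``transcript_ec.tsv`` and ``gene_ec.tsv`` stratified functional tables,
    ``catalog.tsv``, ``ground_truth.tsv``, ``planted_edges.tsv`` and
    ``manifest.json`` with per-file sha256 checksums and the config.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {outdir}: {exc}") from exc
    com = simulate_community(config, catalog, with_other_gh=True)
    files: list[Path] = []
    files += com.abundance.write_profiles(outdir / "profiles")
    mt_path = outdir / "transcript_ec.tsv"
    com.transcripts.to_tsv(mt_path)
    mg_path = outdir / "gene_ec.tsv"
    com.metagenome.to_tsv(mg_path)
    cat_path = outdir / "catalog.tsv"
    com.catalog.entries.to_csv(cat_path, sep="\t", index=False)
    gt_path = outdir / "ground_truth.tsv"
    com.truth.to_frame().to_csv(gt_path, sep="\t", index=False)
    pe_path = outdir / "planted_edges.tsv"
    pd.DataFrame(
        com.truth.planted_edges, columns=["predictor", "response", "ec", "sign"]
    ).to_csv(pe_path, sep="\t", index=False)
    files += [mt_path, mg_path, cat_path, gt_path, pe_path]
    manifest = {
        "config": asdict(config),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(files)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
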