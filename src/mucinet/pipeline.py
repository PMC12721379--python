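"""End-to-end orchestration: tables -> screen -> networks -> regressions.

A single :class:`RunConfig` carries every threshold of the analysis with its
standard default (species prevalence 0.10, EC prevalence 0.05, minimum
retained rho 0.2, 99% null CI from 1000 shuffles, per-coefficient alpha
0.05, competitive threshold 0.2, species universe >= 20 present samples),
and :func:`run_pipeline` executes the stages deterministically for a given
seed, writing tidy TSV artifacts plus a machine-readable run report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from mucinet import __version__
from mucinet.tables import (
    AbundanceTable,
    StratifiedFunctionTable,
    ValidationError,
    clr_transform,
    config_hash,
    load_ec_catalog,
    read_abundance_profiles,
    read_stratified_ec_table,
)
from mucinet.simulate import GeneratorConfig, simulate_community
from mucinet.screen import DegraderScreen
from mucinet.cooccurrence import CooccurrenceModel
from mucinet.regression import TranscriptionModel

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs, thresholds and seed of one pipeline run."""

    # either file inputs ...
    profile_paths: list[str] = field(default_factory=list)
    metagenome_ec_path: str | None = None
    transcript_ec_path: str | None = None
    # ... or the generator
    generator: GeneratorConfig | None = None
    catalog_path: str | None = None
    outdir: str = "mucinet_run"
    min_prevalence: float = 0.10
    ec_prevalence: float = 0.05
    min_rho: float = 0.2
    ci_level: float = 0.99
    n_reps: int = 1000
    alpha: float = 0.05
    competitive_threshold: float = 0.2
    min_present_samples: int = 20
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 100:
            raise ValidationError("n_reps must be >= 100")
        for name, lo, hi in (
            ("min_prevalence", 0, 1),
            ("ec_prevalence", 0, 1),
            ("ci_level", 0, 1),
            ("alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_rho < 0:
            raise ValidationError("min_rho must be >= 0")
        has_files = bool(self.transcript_ec_path)
        if not has_files and self.generator is None:
            raise ValidationError("either file inputs or a generator config required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a YAML mapping")
        gen = raw.pop("generator", None)
        try:
            return cls(**raw, generator=GeneratorConfig(**gen) if gen else None)
        except TypeError as exc:
            raise ValidationError(f"{path}: {exc}") from exc

    def hash(self) -> str:
        d = asdict(self)
        d.pop("outdir")  # where results land does not change what they are
        return config_hash(d)


@dataclass
class RunReport:
    """Stage-by-stage record counts, attrition, warnings and provenance."""

    config_hash: str
    version: str
    seed: int
    counts: dict[str, int]
    attrition: dict[str, int]
    warnings: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    def validate(self) -> None:
        a = self.attrition
        chain = ["transcribers", "versatile", "prevalent_versatile"]
        for up, down in zip(chain, chain[1:]):
            if a[down] > a[up]:
                raise ValidationError(f"attrition inconsistent: {down} > {up}")


def _load_inputs(config: RunConfig):
    catalog = load_ec_catalog(config.catalog_path)
    if config.generator is not None:
        com = simulate_community(config.generator, catalog)
        return com.abundance, com.metagenome, com.transcripts, catalog
    abund = (
        read_abundance_profiles(config.profile_paths)
        if config.profile_paths
        else None
    )
    mt = read_stratified_ec_table(config.transcript_ec_path)
    mg = (
        read_stratified_ec_table(config.metagenome_ec_path)
        if config.metagenome_ec_path
        else None
    )
    if abund is None:
        raise ValidationError("taxonomic profiles are required for file inputs")
    return abund, mg, mt, catalog


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages; write artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")
        abund, mg, mt, catalog = _load_inputs(config)

        screen = DegraderScreen(
            mg, mt, catalog,
            min_prevalence=config.min_prevalence,
            ec_prevalence_threshold=config.ec_prevalence,
        )
        calls = screen.fit()
        calls.write(outdir)

        degraders = set(calls.prevalent_versatile)
        net = None
        if degraders:
            model = CooccurrenceModel(
                abund,
                degraders,
                min_present_samples=config.min_present_samples,
                pseudocount=config.pseudocount,
                n_reps=config.n_reps,
                ci_level=config.ci_level,
                min_rho=config.min_rho,
            )
            net = model.fit(seed=config.seed)
            net.write(outdir)

        clr = clr_transform(abund, pseudocount=config.pseudocount)
        tmodel = TranscriptionModel(
            mt,
            clr,
            catalog,
            species_subset=degraders or None,
            min_prevalence=config.min_prevalence,
            alpha=config.alpha,
            competitive_threshold=config.competitive_threshold,
        )
        tres = tmodel.fit()
        tres.write(outdir)
        caught = [str(w.message) for w in wlog]

    counts = {
        "samples": abund.n_samples,
        "species": abund.n_species,
        "network_nodes": net.network.number_of_nodes() if net else 0,
        "network_edges": net.network.number_of_edges() if net else 0,
        "network_clusters": len(set(net.clusters.values())) if net else 0,
        "abundance_fits": len(tres.abundance_fits),
        "rp_edges": len(tres.rp_edges),
        "consensus_pairs": len(tres.consensus),
    }
    attrition = {
        "encoders": len(calls.encoders),
        "transcribers": len(calls.transcribers),
        "versatile": len(calls.versatile),
        "prevalent_versatile": len(calls.prevalent_versatile),
    }
    report = RunReport(
        config_hash=config.hash(),
        version=__version__,
        seed=config.seed,
        counts=counts,
        attrition=attrition,
        warnings=caught,
    )
    report.validate()
    report.to_json(outdir / "run_report.json")
    return report
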