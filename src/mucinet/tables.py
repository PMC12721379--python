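"""Data model and I/O for taxonomic and species-stratified functional profiles.

Two TSV dialects are supported:

* per-sample taxonomic profiles in the MetaPhlAn ``rel_ab_w_read_stats`` style
  (``clade_name`` / ``relative_abundance`` / ``estimated_number_of_reads_from_the_clade``
  columns, species rows identified by the ``s__`` rank prefix), merged into an
  :class:`AbundanceTable`;
* multi-sample functional profiles in the HUMAnN regrouped style
  (``# Gene Family`` header, bare ``EC`` rows as community totals and
  ``EC|g__X.s__Y`` rows as per-species strata), parsed into a
  :class:`StratifiedFunctionTable` in copies per million (cpm).

The module also houses the centered log-ratio (clr) transform shared by all
downstream analyses and the catalog of mucin-glycan-degradation enzyme
commission numbers (ECs).
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AbundanceTable",
    "ClrMatrix",
    "StratifiedFunctionTable",
    "ECCatalog",
    "ParseError",
    "ValidationError",
    "ConsistencyError",
    "read_abundance_profiles",
    "read_stratified_ec_table",
    "clr_transform",
    "load_ec_catalog",
    "UNCLASSIFIED",
    "ZERO_TOL",
]

#: sentinel species id for the unclassified stratum of a functional profile
UNCLASSIFIED = "UNCLASSIFIED"

#: cpm / count values at or below this magnitude are exact zeros for
#: presence/absence logic
ZERO_TOL = 1e-12

EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.\d+$")

_GALACTOSIDASE_ECS = frozenset({"3.2.1.22", "3.2.1.23"})


class ParseError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """A table or config violates a structural invariant."""


class ConsistencyError(ValueError):
    """Numerically inconsistent data (e.g. stratum exceeding its total)."""


def _tool_header(config_hash: str | None = None) -> str:
    from mucinet import __version__

    h = f" config={config_hash}" if config_hash else ""
    return f"# generated by mucinet v{__version__}{h}"


def config_hash(obj) -> str:
    """Stable short hash of an arbitrary (YAML-serialisable) config object."""
    blob = yaml.safe_dump(obj, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Samples x species estimated read counts plus relative abundances (%).

    ``read_counts`` and ``rel_abundance`` are aligned DataFrames indexed by
    sample id with one column per species. Relative abundances are
    percentages; row sums may fall below 100 (an unclassified fraction is
    permitted) but never exceed it.
    """

    read_counts: pd.DataFrame
    rel_abundance: pd.DataFrame

    def __post_init__(self) -> None:
        rc, ra = self.read_counts, self.rel_abundance
        if not rc.index.equals(ra.index) or not rc.columns.equals(ra.columns):
            raise ValidationError("read_counts and rel_abundance axes differ")
        if rc.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if rc.columns.has_duplicates:
            raise ValidationError("duplicate species ids")
        if (rc.to_numpy() < 0).any():
            raise ValidationError("negative read counts")
        row_sums = ra.sum(axis=1)
        if (row_sums > 100 + 1e-6).any():
            bad = row_sums[row_sums > 100 + 1e-6].index[0]
            raise ValidationError(
                f"relative abundances of sample {bad!r} sum to {row_sums[bad]:.6f} > 100"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.read_counts.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.read_counts.columns)

    @property
    def n_samples(self) -> int:
        return self.read_counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.read_counts.shape[1]

    def presence_counts(self) -> pd.Series:
        """Number of samples in which each species has a nonzero read count."""
        return (self.read_counts > ZERO_TOL).sum(axis=0)

    def write_profiles(
        self,
        outdir: str | Path,
        lineage: Mapping[str, str] | None = None,
        config_hash: str | None = None,
    ) -> list[Path]:
        """Write one MetaPhlAn-style profile file per sample; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for sample in self.sample_ids:
            path = outdir / f"{sample}.tsv"
            with open(path, "w") as fh:
                fh.write(_tool_header(config_hash) + "\n")
                fh.write(
                    "clade_name\trelative_abundance\testimated_number_of_reads_from_the_clade\n"
                )
                for sp in self.species_ids:
                    clade = lineage[sp] if lineage else f"k__Bacteria|s__{sp}"
                    fh.write(
                        f"{clade}\t{self.rel_abundance.at[sample, sp]:.10g}"
                        f"\t{self.read_counts.at[sample, sp]:.10g}\n"
                    )
            paths.append(path)
        return paths


@dataclass
class ClrMatrix:
    """Centered log-ratio values on the same axes as an AbundanceTable."""

    values: pd.DataFrame
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("nonfinite clr values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.columns)


def clr_transform(
    table: AbundanceTable | pd.DataFrame,
    pseudocount: float = 1.0,
    where: str = "counts",
) -> ClrMatrix:
    """Centered log-ratio transform of estimated read counts, per sample.

    With ``where="counts"`` (default) the pseudocount is added to the read
    counts before taking the geometric mean, so each transformed row sums to
    exactly zero: ``clr = ln(c + pc) - mean(ln(c + pc))``. With
    ``where="ratio"`` the pseudocount is instead added to the ratio to the
    geometric mean of the positive counts (``ln(c / g + pc)``); rows are then
    not exactly centered. Both variants exist for sensitivity checks.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    counts = table.read_counts if isinstance(table, AbundanceTable) else table
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("negative counts in clr input")
    if where == "counts":
        logv = np.log(x + pseudocount)
        vals = logv - logv.mean(axis=1, keepdims=True)
    elif where == "ratio":
        pos = np.where(x > ZERO_TOL, x, np.nan)
        log_g = np.nanmean(np.log(pos), axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            vals = np.log(x / np.exp(log_g) + pseudocount)
        vals = np.nan_to_num(vals, nan=np.log(pseudocount))
    else:
        raise ValidationError(f"unknown clr variant {where!r}")
    return ClrMatrix(
        pd.DataFrame(vals, index=counts.index, columns=counts.columns),
        pseudocount=pseudocount,
    )


_SPECIES_RE_DEFAULT = r"\|?s__([^|\t]+)$"


def read_abundance_profiles(
    paths: Sequence[str | Path],
    dialect: str = "metaphlan",
    species_regex: str = _SPECIES_RE_DEFAULT,
) -> AbundanceTable:
    """Merge per-sample MetaPhlAn-style profiles into one AbundanceTable.

    Only species-level clades (terminal ``s__`` rank, no strain suffix) are
    retained; the union of species across files is taken and absent species
    get zero counts. The sample id is the file stem.
    """
    if dialect != "metaphlan":
        raise ParseError(f"unknown profile dialect {dialect!r}")
    sp_re = re.compile(species_regex)
    count_rows: dict[str, dict[str, float]] = {}
    rel_rows: dict[str, dict[str, float]] = {}
    for path in paths:
        path = Path(path)
        sample = path.stem
        if sample in count_rows:
            raise ParseError(f"duplicate sample id {sample!r} from {path}")
        counts: dict[str, float] = {}
        rels: dict[str, float] = {}
        cols: dict[str, int] | None = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    # MetaPhlAn headers are comment lines; the column header
                    # may itself be commented ("#clade_name\t...")
                    stripped = line.lstrip("# ")
                    if stripped.startswith("clade_name"):
                        cols = {c: i for i, c in enumerate(stripped.split("\t"))}
                    continue
                fields = line.split("\t")
                if cols is None:
                    if fields[0] == "clade_name":
                        cols = {c: i for i, c in enumerate(fields)}
                        continue
                    raise ParseError(
                        f"{path}:{lineno}: no clade_name header before data"
                    )
                for required in (
                    "clade_name",
                    "relative_abundance",
                    "estimated_number_of_reads_from_the_clade",
                ):
                    if required not in cols:
                        raise ParseError(f"{path}: missing column {required!r}")
                clade = fields[cols["clade_name"]]
                if "t__" in clade:
                    continue  # strain-level rows sit below species rank
                m = sp_re.search(clade)
                if not m:
                    continue
                sp = m.group(1)
                try:
                    rel = float(fields[cols["relative_abundance"]])
                    cnt = float(
                        fields[cols["estimated_number_of_reads_from_the_clade"]]
                    )
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{lineno}: bad numeric field") from exc
                counts[sp] = cnt
                rels[sp] = rel
        if not counts:
            warnings.warn(f"no species-level rows in {path}", stacklevel=2)
        count_rows[sample] = counts
        rel_rows[sample] = rels
    rc = pd.DataFrame.from_dict(count_rows, orient="index").fillna(0.0)
    ra = pd.DataFrame.from_dict(rel_rows, orient="index").fillna(0.0)
    rc = rc.reindex(sorted(rc.columns), axis=1).sort_index()
    ra = ra.reindex(columns=rc.columns, index=rc.index).fillna(0.0)
    return AbundanceTable(rc.astype(float), ra.astype(float))


# ---------------------------------------------------------------------------
# stratified functional tables
# ---------------------------------------------------------------------------


@dataclass
class StratifiedFunctionTable:
    """(sample, EC, species) copies-per-million values with community totals.

    ``strata`` is a long DataFrame with columns ``sample``, ``ec``,
    ``species`` (the :data:`UNCLASSIFIED` sentinel marks the unclassified
    stratum) and ``cpm``. ``totals`` is a samples x ECs DataFrame of
    community totals (the bare-EC rows of the HUMAnN dialect).
    """

    strata: pd.DataFrame
    totals: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"sample", "ec", "species", "cpm"}
        if not need.issubset(self.strata.columns):
            raise ValidationError(f"strata must have columns {sorted(need)}")
        if (self.strata["cpm"].to_numpy() < 0).any():
            raise ValidationError("negative cpm values")
        if (self.totals.to_numpy() < 0).any():
            raise ValidationError("negative community totals")
        for ec in self.totals.columns:
            if not EC_PATTERN.match(ec):
                raise ValidationError(f"malformed EC id {ec!r}")
        sums = (
            self.strata.groupby(["sample", "ec"])["cpm"].sum()
            if len(self.strata)
            else pd.Series(dtype=float)
        )
        for (sample, ec), s in sums.items():
            tot = self.totals.at[sample, ec] if ec in self.totals.columns else 0.0
            if s > tot + 1e-6:
                raise ConsistencyError(
                    f"strata of ({sample}, {ec}) sum to {s:.6g} > total {tot:.6g}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.totals.index)

    @property
    def ec_ids(self) -> list[str]:
        return list(self.totals.columns)

    @property
    def species_ids(self) -> list[str]:
        sp = self.strata.loc[self.strata["species"] != UNCLASSIFIED, "species"]
        return sorted(sp.unique())

    def community_total(self, sample: str, ec: str) -> float:
        if ec not in self.totals.columns:
            return 0.0
        return float(self.totals.at[sample, ec])

    def stratum_matrix(self, ec: str) -> pd.DataFrame:
        """Samples x species cpm matrix for one EC (UNCLASSIFIED excluded)."""
        sub = self.strata[
            (self.strata["ec"] == ec) & (self.strata["species"] != UNCLASSIFIED)
        ]
        mat = sub.pivot_table(
            index="sample", columns="species", values="cpm", aggfunc="sum"
        )
        return mat.reindex(self.sample_ids).fillna(0.0)

    def species_ec_presence(self) -> pd.DataFrame:
        """Species x EC boolean: any sample with cpm above the zero rule."""
        sub = self.strata[self.strata["species"] != UNCLASSIFIED]
        detected = sub[sub["cpm"] > ZERO_TOL]
        return detected.pivot_table(
            index="species", columns="ec", values="cpm", aggfunc="size"
        ).notna()

    def to_tsv(self, path: str | Path, config_hash: str | None = None) -> None:
        """Write in the HUMAnN-regrouped dialect (totals + stratified rows)."""
        samples = self.sample_ids
        lines = [_tool_header(config_hash), "# Gene Family\t" + "\t".join(samples)]
        piv = self.strata.pivot_table(
            index=["ec", "species"], columns="sample", values="cpm", aggfunc="sum"
        ).reindex(columns=samples).fillna(0.0)
        for ec in self.ec_ids:
            vals = "\t".join(f"{v:.10g}" for v in self.totals[ec].reindex(samples))
            lines.append(f"{ec}\t{vals}")
            if ec in piv.index.get_level_values(0):
                for (_, sp), row in piv.loc[[ec]].iterrows():
                    label = "unclassified" if sp == UNCLASSIFIED else f"g__unknown.s__{sp}"
                    vals = "\t".join(f"{v:.10g}" for v in row)
                    lines.append(f"{ec}|{label}\t{vals}")
        Path(path).write_text("\n".join(lines) + "\n")


def read_stratified_ec_table(
    path: str | Path, dialect: str = "humann"
) -> StratifiedFunctionTable:
    """Parse a HUMAnN-regrouped-style TSV into a StratifiedFunctionTable.

    Bare-EC rows become community totals; ``EC|g__X.s__Y`` rows become
    species strata; ``EC|unclassified`` maps to the UNCLASSIFIED stratum.
    A missing bare-EC row is imputed as the sum of its strata (warning).
    """
    if dialect != "humann":
        raise ParseError(f"unknown functional-table dialect {dialect!r}")
    path = Path(path)
    samples: list[str] | None = None
    totals: dict[str, dict[str, float]] = {}
    records: list[tuple[str, str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("# ")
                if stripped.lower().startswith("gene family"):
                    samples = stripped.split("\t")[1:]
                continue
            fields = line.split("\t")
            if samples is None:
                raise ParseError(f"{path}:{lineno}: no '# Gene Family' header")
            if len(fields) != len(samples) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(samples) + 1} columns, "
                    f"got {len(fields)}"
                )
            feature = fields[0]
            try:
                values = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad numeric field") from exc
            if "|" in feature:
                ec, taxon = feature.split("|", 1)
                if taxon == "unclassified":
                    sp = UNCLASSIFIED
                else:
                    m = re.search(r"s__(.+)$", taxon)
                    sp = m.group(1) if m else taxon
                for sample, v in zip(samples, values):
                    if v != 0.0:
                        records.append((sample, ec, sp, v))
            else:
                if not EC_PATTERN.match(feature):
                    raise ParseError(f"{path}:{lineno}: malformed EC id {feature!r}")
                totals[feature] = dict(zip(samples, values))
    strata = pd.DataFrame(records, columns=["sample", "ec", "species", "cpm"])
    ecs = sorted(set(totals) | set(strata["ec"].unique()))
    tot_df = pd.DataFrame(0.0, index=samples, columns=ecs)
    for ec, row in totals.items():
        for sample, v in row.items():
            tot_df.at[sample, ec] = v
    missing = [ec for ec in ecs if ec not in totals]
    if missing:
        warnings.warn(
            f"no community-total row for {missing}; imputed as sum of strata",
            stacklevel=2,
        )
        sums = strata.groupby(["sample", "ec"])["cpm"].sum()
        for ec in missing:
            for sample in samples:
                if (sample, ec) in sums.index:
                    tot_df.at[sample, ec] = sums[(sample, ec)]
    return StratifiedFunctionTable(strata, tot_df)


# ---------------------------------------------------------------------------
# EC catalog
# ---------------------------------------------------------------------------


@dataclass
class ECCatalog:
    """Catalog of mucin-degradation ECs with class and CAZy family metadata."""

    entries: pd.DataFrame  # ec_id, name, enzyme_class, gh_families, versatility_excluded, active

    _CLASSES = {"glycosyl_hydrolase", "lyase", "sulfatase"}

    def __post_init__(self) -> None:
        need = {
            "ec_id",
            "name",
            "enzyme_class",
            "gh_families",
            "versatility_excluded",
            "active",
        }
        if not need.issubset(self.entries.columns):
            raise ValidationError(f"catalog must have columns {sorted(need)}")
        if self.entries["ec_id"].duplicated().any():
            dup = self.entries.loc[self.entries["ec_id"].duplicated(), "ec_id"].iloc[0]
            raise ValidationError(f"duplicate EC id {dup!r} in catalog")
        for ec in self.entries["ec_id"]:
            if not EC_PATTERN.match(ec):
                raise ValidationError(f"malformed EC id {ec!r}")
        bad = set(self.entries["enzyme_class"]) - self._CLASSES
        if bad:
            raise ValidationError(f"unknown enzyme class(es) {sorted(bad)}")

    @property
    def ec_ids(self) -> list[str]:
        return list(self.entries["ec_id"])

    @property
    def active_ecs(self) -> list[str]:
        return list(self.entries.loc[self.entries["active"], "ec_id"])

    @property
    def versatility_excluded_ecs(self) -> frozenset[str]:
        return frozenset(
            self.entries.loc[self.entries["versatility_excluded"], "ec_id"]
        )

    def name_of(self, ec: str) -> str:
        row = self.entries.loc[self.entries["ec_id"] == ec, "name"]
        return row.iloc[0] if len(row) else ec

    def gh_families_of(self, ec: str) -> list[str]:
        row = self.entries.loc[self.entries["ec_id"] == ec, "gh_families"]
        if not len(row) or not row.iloc[0]:
            return []
        return row.iloc[0].split(";")


def load_ec_catalog(path: str | Path | None = None) -> ECCatalog:
    """Load an EC catalog from TSV or YAML; with no path, the shipped default.

    The default catalog mirrors the curated mucin-degradation enzyme list:
    11 detectable ECs, the GlcNAc-6-sulfatase flagged inactive (detected too
    rarely to analyse), and the two galactosidases flagged as excluded from
    the versatility count because galactose is widespread in dietary glycans.
    """
    if path is None:
        ref = resources.files("mucinet.data") / "mucin_ec_catalog.tsv"
        with resources.as_file(ref) as p:
            return load_ec_catalog(p)
    path = Path(path)
    if path.suffix in {".yml", ".yaml"}:
        raw = yaml.safe_load(path.read_text())
        df = pd.DataFrame(raw)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    for col, default in (("versatility_excluded", "False"), ("active", "True")):
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].astype(str).str.lower().isin({"true", "1", "yes"})
    if "gh_families" not in df.columns:
        df["gh_families"] = ""
    df["gh_families"] = df["gh_families"].fillna("")
    return ECCatalog(df.reset_index(drop=True))
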