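# Methods

This note documents the statistical procedures implemented in `mucinet`,
the choices that were genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Data model

Inputs are the standard outputs of taxonomic/functional profilers:
per-sample taxonomic profiles carrying relative abundances and estimated
read counts per species (MetaPhlAn `rel_ab_w_read_stats` dialect), and
multi-sample species-stratified EC tables in copies per million (HUMAnN
regrouped dialect: bare `EC` rows are community totals, `EC|g__X.s__Y` rows
are per-species strata, `EC|unclassified` is the unassigned remainder).
Values below 1e-12 are treated as exact zeros for all presence/absence
logic. Unclassified strata are retained and count toward community totals;
this choice propagates into the contribution denominator below (a
classified-only denominator is available via
`contributions(..., include_unclassified_denominator=False)`).

## Compositional transform

Read-count data are compositional, so all abundance analyses use the
centered log-ratio: per sample, `clr_i = ln(c_i + 1) − mean_j ln(c_j + 1)`.
The pseudocount of 1 (needed because zeros are ubiquitous) is added to the
counts *before* the geometric mean rather than to the ratio; the two
placements express the same intent, but the counts-side placement makes
every transformed row sum to exactly zero, which downstream code relies on
as an invariant. The ratio-side variant is kept as
`clr_transform(..., where="ratio")` for sensitivity analyses. With strictly
positive counts and a vanishing pseudocount, clr is exactly invariant to
per-sample scaling; with the pseudocount it is approximately so.

## Degrader screen

The shipped catalog lists the detectable mucin-glycan-degradation ECs with
enzyme class and associated CAZy GH families; the GlcNAc-6-sulfatase entry
is flagged inactive (detected too rarely and unmappable to references to be
analysable) and the two galactosidases are flagged as excluded from the
versatility criterion. The cascade is:

1. *encoders*: any catalog EC with nonzero gene cpm in ≥1 sample;
2. *transcribers*: same rule on the transcript table;
3. drop species whose transcribed set is contained in
   {α-galactosidase, β-galactosidase} — galactose is widespread in dietary
   glycans, so galactosidase-only transcription is uninformative about the
   mucin niche;
4. drop species transcribing exactly one catalog EC (*versatile* = the
   survivors). The >1-EC count includes the galactosidases themselves: a
   species transcribing β-galactosidase plus a sialidase is versatile. The
   alternative (counting non-galactosidase ECs only) is exposed as
   `count_galactosidases_in_versatility=False`;
5. keep species whose transcription prevalence is ≥ 0.10 for at least one
   EC (*prevalent versatile*). Prevalence is per-EC: the fraction of
   samples with detectable transcription of the focal EC (community total
   > 0, irrespective of who transcribes it) in which the species has a
   detectable stratum. The 10% floor reflects the sample size (~20+)
   needed for robust downstream network inference.

Boundary semantics: the species-level rule is inclusive (≥ 10%), the
EC-level detection rule is strict (> 5%). Both are configurable. There is
no minimum-cpm floor beyond the 1e-12 zero rule. Encoders and transcribers
come from different omes, so `transcribers ⊆ encoders` is *not* enforced;
the enforced chain is `prevalent_versatile ⊆ versatile ⊆ transcribers`.

## Cooccurrence network

Pairwise Spearman correlations are computed between clr values of all
species present in at least `min_present_samples` (default 20) samples.
Ties get average ranks; a constant vector has no defined correlation and is
recorded as missing. Significance uses a permutation null: every species'
values are permuted independently across samples (destroying all
cross-species association while preserving marginals) and all pairwise
correlations are computed; 1000 repetitions are pooled into one global null
whose central 99% interval defines significance. Pooling (rather than
per-pair nulls) is used because at 1000 repetitions a per-pair 99% interval
rests on ~5 tail points; under the independent-shuffle unit all pairs share
the same exchangeable null, so pooling is both valid and far more stable.
A per-pair mode remains available (`null_mode="per_pair"`). Because
Spearman correlation depends only on ranks, shuffling raw counts and
shuffling clr values are equivalent here.

Edges are retained only when significant *and* positive with ρ ≥ 0.2.
The network is restricted to degraders and their first neighbors (species
sharing a retained edge with a degrader); edges among retained nodes are
kept, and isolated degraders remain as singletons. Communities are found by
greedy modularity maximisation on the unweighted adjacency; nodes are
inserted in lexicographic order and cluster ids are assigned by decreasing
size (ties broken by smallest member), making the labelling reproducible.

## Regression networks

Per (sample, EC), each species' transcription is normalised to the percent
of the EC's community total; samples where the EC is not transcribed are
excluded for that EC. Within the samples where an EC is transcribed, a
species with no stratum contributed 0% — those structural zeros are part of
the response, not missing data.

*Abundance-driven transcription* is the adjusted R² of OLS share ~ own clr,
fitted when ≥ 10 observations are available (`min_n_obs`, configurable; the
floor is pragmatic). Adjusted R² can be slightly negative for
uninformative fits and is reported as-is.

*Response–predictor models* regress, per EC, each prevalent transcriber's
share jointly on the clr abundances of all **other** prevalent transcribers
of that EC (self-abundance excluded; an include-self variant exists for
sensitivity). Every coefficient with p < 0.05 becomes a directed signed
edge. No multiple-testing correction is applied by default — edges are
per-coefficient calls at nominal alpha; Benjamini–Hochberg within each EC
network is available (`fdr=True`). Models are skipped (and recorded) when
n ≤ p + 1 or a variable is constant; collinear predictors are tolerated
with the condition number logged. Shares are modelled untransformed on the
percent scale.

The *consensus network* groups directed pairs across ECs and labels them
always-positive, always-negative, or mixed (iff both signs occur). The
*continuum summary* reports per species the median adjusted R² across its
ECs and the average number of species inhibited/facilitated — negative or
positive out-edges divided by the number of EC networks in which the
species was an eligible predictor (i.e. at least one other response model
ran). An all-networks denominator is a config alternative. Two
cross-species trends are fitted: avg_inhibited ~ median adjusted R² and
avg_facilitated ~ avg_inhibited. Species classify as competitive when
median adjusted R² > 0.2, else opportunistic.

Cohort designs with repeated samples per subject violate OLS independence;
the models here are pooled OLS without subject terms, and that caveat
should be attached to any application to longitudinal cohorts rather than
silently "fixed" by the package.

## Synthetic community generator

The generator produces paired taxonomic and functional tables with planted
structure, sized like a desk-scale cohort:

* **Abundances.** Latent per-species log-abundances are multivariate normal
  with block-diagonal correlation: `n_clusters` (4) contiguous blocks with
  within-block correlation `within_cluster_rho` (0.8), zero between.
  Species means spread with sd 1.5 so abundances vary over orders of
  magnitude. Rows are softmax-closed and multinomially sampled to
  `total_reads_per_sample` (100k), giving log-normal + multinomial
  overdispersion and realistic zeros. Defaults: 300 samples, 40 species.
* **Roles.** 25% of species are competitive, 20% opportunistic, the rest
  non-degraders; each degrader gets 2–4 catalog ECs and every EC is
  guaranteed a transcriber of each guild. Competitive species are placed in
  the first half of the blocks and opportunists in the second half
  (round-robin within each half so degraders span every block). This
  separation is deliberate: an opportunist's transcription is driven by its
  *suppressors'* abundance, so if suppressors shared its correlation block,
  its own abundance would proxy for theirs and the planted "decoupled"
  regime would be unidentifiable by construction rather than recoverable by
  inference.
* **Transcription** (cpm units). Competitive:
  `max(0, baseline + coupling · (clr − mean clr) + ε)` with baseline 10 cpm,
  coupling 5 cpm per clr unit and ε ~ N(0, 2²) — own-abundance signal
  clearly above noise but with overlap at the margins. Opportunistic:
  `max(0, 2·baseline · σ(−k·(C − median C)) + ε)` where C is the summed clr
  of the EC's competitive transcribers and k = `suppression_strength` (1);
  the logistic (rather than a hard switch) keeps edge recovery a fair
  statistical test instead of a separability artifact. Non-degraders emit
  nothing; a ~5% unclassified stratum is added to community totals. Every
  (competitive predictor → opportunist response, EC) pair is recorded as a
  planted negative edge.
* **Gene content.** Degrader repertoires appear in the metagenome wherever
  the species is present; about half the non-degraders get encoder-only
  ECs, and every encoder receives a complement of non-catalog GH ECs
  proportional to its mucin repertoire (slope 2), 70% of which are also
  transcribed — exercising the repertoire-comparison analysis.

Everything derives from a single integer seed; the packaged fixture config
(12 samples, 20 species, seed 20240901) underlies the frozen golden files
in `tests/data/`.

**What the generator does not emulate:** real taxonomic mis-assignment,
strain-level variation, sequencing-depth heterogeneity, subject-level
repeated measures, dietary covariates, or enzyme multifunctionality across
niches. Passing recovery tests therefore demonstrates that the estimators
are correct and calibrated under the stated generative assumptions — not
that those assumptions hold in any particular cohort.

## Numerical choices and degenerate inputs

Problem sizes in the tests and acceptance script (300×40 communities,
10–20 simulation replicates, 1000-permutation nulls on 200×50 matrices)
were chosen as the smallest sizes at which the planted effects are
comfortably identifiable. Quantiles use linear interpolation
(`numpy.quantile` default). Spearman matrices are computed as Pearson on
average ranks; the permutation loop shuffles standardised ranks, making
each repetition an O(np + p²n) matrix product. Constant species are
excluded from correlation and regression with explicit status flags rather
than NaN propagation. Cluster labelling and node insertion are
lexicographic so repeated runs are byte-identical; the pipeline writes a
config hash (excluding the output directory) and seed into every run
report.

## Known limitations

* Pooled OLS ignores within-subject correlation in longitudinal designs.
* Contribution percentages are bounded responses fitted by linear models;
  severe boundary pile-up (one species at ~100% everywhere) degrades both
  R² interpretation and edge calling, mirroring the underlying procedure.
* The permutation null calibrates marginal pairwise tests; it does not
  control graph-wise error, and the ρ ≥ 0.2 filter is a biological
  relevance cutoff, not an inferential one.
* Greedy modularity has a resolution limit; very small planted blocks may
  be merged.
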