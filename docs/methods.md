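# Methods

This note documents the statistical procedures implemented in `acetoprot`,
the choices made where the conventions of the field leave room, and what
the synthetic-data generator does and does not establish about real data.

## Data model and detection

A protein group carries identification metadata (search-engine score,
peptide count, categorical protein-level FDR confidence) and one abundance
per sample. A blank or zero abundance cell is treated as *not detected*
rather than as a measured zero: label-free LC–MS/MS abundances are
integrated precursor-ion areas, and absence of a value reflects a failed
identification or integration, not a concentration of zero. All presence
rules therefore reason about detection (present and positive), and no
value is ever imputed.

Taxonomy is parsed from the UniProt-style `OS=` field of the description
(`OS=Genus epithet …`): genus is the first token, species the binomial with
subspecies/strain qualifiers dropped, and family is resolved through a
genus→family lookup bundled for the Acetobacteraceae genera common in
vinegar microbiotas (extendable via a TSV). Unparseable descriptions fall
into an explicit `unassigned` bin so profile frequencies always total 100 %.

## Filters

* **Identification**: retain records with high FDR confidence (< 0.01),
  score ≥ 2 and peptide count ≥ 3. The score and peptide thresholds are
  applied as independent gates (removal on either), the conventional
  reading of paired quality criteria; a literal conjunctive mode
  (`rule="and"`, removal only when both fail) is available. A removed
  record is attributed to the first failing rule (confidence, score,
  peptides, presence) so the report counts reconcile exactly.
* **Replicate presence**: retain proteins detected in ≥ 50 % (inclusive:
  2 of 4 and 2 of 3 both qualify) of the replicates of at least one
  sampling-time group. The same ≥ 50 % rule defines the per-group presence
  sets used by profiling and the intersection analysis, and the
  "exclusive" rule for pairwise comparisons (≥ 50 % in one group, zero
  detections in the other). Both filters are record-wise predicates on
  disjoint evidence, hence idempotent and order-exchangeable.

## Normalization

Each sample is rescaled to the mean overall sample intensity:
`q'_ij = q_ij / S_j × mean_k(S_k)`, with `S_j` summed over detected entries
only. Sample totals are computed *after* filtering, matching the stage
order (normalization follows retention). The transform multiplies each
column by one positive factor, so within-sample ratios and rank order are
exact invariants, every normalized column total equals the mean of the
original totals (asserted to 1 × 10⁻⁹ relative), and the grand total is
conserved. A sample with no detected values has `S_j = 0` and is reported
as an error naming the sample rather than silently propagating infinities.

Total-intensity normalization assumes the community's summed signal is
comparable across samples. When a substantial fraction of proteins shifts
in one direction in one condition, that assumption bends: the shifted
proteins move `S_j`, and the correction transfers a small opposite-signed
effect onto every other protein of that sample. The simulation reproduces
this (see *Calibration* below); it is inherent to the method, not an
implementation artifact.

## Clustering

Clustering operates on per-sampling-time means of normalized abundances
(mean over detected replicates), restricted to proteins with at least three
non-missing group means, z-scored per row with the sample standard
deviation (n − 1); flat or too-sparse rows are dropped and reported. The
distance is the Pearson correlation distance `d = 1 − r` (not `(1 − r)/2`,
not `1 − |r|`), computed over pairwise-complete columns, and the
agglomeration is complete linkage: repeatedly merge the two clusters with
the smallest maximum inter-point distance. Merge heights are therefore
non-decreasing. Ties are broken deterministically in favour of the pair
whose smallest-member leaf indices are lexicographically least, and rows
enter in accession order, so the dendrogram is a pure function of the data.
The agglomeration is implemented in the package (an O(n²)-per-merge
vectorized scan) because the tie-break is part of the contract; tests
cross-check it against both a naive set-based agglomeration and SciPy's
`linkage`. The number of clusters `k` is a user parameter — no automatic
cut rule is imposed — and the heat-map export preserves the dendrogram
leaf order exactly.

## Differential quantification

Per protein, a one-way ANOVA across sampling-time groups runs on
replicate-level normalized abundances (group means would leave zero
residual degrees of freedom). Groups with fewer than two detected
replicates are dropped per protein; proteins with fewer than two usable
groups are reported as untestable, not silently skipped. `F` is computed
from textbook sums of squares with `(g − 1, N − g)` degrees of freedom;
Tukey's HSD uses the studentized-range distribution with Tukey–Kramer
standard errors `√(MSW/2 · (1/n₁ + 1/n₂))`, so with two groups the Tukey
p equals the ANOVA p and `F = t²`. If `MS_within` is exactly zero the
p-value degenerates to 0 (or 1 when the group means also coincide).

Multiple testing uses Storey q-values: `q(i) = min_{j≥i} π₀ m p(j)/j`,
with `π₀` estimated by a smoother — `π₀(λ) = #{p > λ}/(m(1 − λ))` on the
grid λ = 0.05, 0.10, …, 0.95, summarized by a cubic polynomial fit
evaluated at λ = 0.95 and clipped to (0, 1]. For families of fewer than
100 tests the estimate is too unstable, and `π₀` is fixed at 1, which makes
the q-values exactly Benjamini–Hochberg adjusted p-values; `method="bh"`
forces that behaviour at any size. The cubic fit tracks a degrees-of-
freedom-3 smoothing spline to within 0.01 in mean on test mixtures while
staying dependency-light and deterministic.

ANOVA normality is assumed on the raw abundance scale, as is conventional
for this pipeline; with log-normal replicate noise at CV ≈ 30 % the F-test
is mildly anti-conservative in the extreme tail but calibrated in
distribution (see below).

## Synthetic data

The generator emulates one semicontinuous acetification profile:

| parameter | default | meaning |
| --- | --- | --- |
| `phases` | FL/DL/UL × 3 | sampling times × biological replicates |
| `taxa` | 7 species, dominant weight 0.75 | *K. europaeus*-dominated multinomial mix |
| `meanlog_loc`, `meanlog_scale` | 13, 1.5 | between-protein base log-abundance (ln scale) |
| `sdlog` | 0.3 | replicate noise, ≈ 30 % CV — typical label-free precision |
| `differential_fraction` | 0.2 | planted differential proteins |
| `n_clusters` | 3 | each cluster up-shifted in one phase |
| `effect_sdlog_multiple` | 4 | log effect = 4 × sdlog = 1.2 (≈ 3.3-fold) |
| `missingness` | `mnar` | detection probability logistic in log-abundance |
| `low_quality_fraction` | 0.1 | records planted to fail the identification filter |

Missingness is missing-not-at-random by default because label-free dropout
is intensity-driven; the logistic midpoint sits two between-protein
standard deviations below the mean log-abundance, so dropout concentrates
in the faint tail (MCAR and no-missingness modes exist for unit tests).
Ground truth records each protein's taxon, planted effects, cluster,
quality defects and expected filter fate, and `recovery_report` scores
taxon-frequency recovery, differential sensitivity and false-discovery
proportion at q < 0.05, and the adjusted Rand index of recovered clusters.

What the simulation does **not** model: correlated proteins within
operons/pathways, shared peptides between homologous proteins of related
species (protein-group inference artifacts), batch effects, retention-time
drift, or abundance-dependent quantification error. Passing recovery tests
therefore demonstrates the correctness of the computations under the
stated statistical model, not robustness to those real-data phenomena.

## Calibration

With no planted effects, per-protein ANOVA p-values are uniform
(Kolmogorov–Smirnov p > 0.01 in 20 of 20 development seeds) and false
discoveries at q < 0.05 are rare. At default settings (20 % differential
proteins, 3.3-fold effects), the planted shifts perturb per-sample totals
enough that normalization induces faint counter-effects in null proteins;
the π₀ smoother then under-estimates (the null p-distribution is no longer
exactly uniform), and the realized false-discovery proportion averages
≈ 0.095 — near, but within, the 0.1 working bound, and a useful reminder
that q-value guarantees degrade when the normalization assumption is
stressed. Differential sensitivity under the defaults averages ≈ 0.62,
consistent with an independent power computation (scipy `f_oneway` + BH on
the same group model, mean 0.53): three replicates against ≈ 30 % CV noise
on the raw scale, MNAR dropout and multiplicity leave roughly half to
two-thirds of 4-sd effects detectable. The forced-geometry regime (three
clusters shifted in three distinct phases, no missingness) is recovered
with adjusted Rand index 1.0.

## Problem sizes

Defaults were chosen so a full simulated profile (300 proteins × 9 samples)
runs the entire pipeline in a few seconds and the whole test suite,
including Monte-Carlo calibration over dozens of simulations, completes in
a few minutes on one CPU. The statistics are per-protein and scale
linearly in proteins; clustering is cubic in the number of clustered rows
and comfortable into the low thousands.

## Known limitations

* Normalization is total-intensity only (no median/quantile/VSN options),
  by design — alternatives would change the stated invariants.
* GO profiling counts explicit annotations; no ontology-graph propagation
  to ancestor terms and no enrichment statistics.
* Protein–protein interaction analysis is out of scope; the accession-list
  export exists precisely to hand clusters to external services.
* The exclusivity rule interprets "replicates of a given sample" as the
  replicates of a sampling-time group, the only reading consistent with
  the replicate structure of the design.
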