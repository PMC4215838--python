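# Methods

## Data model

The observation unit is a rarefied OTU count table (samples × OTUs,
non-negative integers, every sample total positive) with sample metadata
giving, per algal replicate, the experiment (`temperature` or `light`),
treatment level, replicate index and the measured surface concentration of
each defence compound in ng cm⁻². Taxonomy is a Greengenes-style lineage
string per OTU; a *clade scheme* — a priority-ordered list of mixed-rank
selectors with catch-all buckets — maps every OTU to exactly one of (by
default) 26 clades. Published reference tables bundled with the package:
per-condition mean (sd) surface concentrations for 5 temperature and 6
light levels, and an EC50 panel of five marine bacterial isolates (DMSP
0.05 ng cm⁻² for four strains and 0.38 for the most resistant; proline
0.01–0.13 ng cm⁻²; fucoxanthin 1.4–6 µg cm⁻², 6 µg cm⁻² for the least
sensitive isolate). Fucoxanthin thresholds are normalised to ng cm⁻² on
load; EC50 ranges carry both extremes and every call is reported at the
range minimum (default) and maximum (conservative).

## Rarefaction and detection

Rarefaction draws a multivariate hypergeometric subsample per sample —
i.e. a uniform random subset of that sample's reads, without replacement,
which is what subsampling physical reads amounts to. Samples below the
target depth are dropped (padding would fabricate reads) with a logged
warning; the seed and depth are logged and recorded in the run manifest.
The default depth is the minimum sample total; the two experiments'
published depths (1352 and 1024 reads) are the generator defaults. An OTU
is *detected* at a treatment level when it has a nonzero count in at least
one of that level's replicates; each level's detected set is the universe
for that stratum. Whether rarefaction should be a single draw or an
average over draws is not settled in general; the pipeline does a single
seeded draw, which keeps counts integral and the run reproducible.

## Within-level screen and response classes

For each treatment level, compound and detected OTU, Spearman's ρ is
computed across the level's replicates between relative abundance and
concentration (average ranks for ties; scipy's implementation, validated
against a brute-force average-rank Pearson oracle on all 120 rank
permutations of n = 5 and on random tie-containing vectors). A constant
vector on either side makes ρ undefined. |ρ| ≤ 1e-12 is treated as exactly
zero — rank arithmetic at n = 5 produces true zeros up to float rounding.

Classification per (OTU, compound, experiment): **positive**/**negative**
when at least `min_levels` (default 1) evaluable levels all agree in sign;
**neutral** when signs disagree or any level gives ρ = 0 (the dichotomy is
strictly positive-or-negative, so an exact zero breaks consistency);
**unevaluable** when no level yields a defined sign, or a consistent run
has fewer than `min_levels` supporting levels (insufficient evidence is
not the same as contradictory evidence, so the gate maps to unevaluable,
not neutral). Significance of individual correlations is deliberately not
tested: with n = 5 per level the screen has no per-OTU power, and the
design extracts information only from sign consistency and from
aggregation over clades. Under a null with no coupling the positive and
negative fractions are symmetric; for an OTU evaluable at L tie-free
levels the probability of a consistent sign is 2·p₀ᴸ with
p₀ = P(ρ > 0 | random ranks, n=5) = 57/120, so the observed ~30%
subgroups are dominated by OTUs evaluable at one or two levels. This is
why subgroup membership is only interpreted in aggregate.

## Clade enrichment

Odds of presence of clade X in subgroup S relative to the community:
`[a/(m−a)] / [A/(M−A)]` with a = |X∩S|, m = |S|, A = |X|, M = community
size. If the subgroup's composition equals the community's (a/m = A/M,
which covers the saturated-clade corner where the raw ratio is 0/0) the
odds are 1 by definition; otherwise any zero among a, m−a, A, M−A
triggers a Haldane–Anscombe +0.5 on all four terms and the cell is
flagged (`n_continuity_cells`). Strata: one odds value per treatment
level (11 with the default two-experiment design; universe = that level's
detected OTUs, subgroup membership from the experiment-wide
classification), pooled as GM = exp(mean ln odds) with a 95% t-interval
on the log scale (k−1 df; a single stratum gives a degenerate point
interval, flagged). A `per_experiment` strata mode (k = 2) is available.

The χ² statistic compares the clade count inside the subgroup with its
expectation from the community, E = m·A/M, pooled over the two
experiment-wide universes: χ² = (a−E)²·(1/E + 1/(m−E)), 1 df, no Yates
correction, stars at p < 0.05 / < 0.025 / < 0.001. No multiple-testing
correction is applied by default (the screen reports per-clade evidence,
not a discovery set); Benjamini–Hochberg can be applied downstream on the
`p_value` column. Note a structural property of this statistic: because
the reference proportion A/M is taken from the *total* community, which
contains the subgroup, the test is conservative by a factor of roughly
(1 − m/M) when the subgroup is a large fraction of the community — at the
pipeline's typical m/M ≈ 0.2–0.3 the realised type-I error is ~0.02
rather than 0.05. The type-I calibration therefore uses uniformly drawn
subgroups with a small sampling fraction (m = 400 of M = 8000, the scale
of the pooled two-experiment OTU universe), where the nominal level holds.

## Defence assessment

A strain counts as inhibited under a condition when the mean surface
concentration ≥ EC50 (inclusive boundary). Calls are made on
treatment-level means; a per-replicate sensitivity mode reports the
fraction of replicates above threshold instead. A condition has
`any_defence` when at least one (strain, compound) pair is inhibited.
With the bundled tables this reproduces the published threshold
comparisons: the most resistant strain is inhibited by DMSP up to 20 °C,
the 0.01 ng cm⁻² proline threshold is met only at 15 °C in the
temperature experiment, and fucoxanthin (≥ 1400 ng cm⁻²) never reaches an
inhibitory concentration. One published verbal claim does not survive the
strict rule: the mean DMSP concentration under the 44% light regime
(0.03 ng cm⁻²) falls below the 0.05 threshold of the sensitive strains,
so that condition's defence rests on proline.

## Treatment statistics

One-way ANOVA per compound and experiment with Shapiro–Wilk (pooled
residuals) and Levene gates at α = 0.05; when Levene rejects, the
response is Box-Cox transformed and the ANOVA re-run, mirroring the
conditional use in this kind of workflow. Box-Cox λ maximises the profile
log-likelihood on a fixed grid [−3, 3] in steps of 0.01 (λ = 0 → log);
zeros require an explicit shift of half the smallest positive value. Note
the mean-centred Levene test is markedly conservative at n = 5 per group;
its level is calibrated at n = 25. Tukey HSD p-values come from the
studentized-range distribution; the compact letter display uses the
greedy insert-and-absorb algorithm over the significant-pair set (letter
displays are not unique; this one is deterministic given the
descending-mean group order). Degenerate inputs (zero within-group
variance, constant vectors) are flagged rather than propagated as NaNs.

## Synthetic studies

The generator emulates the downstream product of the two experiments:
default design 5 × 5 + 6 × 5 samples at depths 1352/1024, 2000 OTUs.
Per-replicate concentrations are lognormal with the bundled per-level
mean/sd (moment-matched: σ² = ln(1 + cv²)); `cv_scale=0` gives noise-free
levels. Base OTU intensities are lognormal(0, σ = 2), giving the long
abundance tail of real amplicon tables; per-OTU occupancy is
Beta(0.4, 1.2) (mean ≈ 0.25), so most OTUs are absent from most samples.
A planted effect multiplies the intensity of its OTUs by exp(β·z), where
z is the within-level z-score of the sample's compound concentration —
coupling on z makes planted effects visible to the within-level screen
without creating across-level trends. Counts are multinomial at the
experiment's depth (rows sum exactly to depth); an optional Dirichlet
layer adds compositional overdispersion. Ground truth (clade, β per
compound, occupancy, base intensity) is emitted alongside the tables.

What the generator does *not* emulate: taxonomic misassignment,
sequencing error and chimeras, phylogenetic correlation of abundances
within clades, across-level (direct treatment) effects on bacteria, and
compound–compound correlation beyond what the published level means
induce. Passing recovery tests therefore show that the statistical
machinery detects monotone within-level coupling at the study's design
and depths — not that the biological effect sizes in any real survey are
detectable.

## Calibration results and problem sizes

All validation is property-based at desk scale (single CPU, minutes):

* oracle equivalence of the rank correlation on 1120 vectors (exact to
  float precision);
* null calibration on 50 synthetic null studies of 2000 OTUs: mean
  positive-vs-negative fraction difference within 3 Monte-Carlo SE of 0;
* χ² type-I error on 10 000 uniformly drawn subgroups (m = 400,
  M = 8000): ≈ 0.045–0.05;
* planted-clade recovery (20-OTU clade, β = −3, full occupancy, 200
  studies): the clade is flagged (GM odds > 1 and p < 0.05) in ≈ 100% of
  runs; the single-OTU, β = −2 per-level detection rate was calibrated by
  simulation at ≈ 0.91 over 1000 runs;
* pooled-odds CI coverage under lognormal odds (k = 11, 10 000 reps):
  ≈ 0.95.

These sizes are the package's chosen validation conditions and are the
same ones `scripts/acceptance.py` re-runs.

## Known limitations

* The screen is sign-based and cannot rank effect strengths; β is not
  estimable from the classification.
* Consistency classification with `min_levels=1` admits many
  single-level OTUs, inflating subgroup sizes; raise `min_levels` for a
  stricter (but smaller-universe) classification.
* The χ² statistic's conservatism for large subgroups (above) means
  borderline clade enrichments are under- rather than over-called.
* EC50 thresholds treat inhibition as a step function of the mean
  concentration; dose–response shape and replicate-level variability
  enter only through the sensitivity mode.
* BIOM input requires the optional `biom-format` package; the native
  format is TSV.
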