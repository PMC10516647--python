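# Methods

## The problem

When a transposable element (TE) invades a genome, its final genomic
distribution reflects two confounded forces: where the element prefers
to insert (insertion bias) and where its insertions are tolerated
(purifying selection of locally varying strength). A single snapshot of
insertion positions cannot separate the two. The two-phase Evolve &
Resequence (E&R) design breaks the confound by manipulating the
*efficacy* of selection while holding the insertion machinery constant:

* **Phase 1** — the element proliferates in many small isofemale lines
  (tens of individuals). Drift overwhelms selection (|N·s| small), so
  the accumulated insertions record the insertion bias nearly
  unfiltered.
* **Phase 2** — lines are pooled into large outbred replicate
  populations (census ~1250) and evolved for 10 generations. Selection
  is now efficient, so the *fate* of phase-1 insertions (persistent vs
  lost) and the placement of new phase-2 insertions record selection.

The package implements the full inferential chain for this design plus
a forward simulator that generates data with exactly the statistical
structure the analysis assumes, so every estimator can be validated
against a known truth.

## Coordinate and annotation model

All intervals are 0-based half-open (BED convention); insertion sites
are length-0 point anchors. When annotation tracks overlap, a point
receives the most detailed / functionally most important label using
the precedence order `CDS > 5'UTR > 3'UTR > other exon > intron`
(configurable); points covered by no track are intergenic. The
precedence-resolved tracks partition each chromosome exactly, which the
code enforces (`sum(f_l) == G_l`). Bookended intervals merge; region
sets (ORC binding sites, shared sites) may apply a minimum-length
threshold at load. Chromosome names match by exact string equality.

## Classification of insertion sites

Detected sites from the six Pool-Seq samples (3 replicates × 2
timepoints) are matched by single-linkage clustering within 500 bp (the
signature-merging distance of PopoolationTE2-style callers), with the
cluster's minimum position as representative; ties break by (chrom,
pos). Per replicate, joint mode classifies a matched site as

* *lost*: detected at generation 0 in **any** replicate, absent at
  generation 10 of the focal replicate;
* *persistent*: detected at generation 0 in any replicate and at
  generation 10 of the focal replicate;
* *phase-2*: absent at generation 0 in all replicates, detected at
  generation 10 of the focal replicate.

Separate mode applies the same rules within one replicate. The
replicate frequency spectrum matches persistent sites across replicates
at 1 kb (gap ≤ 1000, the semantics of `bedtools merge -d`) and bins
them by the number of replicates sharing the site, split by ORC/shared
membership of the representative position.

## Enrichment

Under a homogeneous insertion process the expected count in a feature
of summed length `f_l` is `P_exp = f_l · P_obs_total / G_l`; enrichment
is `P_obs / P_exp`. For phase-2 insertions into a region set, `f_l` is
reduced by the summed lengths of member intervals already occupied by a
phase-1 insertion, since a re-insertion there is not a "new" target.
Departures are tested with a two-cell chi-square goodness-of-fit
(inside/outside the feature, df=1, no continuity correction).
Replicate summaries are unweighted means with SEM = sd/√n.

## The aggregation estimator

Aggregation of insertions into a focal region set (ORCs or shared
sites) is the fraction of insertions inside it. Under spatially uniform
selection the aggregation is the same in both phases regardless of
bias; stronger phase-2 aggregation indicates weaker selection inside
the region. Because a lost phase-1 insertion can be *restored* by a new
biased insertion, the phase-2 estimate needs a correction:

1. rediscovery rate `r` = persistent / phase-1 counted **outside** the
   union of all hotspot region sets (where re-insertion is negligible);
2. excess persistence inside the focal region,
   `X = persistent_in − r · phase1_in`, estimates the number of
   re-insertions;
3. corrected phase-2 aggregation
   `A2 = (phase2_new_in + X) / (phase2_new_total + X)`, against
   `A1 = phase1_in / phase1_total`; the reported quantity is
   `100 · (A2 − A1) / A1`, summarised across replicates as mean ± SEM.

`X` enters A2 un-floored: truncating sampling-noise-negative values at
zero would add `E[max(0, X)] > 0` to both numerator and denominator and
bias the estimated change upward by several percent under the
no-difference null (measured on the simulator: ~+9% at the calibration
scale). The *reported* re-insertion count is floored at zero, since a
negative count of events is meaningless. `r` is estimated once outside
the ORC ∪ shared union and applied to each focal region.

## The forward simulator

Insertions segregate as independent biallelic presence/absence loci
(no linkage — insertions are sparse and low-frequency, and the analysis
is site-wise). Each generation applies, in order: new insertions
(Poisson with mean `2N·u`; positions from a per-base distribution with
weight β on hotspot bases and 1 elsewhere; starting frequency `1/2N`),
optional per-copy excision, deterministic viability selection with
fitnesses (1+s, 1+h·s, 1) and `h = 0.5` by default (P-element
insertions behave as not recessive), and binomial drift. The selection
coefficient of a locus is set by its annotation feature and can be
overridden inside the hotspot set.

Phase 1 runs each line at its census size for 60 generations (the
source design specifies a 4.5-year duration, not generations; 60 ≈
monthly generations). Phase 2 founds each replicate as one panmictic
pool — a line-private insertion enters at its within-line frequency
divided by the number of lines — and evolves it at the large census
size. Founder sampling noise at the pooling step, female-only ancestral
sequencing, and X-chromosome dosage are ignored; all loci are treated
as autosomal-like.

Pool-Seq detection draws supporting read-pair counts Binomial(C, f) at
uniform physical coverage C (default 50×), detects a site when the
count reaches `min_count` (default 1), estimates its frequency as
count/C, and merges detected sites within 500 bp. Detection sensitivity
is by construction identical across annotation features at a given
frequency.

A truth log records every locus's founder and final frequency, its true
lost/persistent/phase-2 class per replicate, and re-insertion events
(a surviving phase-2 locus within 500 bp of a lost phase-1 locus).

### What the generator emulates, and what it does not

It reproduces the statistical structure the analysis assumes: replicate
structure, low insertion frequencies, biased insertion targeting,
feature-specific selection, and coverage-limited detection. It does not
model piRNA-mediated transposition shutdown, hybrid dysgenesis,
linkage, sequence-level reads, or caller-internal signature detection.
Passing tests therefore validate the *inference machinery* under the
stated model, not the wet-lab pipeline upstream of insertion tables.

### Calibration-scale study

Monte-Carlo validation uses a scaled-down study so that hundreds of
full experiments run in minutes on one CPU: a 1 Mb single-chromosome
genome tiled with repeating gene models, 20 isofemale lines, and an
insertion rate of u = 0.10 per haploid genome per generation, chosen
once so that roughly 300 phase-1 insertions are detected at 50×
coverage. Hotspots are 1000 intervals of 50 bp (5% of the genome):
many short intervals keep per-interval occupancy low (~0.06), matching
the real ORC regime in which only ~5% of regions carry an insertion.
With few large hotspot intervals instead, several independent
insertions would stack inside one interval and the 500 bp signature
merging would fuse them into single "sites" with inflated rediscovery —
a detection artifact, not a property of the estimator. Shared-site
regions are 100 × 100 bp intervals (1%) placed in intergenic DNA.

Measured behaviour at this scale (reproduced by the test suite and
`scripts/acceptance.py`): under uniform s = −0.02 and β = 5 the mean
aggregation change over 500 experiments is 0 within its Monte-Carlo CI
(±~2.6%); with neutral hotspots and s = −0.01/−0.03/−0.05 outside, the
mean change is positive and increases monotonically.

## Stratified statistics

The generalized Cochran–Mantel–Haenszel statistic for I×J×K stratified
counts is implemented from the multiple-hypergeometric score form:
per-stratum deviations of the leading (I−1)(J−1) cells from their
margin-conditional expectations, pooled across strata and combined as
`M² = U' V⁻¹ U`, df = (I−1)(J−1), no continuity correction (for one
2×2 stratum this reduces to `(ad−bc)²(N−1)/(r1 r2 c1 c2)`). Fisher's
exact test uses the two-sided minimum-likelihood summation rule;
Benjamini–Hochberg adjustment is applied across the pooled set of all
replicate × comparison p-values; Kruskal–Wallis uses mid-rank tie
correction. Degenerate margins (a row or column empty in every
stratum) raise an error naming the margin.

## Diversity and conservation

Site diversity from pooled read counts: sites outside the
[min_coverage, max_coverage] = [10, 500] depth band are masked, alleles
below min_count = 2 are zeroed, and
`pi = (1 − Σ (c_a/D)²) · D/(D−1)`. Window values (2 kb,
non-overlapping) are means over unmasked sites, masked when the covered
fraction falls below 0.75; feature averages weight windows by bp
overlap. This is the plain bias-corrected heterozygosity estimator:
absolute values can differ from pool-size-aware estimators by a small
factor, but feature contrasts — the quantity of interest — are
preserved, and `window_pi` accepts a substitute per-site estimator via
`site_pi_fn`. The low-recombination flag marks sites whose map window
rate is at or below the 10th percentile (type-7 linear interpolation;
ties flag as low). Conservation ratios reuse the interval
coverage-fraction operation.

## Numerical and degenerate-input conventions

* Merging: single-linkage, transitive; representative = minimum
  position; bookended intervals merge.
* Enrichment with zero expected count, rediscovery with zero outside
  sites, aggregation with zero denominators: errors, not zeros. The
  pipeline records per-replicate undefined aggregations as NaN rows.
* All randomness flows through one `numpy` Generator seeded per run;
  equal seeds give byte-identical output tables
  (float format `%.6g`).
* Kruskal–Wallis on all-identical observations returns statistic 0,
  p = 1.

## Known limitations

* The null calibration of the aggregation estimator is exact only when
  detected sites map 1:1 to insertions; at densities where the 500 bp
  merge fuses independent insertions, rediscovery inside hotspots is
  inflated (the toy geometry is chosen to stay out of that regime, as
  the real data are).
* The diversity estimator omits the pool-size correction for the
  min-count filter (see above).
* The simulator's phase-2 founding is deterministic in expectation
  (no multinomial sampling of line contributions).
* CMH p-values are asymptotic; no exact conditional version for
  general I×J×K tables is provided.
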