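# pelement-er

Separating transposable-element **insertion bias** from spatially
variable **purifying selection** in two-phase Evolve & Resequence (E&R)
experiments, modelled on a P-element invasion of *Drosophila simulans*.

A TE's genomic distribution confounds where the element likes to insert
with where its insertions are tolerated. The two-phase design breaks
the confound: in phase 1 the element accumulates in many small
isofemale lines where drift swamps selection (insertions record the
bias); in phase 2 the lines are pooled into large replicate populations
evolved for 10 generations where selection is efficient (the *fate* of
insertions records selection). This package implements the complete
inferential chain for such data, plus a forward simulator that
generates Pool-Seq-like insertion catalogs with known ground truth.

## What's inside

| module | contents |
| --- | --- |
| `pelement_er.genome` | BED-convention interval algebra, annotation precedence (CDS > 5′UTR > 3′UTR > exon > intron > intergenic), feature-length accounting, region sets |
| `pelement_er.catalog` | 500 bp signature matching across samples, lost / persistent / phase-2 classification (joint and separate modes), replicate frequency spectrum |
| `pelement_er.enrichment` | expected counts under homogeneous insertion `P_exp = f_l·P_obs_total/G_l`, enrichment ratios, occupied-region correction for phase-2, chi-square goodness-of-fit |
| `pelement_er.aggregation` | the rediscovery-rate-corrected aggregation estimator (see below) |
| `pelement_er.stats` | generalized Cochran–Mantel–Haenszel for I×J×K strata, Fisher's exact, Benjamini–Hochberg, Kruskal–Wallis |
| `pelement_er.simulate` | two-phase Wright–Fisher forward simulator with hotspot insertion bias, feature-specific selection, and a physical-coverage Pool-Seq detection emulator |
| `pelement_er.diversity` | windowed pooled θπ, overlap-weighted feature averages, low-recombination flagging |
| `pelement_er.calibration`, `pelement_er.pipeline`, CLI `pelement-er` | Monte-Carlo validation experiments and end-to-end orchestration |

## The core estimator

Aggregation of insertions into a focal region set (e.g. ORC binding
sites — reported P-element insertion hotspots) is the fraction of
insertions inside it. Under spatially *uniform* selection, aggregation
is identical in both phases no matter how strong the insertion bias;
an increase in phase 2 indicates relaxed selection inside the region.
Because new biased insertions can restore lost phase-1 sites, phase 2
is corrected with the **rediscovery rate** r (persistent/phase-1
outside all hotspot regions):

    X  = persistent_in − r · phase1_in        # estimated re-insertions
    A1 = phase1_in / phase1_total
    A2 = (phase2_new_in + X) / (phase2_new_total + X)
    change = 100 · (A2 − A1) / A1             # mean ± SEM over replicates

## Worked example

The estimator on a documented count walk — 100 phase-1 insertions, 20
inside the region; 40 of 80 outside sites rediscovered (r = 0.5); 16
persistent inside; 30 new phase-2 insertions, 12 inside:

```python
>>> from pelement_er import AggregationInput, aggregation
>>> res = aggregation(AggregationInput(phase1_in=20, phase1_out=80,
...     persistent_in=16, persistent_out=40,
...     phase2_new_in=12, phase2_new_total=30))
>>> print(f"A1={res.a1:.3f} r={res.rediscovery:.3f} R={res.reinsertions:.0f} "
...       f"A2={res.a2:.3f} change={res.pct_change:+.0f}%")
A1=0.200 r=0.500 R=6 A2=0.500 change=+150%
```

A1 = 0.2 of phase-1 insertions sat in the region; 6 more persistent
sites survived inside than the outside rediscovery rate predicts, so 6
re-insertions are added to the 30 observed phase-2 insertions; half of
the corrected phase-2 insertions fall inside — aggregation rose 150%,
i.e. selection is much weaker inside the region.

End to end on simulated data — a study where hotspots are neutral
(s = 0) but the rest of the genome is under purifying selection
(s = −0.05 per insertion copy):

```
$ printf 's_uniform: -0.05\ns_hotspot: 0.0\n' > relaxed_orc.yaml
$ pelement-er simulate --config relaxed_orc.yaml --out sim --seed 1
$ pelement-er analyze --in sim --out results
$ cat results/aggregation.tsv
region  replicate  a1        a2        rediscovery  reinsertions  pct_change  pct_change_sem
ORC     1          0.277108  0.42204   0.264045     9.7809        52.3013
ORC     2          0.277108  0.303741  0.303371     8.06742       9.61106
ORC     3          0.277108  0.38569   0.337079     5.74157       39.1839
...
ORC     mean       0.277108  0.37049                              33.6987     12.6251
```

The estimator recovers the planted signal: aggregation into the
(neutral) hotspots rose by a mean of +34% (SEM 13%) across the three
replicates. `results/` also contains the classified site table,
per-feature enrichment with replicate SEMs, the stratified CMH /
Fisher+BH / Kruskal–Wallis statistics, and the replicate frequency
spectrum.

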