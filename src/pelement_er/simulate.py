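"""Two-phase forward simulator of a P-element invasion with insertion
bias and spatially variable purifying selection, plus a Pool-Seq
physical-coverage detection emulator.

Phase 1 emulates TE accumulation in many small isofemale lines (strong
drift, weak selection efficacy): each line runs Wright–Fisher dynamics
at the line's census size, with new insertions arriving at rate ``u``
per haploid genome per generation at positions drawn from a per-base
distribution that up-weights hotspot bases by the bias factor beta.

Phase 2 founds large outbred replicate populations by pooling one
genome's worth of each line (a line-private insertion enters at its
within-line frequency divided by the number of lines) and evolves them
for a few generations at large census size, where selection is
efficient. Selection is per insertion copy with multiplicative fitness
(1 + h*s heterozygote, 1 + s homozygote); the coefficient of a site is
set by its annotation feature, optionally overridden inside the hotspot
region set. Insertions segregate as independent biallelic loci
(presence/absence); linkage is ignored.

Detection emulates Pool-Seq physical coverage: at a site of true
frequency f, the number of supporting read pairs is Binomial(C, f); the
site is detected iff the count reaches ``min_count``, its estimated
frequency is count/C, and detected sites within the merge radius
collapse to one record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import SampleCatalog, _cluster_positions
from .genome import (
    AnnotationSet,
    GenomicInterval,
    RegionSet,
    complement,
)


def _default_s_by_feature() -> dict[str, float]:
    # Feature-specific deleterious effects per insertion copy; strongest
    # in coding sequence, weakest in the 5'UTR and intergenic DNA.
    return {
        "CDS": -0.1,
        "five_prime_UTR": -0.01,
        "three_prime_UTR": -0.05,
        "exon": -0.05,
        "intron": -0.03,
        "intergenic": -0.02,
    }


@dataclass
class SimulationConfig:
    annotation: AnnotationSet
    hotspots: RegionSet
    shared: RegionSet | None = None
    n_lines: int = 191
    line_size: int = 45
    phase1_generations: int = 60
    founder_size: int = 1250
    phase2_generations: int = 10
    n_replicates: int = 3
    insertion_rate: float = 0.05  # new insertions per haploid genome per generation
    bias_weight: float = 1.0  # per-base insertion propensity in hotspots vs elsewhere
    s_by_feature: Mapping[str, float] = field(default_factory=_default_s_by_feature)
    s_hotspot: float | None = None  # overrides s_by_feature inside hotspots
    dominance: float = 0.5
    excision_rate: float = 0.0
    coverage: int = 50
    min_count: int = 1
    merge_radius: int = 500

    def __post_init__(self) -> None:
        for name in ("insertion_rate", "excision_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bias_weight <= 0:
            raise ValueError("bias_weight must be positive")
        if not 0 <= self.dominance <= 1:
            raise ValueError("dominance must lie in [0, 1]")


class InsertionSampler:
    """Draws insertion positions from the biased per-base distribution:
    weight beta on hotspot bases, 1 elsewhere."""

    def __init__(self, annotation: AnnotationSet, hotspots: RegionSet, beta: float):
        hot = hotspots.intervals
        cold = complement(hot, annotation.chrom_sizes)
        self._segments: list[tuple[str, int, int]] = []
        lengths = []
        weights = []
        for ivs, w in ((hot, beta), (cold, 1.0)):
            for iv in ivs:
                self._segments.append((iv.chrom, iv.start, iv.end))
                lengths.append(len(iv))
                weights.append(w * len(iv))
        self._lengths = np.array(lengths, dtype=np.int64)
        w = np.array(weights, dtype=float)
        self._probs = w / w.sum()
        self.hotspot_fraction_weighted = float(
            w[: len(hot)].sum() / w.sum()
        )

    def sample(self, n: int, rng: np.random.Generator) -> list[tuple[str, int]]:
        if n == 0:
            return []
        seg = rng.choice(len(self._segments), size=n, p=self._probs)
        offs = rng.integers(0, self._lengths[seg])
        return [
            (self._segments[s][0], int(self._segments[s][1] + o))
            for s, o in zip(seg, offs)
        ]


class _SelectionMap:
    """Selection coefficient per genomic point: feature-specific s,
    optionally overridden inside the hotspot region set."""

    def __init__(self, config: SimulationConfig):
        self._annotation = config.annotation
        self._hotspots = config.hotspots
        self._s_hot = config.s_hotspot
        labels = config.annotation.labels
        self._s_by_code = np.array(
            [config.s_by_feature.get(lab, 0.0) for lab in labels]
        )

    def lookup(self, sites: Sequence[tuple[str, int]]) -> np.ndarray:
        s = np.empty(len(sites))
        by_chrom: dict[str, list[int]] = {}
        for i, (chrom, _pos) in enumerate(sites):
            by_chrom.setdefault(chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            pos = np.array([sites[i][1] for i in idx], dtype=np.int64)
            codes = self._annotation.annotate_points(chrom, pos)
            vals = self._s_by_code[codes]
            if self._s_hot is not None:
                hot = self._hotspots.contains(chrom, pos)
                vals = np.where(hot, self._s_hot, vals)
            s[idx] = vals
        return s


@dataclass
class Population:
    """Independently segregating insertion loci of one (sub)population."""

    sites: list[tuple[str, int]]
    freq: np.ndarray
    s: np.ndarray
    origin_phase: np.ndarray  # 1 or 2 per site

    @classmethod
    def empty(cls) -> "Population":
        return cls([], np.empty(0), np.empty(0), np.empty(0, dtype=np.int64))


def _selection_update(p: np.ndarray, s: np.ndarray, h: float) -> np.ndarray:
    """Deterministic allele-frequency change under diploid viability
    selection with fitnesses (1+s, 1+h*s, 1) for (AA, Aa, aa)."""
    w11 = 1.0 + s
    w12 = 1.0 + h * s
    num = p * p * w11 + p * (1.0 - p) * w12
    wbar = p * p * w11 + 2.0 * p * (1.0 - p) * w12 + (1.0 - p) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wbar > 0, num / wbar, 0.0)
    return np.clip(out, 0.0, 1.0)


def _wf_generation(
    pop: Population,
    n_diploid: int,
    config: SimulationConfig,
    sampler: InsertionSampler,
    smap: _SelectionMap,
    rng: np.random.Generator,
    origin_phase: int,
) -> None:
    """One Wright–Fisher generation in place: new insertions, excision,
    selection, binomial drift."""
    two_n = 2 * n_diploid
    n_new = rng.poisson(two_n * config.insertion_rate)
    if n_new:
        new_sites = sampler.sample(n_new, rng)
        pop.sites.extend(new_sites)
        pop.freq = np.concatenate([pop.freq, np.full(n_new, 1.0 / two_n)])
        pop.s = np.concatenate([pop.s, smap.lookup(new_sites)])
        pop.origin_phase = np.concatenate(
            [pop.origin_phase, np.full(n_new, origin_phase, dtype=np.int64)]
        )
    p = pop.freq
    if config.excision_rate > 0:
        p = p * (1.0 - config.excision_rate)
    p = _selection_update(p, pop.s, config.dominance)
    pop.freq = rng.binomial(two_n, p) / two_n


def _compact(pop: Population) -> Population:
    keep = pop.freq > 0
    if keep.all():
        return pop
    return Population(
        sites=[st for st, k in zip(pop.sites, keep) if k],
        freq=pop.freq[keep],
        s=pop.s[keep],
        origin_phase=pop.origin_phase[keep],
    )


def simulate_phase1(
    config: SimulationConfig, rng: np.random.Generator
) -> list[Population]:
    """Accumulation of insertions in ``n_lines`` small isofemale lines."""
    sampler = InsertionSampler(config.annotation, config.hotspots, config.bias_weight)
    smap = _SelectionMap(config)
    lines = []
    for _ in range(config.n_lines):
        pop = Population.empty()
        for _ in range(config.phase1_generations):
            _wf_generation(pop, config.line_size, config, sampler, smap, rng, 1)
        lines.append(_compact(pop))
    return lines


def found_replicate(lines: Sequence[Population], config: SimulationConfig) -> Population:
    """Panmictic founder pool: each line contributes equally, so a
    line-private insertion enters at its within-line frequency divided
    by the number of lines (summed, capped at 1, if several lines carry
    the same site)."""
    acc: dict[tuple[str, int], list[float]] = {}
    s_of: dict[tuple[str, int], float] = {}
    for line in lines:
        for site, f, s in zip(line.sites, line.freq, line.s):
            acc.setdefault(site, []).append(float(f))
            s_of[site] = float(s)
    sites = sorted(acc)
    freq = np.array([min(1.0, sum(acc[st]) / len(lines)) for st in sites])
    s = np.array([s_of[st] for st in sites])
    return Population(
        sites=sites, freq=freq, s=s,
        origin_phase=np.ones(len(sites), dtype=np.int64),
    )


def evolve_phase2(
    founders: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[Population, np.ndarray]:
    """Phase-2 evolution of one replicate at large census size.

    Returns the final population (all founder loci retained, possibly at
    frequency 0, plus any new phase-2 loci) and the founder frequencies
    aligned with the returned site order.
    """
    pop = Population(
        sites=list(founders.sites),
        freq=founders.freq.copy(),
        s=founders.s.copy(),
        origin_phase=founders.origin_phase.copy(),
    )
    sampler = InsertionSampler(config.annotation, config.hotspots, config.bias_weight)
    smap = _SelectionMap(config)
    for _ in range(config.phase2_generations):
        _wf_generation(pop, config.founder_size, config, sampler, smap, rng, 2)
    founder_freq = np.concatenate(
        [founders.freq, np.zeros(len(pop.sites) - len(founders.sites))]
    )
    return pop, founder_freq


def poolseq_detect(
    sites: Sequence[tuple[str, int]],
    freq: np.ndarray,
    replicate: int,
    generation: int,
    rng: np.random.Generator,
    coverage: int = 50,
    min_count: int = 1,
    merge_radius: int = 500,
) -> SampleCatalog:
    """Pool-Seq detection emulator at uniform physical coverage.

    Supporting read pairs per site ~ Binomial(coverage, f); a site is
    detected iff the count reaches ``min_count``; the estimated frequency
    is count/coverage; detected sites within ``merge_radius`` merge into
    one record (representative = minimum position, frequency = mean).
    """
    if coverage < 1 or min_count < 1:
        raise ValueError("coverage and min_count must be >= 1")
    freq = np.asarray(freq, dtype=float)
    k = rng.binomial(coverage, np.clip(freq, 0.0, 1.0))
    detected = k >= min_count
    df = pd.DataFrame(
        {
            "chrom": [sites[i][0] for i in np.flatnonzero(detected)],
            "pos": [sites[i][1] for i in np.flatnonzero(detected)],
            "frequency": k[detected] / coverage,
        }
    )
    merged = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        cluster = _cluster_positions(grp["pos"].to_numpy(), merge_radius)
        agg = grp.assign(_cluster=cluster).groupby("_cluster").agg(
            pos=("pos", "min"), frequency=("frequency", "mean")
        )
        agg["chrom"] = chrom
        merged.append(agg[["chrom", "pos", "frequency"]])
    frame = (
        pd.concat(merged, ignore_index=True)
        if merged
        else pd.DataFrame(columns=["chrom", "pos", "frequency"])
    )
    return SampleCatalog(replicate=replicate, generation=generation, frame=frame)


@dataclass
class SimulationResult:
    catalogs: list[SampleCatalog]
    truth: dict[int, pd.DataFrame]  # per replicate: site-level ground truth
    config: SimulationConfig


def _truth_frame(
    pop: Population, founder_freq: np.ndarray, merge_radius: int
) -> pd.DataFrame:
    """Ground-truth classification of every locus of one replicate.

    lost / persistent / phase-2 follow the true frequencies (founder
    presence vs final presence); a surviving phase-2 locus within the
    merge radius of a lost phase-1 locus is flagged as a re-insertion.
    """
    final = pop.freq
    origin = pop.origin_phase
    cls = np.full(len(final), "none", dtype=object)
    cls[(founder_freq > 0) & (final > 0)] = "persistent"
    cls[(founder_freq > 0) & (final == 0)] = "lost"
    cls[(founder_freq == 0) & (final > 0) & (origin == 2)] = "phase-2"
    df = pd.DataFrame(
        {
            "chrom": [c for c, _ in pop.sites],
            "pos": [p for _, p in pop.sites],
            "origin_phase": origin,
            "founder_freq": founder_freq,
            "final_freq": final,
            "true_class": cls,
        }
    ).sort_values(["chrom", "pos"], ignore_index=True)
    # re-insertion flag: surviving phase-2 site near a lost phase-1 site
    reins = np.zeros(len(df), dtype=bool)
    lost = df[df["true_class"] == "lost"]
    p2 = df[df["true_class"] == "phase-2"]
    for chrom, sub in p2.groupby("chrom"):
        lost_pos = lost.loc[lost["chrom"] == chrom, "pos"].to_numpy()
        if lost_pos.size == 0:
            continue
        pos = sub["pos"].to_numpy()
        j = np.searchsorted(lost_pos, pos)
        near = np.zeros(len(pos), dtype=bool)
        left = np.clip(j - 1, 0, len(lost_pos) - 1)
        right = np.clip(j, 0, len(lost_pos) - 1)
        near |= np.abs(pos - lost_pos[left]) <= merge_radius
        near |= np.abs(pos - lost_pos[right]) <= merge_radius
        reins[sub.index] = near
    df["reinsertion"] = reins
    return df


def simulate_experiment(config: SimulationConfig, seed: int) -> SimulationResult:
    """Full two-phase experiment: phase-1 lines, replicate founding,
    phase-2 evolution, and Pool-Seq detection of all six samples.
    Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    lines = simulate_phase1(config, rng)
    founders = found_replicate(lines, config)
    catalogs: list[SampleCatalog] = []
    truth: dict[int, pd.DataFrame] = {}
    for rep in range(1, config.n_replicates + 1):
        pop, founder_freq = evolve_phase2(founders, config, rng)
        truth[rep] = _truth_frame(pop, founder_freq, config.merge_radius)
        catalogs.append(
            poolseq_detect(
                founders.sites, founders.freq, rep, 0, rng,
                coverage=config.coverage, min_count=config.min_count,
                merge_radius=config.merge_radius,
            )
        )
        catalogs.append(
            poolseq_detect(
                pop.sites, pop.freq, rep, 10, rng,
                coverage=config.coverage, min_count=config.min_count,
                merge_radius=config.merge_radius,
            )
        )
    return SimulationResult(catalogs=catalogs, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Deterministic toy genome used by tests, fixtures, and calibration runs.


def toy_genome(
    chrom_length: int = 1_000_000,
    chrom: str = "2L",
    gene_unit: int = 10_000,
    hotspot_spacing: int = 1_000,
    hotspot_length: int = 50,
    shared_spacing: int = 10_000,
    shared_length: int = 100,
) -> tuple[AnnotationSet, RegionSet, RegionSet]:
    """A 1 Mb single-chromosome genome tiled with repeating gene models
    (5'UTR, CDS, intron, CDS, 3'UTR per 10 kb unit), hotspot regions
    emulating ORC binding sites, and a sparser set of shared-site
    regions.

    Hotspots are many and short (1000 x 50 bp by default, ~5% of the
    genome) so that, as in real ORC data, only a small fraction of
    hotspot intervals is occupied and the 500 bp signature merging does
    not collapse independent hotspot insertions into stacked sites."""
    tracks: dict[str, list[GenomicInterval]] = {
        "five_prime_UTR": [],
        "CDS": [],
        "intron": [],
        "three_prime_UTR": [],
    }
    for start in range(0, chrom_length, gene_unit):
        tracks["five_prime_UTR"].append(GenomicInterval(chrom, start, start + 200))
        tracks["CDS"].append(GenomicInterval(chrom, start + 200, start + 1700))
        tracks["intron"].append(GenomicInterval(chrom, start + 1700, start + 2700))
        tracks["CDS"].append(GenomicInterval(chrom, start + 2700, start + 3200))
        tracks["three_prime_UTR"].append(GenomicInterval(chrom, start + 3200, start + 3500))
    annotation = AnnotationSet(tracks, {chrom: chrom_length})
    hotspots = RegionSet(
        "ORC",
        [
            GenomicInterval(chrom, start + 200, start + 200 + hotspot_length)
            for start in range(0, chrom_length, hotspot_spacing)
        ],
        min_length=hotspot_length,
    )
    # shared sites placed in the intergenic stretch of each gene unit,
    # clear of the hotspot offsets
    shared = RegionSet(
        "shared",
        [
            GenomicInterval(chrom, start + 4400, start + 4400 + shared_length)
            for start in range(0, chrom_length, shared_spacing)
        ],
    )
    return annotation, hotspots, shared


def toy_config(
    beta: float = 5.0,
    s_uniform: float | None = -0.02,
    s_hotspot: float | None = None,
    n_lines: int = 20,
    insertion_rate: float = 0.10,
    **kwargs,
) -> SimulationConfig:
    """Calibration-scale study: toy 1 Mb genome, 20 isofemale lines,
    insertion rate tuned to roughly 300 detected phase-1 sites.

    ``s_uniform`` sets one coefficient for every feature (None keeps the
    feature-specific defaults); ``s_hotspot`` optionally overrides it
    inside the hotspot regions.
    """
    annotation, hotspots, shared = toy_genome()
    s_by_feature = (
        {lab: s_uniform for lab in annotation.labels}
        if s_uniform is not None
        else _default_s_by_feature()
    )
    return SimulationConfig(
        annotation=annotation,
        hotspots=hotspots,
        shared=shared,
        n_lines=n_lines,
        line_size=45,
        phase1_generations=60,
        founder_size=1250,
        phase2_generations=10,
        n_replicates=3,
        insertion_rate=insertion_rate,
        bias_weight=beta,
        s_by_feature=s_by_feature,
        s_hotspot=s_hotspot,
        **kwargs,
    )
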