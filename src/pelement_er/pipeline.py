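"""Orchestration: simulate -> classify -> enrichment / aggregation /
statistics, with TSV outputs and a reproducible run log."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import aggregation, summarize_replicates
from .catalog import (
    LOST,
    PERSISTENT,
    PHASE2,
    SampleCatalog,
    annotate_sites,
    build_aggregation_input,
    classify_joint,
    classify_separate,
    match_sites,
    replicate_frequency_spectrum,
)
from .enrichment import (
    enrichment_result,
    gof_chi2,
    phase2_effective_length,
    replicate_mean_sem,
)
from .genome import (
    AnnotationSet,
    RegionSet,
    read_bed,
    read_chrom_sizes,
    write_bed,
    write_chrom_sizes,
)
from .simulate import SimulationConfig, simulate_experiment, toy_config, toy_genome
from .stats import bh_adjust, cmh_general, fisher_exact_2x2, kruskal_wallis

_FLOAT_FMT = "%.6g"


@dataclass
class AnalysisBundle:
    """In-memory results of one analysis run."""

    classified: pd.DataFrame
    enrichment: pd.DataFrame
    aggregation: pd.DataFrame
    statistics: pd.DataFrame
    rfs: pd.DataFrame
    separate: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("classified", "enrichment", "aggregation", "statistics",
                     "rfs", "separate"):
            getattr(self, name).to_csv(
                outdir / f"{name}.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT,
            )


def analyze_catalogs(
    catalogs: list[SampleCatalog],
    annotation: AnnotationSet,
    orc: RegionSet,
    shared: RegionSet,
    merge_radius: int = 500,
    cross_radius: int = 1000,
    replicates: tuple[int, ...] = (1, 2, 3),
) -> AnalysisBundle:
    """Full inferential pipeline on six sample catalogs."""
    matrix = match_sites(catalogs, radius=merge_radius)
    classified = classify_joint(matrix, replicates=replicates)
    classified = annotate_sites(classified, annotation, orc, shared)

    ft = annotation.feature_lengths()
    union = RegionSet("hotspot-union", orc.intervals + shared.intervals)

    enr_rows = []
    stat_rows = []
    fisher_ps: list[dict] = []
    agg_rows = []
    kw_groups: dict[str, list[float]] = {}
    cmh_tables = []
    persistent_by_rep: dict[int, list[tuple[str, int]]] = {}

    features = [f for f in annotation.labels if ft.f_l[f] > 0]
    for rep in replicates:
        cls = classified[f"class_r{rep}"]
        feat = classified["feature"]
        is_phase1 = cls.isin([LOST, PERSISTENT])
        by_class = {
            "phase-1": is_phase1,
            "persistent": cls == PERSISTENT,
            "lost": cls == LOST,
            "phase-2": cls == PHASE2,
        }
        phase1_sites = list(
            classified.loc[is_phase1, ["chrom", "pos"]].itertuples(index=False, name=None)
        )
        persistent_by_rep[rep] = list(
            classified.loc[cls == PERSISTENT, ["chrom", "pos"]]
            .itertuples(index=False, name=None)
        )
        # per-feature enrichment and per-region enrichment per class
        for label, mask in by_class.items():
            total = int(mask.sum())
            if total == 0:
                continue
            for f in features:
                res = enrichment_result(
                    f, label, int((mask & (feat == f)).sum()), ft.f_l[f],
                    total, ft.g_l,
                )
                enr_rows.append({**vars(res), "replicate": rep})
            for region in (orc, shared):
                f_l = region.total_length
                if label == "phase-2":
                    f_l = phase2_effective_length(region, phase1_sites)
                obs = int(
                    (mask & classified[
                        "in_orc" if region is orc else "in_shared"
                    ]).sum()
                )
                if f_l > 0:
                    res = enrichment_result(region.name, label, obs, f_l, total, ft.g_l)
                    enr_rows.append({**vars(res), "replicate": rep})
        # goodness-of-fit of the homogeneous model per feature (phase-1)
        n_phase1 = int(is_phase1.sum())
        if n_phase1:
            for f in features:
                if not 0 < ft.f_l[f] < ft.g_l:
                    continue
                res = gof_chi2(
                    int((is_phase1 & (feat == f)).sum()), n_phase1, ft.f_l[f], ft.g_l
                )
                stat_rows.append(
                    {
                        "test": "gof-chi2", "scope": f, "replicate": rep,
                        "statistic": res.statistic, "df": res.df,
                        "p_value": res.p_value,
                    }
                )
        # CMH stratum: lost/persistent x feature
        tab = np.array(
            [
                [int(((cls == c) & (feat == f)).sum()) for f in features]
                for c in (LOST, PERSISTENT)
            ],
            dtype=float,
        )
        cmh_tables.append(tab)
        # Fisher: shared sites vs each feature (lost vs persistent),
        # excluding shared-site insertions also inside the feature
        in_shared = classified["in_shared"]
        for f in features:
            shared_mask = in_shared
            feat_mask = (feat == f) & ~in_shared
            table = [
                [int((shared_mask & (cls == LOST)).sum()),
                 int((shared_mask & (cls == PERSISTENT)).sum())],
                [int((feat_mask & (cls == LOST)).sum()),
                 int((feat_mask & (cls == PERSISTENT)).sum())],
            ]
            res = fisher_exact_2x2(table)
            fisher_ps.append(
                {
                    "test": "fisher-shared-vs-feature", "scope": f,
                    "replicate": rep, "statistic": res.statistic,
                    "df": np.nan, "p_value": res.p_value,
                }
            )
        # phase-1 frequency by feature (pooled across replicates below)
        for f in features:
            vals = classified.loc[
                is_phase1 & (feat == f), f"freq_gen0_r{rep}"
            ].dropna()
            kw_groups.setdefault(f, []).extend(vals.tolist())
        # aggregation per focal region; undefined (e.g. no phase-1 sites
        # inside the region for this replicate) is recorded as NaN
        for region in (orc, shared):
            inp = build_aggregation_input(classified, rep, region, union)
            try:
                res = aggregation(inp)
                row = {
                    "region": region.name, "replicate": rep, "a1": res.a1,
                    "a2": res.a2, "rediscovery": res.rediscovery,
                    "reinsertions": res.reinsertions,
                    "pct_change": res.pct_change,
                }
            except ValueError:
                row = {
                    "region": region.name, "replicate": rep, "a1": np.nan,
                    "a2": np.nan, "rediscovery": np.nan,
                    "reinsertions": np.nan, "pct_change": np.nan,
                }
            agg_rows.append(row)

    # stratified CMH across replicates
    drop = [
        j for j in range(len(features))
        if all(tab[:, j].sum() == 0 for tab in cmh_tables)
    ]
    keep = [j for j in range(len(features)) if j not in drop]
    if keep and len(keep) >= 2:
        stacked = np.stack([tab[:, keep] for tab in cmh_tables])
        if stacked.sum(axis=(0, 2)).min() > 0:
            res = cmh_general(stacked)
            stat_rows.append(
                {
                    "test": "cmh-lost-persistent-by-feature", "scope": "joint",
                    "replicate": np.nan, "statistic": res.statistic,
                    "df": res.df, "p_value": res.p_value,
                }
            )
    # BH across all replicate x feature Fisher tests
    if fisher_ps:
        adj = bh_adjust([row["p_value"] for row in fisher_ps])
        for row, p_adj in zip(fisher_ps, adj):
            row["p_adjusted"] = p_adj
            stat_rows.append(row)
    # Kruskal-Wallis of phase-1 frequencies across features
    groups = [v for v in kw_groups.values() if len(v) > 0]
    if len(groups) >= 2:
        res = kruskal_wallis(groups)
        stat_rows.append(
            {
                "test": "kruskal-wallis-freq-by-feature", "scope": "pooled",
                "replicate": np.nan, "statistic": res.statistic,
                "df": res.df, "p_value": res.p_value,
            }
        )

    enr = pd.DataFrame(enr_rows)
    # replicate means and SEM per label x class
    summary_rows = []
    if not enr.empty:
        for (label, icls), grp in enr.groupby(["label", "insertion_class"]):
            mean, sem = replicate_mean_sem(grp["enrichment"].tolist())
            summary_rows.append(
                {
                    "label": label, "insertion_class": icls, "p_obs": np.nan,
                    "p_exp": np.nan, "f_l": np.nan, "p_obs_total": np.nan,
                    "g_l": np.nan, "enrichment": mean, "replicate": "mean",
                    "sem": sem,
                }
            )
    enr["sem"] = np.nan
    enr = pd.concat([enr, pd.DataFrame(summary_rows)], ignore_index=True)

    agg = pd.DataFrame(agg_rows)
    agg_summaries = []
    for region_name, grp in agg.groupby("region"):
        from .aggregation import AggregationResult

        grp = grp.dropna(subset=["pct_change"])
        if grp.empty:
            continue
        results = [
            AggregationResult(
                a1=row.a1, a2=row.a2, rediscovery=row.rediscovery,
                reinsertions=row.reinsertions, pct_change=row.pct_change,
            )
            for row in grp.itertuples()
        ]
        summ = summarize_replicates(results)
        agg_summaries.append(
            {
                "region": region_name, "replicate": "mean",
                "a1": summ["a1_mean"], "a2": summ["a2_mean"],
                "rediscovery": np.nan, "reinsertions": np.nan,
                "pct_change": summ["pct_change_mean"],
                "pct_change_sem": summ["pct_change_sem"],
            }
        )
    agg["pct_change_sem"] = np.nan
    agg = pd.concat([agg, pd.DataFrame(agg_summaries)], ignore_index=True)

    rfs = replicate_frequency_spectrum(
        persistent_by_rep, orc, shared, cross_radius=cross_radius
    )

    # separate (within-replicate) classification for robustness checks
    sep_frames = []
    by_key = {(c.replicate, c.generation): c for c in catalogs}
    for rep in replicates:
        sep_frames.append(
            classify_separate(by_key[(rep, 0)], by_key[(rep, 10)], radius=merge_radius)
        )
    separate = pd.concat(sep_frames, ignore_index=True)

    return AnalysisBundle(
        classified=classified,
        enrichment=enr,
        aggregation=agg,
        statistics=pd.DataFrame(stat_rows),
        rfs=rfs,
        separate=separate,
    )


# ---------------------------------------------------------------------------
# Path-based entry points used by the CLI.


def run_simulate(config: SimulationConfig, outdir: str | Path, seed: int) -> None:
    """Simulate one experiment and write catalogs, truth logs, and the
    genome bundle (annotation BEDs, region BEDs, chromosome sizes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = simulate_experiment(config, seed)
    for cat in result.catalogs:
        cat.write_tsv(outdir / f"catalog_{cat.key}.tsv")
    for rep, truth in result.truth.items():
        truth.to_csv(
            outdir / f"truth_r{rep}.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
    for label, ivs in config.annotation.tracks.items():
        write_bed(ivs, outdir / f"annotation_{label}.bed")
    write_bed(config.hotspots.intervals, outdir / "orc.bed")
    if config.shared is not None:
        write_bed(config.shared.intervals, outdir / "shared.bed")
    write_chrom_sizes(config.annotation.chrom_sizes, outdir / "chrom_sizes.tsv")
    _write_log(
        outdir,
        seed=seed,
        mode="simulate",
        n_lines=config.n_lines,
        line_size=config.line_size,
        phase1_generations=config.phase1_generations,
        founder_size=config.founder_size,
        phase2_generations=config.phase2_generations,
        n_replicates=config.n_replicates,
        insertion_rate=config.insertion_rate,
        bias_weight=config.bias_weight,
        dominance=config.dominance,
        excision_rate=config.excision_rate,
        coverage=config.coverage,
        min_count=config.min_count,
        merge_radius=config.merge_radius,
    )


def run_analyze(
    indir: str | Path,
    outdir: str | Path,
    merge_radius: int = 500,
    cross_radius: int = 1000,
    orc_min_length: int = 1,
) -> AnalysisBundle:
    """Analyze a directory holding the six catalog TSVs plus the genome
    bundle written by ``run_simulate`` (or assembled by hand in the same
    layout)."""
    indir = Path(indir)
    catalogs = []
    for path in sorted(indir.glob("catalog_*.tsv")):
        catalogs.append(SampleCatalog.read_tsv(path))
    if not catalogs:
        raise FileNotFoundError(f"no catalog_*.tsv files in {indir}")
    sizes_path = indir / "chrom_sizes.tsv"
    if not sizes_path.exists():
        raise FileNotFoundError(f"chromosome-sizes table missing: {sizes_path}")
    chrom_sizes = read_chrom_sizes(sizes_path)
    tracks = {}
    for path in sorted(indir.glob("annotation_*.bed")):
        label = path.stem.removeprefix("annotation_")
        tracks[label] = read_bed(path)
    if not tracks:
        raise FileNotFoundError(f"no annotation_*.bed tracks in {indir}")
    annotation = AnnotationSet(tracks, chrom_sizes)
    orc_path = indir / "orc.bed"
    shared_path = indir / "shared.bed"
    for role, path in (("ORC regions", orc_path), ("shared sites", shared_path)):
        if not path.exists():
            raise FileNotFoundError(f"{role} BED missing: {path}")
    # BED region sets are consumed as final products; apply a minimum
    # length only if the caller asks for it (e.g. 100 bp when building
    # an ORC set from raw mapped sequences)
    orc = RegionSet("ORC", read_bed(orc_path), min_length=orc_min_length)
    shared = RegionSet("shared", read_bed(shared_path))
    replicates = tuple(sorted({c.replicate for c in catalogs}))
    bundle = analyze_catalogs(
        catalogs, annotation, orc, shared,
        merge_radius=merge_radius, cross_radius=cross_radius,
        replicates=replicates,
    )
    # optional tracks: per-site allele counts -> windowed diversity per
    # feature; recombination map -> low-recombination flag per site
    sync_path = indir / "allele_counts.sync"
    if sync_path.exists():
        from .diversity import DiversityConfig, feature_weighted_mean, read_sync, window_pi

        sites = read_sync(sync_path)
        windows = window_pi(sites, chrom_sizes, DiversityConfig())
        div_rows = []
        for label, ivs in annotation.exclusive_tracks().items():
            try:
                value = feature_weighted_mean(windows, ivs)
            except ValueError:
                value = np.nan
            div_rows.append({"feature": label, "theta_pi": value})
        Path(outdir).mkdir(parents=True, exist_ok=True)
        windows.to_csv(
            Path(outdir) / "pi_windows.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
        pd.DataFrame(div_rows).to_csv(
            Path(outdir) / "diversity.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
    rec_path = indir / "rec_map.tsv"
    if rec_path.exists():
        from .diversity import low_recombination_flag, read_rec_map

        rec_map = read_rec_map(rec_path)
        bundle.classified = bundle.classified.assign(
            low_recombination=low_recombination_flag(bundle.classified, rec_map)
        )
    bundle.write(outdir)
    _write_log(
        Path(outdir), mode="analyze", indir=str(indir),
        merge_radius=merge_radius, cross_radius=cross_radius,
    )
    return bundle


def make_fixtures(outdir: str | Path, seed: int = 5) -> None:
    """Write a small committed-size synthetic dataset: a scaled-down
    simulated experiment (3 replicates x 2 generations on a 200 kb toy
    genome) plus the worked aggregation-example count table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, hotspots, shared = toy_genome(chrom_length=200_000)
    config = SimulationConfig(
        annotation=annotation, hotspots=hotspots, shared=shared,
        n_lines=10, line_size=45, phase1_generations=40,
        founder_size=500, phase2_generations=10, n_replicates=3,
        insertion_rate=0.05, bias_weight=5.0,
        s_by_feature={lab: -0.02 for lab in annotation.labels},
    )
    run_simulate(config, outdir, seed)
    # worked aggregation-example counts (A1=0.2, r=0.5, R=6, A2=0.5, +150%)
    example = pd.DataFrame(
        [
            {
                "region": "ORC", "replicate": 1, "phase1_in": 20,
                "phase1_out": 80, "persistent_in": 16, "persistent_out": 40,
                "phase2_new_in": 12, "phase2_new_total": 30,
                "phase1_total": 100,
            }
        ]
    )
    example.to_csv(outdir / "aggregation_example.tsv", sep="\t", index=False)


def _write_log(outdir: Path, **params) -> None:
    log = {"package": "pelement-er", "version": __version__, **params}
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
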