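"""Monte-Carlo calibration experiments for the estimator and detector.

These functions run the full simulate -> detect -> classify -> estimate
chain on the calibration-scale study (see ``toy_config``) and summarise
the behaviour of the aggregation estimator under a known truth: the
no-selection-difference null (uniform s, any insertion bias) and the
spatially-variable-selection alternative (neutral hotspots, deleterious
elsewhere).
"""

from __future__ import annotations

import numpy as np

from .aggregation import aggregation
from .catalog import build_aggregation_input, classify_joint, match_sites
from .enrichment import gof_chi2
from .genome import RegionSet
from .simulate import Population, poolseq_detect, simulate_experiment, toy_config


def aggregation_pct_change(
    seed: int,
    beta: float = 5.0,
    s_uniform: float | None = -0.02,
    s_hotspot: float | None = None,
    region: str = "ORC",
    **config_kwargs,
) -> float:
    """Replicate-mean aggregation change (%) of one simulated experiment."""
    cfg = toy_config(
        beta=beta, s_uniform=s_uniform, s_hotspot=s_hotspot, **config_kwargs
    )
    res = simulate_experiment(cfg, seed)
    matrix = match_sites(res.catalogs, radius=cfg.merge_radius)
    classified = classify_joint(matrix)
    union = RegionSet("union", cfg.hotspots.intervals + cfg.shared.intervals)
    focal = cfg.hotspots if region == "ORC" else cfg.shared
    vals = [
        aggregation(build_aggregation_input(classified, rep, focal, union)).pct_change
        for rep in (1, 2, 3)
    ]
    return float(np.mean(vals))


def pct_change_sample(
    n_runs: int, seed0: int = 0, **kwargs
) -> dict[str, float]:
    """Mean, SD, and 95% CI of the aggregation change over repeated
    simulated experiments."""
    vals = np.array(
        [aggregation_pct_change(seed0 + i, **kwargs) for i in range(n_runs)]
    )
    se = vals.std(ddof=1) / np.sqrt(n_runs)
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)),
        "se": float(se),
        "ci_low": float(vals.mean() - 1.96 * se),
        "ci_high": float(vals.mean() + 1.96 * se),
        "n": n_runs,
    }


def neutral_enrichment(
    n_runs: int = 30, seed0: int = 0
) -> dict[str, dict[str, float]]:
    """Per-feature enrichment of detected phase-1 insertions under a
    homogeneous insertion process (beta=1, s=0): expectation 1.0."""
    per_feature: dict[str, list[float]] = {}
    for i in range(n_runs):
        cfg = toy_config(beta=1.0, s_uniform=0.0)
        res = simulate_experiment(cfg, seed0 + i)
        matrix = match_sites(res.catalogs, radius=cfg.merge_radius)
        gen0_any = matrix[[f"in_r{r}_g0" for r in (1, 2, 3)]].any(axis=1)
        sites = matrix.loc[gen0_any, ["chrom", "pos"]]
        ft = cfg.annotation.feature_lengths()
        total = len(sites)
        codes = cfg.annotation.annotate_points("2L", sites["pos"].to_numpy())
        labels = cfg.annotation.labels
        counts = np.bincount(codes, minlength=len(labels))
        for lab, obs in zip(labels, counts):
            if ft.f_l[lab] == 0:
                continue
            expected = ft.f_l[lab] * total / ft.g_l
            per_feature.setdefault(lab, []).append(obs / expected)
    return {
        lab: {
            "mean": float(np.mean(v)),
            "sem": float(np.std(v, ddof=1) / np.sqrt(len(v))),
            "n": len(v),
        }
        for lab, v in per_feature.items()
    }


def gof_type1_rate(
    n_sims: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    feature_fraction: float = 0.2,
    n_insertions: int = 300,
) -> float:
    """Empirical rejection rate of the two-cell goodness-of-fit test
    under the homogeneous null (binomially distributed feature counts)."""
    rng = np.random.default_rng(seed)
    g_l = 1_000_000
    f_l = int(feature_fraction * g_l)
    rejections = 0
    for _ in range(n_sims):
        obs_in = rng.binomial(n_insertions, feature_fraction)
        if gof_chi2(obs_in, n_insertions, f_l, g_l).p_value < alpha:
            rejections += 1
    return rejections / n_sims


def detection_probability_mc(
    f: float = 0.1,
    coverage: int = 50,
    n_sites: int = 20_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo detection probability of the Pool-Seq emulator at a
    fixed true frequency (closed form: 1 - (1-f)^coverage)."""
    rng = np.random.default_rng(seed)
    sites = [("2L", 1000 * i) for i in range(n_sites)]
    cat = poolseq_detect(
        sites, np.full(n_sites, f), 1, 0, rng, coverage=coverage
    )
    return len(cat.frame) / n_sites


def classification_truth_check(
    seed: int = 0, coverage: int = 5000, n_per_class: int = 50
) -> dict[str, int]:
    """Exactness of the joint classifier in the perfect-detection limit.

    Builds a population of well-separated sites with known fates
    (persistent / lost / phase-2 at comfortably detectable frequencies),
    emulates all six Pool-Seq samples at high physical coverage, and
    counts classification mismatches against the constructed truth.
    """
    rng = np.random.default_rng(seed)
    spacing = 5000
    sites, founder, final, truth = [], [], [], []
    for i in range(3 * n_per_class):
        sites.append(("2L", 1000 + i * spacing))
        kind = i % 3
        if kind == 0:
            founder.append(0.6), final.append(0.5), truth.append("persistent")
        elif kind == 1:
            founder.append(0.6), final.append(0.0), truth.append("lost")
        else:
            founder.append(0.0), final.append(0.4), truth.append("phase-2")
    founder = np.array(founder)
    final = np.array(final)
    catalogs = []
    for rep in (1, 2, 3):
        catalogs.append(poolseq_detect(sites, founder, rep, 0, rng, coverage=coverage))
        catalogs.append(poolseq_detect(sites, final, rep, 10, rng, coverage=coverage))
    classified = classify_joint(match_sites(catalogs))
    mismatches = 0
    lookup = {
        (c, p): t for (c, p), t in zip(sites, truth)
    }
    for row in classified.itertuples():
        expected = lookup[(row.chrom, row.pos)]
        for rep in (1, 2, 3):
            if getattr(row, f"class_r{rep}") != expected:
                mismatches += 1
    return {"n_sites": len(sites), "n_calls": 3 * len(sites), "mismatches": mismatches}
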