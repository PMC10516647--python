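"""Enrichment of TE insertions per genomic feature or region.

Under a homogeneous insertion process the expected number of insertions
in a feature of total length f_l is

    P_exp = f_l * P_obs_total / G_l

with P_obs_total the genome-wide observed count and G_l the total length
of the main chromosome arms. Enrichment is the observed/expected ratio;
1.0 marks a homogeneous distribution (no insertion bias or selection).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import RegionSet
from .stats import TestResult


@dataclass
class EnrichmentResult:
    label: str
    insertion_class: str
    p_obs: float
    p_exp: float
    f_l: float
    p_obs_total: float
    g_l: float
    enrichment: float


def expected_count(f_l: float, p_obs_total: float, g_l: float) -> float:
    """Expected insertion count in a feature under homogeneous insertion."""
    if g_l <= 0:
        raise ValueError("total genome length G_l must be positive")
    if not 0 <= f_l <= g_l:
        raise ValueError("feature length f_l must lie in [0, G_l]")
    return f_l * p_obs_total / g_l


def enrichment(p_obs: float, p_exp: float) -> float:
    """Observed/expected ratio; requires a positive expectation."""
    if p_exp <= 0:
        raise ValueError("enrichment undefined for non-positive expected count")
    return p_obs / p_exp


def enrichment_result(
    label: str, insertion_class: str, p_obs: float, f_l: float,
    p_obs_total: float, g_l: float,
) -> EnrichmentResult:
    p_exp = expected_count(f_l, p_obs_total, g_l)
    return EnrichmentResult(
        label=label, insertion_class=insertion_class, p_obs=p_obs, p_exp=p_exp,
        f_l=f_l, p_obs_total=p_obs_total, g_l=g_l,
        enrichment=enrichment(p_obs, p_exp),
    )


def phase2_effective_length(
    region: RegionSet, phase1_sites: Iterable[tuple[str, int]]
) -> int:
    """Region length available to new (phase-2) insertions: the total
    region length minus the summed lengths of member intervals already
    occupied by at least one phase-1 insertion."""
    occupied: set[tuple[str, int]] = set()
    for chrom, pos in phase1_sites:
        idx = int(region.member_index(chrom, pos)[0])
        if idx >= 0:
            occupied.add((chrom, idx))
    occupied_bp = 0
    by_chrom: dict[str, list] = {}
    for iv in region.intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, idx in occupied:
        occupied_bp += len(by_chrom[chrom][idx])
    return region.total_length - occupied_bp


def gof_chi2(
    p_obs_in: float, p_obs_total: float, f_l: float, g_l: float
) -> TestResult:
    """Two-cell goodness-of-fit test of the homogeneous insertion model
    for one feature: {inside, outside} observed counts against
    expectations proportional to feature length. No continuity correction.
    """
    if not 0 < f_l < g_l:
        raise ValueError("need 0 < f_l < G_l for a two-cell test")
    if p_obs_in < 0 or p_obs_total < p_obs_in:
        raise ValueError("invalid observed counts")
    exp_in = expected_count(f_l, p_obs_total, g_l)
    exp_out = p_obs_total - exp_in
    if exp_in == 0 or exp_out == 0:
        raise ValueError("expected cell count of zero")
    obs_out = p_obs_total - p_obs_in
    stat = (p_obs_in - exp_in) ** 2 / exp_in + (obs_out - exp_out) ** 2 / exp_out
    return TestResult(
        statistic=float(stat), df=1, p_value=float(sps.chi2.sf(stat, 1)),
        method="chi2-gof",
    )


def feature_enrichment_table(
    counts_by_feature: dict[str, float],
    f_l: dict[str, float],
    g_l: float,
    insertion_class: str = "phase-1",
) -> pd.DataFrame:
    """Per-feature enrichment for one sample/replicate.

    ``counts_by_feature`` must cover a mutually exclusive feature
    partition; P_obs_total is its sum, so summing P_exp over features
    recovers P_obs_total exactly.
    """
    total = float(sum(counts_by_feature.values()))
    rows = []
    for label, obs in counts_by_feature.items():
        res = enrichment_result(label, insertion_class, obs, f_l[label], total, g_l)
        rows.append(vars(res))
    return pd.DataFrame(rows)


def replicate_mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Unweighted mean and SEM (= sd/sqrt(n), ddof=1) across replicates."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    if arr.size == 1:
        return float(arr[0]), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))
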