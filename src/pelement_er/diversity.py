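"""Pooled nucleotide diversity (theta-pi) in fixed windows, overlap-
weighted feature averages, and the low-recombination flag.

Site diversity is the bias-corrected heterozygosity of the pooled read
counts: after masking sites outside the [min_coverage, max_coverage]
depth band and zeroing alleles below the min_count threshold,

    pi = (1 - sum_a (c_a / D)^2) * D / (D - 1)

with D the filtered depth. Window values are means of unmasked site
values; windows with insufficient covered fraction are masked. Absolute
values may differ from pool-size-corrected estimators by a small
factor, but contrasts between annotation features — the quantity of
interest — are preserved; ``site_pi_fn`` hooks in an alternative
estimator if exact matching is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval

ALLELES = ("A", "T", "C", "G")


@dataclass
class DiversityConfig:
    pool_size: int = 955  # haploid genomes in the pool
    min_count: int = 2
    min_coverage: int = 10
    max_coverage: int = 500
    min_covered_fraction: float = 0.75
    window_size: int = 2000

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage <= self.max_coverage:
            raise ValueError("need 0 < min_coverage <= max_coverage")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def site_pi(counts: Sequence[float], config: DiversityConfig) -> float:
    """Per-site diversity from {A,T,C,G} read counts; NaN marks a masked
    site (depth outside the allowed band, or <2 reads after filtering)."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative allele count")
    depth = c.sum()
    if depth < config.min_coverage or depth > config.max_coverage:
        return float("nan")
    c = np.where(c >= config.min_count, c, 0.0)
    d = c.sum()
    if d <= 1:
        return float("nan")
    return float((1.0 - np.sum((c / d) ** 2)) * d / (d - 1.0))


def window_pi(
    sites: pd.DataFrame,
    chrom_sizes: dict[str, int],
    config: DiversityConfig,
    site_pi_fn: Callable[[Sequence[float], DiversityConfig], float] = site_pi,
) -> pd.DataFrame:
    """Theta-pi in non-overlapping fixed windows.

    ``sites`` columns: chrom, pos, A, T, C, G. Positions absent from the
    table count as uncovered. Window value = mean of unmasked site
    values; covered_fraction = unmasked sites / window length; windows
    below min_covered_fraction are masked.
    """
    pi_vals = np.array(
        [site_pi_fn(row, config) for row in sites[list(ALLELES)].to_numpy()]
    )
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = sites[sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        vals = pi_vals[sites["chrom"].to_numpy() == chrom]
        ok = ~np.isnan(vals)
        for start in range(0, size, config.window_size):
            end = min(start + config.window_size, size)
            in_win = (pos >= start) & (pos < end) & ok
            n_cov = int(in_win.sum())
            covered = n_cov / (end - start)
            masked = covered < config.min_covered_fraction
            theta = float(vals[in_win].mean()) if n_cov else float("nan")
            rows.append(
                {
                    "chrom": chrom, "start": start, "end": end,
                    "theta_pi": float("nan") if masked else theta,
                    "covered_fraction": covered, "masked": masked,
                }
            )
    return pd.DataFrame(rows)


def feature_weighted_mean(
    windows: pd.DataFrame, intervals: Sequence[GenomicInterval]
) -> float:
    """Average window theta-pi weighted by bp overlap with the feature's
    intervals; masked windows contribute neither value nor weight."""
    total_w = 0.0
    acc = 0.0
    ivs_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        ivs_by_chrom.setdefault(iv.chrom, []).append(iv)
    for row in windows.itertuples():
        if row.masked or np.isnan(row.theta_pi):
            continue
        for iv in ivs_by_chrom.get(row.chrom, []):
            ov = min(row.end, iv.end) - max(row.start, iv.start)
            if ov > 0:
                acc += row.theta_pi * ov
                total_w += ov
    if total_w == 0:
        raise ValueError("no unmasked overlap between windows and intervals")
    return acc / total_w


def low_recombination_flag(
    sites: pd.DataFrame, rec_map: pd.DataFrame, percentile: float = 10.0
) -> np.ndarray:
    """Boolean flag per site: local recombination rate at or below the
    given percentile of the map's per-window rates.

    ``rec_map`` columns: chrom, start, end, rate (cM/Mb). The percentile
    is linear-interpolation (type 7); ties at the threshold flag as low.
    Every site must fall inside one map window.
    """
    threshold = float(np.percentile(rec_map["rate"].to_numpy(), percentile))
    flags = np.zeros(len(sites), dtype=bool)
    for i, row in enumerate(sites.itertuples()):
        hit = rec_map[
            (rec_map["chrom"] == row.chrom)
            & (rec_map["start"] <= row.pos)
            & (row.pos < rec_map["end"])
        ]
        if hit.empty:
            raise ValueError(
                f"site {row.chrom}:{row.pos} not covered by the recombination map"
            )
        flags[i] = float(hit["rate"].iloc[0]) <= threshold
    return flags


def read_sync(path: str | Path) -> pd.DataFrame:
    """Read a sync-style per-site allele-count table: chrom, pos (1-based
    in the file, converted to 0-based), ref, and colon-separated
    A:T:C:G:N:del counts per sample column (first sample column used)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 sync columns")
            counts = fields[3].split(":")
            if len(counts) < 4:
                raise ValueError(f"{path}:{lineno}: malformed count field")
            rows.append(
                {
                    "chrom": fields[0],
                    "pos": int(fields[1]) - 1,
                    "ref": fields[2],
                    "A": int(counts[0]), "T": int(counts[1]),
                    "C": int(counts[2]), "G": int(counts[3]),
                }
            )
    return pd.DataFrame(rows)


def read_rec_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "rate"],
        dtype={"chrom": str}, comment="#",
    )
    if df.empty:
        raise ValueError(f"{path}: empty recombination map")
    return df
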