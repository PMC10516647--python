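"""Stratified contingency statistics.

The workhorse is the generalized Cochran–Mantel–Haenszel (CMH) test for
I x J tables replicated across K strata (here: insertion classes x
annotation features x experimental replicates), implemented from the
multiple-hypergeometric score form without continuity correction.
Fisher's exact test, Benjamini–Hochberg adjustment, and Kruskal–Wallis
are delegated to scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str


def cmh_general(tables: np.ndarray | list) -> TestResult:
    """Generalized CMH test of conditional independence for a K-stratum
    collection of I x J count tables.

    Per stratum k the score vector holds the deviations of the (I-1)(J-1)
    leading cell counts from their margin-conditional expectations
    ``n_ij - r_i c_j / N``; its null covariance under the multiple
    hypergeometric distribution is

        Cov(n_ij, n_i'j') = r_i (d_ii' N - r_i') c_j (d_jj' N - c_j')
                            / (N^2 (N - 1)).

    Scores and covariances are summed over strata and combined into
    M^2 = U' V^{-1} U with df = (I-1)(J-1). No continuity correction.
    For a single 2x2 stratum this reduces to the classical
    (ad - bc)^2 (N-1) / (r1 r2 c1 c2) identity.
    """
    arr = np.asarray(tables, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError("expected a K x I x J array of counts")
    if np.any(arr < 0):
        raise ValueError("negative counts")
    k_, i_, j_ = arr.shape
    if i_ < 2 or j_ < 2:
        raise ValueError("tables must be at least 2x2")
    row_tot = arr.sum(axis=(0, 2))
    col_tot = arr.sum(axis=(0, 1))
    if np.any(row_tot == 0) or np.any(col_tot == 0):
        deg = "row" if np.any(row_tot == 0) else "column"
        idx = int(np.argmin(row_tot if deg == "row" else col_tot))
        raise ValueError(
            f"degenerate margin: {deg} {idx} is empty in every stratum"
        )
    d = (i_ - 1) * (j_ - 1)
    u = np.zeros(d)
    v = np.zeros((d, d))
    for tab in arr:
        n = tab.sum()
        if n <= 0:
            raise ValueError("stratum with zero total")
        if n == 1:
            continue  # no information; covariance undefined
        r = tab.sum(axis=1)
        c = tab.sum(axis=0)
        exp = np.outer(r, c) / n
        u += (tab - exp)[:-1, :-1].ravel()
        vr = (np.diag(r[:-1]) * n - np.outer(r[:-1], r[:-1]))
        vc = (np.diag(c[:-1]) * n - np.outer(c[:-1], c[:-1]))
        v += np.kron(vr, vc) / (n * n * (n - 1))
    try:
        stat = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        raise ValueError("singular pooled covariance; check table margins")
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, d))
    return TestResult(statistic=stat, df=d, p_value=p, method="cmh-general")


def fisher_exact_2x2(table: np.ndarray | list) -> TestResult:
    """Two-sided Fisher's exact test (minimum-likelihood summation rule)."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(arr < 0):
        raise ValueError("negative counts")
    res = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        method="fisher-exact-two-sided",
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis rank-sum test with mid-rank tie correction."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, df, 1.0, "kruskal-wallis")
    res = sps.kruskal(*groups)
    return TestResult(float(res.statistic), df, float(res.pvalue), "kruskal-wallis")


def read_stratified_tsv(
    path: str | Path,
) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Read a long-format stratified count table (columns: stratum, row,
    column, count) into a K x I x J array plus the label orders (sorted;
    missing cells are zero)."""
    df = pd.read_csv(path, sep="\t", dtype={"stratum": str, "row": str, "column": str})
    required = {"stratum", "row", "column", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    strata = sorted(df["stratum"].unique())
    rows = sorted(df["row"].unique())
    cols = sorted(df["column"].unique())
    arr = np.zeros((len(strata), len(rows), len(cols)))
    for rec in df.itertuples():
        arr[strata.index(rec.stratum), rows.index(rec.row), cols.index(rec.column)] += rec.count
    return arr, strata, rows, cols


def test_results_frame(results: list[TestResult]) -> pd.DataFrame:
    """TestResult rows as a writable table."""
    return pd.DataFrame(
        [
            {
                "method": r.method, "statistic": r.statistic,
                "df": r.df, "p_value": r.p_value,
            }
            for r in results
        ]
    )


def cmh_permutation_pvalue(
    tables: np.ndarray | list, n_shuffles: int = 10_000, seed: int = 0
) -> float:
    """Permutation-null p-value for the generalized CMH statistic.

    Within each stratum, row labels are shuffled across the stratum's
    units (keeping both margins' totals by reassignment of row labels to
    column observations), the statistic recomputed, and the upper-tail
    proportion returned. Serves as an independent check of the
    chi-square reference distribution.
    """
    rng = np.random.default_rng(seed)
    arr = np.asarray(tables, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    observed = cmh_general(arr).statistic
    k_, i_, j_ = arr.shape
    # expand each stratum into per-unit (row, col) labels
    strata = []
    for tab in arr:
        rows = np.repeat(
            np.arange(i_), tab.sum(axis=1).astype(int)
        )
        cols = np.concatenate(
            [np.repeat(np.arange(j_), tab[i].astype(int)) for i in range(i_)]
        )
        strata.append((rows, cols))
    hits = 0
    for _ in range(n_shuffles):
        perm_tabs = np.empty_like(arr)
        for k, (rows, cols) in enumerate(strata):
            shuffled = rng.permutation(rows)
            tab = np.zeros((i_, j_))
            np.add.at(tab, (shuffled, cols), 1.0)
            perm_tabs[k] = tab
        if cmh_general(perm_tabs).statistic >= observed - 1e-12:
            hits += 1
    return hits / n_shuffles
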