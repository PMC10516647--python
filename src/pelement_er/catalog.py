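"""Insertion-site catalogs: cross-sample matching and classification.

Detected insertion sites from the six Pool-Seq samples (three replicates
x generations 0 and 10) are matched into orthologous sites by
single-linkage clustering within a merge radius (500 bp by default, the
signature-merging distance of PopoolationTE2-style callers), then
classified per replicate as

* lost        — detected at generation 0 (in any replicate, joint mode)
                but not at generation 10 of the focal replicate;
* persistent  — detected at generation 0 and at generation 10 of the
                focal replicate;
* phase-2     — not detected at generation 0 in any replicate, detected
                at generation 10 of the focal replicate;
* absent      — otherwise.

The separate mode evaluates presence within one replicate only. The
replicate frequency spectrum matches persistent sites across replicates
at a wider radius (1 kb).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import AggregationInput
from .genome import AnnotationSet, RegionSet

LOST = "lost"
PERSISTENT = "persistent"
PHASE2 = "phase-2"
ABSENT = "absent"

REGION_CLASSES = ("!ORC & !shared", "ORC & !shared", "!ORC & shared", "ORC & shared")


@dataclass
class SampleCatalog:
    """Detected insertion sites of one sequenced sample."""

    replicate: int
    generation: int
    frame: pd.DataFrame  # columns: chrom, pos, frequency

    @property
    def key(self) -> str:
        return f"r{self.replicate}_g{self.generation}"

    def write_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["sample"] = self.key
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"chrom", "pos", "frequency", "sample"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        keys = df["sample"].unique()
        if len(keys) > 1:
            raise ValueError(f"{path}: multiple samples in one catalog file")
        if len(keys) == 0:
            raise ValueError(f"{path}: empty catalog (no sample id)")
        rep, gen = keys[0].lstrip("r").split("_g")
        return cls(
            replicate=int(rep), generation=int(gen),
            frame=df[["chrom", "pos", "frequency"]].reset_index(drop=True),
        )


def _cluster_positions(pos: np.ndarray, radius: int) -> np.ndarray:
    """Single-linkage cluster ids for sorted positions; neighbours within
    ``radius`` chain into one cluster (transitive merging)."""
    if pos.size == 0:
        return np.array([], dtype=np.int64)
    breaks = np.diff(pos) > radius
    return np.concatenate([[0], np.cumsum(breaks)])


def match_sites(catalogs: Sequence[SampleCatalog], radius: int = 500) -> pd.DataFrame:
    """Unified site table across samples.

    Returns one row per matched site with the cluster's minimum position
    as representative, boolean presence columns ``in_<sample>``, and
    frequency columns ``freq_<sample>`` (mean over a sample's merged
    records, NaN where absent).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    pieces = []
    for cat in catalogs:
        df = cat.frame[["chrom", "pos", "frequency"]].copy()
        df["sample"] = cat.key
        pieces.append(df)
    pooled = pd.concat(pieces, ignore_index=True)
    keys = [cat.key for cat in catalogs]
    if pooled.empty:
        cols = ["chrom", "pos"]
        cols += [f"in_{k}" for k in keys] + [f"freq_{k}" for k in keys]
        return pd.DataFrame(columns=cols)
    rows = []
    for chrom, grp in pooled.groupby("chrom", sort=True):
        grp = grp.sort_values(["pos", "sample"], kind="mergesort")
        cluster = _cluster_positions(grp["pos"].to_numpy(), radius)
        grp = grp.assign(_cluster=cluster)
        for _, sub in grp.groupby("_cluster"):
            row: dict = {"chrom": chrom, "pos": int(sub["pos"].min())}
            freqs = sub.groupby("sample")["frequency"].mean()
            for key in keys:
                row[f"in_{key}"] = key in freqs.index
                row[f"freq_{key}"] = float(freqs.get(key, np.nan))
            rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["chrom", "pos"], ignore_index=True)


def classify_joint(
    matrix: pd.DataFrame, replicates: Sequence[int] = (1, 2, 3)
) -> pd.DataFrame:
    """Per-replicate lost/persistent/phase-2/absent calls from a joint
    six-sample site matrix (generations 0 and 10 for every replicate)."""
    for rep in replicates:
        for gen in (0, 10):
            if f"in_r{rep}_g{gen}" not in matrix.columns:
                raise ValueError(f"missing sample r{rep}_g{gen} in site matrix")
    out = matrix[["chrom", "pos"]].copy()
    gen0_any = np.zeros(len(matrix), dtype=bool)
    for rep in replicates:
        gen0_any |= matrix[f"in_r{rep}_g0"].to_numpy()
    for rep in replicates:
        gen10 = matrix[f"in_r{rep}_g10"].to_numpy()
        cls = np.full(len(matrix), ABSENT, dtype=object)
        cls[gen0_any & gen10] = PERSISTENT
        cls[gen0_any & ~gen10] = LOST
        cls[~gen0_any & gen10] = PHASE2
        out[f"class_r{rep}"] = cls
        out[f"freq_gen0_r{rep}"] = matrix[f"freq_r{rep}_g0"].to_numpy()
    return out


def classify_separate(
    gen0: SampleCatalog, gen10: SampleCatalog, radius: int = 500
) -> pd.DataFrame:
    """Lost/persistent/phase-2 calls for one replicate evaluated in
    isolation (no cross-replicate evidence)."""
    if gen0.replicate != gen10.replicate:
        raise ValueError("generation-0 and generation-10 catalogs from different replicates")
    matrix = match_sites([gen0, gen10], radius=radius)
    rep = gen0.replicate
    present0 = matrix[f"in_r{rep}_g0"].to_numpy()
    present10 = matrix[f"in_r{rep}_g10"].to_numpy()
    cls = np.full(len(matrix), ABSENT, dtype=object)
    cls[present0 & present10] = PERSISTENT
    cls[present0 & ~present10] = LOST
    cls[~present0 & present10] = PHASE2
    out = matrix[["chrom", "pos"]].copy()
    out["class"] = cls
    out["freq_gen0"] = matrix[f"freq_r{rep}_g0"].to_numpy()
    out["replicate"] = rep
    return out


def annotate_sites(
    sites: pd.DataFrame,
    annotation: AnnotationSet | None = None,
    orc: RegionSet | None = None,
    shared: RegionSet | None = None,
) -> pd.DataFrame:
    """Attach feature label and ORC/shared membership to a site table
    (point-in-interval on the representative position)."""
    out = sites.copy()
    feature = np.full(len(out), "", dtype=object)
    in_orc = np.zeros(len(out), dtype=bool)
    in_shared = np.zeros(len(out), dtype=bool)
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        pos = out.loc[idx, "pos"].to_numpy()
        if annotation is not None:
            codes = annotation.annotate_points(str(chrom), pos)
            feature[out.index.get_indexer(idx)] = [
                annotation.labels[c] for c in codes
            ]
        if orc is not None:
            in_orc[out.index.get_indexer(idx)] = orc.contains(str(chrom), pos)
        if shared is not None:
            in_shared[out.index.get_indexer(idx)] = shared.contains(str(chrom), pos)
    if annotation is not None:
        out["feature"] = feature
    if orc is not None:
        out["in_orc"] = in_orc
    if shared is not None:
        out["in_shared"] = in_shared
    return out


def replicate_frequency_spectrum(
    persistent_by_rep: Mapping[int, Iterable[tuple[str, int]]],
    orc: RegionSet,
    shared: RegionSet,
    cross_radius: int = 1000,
) -> pd.DataFrame:
    """Replicate frequency spectrum of persistent insertions.

    Persistent sites are matched across replicates (single linkage at
    ``cross_radius``); each matched site falls into one ORC/shared
    region class and one bin counting in how many replicates it was
    detected. Proportions are per region class.
    """
    records = []
    for rep, sites in persistent_by_rep.items():
        for chrom, pos in sites:
            records.append((chrom, int(pos), rep))
    if not records:
        return pd.DataFrame(
            columns=["region_class", "n_replicates", "count", "proportion"]
        )
    df = pd.DataFrame(records, columns=["chrom", "pos", "replicate"])
    n_max = df["replicate"].nunique()
    counts: dict[tuple[str, int], int] = {
        (rc, k): 0 for rc in REGION_CLASSES for k in range(1, n_max + 1)
    }
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        cluster = _cluster_positions(grp["pos"].to_numpy(), cross_radius)
        grp = grp.assign(_cluster=cluster)
        for _, sub in grp.groupby("_cluster"):
            rep_pos = int(sub["pos"].min())
            n_reps = sub["replicate"].nunique()
            rc = _region_class(
                orc.contains_point(str(chrom), rep_pos),
                shared.contains_point(str(chrom), rep_pos),
            )
            counts[(rc, n_reps)] += 1
    rows = []
    for rc in REGION_CLASSES:
        total = sum(counts[(rc, k)] for k in range(1, n_max + 1))
        for k in range(1, n_max + 1):
            rows.append(
                {
                    "region_class": rc,
                    "n_replicates": k,
                    "count": counts[(rc, k)],
                    "proportion": counts[(rc, k)] / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _region_class(in_orc: bool, in_shared: bool) -> str:
    if in_orc and in_shared:
        return "ORC & shared"
    if in_orc:
        return "ORC & !shared"
    if in_shared:
        return "!ORC & shared"
    return "!ORC & !shared"


def build_aggregation_input(
    classified: pd.DataFrame,
    replicate: int,
    focal: RegionSet,
    hotspot_union: RegionSet,
) -> AggregationInput:
    """Counts for the aggregation estimator from a joint classification
    table for one replicate and one focal region set.

    The rediscovery rate's reference counts (``*_out``) exclude the full
    hotspot union (ORC plus shared), while A1's denominator is all
    phase-1 sites of the replicate.
    """
    cls = classified[f"class_r{replicate}"].to_numpy()
    in_focal = np.zeros(len(classified), dtype=bool)
    in_union = np.zeros(len(classified), dtype=bool)
    for chrom, idx in classified.groupby("chrom", sort=False).groups.items():
        pos = classified.loc[idx, "pos"].to_numpy()
        loc = classified.index.get_indexer(idx)
        in_focal[loc] = focal.contains(str(chrom), pos)
        in_union[loc] = hotspot_union.contains(str(chrom), pos)
    is_phase1 = (cls == LOST) | (cls == PERSISTENT)
    is_persistent = cls == PERSISTENT
    is_phase2 = cls == PHASE2
    return AggregationInput(
        phase1_in=int((is_phase1 & in_focal).sum()),
        phase1_out=int((is_phase1 & ~in_union).sum()),
        persistent_in=int((is_persistent & in_focal).sum()),
        persistent_out=int((is_persistent & ~in_union).sum()),
        phase2_new_in=int((is_phase2 & in_focal).sum()),
        phase2_new_total=int(is_phase2.sum()),
        phase1_total=int(is_phase1.sum()),
        replicate=replicate,
    )
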