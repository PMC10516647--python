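"""Genome interval algebra, annotation precedence, and BED I/O.

All coordinates are 0-based, half-open (BED convention). TE insertion
sites are treated as length-0 point anchors at the reported position.
Chromosome names are matched by exact string equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Precedence used when annotation tracks overlap: the most detailed /
#: functionally most important feature wins. Points covered by no track
#: are ``intergenic``.
DEFAULT_PRECEDENCE: tuple[str, ...] = (
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "exon",
    "intron",
)

INTERGENIC = "intergenic"

#: Main chromosome arms of the default D. simulans genome model.
MAIN_CHROMOSOMES: tuple[str, ...] = ("X", "2L", "2R", "3L", "3R", "4")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (end <= start)"
            )

    def __len__(self) -> int:
        return self.end - self.start


def normalize_intervals(
    intervals: Iterable[GenomicInterval],
    min_length: int = 1,
    merge_bookended: bool = True,
) -> list[GenomicInterval]:
    """Sort, merge overlapping (and by default bookended) intervals, and
    drop merged intervals shorter than ``min_length``.

    Idempotent: applying it twice yields the same result.
    """
    ivs = sorted(intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom:
            prev = out[-1]
            touches = iv.start <= prev.end if merge_bookended else iv.start < prev.end
            if touches:
                if iv.end > prev.end:
                    out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
                continue
        out.append(iv)
    return [iv for iv in out if len(iv) >= min_length]


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def _check_bounds(intervals: Sequence[GenomicInterval], chrom_sizes: Mapping[str, int]) -> None:
    for iv in intervals:
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} beyond chromosome "
                f"end ({chrom_sizes[iv.chrom]})"
            )


def complement(
    intervals: Iterable[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> list[GenomicInterval]:
    """Bases of each chromosome in ``chrom_sizes`` not covered by ``intervals``."""
    ivs = normalize_intervals(intervals)
    _check_bounds(ivs, chrom_sizes)
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_sizes}
    for iv in ivs:
        by_chrom[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for chrom, size in chrom_sizes.items():
        cursor = 0
        for iv in by_chrom[chrom]:
            if iv.start > cursor:
                out.append(GenomicInterval(chrom, cursor, iv.start))
            cursor = iv.end
        if cursor < size:
            out.append(GenomicInterval(chrom, cursor, size))
    return out


def subtract(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of normalized ``a`` not covered by normalized ``b``."""
    b_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in a:
        cuts = b_by_chrom.get(iv.chrom, [])
        cursor = iv.start
        for cut in cuts:
            if cut.end <= cursor or cut.start >= iv.end:
                continue
            if cut.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, cut.start))
            cursor = max(cursor, cut.end)
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return out


def intersect_length(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Total overlap in bp between two normalized interval lists."""
    b_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    bp = 0
    for iv in a:
        for cov in b_by_chrom.get(iv.chrom, []):
            lo = max(iv.start, cov.start)
            hi = min(iv.end, cov.end)
            if hi > lo:
                bp += hi - lo
    return bp


class _PointIndex:
    """Vectorised point-in-interval lookup over a normalized interval list."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            self._starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)

    def which(self, chrom: str, pos: np.ndarray | int) -> np.ndarray:
        """Index of the containing interval per position, -1 if none."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if chrom not in self._starts:
            return np.full(pos.shape, -1, dtype=np.int64)
        idx = np.searchsorted(self._starts[chrom], pos, side="right") - 1
        ok = (idx >= 0) & (pos < self._ends[chrom][np.clip(idx, 0, None)])
        return np.where(ok, idx, -1)

    def contains(self, chrom: str, pos: np.ndarray | int) -> np.ndarray:
        return self.which(chrom, pos) >= 0


@dataclass
class FeatureTable:
    """Total bp per mutually exclusive feature; sums to the genome length."""

    f_l: dict[str, int]
    g_l: int

    def __post_init__(self) -> None:
        if sum(self.f_l.values()) != self.g_l:
            raise ValueError("feature lengths do not partition the genome")


class AnnotationSet:
    """Per-feature interval tracks over a genome, with precedence resolution.

    Tracks may overlap on input; every point query and length computation
    resolves overlaps by the configured precedence order (first label wins),
    and points covered by no track are ``intergenic``.
    """

    def __init__(
        self,
        tracks: Mapping[str, Iterable[GenomicInterval]],
        chrom_sizes: Mapping[str, int],
        precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    ):
        self.chrom_sizes = dict(chrom_sizes)
        self.tracks = {
            label: normalize_intervals(ivs) for label, ivs in tracks.items()
        }
        for label, ivs in self.tracks.items():
            _check_bounds(ivs, self.chrom_sizes)
        # effective order: configured precedence first, then any extra tracks
        self.precedence = [f for f in precedence if f in self.tracks]
        self.precedence += [f for f in self.tracks if f not in self.precedence]
        self._exclusive: dict[str, list[GenomicInterval]] | None = None
        self._maps: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def labels(self) -> list[str]:
        return self.precedence + [INTERGENIC]

    def exclusive_tracks(self) -> dict[str, list[GenomicInterval]]:
        """Precedence-resolved, mutually exclusive tracks tiling the genome
        together with the intergenic complement."""
        if self._exclusive is None:
            covered: list[GenomicInterval] = []
            exclusive: dict[str, list[GenomicInterval]] = {}
            for label in self.precedence:
                exclusive[label] = subtract(self.tracks[label], covered)
                covered = normalize_intervals(covered + self.tracks[label])
            exclusive[INTERGENIC] = complement(covered, self.chrom_sizes)
            self._exclusive = exclusive
        return self._exclusive

    def _feature_maps(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per chromosome: (breakpoints, label codes) for vectorised lookup."""
        if self._maps is None:
            codes = {label: i for i, label in enumerate(self.labels)}
            pieces: dict[str, list[tuple[int, int, int]]] = {
                c: [] for c in self.chrom_sizes
            }
            for label, ivs in self.exclusive_tracks().items():
                for iv in ivs:
                    pieces[iv.chrom].append((iv.start, iv.end, codes[label]))
            maps = {}
            for chrom, segs in pieces.items():
                segs.sort()
                starts = np.array([s for s, _, _ in segs], dtype=np.int64)
                lab = np.array([c for _, _, c in segs], dtype=np.int64)
                maps[chrom] = (starts, lab)
            self._maps = maps
        return self._maps

    def annotate_points(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Feature code (index into ``labels``) per position on one chromosome."""
        if chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        pos = np.asarray(pos, dtype=np.int64)
        if pos.size and (pos.min() < 0 or pos.max() >= self.chrom_sizes[chrom]):
            raise ValueError(f"position outside chromosome {chrom!r} bounds")
        starts, lab = self._feature_maps()[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        return lab[idx]

    def annotate_point(self, chrom: str, pos: int) -> str:
        """Single feature label for one genomic point."""
        code = self.annotate_points(chrom, np.array([pos]))[0]
        return self.labels[code]

    def feature_lengths(self) -> FeatureTable:
        f_l = {
            label: total_length(ivs) for label, ivs in self.exclusive_tracks().items()
        }
        return FeatureTable(f_l=f_l, g_l=sum(self.chrom_sizes.values()))


@dataclass
class RegionSet:
    """Named set of normalized regions (e.g. ORC binding sites, shared sites)."""

    name: str
    intervals: list[GenomicInterval]
    min_length: int = 1

    def __post_init__(self) -> None:
        self.intervals = normalize_intervals(self.intervals, min_length=self.min_length)
        self._index = _PointIndex(self.intervals)

    @property
    def total_length(self) -> int:
        return total_length(self.intervals)

    def contains(self, chrom: str, pos: np.ndarray | int) -> np.ndarray:
        return self._index.contains(chrom, pos)

    def contains_point(self, chrom: str, pos: int) -> bool:
        return bool(self._index.contains(chrom, np.array([pos]))[0])

    def member_index(self, chrom: str, pos: np.ndarray | int) -> np.ndarray:
        """Index of the member interval containing each point, -1 outside.

        Indices refer to a per-chromosome ordering; combine with ``chrom``
        to identify the member globally.
        """
        return self._index.which(chrom, pos)


def coverage_fraction(
    query: RegionSet | Sequence[GenomicInterval],
    cover: Sequence[GenomicInterval],
) -> float:
    """Fraction of query bases covered by ``cover`` (both normalized)."""
    q = query.intervals if isinstance(query, RegionSet) else list(query)
    qlen = total_length(q)
    if qlen == 0:
        raise ValueError("empty query region set; coverage fraction undefined")
    return intersect_length(q, normalize_intervals(cover)) / qlen


# ---------------------------------------------------------------------------
# I/O: BED (3+ columns) and two-column chromosome-sizes tables. Strand and
# any columns past the name field are ignored.


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
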