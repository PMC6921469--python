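"""Strand-free genomic interval algebra.

All coordinates are 0-based half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` bases.  Peaks, reference sites,
windows and anchors throughout the package are represented this way.
Strand is never used in interval arithmetic; where inputs carry strand
(TSS annotations) it is retained only as metadata.

The two containers are :class:`GenomicInterval` (a single region) and
:class:`IntervalSet` (per-chromosome sorted arrays plus an optional genome
size map).  The operations — :func:`normalize`, :func:`merge_within`,
:func:`intersect_all`, :func:`subtract`, :func:`overlaps_by`,
:func:`nearest_distance` — implement exactly the base-level semantics the
downstream site-assembly steps rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "MalformedIntervalError",
    "GenomeMismatchError",
    "UnknownChromosomeError",
    "normalize",
    "merge_within",
    "intersect_all",
    "subtract",
    "overlaps_by",
    "overlap_any",
    "nearest_distance",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
]


class MalformedIntervalError(ValueError):
    """An interval violates ``0 <= start < end``."""


class GenomeMismatchError(ValueError):
    """Two interval sets carry incompatible genome size maps."""


class UnknownChromosomeError(ValueError):
    """An interval names a chromosome absent from the genome map."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A single 0-based half-open genomic region."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)
    score: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise MalformedIntervalError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """An ordered collection of intervals, stored per chromosome.

    Internally each chromosome maps to an ``(n, 2)`` int64 array of
    ``[start, end)`` pairs sorted by ``(start, end)``.  Construction
    validates bounds; call :func:`normalize` to obtain the canonical
    pairwise-disjoint form most operations require.

    Parameters
    ----------
    intervals
        Any iterable of :class:`GenomicInterval`, or a mapping
        ``chrom -> (n, 2) array``.
    genome
        Optional ``chrom -> length`` map.  When given, intervals must lie
        within their chromosome and unknown chromosomes raise.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] | Mapping[str, np.ndarray] = (),
        genome: Optional[Mapping[str, int]] = None,
    ) -> None:
        self.genome: Optional[Dict[str, int]] = dict(genome) if genome is not None else None
        data: Dict[str, np.ndarray] = {}
        if isinstance(intervals, Mapping):
            for chrom, arr in intervals.items():
                a = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                data[chrom] = a
        else:
            buckets: Dict[str, List[tuple]] = {}
            for iv in intervals:
                buckets.setdefault(iv.chrom, []).append((iv.start, iv.end))
            for chrom, rows in buckets.items():
                data[chrom] = np.asarray(rows, dtype=np.int64)
        for chrom, a in data.items():
            if a.size and np.any(a[:, 0] >= a[:, 1]):
                bad = a[a[:, 0] >= a[:, 1]][0]
                raise MalformedIntervalError(
                    f"malformed interval {chrom}:{bad[0]}-{bad[1]} (start >= end)"
                )
            if a.size and np.any(a[:, 0] < 0):
                raise MalformedIntervalError(f"negative coordinate on {chrom}")
            if self.genome is not None:
                if chrom not in self.genome:
                    raise UnknownChromosomeError(f"unknown chromosome {chrom!r}")
                if a.size and int(a[:, 1].max()) > self.genome[chrom]:
                    raise MalformedIntervalError(
                        f"interval on {chrom} exceeds chromosome length {self.genome[chrom]}"
                    )
            order = np.lexsort((a[:, 1], a[:, 0]))
            data[chrom] = a[order]
        # drop empty chromosomes for a canonical representation
        self._data: Dict[str, np.ndarray] = {
            c: a for c, a in sorted(data.items()) if a.size
        }

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return sum(a.shape[0] for a in self._data.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, a in self._data.items():
            for s, e in a:
                yield GenomicInterval(chrom, int(s), int(e))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(np.array_equal(self._data[c], other._data[c]) for c in self._data)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self._data)} chromosomes)"

    @property
    def chroms(self) -> List[str]:
        return list(self._data)

    def arrays(self, chrom: str) -> np.ndarray:
        """``(n, 2)`` start/end array for one chromosome (empty if absent)."""
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def covered_bases(self) -> int:
        """Total bases covered, counting overlapping bases once."""
        norm = normalize(self)
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in norm._data.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, int(s), int(e)) for c, a in self._data.items() for s, e in a]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def _same_genome(self, other: "IntervalSet") -> None:
        if self.genome is not None and other.genome is not None and self.genome != other.genome:
            raise GenomeMismatchError("interval sets carry different genome size maps")

    def _merged_genome(self, other: "IntervalSet") -> Optional[Dict[str, int]]:
        return self.genome if self.genome is not None else other.genome


def _merge_arr(a: np.ndarray, gap: int) -> np.ndarray:
    """Fuse sorted intervals whose inter-interval gap is <= ``gap``."""
    if a.shape[0] <= 1:
        return a.copy()
    starts, run_end = a[:, 0], np.maximum.accumulate(a[:, 1])
    # new block wherever this start exceeds the running max end by more than gap
    new_block = np.empty(a.shape[0], dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] - run_end[:-1] > gap
    block = np.cumsum(new_block) - 1
    n = int(block[-1]) + 1
    out = np.empty((n, 2), dtype=np.int64)
    first = np.flatnonzero(new_block)
    out[:, 0] = starts[first]
    out[:, 1] = 0
    np.maximum.at(out[:, 1], block, a[:, 1])
    return out


def normalize(s: IntervalSet) -> IntervalSet:
    """Sort and union overlapping or exactly adjacent intervals.

    Idempotent; preserves the covered-base set.
    """
    return merge_within(s, 0)


def merge_within(s: IntervalSet, gap: int) -> IntervalSet:
    """Fuse consecutive intervals separated by at most ``gap`` bases.

    ``gap=0`` unions overlapping/adjacent intervals (i.e. :func:`normalize`);
    ``gap=100`` reproduces the reference-site rule that sites within 100 bp
    of each other are merged.  Applied transitively along each chromosome.
    """
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    out = {c: _merge_arr(a, gap) for c, a in s._data.items()}
    return IntervalSet(out, genome=s.genome)


def _intersect_two(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Base-level intersection of two sorted disjoint interval arrays."""
    out: List[List[int]] = []
    i = j = 0
    na, nb = a.shape[0], b.shape[0]
    while i < na and j < nb:
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append([lo, hi])
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def intersect_all(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Maximal intervals covered by *every* input set (N-way intersection)."""
    if len(sets) == 0:
        raise ValueError("intersect_all requires at least one interval set")
    acc = normalize(sets[0])
    for s in sets[1:]:
        acc._same_genome(s)
        sn = normalize(s)
        common = set(acc._data) & set(sn._data)
        acc = IntervalSet(
            {c: _intersect_two(acc._data[c], sn._data[c]) for c in common},
            genome=acc._merged_genome(sn),
        )
    return acc


def _complement(a: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Gaps of a sorted disjoint array within [lo, hi)."""
    starts = np.concatenate(([lo], a[:, 1]))
    ends = np.concatenate((a[:, 0], [hi]))
    keep = starts < ends
    return np.stack([starts[keep], ends[keep]], axis=1).astype(np.int64)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases of ``a`` not covered by ``b`` (base-wise set difference)."""
    a._same_genome(b)
    an, bn = normalize(a), normalize(b)
    out: Dict[str, np.ndarray] = {}
    for chrom, arr in an._data.items():
        barr = bn._data.get(chrom)
        if barr is None or barr.size == 0:
            out[chrom] = arr
            continue
        hi = int(max(arr[:, 1].max(), barr[:, 1].max())) + 1
        out[chrom] = _intersect_two(arr, _complement(barr, 0, hi))
    return IntervalSet(out, genome=a._merged_genome(b))


def overlaps_by(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff the two intervals share at least ``min_bp`` bases."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


def overlap_any(site: GenomicInterval, s: IntervalSet, min_bp: int = 1) -> bool:
    """True iff ``site`` shares >= ``min_bp`` bases with any interval of ``s``."""
    a = s.arrays(site.chrom)
    if a.size == 0:
        return False
    ov = np.minimum(a[:, 1], site.end) - np.maximum(a[:, 0], site.start)
    return bool((ov >= min_bp).any())


def nearest_distance(
    site: GenomicInterval, points: Mapping[str, np.ndarray]
) -> Optional[int]:
    """Distance in bp from ``site`` to the nearest same-chromosome point.

    A point inside ``[start, end)`` is at distance 0; otherwise the distance
    is to the closest covered base, ``min(|p - start|, |p - (end-1)|)``.
    Returns ``None`` when no point lies on the site's chromosome.  An empty
    ``points`` mapping overall is an error.
    """
    if not any(len(np.atleast_1d(v)) for v in points.values()):
        raise ValueError("no points supplied on any chromosome")
    pos = np.atleast_1d(np.asarray(points.get(site.chrom, []), dtype=np.int64))
    if pos.size == 0:
        return None
    inside = (pos >= site.start) & (pos < site.end)
    if inside.any():
        return 0
    d = np.minimum(np.abs(pos - site.start), np.abs(pos - (site.end - 1)))
    return int(d.min())


# -- BED / chrom-sizes I/O ---------------------------------------------------

def read_chrom_sizes(path: str) -> Dict[str, int]:
    """Read a two-column (name, length) chromosome sizes TSV."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["chrom", "length"], dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def read_bed(
    path: str,
    genome: Optional[Mapping[str, int]] = None,
    alias: Optional[Mapping[str, str]] = None,
) -> IntervalSet:
    """Read BED3/BED6 into an :class:`IntervalSet`.

    ``alias`` remaps chromosome names at load time (e.g. ``{"1": "chr1"}``).
    Name/score columns beyond BED3 are ignored: the set is pure geometry.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise MalformedIntervalError(f"{path}: BED needs >= 3 columns")
    chroms = df[0].astype(str)
    if alias:
        chroms = chroms.map(lambda c: alias.get(c, c))
    data: Dict[str, List[List[int]]] = {}
    for c, s, e in zip(chroms, df[1].astype(int), df[2].astype(int)):
        data.setdefault(c, []).append([s, e])
    return IntervalSet({c: np.asarray(v) for c, v in data.items()}, genome=genome)


def write_bed(s: IntervalSet | Iterable[GenomicInterval], path: str) -> None:
    """Write intervals as BED (BED6 when name/score present, else BED3)."""
    with open(path, "w") as fh:
        for iv in s:
            if iv.name is not None or iv.score is not None:
                score = 0 if iv.score is None else iv.score
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t.\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
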