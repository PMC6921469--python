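"""Assembly of reference active-promoter and enhancer site sets.

The workflow mirrors how multi-donor histone ChIP-seq peak calls are turned
into a single reference catalogue for a lineage:

1. per sample, classify peaks into *active promoters* (H3K4me3 peaks
   overlapping H3K27ac by >= 1 bp) and *enhancers* (H3K27ac peaks with no
   H3K4me3 overlap);
2. per cell type, keep only the sites common to all donor samples
   (base-level intersection) to suppress individual variation, then merge
   sites within 100 bp of each other;
3. merge the per-type references into one catalogue with a site-by-type
   membership matrix; sex chromosomes are excluded throughout;
4. optionally remove any site that overlaps a same-mark peak in an
   exclusion panel of unrelated cell types (lineage-specificity filter),
   and flag enhancer sites more than 10 kb from the nearest TSS as distal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalSet,
    intersect_all,
    merge_within,
    normalize,
)

logger = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3K27ac")
CLASSES = ("promoter", "enhancer")
DEFAULT_SEX_CHROMOSOMES = frozenset({"chrX", "chrY"})
DEFAULT_MERGE_GAP = 100
DEFAULT_DISTAL_THRESHOLD = 10_000


@dataclass
class SamplePeaks:
    """Peak calls for one mark in one sample."""

    sample_id: str
    cell_type: str
    mark: str
    peaks: IntervalSet

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unsupported mark {self.mark!r}; expected one of {MARKS}")
        self.peaks = normalize(self.peaks)


@dataclass
class ClassifiedSites:
    """Active promoter and enhancer sites of one sample (disjoint by construction)."""

    sample_id: str
    cell_type: str
    promoters: IntervalSet
    enhancers: IntervalSet


def _overlap_mask(a: np.ndarray, b: np.ndarray, min_bp: int = 1) -> np.ndarray:
    """For each interval row of ``a``, does it share >= min_bp bases with
    sorted-disjoint ``b``?"""
    if a.size == 0:
        return np.zeros(0, dtype=bool)
    if b.size == 0:
        return np.zeros(a.shape[0], dtype=bool)
    # candidate b intervals are those starting before a.end
    hi = np.searchsorted(b[:, 0], a[:, 1] - min_bp, side="right")
    # b disjoint & sorted => ends are sorted too; check best candidate block
    mask = np.zeros(a.shape[0], dtype=bool)
    for i, h in enumerate(hi):
        if h == 0:
            continue
        ov = np.minimum(b[:h, 1], a[i, 1]) - np.maximum(b[:h, 0], a[i, 0])
        mask[i] = ov.max() >= min_bp
    return mask


def _select_overlapping(query: IntervalSet, against: IntervalSet, keep_overlapping: bool,
                        min_bp: int = 1) -> IntervalSet:
    """Whole intervals of ``query`` that do (or do not) overlap ``against``."""
    out: Dict[str, np.ndarray] = {}
    for chrom in query.chroms:
        a = query.arrays(chrom)
        m = _overlap_mask(a, against.arrays(chrom), min_bp)
        sel = a[m] if keep_overlapping else a[~m]
        if sel.size:
            out[chrom] = sel
    return IntervalSet(out, genome=query.genome)


def classify_sample_sites(k4: SamplePeaks, k27: SamplePeaks) -> ClassifiedSites:
    """Split one sample's peaks into active promoters and enhancers.

    Promoters are the H3K4me3 intervals with >= 1 bp H3K27ac overlap (the
    reported extent is the H3K4me3 interval).  Enhancers are the H3K27ac
    intervals with no H3K4me3 overlap.  H3K4me3-only peaks are dropped as
    not active; H3K27ac peaks overlapping H3K4me3 are consumed by the
    promoter call and contribute to neither output.
    """
    if k4.mark != "H3K4me3" or k27.mark != "H3K27ac":
        raise ValueError(f"expected marks (H3K4me3, H3K27ac), got ({k4.mark}, {k27.mark})")
    if k4.sample_id != k27.sample_id:
        raise ValueError(f"sample_id mismatch: {k4.sample_id!r} vs {k27.sample_id!r}")
    promoters = _select_overlapping(k4.peaks, k27.peaks, keep_overlapping=True)
    enhancers = _select_overlapping(k27.peaks, k4.peaks, keep_overlapping=False)
    return ClassifiedSites(k4.sample_id, k4.cell_type, promoters, enhancers)


def _drop_chromosomes(s: IntervalSet, names: Iterable[str]) -> IntervalSet:
    names = set(names)
    return IntervalSet({c: s.arrays(c) for c in s.chroms if c not in names},
                       genome=s.genome)


def build_celltype_reference(
    samples: Sequence[ClassifiedSites],
    merge_gap: int = DEFAULT_MERGE_GAP,
    sex_chromosomes: Iterable[str] = DEFAULT_SEX_CHROMOSOMES,
) -> Dict[str, IntervalSet]:
    """Sites common to *all* donor samples of one cell type, per class.

    Base-level N-way intersection, then merging of sites within
    ``merge_gap`` bp, then removal of sex chromosomes.
    """
    if not samples:
        raise ValueError("need at least one classified sample")
    out: Dict[str, IntervalSet] = {}
    for klass, attr in (("promoter", "promoters"), ("enhancer", "enhancers")):
        common = intersect_all([getattr(s, attr) for s in samples])
        merged = merge_within(common, merge_gap)
        out[klass] = _drop_chromosomes(merged, sex_chromosomes)
    return out


@dataclass
class ReferenceSiteSet:
    """Merged reference catalogue with a site-by-cell-type membership matrix.

    ``sites`` has columns (site_id, chrom, start, end, klass); ``membership``
    is a boolean frame indexed by site_id with one column per cell type.
    """

    sites: pd.DataFrame
    membership: pd.DataFrame
    cell_types: List[str]
    genome: Optional[Dict[str, int]] = None

    def class_sites(self, klass: str) -> pd.DataFrame:
        return self.sites[self.sites["klass"] == klass]

    def class_set(self, klass: str) -> IntervalSet:
        df = self.class_sites(klass)
        data: Dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            data[str(chrom)] = grp[["start", "end"]].to_numpy(dtype=np.int64)
        return IntervalSet(data, genome=self.genome)

    def mean_width(self, klass: str) -> float:
        df = self.class_sites(klass)
        return float((df["end"] - df["start"]).mean()) if len(df) else float("nan")

    def subset(self, site_ids: Sequence[str]) -> "ReferenceSiteSet":
        ids = list(site_ids)
        return ReferenceSiteSet(
            sites=self.sites[self.sites["site_id"].isin(ids)].reset_index(drop=True),
            membership=self.membership.loc[self.membership.index.isin(ids)],
            cell_types=list(self.cell_types),
            genome=self.genome,
        )

    def __len__(self) -> int:
        return len(self.sites)


def build_merged_reference(
    per_type: Mapping[str, Mapping[str, IntervalSet]],
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> ReferenceSiteSet:
    """Union the per-cell-type references into one catalogue.

    Per class the per-type sets are unioned, normalized and gap-merged; each
    merged site is then marked as belonging to every cell type whose own set
    shares >= 1 bp with it (so every site has at least one member).
    Cross-class overlaps between sites contributed by different types are
    permitted: the two classes are kept as independent catalogues.
    """
    if not per_type:
        raise ValueError("need at least one cell type")
    cell_types = list(per_type)
    genomes = [s.genome for by_class in per_type.values() for s in by_class.values()
               if s.genome is not None]
    for g in genomes[1:]:
        if g != genomes[0]:
            raise ValueError("inconsistent genomes across cell-type references")
    genome = genomes[0] if genomes else None

    rows: List[Tuple[str, str, int, int, str]] = []
    member_rows: List[np.ndarray] = []
    for klass in CLASSES:
        pooled: Dict[str, List[np.ndarray]] = {}
        for ct in cell_types:
            s = per_type[ct].get(klass)
            if s is None:
                continue
            for chrom in s.chroms:
                pooled.setdefault(chrom, []).append(s.arrays(chrom))
        union = IntervalSet(
            {c: np.concatenate(v, axis=0) for c, v in pooled.items()}, genome=genome
        )
        merged = merge_within(normalize(union), merge_gap)
        prefix = "prom" if klass == "promoter" else "enh"
        counter = 0
        for chrom in merged.chroms:
            arr = merged.arrays(chrom)
            mem = np.zeros((arr.shape[0], len(cell_types)), dtype=bool)
            for j, ct in enumerate(cell_types):
                s = per_type[ct].get(klass)
                if s is not None:
                    mem[:, j] = _overlap_mask(arr, s.arrays(chrom))
            for i, (st, en) in enumerate(arr):
                counter += 1
                rows.append((f"{prefix}_{counter:05d}", chrom, int(st), int(en), klass))
                member_rows.append(mem[i])

    sites = pd.DataFrame(rows, columns=["site_id", "chrom", "start", "end", "klass"])
    membership = pd.DataFrame(
        np.vstack(member_rows) if member_rows else np.zeros((0, len(cell_types)), bool),
        index=sites["site_id"], columns=cell_types,
    )
    return ReferenceSiteSet(sites, membership, cell_types, genome)


def shared_ratio(ref: ReferenceSiteSet) -> pd.DataFrame:
    """Fraction of sites per class shared by exactly n cell types, n = 1..T."""
    T = len(ref.cell_types)
    counts = ref.membership.sum(axis=1)
    out = {}
    for klass in CLASSES:
        ids = ref.class_sites(klass)["site_id"]
        n_by_site = counts.loc[ids]
        hist = np.zeros(T, dtype=float)
        if len(n_by_site):
            vc = n_by_site.value_counts()
            for n, c in vc.items():
                if int(n) >= 1:  # membership invariant: every site has >= 1 member
                    hist[int(n) - 1] = c / len(n_by_site)
        out[klass] = hist
    return pd.DataFrame(out, index=pd.RangeIndex(1, T + 1, name="n_types"))


@dataclass
class SpecificSiteSet:
    """Reference sites retained after the exclusion-panel specificity filter."""

    sites: pd.DataFrame
    membership: pd.DataFrame
    cell_types: List[str]
    provenance: List[str] = field(default_factory=list)
    genome: Optional[Dict[str, int]] = None

    def class_sites(self, klass: str) -> pd.DataFrame:
        return self.sites[self.sites["klass"] == klass]

    def __len__(self) -> int:
        return len(self.sites)


_MARK_FOR_CLASS = {"promoter": "H3K4me3", "enhancer": "H3K27ac"}


def filter_specific_sites(
    ref: ReferenceSiteSet,
    panel: Sequence[SamplePeaks],
    exceptions: Sequence[str] = (),
) -> SpecificSiteSet:
    """Keep only reference sites private to the lineage.

    A site is removed *in whole* when it overlaps (>= 1 bp) a same-mark
    panel peak — promoter sites against panel H3K4me3 peaks, enhancer sites
    against panel H3K27ac peaks — from any panel member whose id is not in
    ``exceptions``.  Additional exclusion sets (e.g. an in-house fibroblast
    H3K27ac set) are passed as ordinary panel members.
    """
    exc = set(exceptions)
    active = [p for p in panel if p.sample_id not in exc]
    if not panel:
        warnings.warn("empty exclusion panel: specificity filter is a no-op")
    keep_ids: List[str] = []
    for klass in CLASSES:
        mark = _MARK_FOR_CLASS[klass]
        exclusion_sets = [p.peaks for p in active if p.mark == mark]
        df = ref.class_sites(klass)
        if df.empty:
            continue
        removed = np.zeros(len(df), dtype=bool)
        for s in exclusion_sets:
            for chrom, grp in df.groupby("chrom", sort=False):
                arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
                idx = df.index.get_indexer(grp.index)
                removed[idx] |= _overlap_mask(arr, s.arrays(str(chrom)))
        keep_ids.extend(df.loc[~removed, "site_id"])
    keep = ref.sites["site_id"].isin(keep_ids)
    return SpecificSiteSet(
        sites=ref.sites[keep].reset_index(drop=True),
        membership=ref.membership.loc[ref.sites.loc[keep, "site_id"]],
        cell_types=list(ref.cell_types),
        provenance=sorted({p.sample_id for p in active}),
        genome=ref.genome,
    )


# -- TSS annotation ----------------------------------------------------------

TSS_COLUMNS = ["gene_id", "chrom", "pos", "strand", "biotype"]


def read_tss(path: str) -> pd.DataFrame:
    """Read a TSS annotation TSV with columns gene_id, chrom, pos, strand, biotype."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(TSS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TSS annotation missing columns: {sorted(missing)}")
    return df


def tss_positions(tss: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Sorted TSS positions per chromosome."""
    return {str(c): np.sort(g["pos"].to_numpy(dtype=np.int64))
            for c, g in tss.groupby("chrom")}


def _nearest_vec(arr: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Nearest-point distance for each interval row; edge-based convention."""
    starts, ends = arr[:, 0], arr[:, 1]
    idx = np.searchsorted(pos, starts)
    d = np.full(arr.shape[0], np.inf)
    left = idx - 1
    ok = left >= 0
    d[ok] = np.minimum(d[ok], np.abs(pos[left[ok]] - starts[ok]))
    right = np.minimum(idx, pos.size - 1)
    d = np.minimum(d, np.abs(pos[right] - starts))
    # distance to end-1 edge and containment
    idx2 = np.searchsorted(pos, ends - 1)
    left2 = idx2 - 1
    ok = left2 >= 0
    d[ok] = np.minimum(d[ok], np.abs(pos[left2[ok]] - (ends[ok] - 1)))
    right2 = np.minimum(idx2, pos.size - 1)
    d = np.minimum(d, np.abs(pos[right2] - (ends - 1)))
    # any point inside [start, end) => 0
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends - 1, side="right")
    d[hi > lo] = 0
    return d


def annotate_distal(
    sites: pd.DataFrame,
    tss: pd.DataFrame,
    threshold: int = DEFAULT_DISTAL_THRESHOLD,
    from_midpoint: bool = False,
) -> pd.Series:
    """Flag sites strictly more than ``threshold`` bp from the nearest TSS.

    Returns a nullable boolean series indexed by site_id; sites on a
    chromosome with no TSS get a missing flag (and are logged).
    Distances are edge-based by default (``from_midpoint`` switches to the
    site midpoint).
    """
    if tss.empty:
        raise ValueError("TSS annotation is empty")
    pos_by_chrom = tss_positions(tss)
    flags = pd.Series(pd.NA, index=pd.Index(sites["site_id"], name="site_id"),
                      dtype="boolean")
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = pos_by_chrom.get(str(chrom))
        if pos is None or pos.size == 0:
            logger.warning("no TSS on %s: distal flag missing for %d sites",
                           chrom, len(grp))
            continue
        arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
        if from_midpoint:
            mid = (arr[:, 0] + arr[:, 1]) // 2
            arr = np.stack([mid, mid + 1], axis=1)
        d = _nearest_vec(arr, pos)
        flags.loc[grp["site_id"].to_numpy()] = d > threshold
    return flags


# -- manifest I/O ------------------------------------------------------------

def read_peak_manifest(path: str, genome=None, alias=None) -> List[SamplePeaks]:
    """Read a manifest TSV (sample_id, cell_type, mark, path) into SamplePeaks.

    Relative peak paths are resolved against the manifest's directory.
    """
    import os

    from .intervals import read_bed

    df = pd.read_csv(path, sep="\t")
    base = os.path.dirname(os.path.abspath(path))
    out = []
    for _, row in df.iterrows():
        p = row["path"]
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        out.append(SamplePeaks(str(row["sample_id"]), str(row["cell_type"]),
                               str(row["mark"]), read_bed(p, genome=genome, alias=alias)))
    return out


def read_reference(bed_path: str, membership_path: str,
                   genome: Optional[Dict[str, int]] = None) -> ReferenceSiteSet:
    """Load a catalogue written by :func:`write_reference`."""
    bed = pd.read_csv(bed_path, sep="\t", header=None, dtype={0: str},
                      names=["chrom", "start", "end", "name", "score", "strand"])
    klass_id = bed["name"].str.split(":", n=1, expand=True)
    sites = pd.DataFrame({
        "site_id": klass_id[1], "chrom": bed["chrom"],
        "start": bed["start"].astype(int), "end": bed["end"].astype(int),
        "klass": klass_id[0],
    })
    membership = pd.read_csv(membership_path, sep="\t", index_col=0).astype(bool)
    membership = membership.loc[sites["site_id"]]
    return ReferenceSiteSet(sites, membership, list(membership.columns), genome)


def write_reference(ref: ReferenceSiteSet, bed_path: str, membership_path: str) -> None:
    """Write the catalogue as BED6 (name=class:siteID, score=#member types)
    plus a 0/1 membership TSV."""
    n_members = ref.membership.sum(axis=1)
    with open(bed_path, "w") as fh:
        for _, r in ref.sites.iterrows():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.klass}:{r.site_id}"
                     f"\t{int(n_members[r.site_id])}\t.\n")
    ref.membership.astype(int).to_csv(membership_path, sep="\t")
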