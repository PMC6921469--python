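"""Annotation of chromatin loops against the reference site catalogue.

Loops (e.g. RNA Pol II ChIA-PET interactions) arrive as anchor pairs with
read-pair support and an optional FDR.  Each anchor is labelled P
(overlaps a reference promoter site), E (overlaps an enhancer site only)
or none; the unordered label pair yields the loop category (P-P, E-P,
E-E, other).  E-P loops additionally get a distal flag (when the enhancer
side hits a distal enhancer site) and a gene assignment (genes whose TSS
lies inside the promoter-side site).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .reference import ReferenceSiteSet

CATEGORIES = ("P-P", "E-P", "E-E", "other")


@dataclass
class LoopRecord:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    read_pairs: int = 1
    fdr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.read_pairs < 1:
            raise ValueError("read_pairs must be >= 1")
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValueError("fdr must lie in [0, 1]")


@dataclass
class LoopAnnotation:
    loop: LoopRecord
    labels: Tuple[str, str]            # per-anchor: "P", "E" or "none"
    category: str                      # P-P / E-P / E-E / other
    distal_ep: bool = False
    genes: List[str] = field(default_factory=list)
    promoter_sites: List[str] = field(default_factory=list)
    enhancer_sites: List[str] = field(default_factory=list)
    inter_chromosomal: bool = False


def _truthy(v) -> bool:
    """True only for a present, non-missing, true flag (pd.NA-safe)."""
    return v is not None and pd.notna(v) and bool(v)


def _sites_hit(anchor: GenomicInterval, sites: pd.DataFrame) -> List[str]:
    """site_ids of catalogue rows sharing >= 1 bp with the anchor."""
    sub = sites[sites["chrom"] == anchor.chrom]
    if sub.empty:
        return []
    ov = (np.minimum(sub["end"].to_numpy(), anchor.end)
          - np.maximum(sub["start"].to_numpy(), anchor.start))
    return list(sub.loc[ov >= 1, "site_id"])


def label_anchor(anchor: GenomicInterval, ref: ReferenceSiteSet) -> str:
    """P if the anchor overlaps any promoter site, else E for enhancer,
    else none.  Precedence P > E when both classes are hit."""
    if _sites_hit(anchor, ref.class_sites("promoter")):
        return "P"
    if _sites_hit(anchor, ref.class_sites("enhancer")):
        return "E"
    return "none"


def classify_loops(
    loops: Sequence[LoopRecord],
    ref: ReferenceSiteSet,
    distal_flags: Optional[pd.Series] = None,
    tss: Optional[pd.DataFrame] = None,
) -> List[LoopAnnotation]:
    """Label both anchors of every loop and derive its regulatory category.

    ``distal_flags`` is the per-site distal annotation (nullable boolean,
    indexed by site_id); ``tss`` the TSS table used for gene assignment of
    E-P loops.  Anchors overlapping several same-class sites keep all of
    them.  Inter-chromosomal loops are annotated but flagged and never
    carry the distal E-P flag.
    """
    prom = ref.class_sites("promoter")
    enh = ref.class_sites("enhancer")
    out: List[LoopAnnotation] = []
    for loop in loops:
        anchors = (loop.anchor1, loop.anchor2)
        prom_hits = [_sites_hit(a, prom) for a in anchors]
        enh_hits = [_sites_hit(a, enh) for a in anchors]
        labels = tuple(
            "P" if prom_hits[i] else ("E" if enh_hits[i] else "none")
            for i in range(2)
        )
        key = frozenset(labels)
        if "none" in key:
            category = "other"
        elif key == {"P"}:
            category = "P-P"
        elif key == {"E"}:
            category = "E-E"
        else:
            category = "E-P"
        ann = LoopAnnotation(
            loop=loop, labels=labels, category=category,
            inter_chromosomal=(loop.anchor1.chrom != loop.anchor2.chrom),
        )
        if category == "E-P":
            p_side = 0 if labels[0] == "P" else 1
            e_side = 1 - p_side
            ann.promoter_sites = prom_hits[p_side]
            ann.enhancer_sites = enh_hits[e_side]
            if distal_flags is not None and not ann.inter_chromosomal:
                ann.distal_ep = any(
                    _truthy(distal_flags.get(s)) for s in ann.enhancer_sites
                )
            if tss is not None and ann.promoter_sites:
                psites = prom[prom["site_id"].isin(ann.promoter_sites)]
                genes: Set[str] = set()
                for _, site in psites.iterrows():
                    sub = tss[(tss["chrom"] == site.chrom)
                              & (tss["pos"] >= site.start) & (tss["pos"] < site.end)]
                    genes.update(sub["gene_id"])
                ann.genes = sorted(genes)
        elif category == "P-P":
            ann.promoter_sites = sorted(set(prom_hits[0]) | set(prom_hits[1]))
        elif category == "E-E":
            ann.enhancer_sites = sorted(set(enh_hits[0]) | set(enh_hits[1]))
        out.append(ann)
    return out


def summarize_loops(
    annotations: Sequence[LoopAnnotation],
    significant_fdr: float = 0.05,
) -> pd.DataFrame:
    """Category counts and percentages per stratum (significant / all loops).

    Loops with a missing FDR fall only into the ``all`` stratum.  The
    ``E-P_distal`` row reports distal E-P loops as a percentage of E-P
    loops.  ``percent`` is unrounded; ``percent_rounded`` carries the
    one-decimal reporting value.
    """
    rows = []
    strata = {
        "significant": [a for a in annotations
                        if a.loop.fdr is not None and a.loop.fdr < significant_fdr],
        "all": list(annotations),
    }
    for stratum, anns in strata.items():
        total = len(anns)
        if total == 0:
            continue
        for cat in CATEGORIES:
            n = sum(1 for a in anns if a.category == cat)
            pct = 100.0 * n / total
            rows.append((stratum, cat, n, pct, round(pct, 1)))
        n_ep = sum(1 for a in anns if a.category == "E-P")
        n_distal = sum(1 for a in anns if a.distal_ep)
        pct = 100.0 * n_distal / n_ep if n_ep else 0.0
        rows.append((stratum, "E-P_distal", n_distal, pct, round(pct, 1)))
    return pd.DataFrame(
        rows, columns=["stratum", "category", "count", "percent", "percent_rounded"]
    )


def enhancer_gene_map(
    annotations: Sequence[LoopAnnotation],
) -> Dict[str, Set[str]]:
    """Enhancer site -> target genes, pooled over all E-P loops."""
    out: Dict[str, Set[str]] = {}
    for a in annotations:
        if a.category != "E-P" or not a.genes:
            continue
        for e in a.enhancer_sites:
            out.setdefault(e, set()).update(a.genes)
    return out


def count_looped_distal_enhancers(
    annotations: Sequence[LoopAnnotation],
    distal_flags: pd.Series,
) -> int:
    """Distinct distal enhancer sites connected by at least one E-P loop."""
    hit: Set[str] = set()
    for a in annotations:
        if a.category == "E-P":
            hit.update(s for s in a.enhancer_sites if _truthy(distal_flags.get(s)))
    return len(hit)


# -- BEDPE I/O ---------------------------------------------------------------

def read_bedpe(path: str, genome=None) -> List[LoopRecord]:
    """Read loops from BEDPE: chrom1,start1,end1,chrom2,start2,end2,name,
    read_pairs[,fdr]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str, 3: str})
    loops = []
    for row in df.itertuples(index=False):
        fdr = float(row[8]) if len(row) > 8 and pd.notna(row[8]) else None
        loops.append(LoopRecord(
            anchor1=GenomicInterval(str(row[0]), int(row[1]), int(row[2])),
            anchor2=GenomicInterval(str(row[3]), int(row[4]), int(row[5])),
            read_pairs=int(row[7]) if len(row) > 7 else 1,
            fdr=fdr,
        ))
    return loops


def write_annotated_bedpe(annotations: Sequence[LoopAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(annotations):
            l = a.loop
            fdr = "" if l.fdr is None else f"{l.fdr:g}"
            fh.write("\t".join(map(str, [
                l.anchor1.chrom, l.anchor1.start, l.anchor1.end,
                l.anchor2.chrom, l.anchor2.start, l.anchor2.end,
                f"loop_{i+1}", l.read_pairs, fdr, a.category,
                int(a.distal_ep), ",".join(a.genes) or ".",
            ])) + "\n")
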