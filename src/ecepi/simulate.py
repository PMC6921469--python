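"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes — multi-donor peak calls for two
histone marks, an exclusion panel, TSS annotation, chromosome sizes and
centromeres, chromatin loops, a GWAS SNP catalog, intensity and
expression matrices — can be generated here at desk scale, with truth
tables sufficient to score each stage (site recovery, specificity
filtering, loop categories, enrichment calls, differential calls).

Layout: sites live on a regular grid of slots per chromosome, outside a
central centromeric interval and away from chromosome ends.  Gene TSSs
occupy alternating slots; promoter truth sites sit on TSSs, enhancer
truth sites on gene-free slots (distal by construction) or, for a
designated proximal subset, a little downstream of a TSS.  Shared-core
sites belong to every cell type, type-specific sites to exactly one, and
a subset of shared sites is additionally "ubiquitous": present in the
exclusion panel and therefore expected to be removed by the specificity
filter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, write_bed
from .loops import LoopRecord
from .reference import SamplePeaks
from . import expression as expr_mod


@dataclass
class SyntheticDesign:
    """Parameters of the synthetic study.

    Defaults are a desk-scale profile of the real study design: nine
    endothelial cell types with a few donors each, two sharp marks per
    donor, an exclusion panel with a single exempted member, ~300 truth
    sites, ~2000 SNPs and 500 loops.
    """

    # genome
    n_chrom: int = 5
    chrom_length: int = 10_000_000
    centromere_fraction: float = 0.04
    margin: int = 105_000            # slot-free zone at chromosome ends / centromere
    slot_spacing: int = 35_000
    n_genes: int = 120
    noncoding_every: int = 10        # every n-th gene is non-protein-coding

    # cell types and donors
    n_cell_types: int = 9
    samples_per_type: int = 3

    # site architecture
    n_shared_promoters: int = 40
    n_shared_enhancers: int = 90
    n_specific_promoters_per_type: int = 2
    n_specific_enhancers_per_type: int = 10
    n_proximal_enhancers: int = 20       # shared enhancers placed near a TSS
    n_ubiquitous_promoters: int = 20     # shared sites present in the panel
    n_ubiquitous_enhancers: int = 40
    panel_size: int = 20
    panel_exceptions: Tuple[str, ...] = ("E122",)

    # peak emission
    peak_width: int = 1000
    jitter_sd: float = 20.0
    dropout: float = 0.0

    # intensity matrix
    baseline_log_mean: float = 6.0       # log2 scale
    baseline_log_sd: float = 1.0
    intensity_sigma: float = 0.25        # within-row log2 noise
    diff_fraction: float = 0.05
    fold_shift: float = 4.0

    # expression model
    coef_a: float = 1.0
    coef_b1: float = 0.8
    coef_b2: float = 0.3
    expr_noise_sd: float = 0.1
    pseudocount: float = 1.0

    # SNP catalog
    snp_per_mb: float = 40.0
    snp_enrichment_factor: float = 20.0
    n_enriched_sites: int = 5
    snp_deposit_halfwidth: int = 10_000   # planted SNPs land within +/- this of the site

    # loops
    n_loops: int = 500
    loop_proportions: Tuple[float, float, float, float] = (0.35, 0.45, 0.10, 0.10)
    loop_significant_fraction: float = 0.3

    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.loop_proportions), 1.0):
            raise ValueError("loop category proportions must sum to 1")
        if not (0 <= self.dropout <= 1):
            raise ValueError("dropout must be a probability")
        if self.jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")

    @property
    def cell_types(self) -> List[str]:
        return [f"EC{i+1}" for i in range(self.n_cell_types)]


MATCHING_TRAITS = ("coronary artery disease", "heart rate", "cardiac arrhythmia")
DECOY_TRAITS = ("height", "type 2 diabetes", "body mass index")
TRAIT_VOCAB = MATCHING_TRAITS + DECOY_TRAITS


@dataclass
class SyntheticDataset:
    """All generated inputs plus the truth tables that score them."""

    design: SyntheticDesign
    genome: Dict[str, int]
    centromeres: IntervalSet
    genes: pd.DataFrame                     # gene_id, chrom, pos, strand, biotype
    truth_sites: pd.DataFrame               # site_id, chrom, start, end, klass,
                                            # panel_ubiquitous, proximal, gene_id
    truth_membership: pd.DataFrame          # site_id x cell type (bool)
    sample_peaks: List[SamplePeaks] = field(default_factory=list)
    panel_peaks: List[SamplePeaks] = field(default_factory=list)
    intensity: Optional[pd.DataFrame] = None
    groups: Optional[Dict[str, str]] = None
    truth_differential: Optional[pd.Series] = None
    expression: Optional[pd.DataFrame] = None
    chip_features: Optional[Dict[str, pd.DataFrame]] = None
    snps: Optional[pd.DataFrame] = None
    truth_enriched: List[str] = field(default_factory=list)
    loops: List[LoopRecord] = field(default_factory=list)
    truth_loops: Optional[pd.DataFrame] = None

    # ------------------------------------------------------------------ IO --
    def write(self, outdir: str) -> None:
        """Emit every input in the formats the pipeline reads, plus truth TSVs."""
        os.makedirs(outdir, exist_ok=True)
        peaks_dir = os.path.join(outdir, "peaks")
        panel_dir = os.path.join(outdir, "panel")
        truth_dir = os.path.join(outdir, "truth")
        for d in (peaks_dir, panel_dir, truth_dir):
            os.makedirs(d, exist_ok=True)
        with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
            for c, L in self.genome.items():
                fh.write(f"{c}\t{L}\n")
        write_bed(self.centromeres, os.path.join(outdir, "centromeres.bed"))
        self.genes.to_csv(os.path.join(outdir, "tss.tsv"), sep="\t", index=False)

        def dump(peaks: List[SamplePeaks], d: str, manifest: str) -> None:
            rows = []
            for p in peaks:
                fname = f"{p.sample_id}_{p.mark}.bed"
                write_bed(p.peaks, os.path.join(d, fname))
                rows.append((p.sample_id, p.cell_type, p.mark,
                             os.path.join(os.path.basename(d), fname)))
            pd.DataFrame(rows, columns=["sample_id", "cell_type", "mark", "path"]) \
                .to_csv(os.path.join(outdir, manifest), sep="\t", index=False)

        dump(self.sample_peaks, peaks_dir, "peak_manifest.tsv")
        dump(self.panel_peaks, panel_dir, "panel_manifest.tsv")

        if self.snps is not None:
            self.snps.to_csv(os.path.join(outdir, "snps.tsv"), sep="\t", index=False)
        if self.loops:
            with open(os.path.join(outdir, "loops.bedpe"), "w") as fh:
                for i, l in enumerate(self.loops):
                    fdr = "" if l.fdr is None else f"{l.fdr:.6g}"
                    fh.write("\t".join(map(str, [
                        l.anchor1.chrom, l.anchor1.start, l.anchor1.end,
                        l.anchor2.chrom, l.anchor2.start, l.anchor2.end,
                        f"loop_{i+1}", l.read_pairs, fdr])) + "\n")
        if self.intensity is not None:
            self.intensity.to_csv(os.path.join(outdir, "intensity.tsv"), sep="\t")
            pd.Series(self.groups, name="group").rename_axis("sample") \
                .to_csv(os.path.join(outdir, "groups.tsv"), sep="\t")
        if self.expression is not None:
            self.expression.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t")
        self.truth_sites.to_csv(os.path.join(truth_dir, "sites.tsv"),
                                sep="\t", index=False)
        self.truth_membership.astype(int).to_csv(
            os.path.join(truth_dir, "membership.tsv"), sep="\t")
        if self.truth_differential is not None:
            self.truth_differential.astype(int).rename("differential") \
                .to_csv(os.path.join(truth_dir, "differential.tsv"), sep="\t")
        if self.truth_loops is not None:
            self.truth_loops.to_csv(os.path.join(truth_dir, "loops.tsv"),
                                    sep="\t", index=False)
        if self.truth_enriched:
            pd.Series(self.truth_enriched, name="site_id").to_csv(
                os.path.join(truth_dir, "enriched.tsv"), sep="\t", index=False)

    @property
    def sample_ids(self) -> List[str]:
        return sorted({p.sample_id for p in self.sample_peaks})


# -------------------------------------------------------------------------
# generation stages
# -------------------------------------------------------------------------

def generate_genome(design: SyntheticDesign, rng: np.random.Generator):
    """Chromosome sizes, central centromeres, slot grid and TSS annotation."""
    genome = {f"chr{i+1}": design.chrom_length for i in range(design.n_chrom)}
    cent_half = int(design.chrom_length * design.centromere_fraction / 2)
    mid = design.chrom_length // 2
    centromeres = IntervalSet(
        {c: np.array([[mid - cent_half, mid + cent_half]]) for c in genome},
        genome=genome,
    )
    # slots: grid positions outside centromere +/- margin and chromosome ends,
    # interleaved round-robin across chromosomes so gene and site placement
    # spreads evenly over the genome
    lo_arm = (design.margin, mid - cent_half - design.margin)
    hi_arm = (mid + cent_half + design.margin, design.chrom_length - design.margin)
    per_chrom: List[List[Tuple[str, int]]] = []
    for c in genome:
        per_chrom.append([(c, pos) for a, b in (lo_arm, hi_arm)
                          for pos in range(a, b, design.slot_spacing)])
    slots: List[Tuple[str, int]] = []
    for i in range(max(len(v) for v in per_chrom)):
        for v in per_chrom:
            if i < len(v):
                slots.append(v[i])
    # genes on alternating slots, round-robin over chromosomes via interleaved order
    gene_slots = slots[0::2]
    enh_slots = slots[1::2]
    if design.n_genes > len(gene_slots):
        raise ValueError(
            f"chromosomes too short: {design.n_genes} genes requested but only "
            f"{len(gene_slots)} gene slots available")
    strands = np.where(np.arange(design.n_genes) % 2 == 0, "+", "-")
    genes = pd.DataFrame({
        "gene_id": [f"gene_{i+1:04d}" for i in range(design.n_genes)],
        "chrom": [gene_slots[i][0] for i in range(design.n_genes)],
        "pos": [gene_slots[i][1] for i in range(design.n_genes)],
        "strand": strands,
        "biotype": ["lncRNA" if (i + 1) % design.noncoding_every == 0
                    else "protein_coding" for i in range(design.n_genes)],
    })
    return genome, centromeres, genes, enh_slots


def _plant_sites(design: SyntheticDesign, genes: pd.DataFrame,
                 enh_slots: Sequence[Tuple[str, int]], rng: np.random.Generator):
    """Place truth sites and decide their class, membership and panel status."""
    T = design.n_cell_types
    types = design.cell_types
    half = design.peak_width // 2
    rows, member = [], []

    n_prom = design.n_shared_promoters + T * design.n_specific_promoters_per_type
    if n_prom > len(genes):
        raise ValueError("not enough genes to host the requested promoter sites")
    prom_genes = genes.iloc[:n_prom]

    def add(chrom, start, end, klass, mem, ubiq, proximal, gene_id):
        rows.append((chrom, int(start), int(end), klass, ubiq, proximal, gene_id))
        member.append(mem)

    i = 0
    for _, g in prom_genes.iterrows():
        if i < design.n_shared_promoters:
            mem = np.ones(T, dtype=bool)
            ubiq = i < design.n_ubiquitous_promoters
        else:
            mem = np.zeros(T, dtype=bool)
            mem[(i - design.n_shared_promoters) % T] = True
            ubiq = False
        add(g.chrom, g.pos - half, g.pos + half, "promoter", mem, ubiq, False, g.gene_id)
        i += 1

    # proximal shared enhancers: just downstream of the first promoter genes
    n_prox = min(design.n_proximal_enhancers, design.n_shared_enhancers, len(prom_genes))
    for j in range(n_prox):
        g = prom_genes.iloc[j]
        mem = np.ones(T, dtype=bool)
        add(g.chrom, g.pos + 2500, g.pos + 2500 + design.peak_width,
            "enhancer", mem, j < design.n_ubiquitous_enhancers, True, g.gene_id)

    n_distal_shared = design.n_shared_enhancers - n_prox
    n_specific_enh = T * design.n_specific_enhancers_per_type
    if n_distal_shared + n_specific_enh > len(enh_slots):
        raise ValueError("not enough enhancer slots for the requested architecture")
    k = 0
    for j in range(n_distal_shared):
        c, pos = enh_slots[k]; k += 1
        mem = np.ones(T, dtype=bool)
        add(c, pos - half, pos + half, "enhancer", mem,
            (n_prox + j) < design.n_ubiquitous_enhancers, False, None)
    for j in range(n_specific_enh):
        c, pos = enh_slots[k]; k += 1
        mem = np.zeros(T, dtype=bool)
        mem[j % T] = True
        add(c, pos - half, pos + half, "enhancer", mem, False, False, None)

    sites = pd.DataFrame(rows, columns=["chrom", "start", "end", "klass",
                                        "panel_ubiquitous", "proximal", "gene_id"])
    sites.insert(0, "site_id", [f"truth_{i+1:04d}" for i in range(len(sites))])
    membership = pd.DataFrame(np.vstack(member), index=sites["site_id"],
                              columns=types)
    return sites, membership


def _jitter_interval(start: int, end: int, sd: float, rng: np.random.Generator,
                     chrom_len: int) -> Tuple[int, int]:
    """Gaussian edge jitter, truncated so 0 <= start < end <= chrom_len."""
    if sd == 0:
        return start, end
    s = int(round(start + rng.normal(0, sd)))
    e = int(round(end + rng.normal(0, sd)))
    s = max(0, min(s, chrom_len - 2))
    e = max(s + 1, min(e, chrom_len))
    return s, e


def generate_samples(design: SyntheticDesign, genome: Mapping[str, int],
                     sites: pd.DataFrame, membership: pd.DataFrame,
                     rng: np.random.Generator):
    """Per-donor peak files (both marks) and exclusion-panel peak files.

    Promoter truth sites emit overlapping H3K4me3 + H3K27ac peaks; enhancer
    truth sites H3K27ac only.  Edges are Gaussian-jittered and sites drop
    out per sample with the design's Bernoulli rate.  Panel members carry
    peaks at the panel-ubiquitous sites; exception members (the same
    lineage inside the panel) carry peaks at every truth site.
    """
    samples: List[SamplePeaks] = []
    for t_idx, ct in enumerate(design.cell_types):
        planted = sites[membership[ct].loc[sites["site_id"]].to_numpy()]
        for s_idx in range(design.samples_per_type):
            sid = f"{ct}_d{s_idx+1}"
            k4: List[GenomicInterval] = []
            k27: List[GenomicInterval] = []
            for row in planted.itertuples(index=False):
                if design.dropout > 0 and rng.random() < design.dropout:
                    continue
                L = genome[row.chrom]
                if row.klass == "promoter":
                    s, e = _jitter_interval(row.start, row.end, design.jitter_sd, rng, L)
                    k4.append(GenomicInterval(row.chrom, s, e))
                    s2, e2 = _jitter_interval(row.start, row.end, design.jitter_sd, rng, L)
                    k27.append(GenomicInterval(row.chrom, s2, e2))
                else:
                    s, e = _jitter_interval(row.start, row.end, design.jitter_sd, rng, L)
                    k27.append(GenomicInterval(row.chrom, s, e))
            samples.append(SamplePeaks(sid, ct, "H3K4me3", IntervalSet(k4, genome=genome)))
            samples.append(SamplePeaks(sid, ct, "H3K27ac", IntervalSet(k27, genome=genome)))

    panel: List[SamplePeaks] = []
    panel_ids = [f"E{100+i:03d}" for i in range(design.panel_size)]
    for exc in design.panel_exceptions:
        if exc not in panel_ids:
            panel_ids[-1] = exc
    ubiq = sites[sites["panel_ubiquitous"]]
    for pid in panel_ids:
        exempt = pid in design.panel_exceptions
        src = sites if exempt else ubiq
        for mark, klass in (("H3K4me3", "promoter"), ("H3K27ac", "enhancer")):
            sub = src[src["klass"] == klass]
            ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end))
                   for r in sub.itertuples(index=False)]
            panel.append(SamplePeaks(pid, pid, mark, IntervalSet(ivs, genome=genome)))
    return samples, panel


def generate_matrices(design: SyntheticDesign, sites: pd.DataFrame,
                      membership: pd.DataFrame, genes: pd.DataFrame,
                      samples: List[SamplePeaks], rng: np.random.Generator):
    """Intensity matrix with planted differential rows, and an expression
    matrix tied to the promoter-mark features by the linear model."""
    types = design.cell_types
    sample_ids = [f"{ct}_d{i+1}" for ct in types for i in range(design.samples_per_type)]
    groups = {sid: sid.rsplit("_", 1)[0] for sid in sample_ids}

    n_rows = len(sites)
    base = rng.normal(design.baseline_log_mean, design.baseline_log_sd, size=n_rows)
    logm = np.tile(base[:, None], (1, len(sample_ids))) \
        + rng.normal(0, design.intensity_sigma, size=(n_rows, len(sample_ids)))
    n_diff = int(round(design.diff_fraction * n_rows))
    diff_rows = rng.choice(n_rows, size=n_diff, replace=False)
    shift = np.log2(design.fold_shift)
    col_type = np.array([groups[s] for s in sample_ids])
    for r in diff_rows:
        n_up = rng.integers(1, len(types))          # shift 1..T-1 groups
        up_types = rng.choice(types, size=n_up, replace=False)
        logm[r, np.isin(col_type, up_types)] += shift
    intensity = pd.DataFrame(2.0 ** logm, index=sites["site_id"], columns=sample_ids)
    truth_diff = pd.Series(False, index=sites["site_id"])
    truth_diff.iloc[diff_rows] = True

    # expression: one RNA sample per ChIP sample, linked via the mark features
    by_sample: Dict[str, Dict[str, IntervalSet]] = {}
    cts: Dict[str, str] = {}
    for p in samples:
        by_sample.setdefault(p.sample_id, {})[p.mark] = p.peaks
        cts[p.sample_id] = p.cell_type
    features: Dict[str, pd.DataFrame] = {}
    expr_cols: Dict[str, pd.Series] = {}
    for sid, marks in by_sample.items():
        f = expr_mod.tss_features(marks["H3K4me3"], marks["H3K27ac"], genes,
                                  pseudocount=design.pseudocount)
        features[sid] = f
        y = (design.coef_a + design.coef_b1 * f["x1"] + design.coef_b2 * f["x2"]
             + rng.normal(0, design.expr_noise_sd, size=len(f)))
        tpm = np.exp(y) - design.pseudocount
        expr_cols[sid] = pd.Series(np.maximum(tpm, 0.0), index=f.index)
    expression = pd.DataFrame(expr_cols)
    return intensity, groups, truth_diff, expression, features


def generate_snps_and_loops(design: SyntheticDesign, genome: Mapping[str, int],
                            sites: pd.DataFrame, genes: pd.DataFrame,
                            rng: np.random.Generator):
    """Background-uniform SNPs with planted local enrichment, and loops
    drawn to hit the requested category proportions."""
    # --- SNPs ------------------------------------------------------------
    chroms, poss, traits = [], [], []
    for c, L in genome.items():
        n_bg = rng.poisson(design.snp_per_mb * L / 1e6)
        p = np.sort(rng.integers(0, L, size=n_bg))
        chroms.extend([c] * n_bg)
        poss.extend(p.tolist())
        traits.extend(rng.choice(TRAIT_VOCAB, size=n_bg).tolist())

    # enriched sites: lineage-private distal enhancers
    private_distal = sites[(sites["klass"] == "enhancer")
                           & ~sites["panel_ubiquitous"] & ~sites["proximal"]]
    n_enr = min(design.n_enriched_sites, len(private_distal))
    # designate enriched sites spread across chromosomes (at most one per
    # chromosome while possible) so their 100-kb hotspots stay dispersed,
    # as trait-associated loci are genome-wide in real catalogs
    picked: List[int] = []
    by_chrom = {c: g.index.to_list()
                for c, g in private_distal.groupby("chrom", sort=True)}
    order = list(by_chrom)
    round_i = 0
    while len(picked) < n_enr:
        for c in order:
            cands = [i for i in by_chrom[c] if i not in picked]
            if cands and len(picked) < n_enr:
                picked.append(cands[int(rng.integers(0, len(cands)))])
        round_i += 1
        if round_i > n_enr:
            break
    chosen = private_distal.loc[picked]
    matched_density = design.snp_per_mb * len(MATCHING_TRAITS) / len(TRAIT_VOCAB)
    for row in chosen.itertuples(index=False):
        mid = (row.start + row.end) // 2
        # 20x enrichment of the site's 100-kb window, deposited close to the
        # site so that windows of neighbouring sites stay clean
        lam = (design.snp_enrichment_factor - 1) * matched_density * 0.1
        n_extra = rng.poisson(lam)
        hw = design.snp_deposit_halfwidth
        lo, hi = max(mid - hw, 0), min(mid + hw, genome[row.chrom])
        p = rng.integers(lo, hi, size=n_extra)
        chroms.extend([row.chrom] * n_extra)
        poss.extend(p.tolist())
        traits.extend(rng.choice(MATCHING_TRAITS, size=n_extra).tolist())
    snps = pd.DataFrame({"chrom": chroms, "pos": poss, "trait": traits})
    truth_enriched = list(chosen["site_id"])

    # --- loops -----------------------------------------------------------
    proms = sites[sites["klass"] == "promoter"]
    enhs = sites[sites["klass"] == "enhancer"]
    cats = rng.choice(4, size=design.n_loops, p=list(design.loop_proportions))
    cat_names = ["P-P", "E-P", "E-E", "other"]
    loops: List[LoopRecord] = []
    truth_rows = []

    def anchor_from(row) -> GenomicInterval:
        return GenomicInterval(row.chrom, int(row.start), int(row.end))

    def free_anchor(chrom: Optional[str] = None) -> GenomicInterval:
        # a pocket guaranteed site-free: slots are >= 12.5 kb apart and sites
        # extend < 4 kb from a slot centre, so slot+8..9 kb is always empty
        c = chrom or list(genome)[rng.integers(0, len(genome))]
        base = int(rng.integers(design.margin, genome[c] - design.margin))
        pos = (base // design.slot_spacing) * design.slot_spacing + 8000
        pos = min(pos, genome[c] - 1001)
        return GenomicInterval(c, pos, pos + 1000)

    def pick(df, chrom: Optional[str] = None) -> pd.Series:
        # loops are intra-chromosomal contacts: once the first anchor is
        # placed, the partner is drawn from the same chromosome
        if chrom is not None:
            same = df[df["chrom"] == chrom]
            if len(same):
                df = same
        return df.iloc[int(rng.integers(0, len(df)))]

    for cat_idx in cats:
        cat = cat_names[cat_idx]
        gene_id = None
        if cat == "P-P":
            a = pick(proms)
            b = pick(proms, a.chrom)
            a1, a2 = anchor_from(a), anchor_from(b)
            s1, s2 = a.site_id, b.site_id
        elif cat == "E-P":
            e = pick(enhs)
            p = pick(proms, e.chrom)
            a1, a2 = anchor_from(e), anchor_from(p)
            s1, s2 = e.site_id, p.site_id
            gene_id = p.gene_id
        elif cat == "E-E":
            a = pick(enhs)
            b = pick(enhs, a.chrom)
            a1, a2 = anchor_from(a), anchor_from(b)
            s1, s2 = a.site_id, b.site_id
        else:
            a1 = free_anchor()
            a2 = free_anchor(a1.chrom)
            s1 = s2 = None
        if rng.random() < design.loop_significant_fraction:
            fdr = float(rng.uniform(0, 0.049))
        else:
            fdr = float(rng.uniform(0.05, 1.0))
        rp = 1 + int(rng.poisson(3))
        loops.append(LoopRecord(a1, a2, read_pairs=rp, fdr=fdr))
        truth_rows.append((cat, s1, s2, gene_id, fdr))
    truth_loops = pd.DataFrame(
        truth_rows, columns=["category", "site1", "site2", "gene_id", "fdr"])
    return snps, truth_enriched, loops, truth_loops


def simulate(design: Optional[SyntheticDesign] = None) -> SyntheticDataset:
    """Run every generator stage under one master seed."""
    design = design or SyntheticDesign()
    rng = np.random.default_rng(design.seed)
    genome, centromeres, genes, enh_slots = generate_genome(design, rng)
    sites, membership = _plant_sites(design, genes, enh_slots, rng)
    samples, panel = generate_samples(design, genome, sites, membership, rng)
    intensity, groups, truth_diff, expression, features = generate_matrices(
        design, sites, membership, genes, samples, rng)
    snps, truth_enriched, loops, truth_loops = generate_snps_and_loops(
        design, genome, sites, genes, rng)
    return SyntheticDataset(
        design=design, genome=genome, centromeres=centromeres, genes=genes,
        truth_sites=sites, truth_membership=membership,
        sample_peaks=samples, panel_peaks=panel,
        intensity=intensity, groups=groups, truth_differential=truth_diff,
        expression=expression, chip_features=features,
        snps=snps, truth_enriched=truth_enriched,
        loops=loops, truth_loops=truth_loops,
    )
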