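"""Configuration, orchestration and provenance for the end-to-end pipeline.

Each stage reads its inputs from a working directory, writes its outputs
there, and records a provenance JSON (parameter echo + MD5 checksums of
the inputs it consumed).  Re-running a stage whose inputs and parameters
are unchanged is a no-op.  Stage order::

    simulate -> classify -> reference -> specific -> distal
             -> loops / gwas / regress / diff / cluster

``simulate`` is only needed when working from synthetic data; real
peak/loop/SNP/expression files placed in the directory under the same
names work identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import differential as diff_mod
from . import expression as expr_mod
from . import gwas as gwas_mod
from . import loops as loops_mod
from . import reference as ref_mod
from .simulate import SyntheticDesign, simulate as simulate_dataset
from .intervals import IntervalSet, read_bed, read_chrom_sizes

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "reference", "specific", "distal",
          "loops", "gwas", "regress", "diff", "cluster")


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, with the study defaults."""

    outdir: str = "ecepi_out"
    seed: int = 0
    merge_gap: int = 100
    min_overlap_bp: int = 1
    distal_threshold: int = 10_000
    gwas_window: int = 100_000
    gwas_terms: Tuple[str, ...] = gwas_mod.DEFAULT_TERMS
    z_threshold: float = 5.0
    n_perm: int = 1000
    fdr_threshold: float = 1e-5
    loop_fdr: float = 0.05
    k: int = 6
    pseudocount: float = 1.0
    sex_chromosomes: Tuple[str, ...] = ("chrX", "chrY")
    panel_exceptions: Tuple[str, ...] = ("E122",)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Load a flat ``key: value`` config file (YAML-compatible)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gwas_terms", "sex_chromosomes", "panel_exceptions"):
            if key in raw and isinstance(raw[key], (list, str)):
                v = raw[key]
                raw[key] = tuple(v.split(",") if isinstance(v, str) else v)
        return cls(**raw)

    def echo(self) -> Dict:
        d = dataclasses.asdict(self)
        logger.info("parameters: %s", json.dumps(d, default=str))
        return d


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Stage runner bound to one working directory and one config."""

    def __init__(self, config: Optional[PipelineConfig] = None) -> None:
        self.config = config or PipelineConfig()
        os.makedirs(self.config.outdir, exist_ok=True)

    # -- provenance -------------------------------------------------------
    def _path(self, *parts: str) -> str:
        return os.path.join(self.config.outdir, *parts)

    def _prov_path(self, stage: str) -> str:
        return self._path(f".prov_{stage}.json")

    def _record(self, stage: str, inputs: Sequence[str], outputs: Sequence[str],
                started: float) -> None:
        prov = {
            "stage": stage,
            "params": self.config.echo(),
            "inputs": {os.path.basename(p): _md5(p) for p in inputs
                       if os.path.exists(p)},
            "outputs": [os.path.basename(p) for p in outputs],
            "elapsed_s": round(time.time() - started, 3),
        }
        with open(self._prov_path(stage), "w") as fh:
            json.dump(prov, fh, indent=1, default=str)

    def _current(self, stage: str, inputs: Sequence[str]) -> bool:
        """True when the stage's recorded inputs/params match and its
        outputs still exist."""
        pp = self._prov_path(stage)
        if not os.path.exists(pp):
            return False
        with open(pp) as fh:
            prov = json.load(fh)
        if prov.get("params") != json.loads(
                json.dumps(dataclasses.asdict(self.config), default=str)):
            return False
        want = {os.path.basename(p): _md5(p) for p in inputs if os.path.exists(p)}
        if prov.get("inputs") != want:
            return False
        return all(os.path.exists(self._path(o)) for o in prov.get("outputs", []))

    def _require(self, stage_needed: str, *paths: str) -> None:
        for p in paths:
            if not os.path.exists(p):
                raise FileNotFoundError(
                    f"missing {os.path.basename(p)!r}: run the "
                    f"{stage_needed!r} stage first")

    # -- stages -----------------------------------------------------------
    def run_stage(self, stage: str) -> None:
        if stage == "all":
            for s in STAGES:
                self.run_stage(s)
            return
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; available: "
                             f"{', '.join(STAGES)} or 'all'")
        getattr(self, f"_stage_{stage}")()

    def _run(self, stage: str, inputs: List[str], body) -> None:
        if self._current(stage, inputs):
            logger.info("stage %s: up to date, skipped", stage)
            return
        started = time.time()
        outputs = body()
        self._record(stage, inputs, outputs, started)
        logger.info("stage %s: done (%d output files)", stage, len(outputs))

    def _stage_simulate(self) -> None:
        def body() -> List[str]:
            design = SyntheticDesign(seed=self.config.seed)
            ds = simulate_dataset(design)
            ds.write(self.config.outdir)
            return ["chrom.sizes", "tss.tsv", "peak_manifest.tsv",
                    "panel_manifest.tsv", "snps.tsv", "loops.bedpe",
                    "intensity.tsv", "groups.tsv", "expression.tsv"]
        self._run("simulate", [], body)

    def _genome(self) -> Dict[str, int]:
        return read_chrom_sizes(self._path("chrom.sizes"))

    def _stage_classify(self) -> None:
        manifest = self._path("peak_manifest.tsv")
        self._require("simulate", manifest)

        def body() -> List[str]:
            peaks = ref_mod.read_peak_manifest(manifest, genome=self._genome())
            by_sample: Dict[str, Dict[str, ref_mod.SamplePeaks]] = {}
            for p in peaks:
                by_sample.setdefault(p.sample_id, {})[p.mark] = p
            outdir = self._path("classified")
            os.makedirs(outdir, exist_ok=True)
            rows = []
            from .intervals import write_bed
            for sid, marks in sorted(by_sample.items()):
                cls = ref_mod.classify_sample_sites(marks["H3K4me3"], marks["H3K27ac"])
                for klass, s in (("promoter", cls.promoters), ("enhancer", cls.enhancers)):
                    fname = f"{sid}_{klass}.bed"
                    write_bed(s, os.path.join(outdir, fname))
                    rows.append((sid, cls.cell_type, klass,
                                 os.path.join("classified", fname)))
            pd.DataFrame(rows, columns=["sample_id", "cell_type", "klass", "path"]) \
                .to_csv(self._path("classified_manifest.tsv"), sep="\t", index=False)
            return ["classified_manifest.tsv"]
        self._run("classify", [manifest], body)

    def _load_classified(self) -> Dict[str, List[ref_mod.ClassifiedSites]]:
        mf = pd.read_csv(self._path("classified_manifest.tsv"), sep="\t")
        genome = self._genome()
        per_sample: Dict[str, Dict] = {}
        for _, r in mf.iterrows():
            d = per_sample.setdefault(r.sample_id, {"cell_type": r.cell_type})
            d[r.klass] = read_bed(self._path(r.path), genome=genome)
        by_type: Dict[str, List[ref_mod.ClassifiedSites]] = {}
        for sid, d in per_sample.items():
            cs = ref_mod.ClassifiedSites(
                sid, d["cell_type"],
                d.get("promoter", IntervalSet(genome=genome)),
                d.get("enhancer", IntervalSet(genome=genome)))
            by_type.setdefault(d["cell_type"], []).append(cs)
        return by_type

    def _stage_reference(self) -> None:
        cm = self._path("classified_manifest.tsv")
        self._require("classify", cm)

        def body() -> List[str]:
            by_type = self._load_classified()
            per_type = {
                ct: ref_mod.build_celltype_reference(
                    samples, self.config.merge_gap, self.config.sex_chromosomes)
                for ct, samples in sorted(by_type.items())
            }
            ref = ref_mod.build_merged_reference(per_type, self.config.merge_gap)
            ref_mod.write_reference(ref, self._path("reference.bed"),
                                    self._path("membership.tsv"))
            ratio = ref_mod.shared_ratio(ref)
            ratio.to_csv(self._path("shared_ratio.tsv"), sep="\t")
            return ["reference.bed", "membership.tsv", "shared_ratio.tsv"]
        self._run("reference", [cm], body)

    def _load_reference(self) -> ref_mod.ReferenceSiteSet:
        self._require("reference", self._path("reference.bed"),
                      self._path("membership.tsv"))
        return ref_mod.read_reference(self._path("reference.bed"),
                                      self._path("membership.tsv"),
                                      genome=self._genome())

    def _stage_specific(self) -> None:
        inputs = [self._path("reference.bed"), self._path("membership.tsv"),
                  self._path("panel_manifest.tsv")]
        self._require("reference", *inputs[:2])
        self._require("simulate", inputs[2])

        def body() -> List[str]:
            ref = self._load_reference()
            panel = ref_mod.read_peak_manifest(self._path("panel_manifest.tsv"),
                                               genome=self._genome())
            spec = ref_mod.filter_specific_sites(ref, panel,
                                                 self.config.panel_exceptions)
            spec.sites.to_csv(self._path("specific_sites.tsv"), sep="\t", index=False)
            return ["specific_sites.tsv"]
        self._run("specific", inputs, body)

    def _stage_distal(self) -> None:
        inputs = [self._path("reference.bed"), self._path("tss.tsv")]
        self._require("reference", inputs[0])
        self._require("simulate", inputs[1])

        def body() -> List[str]:
            ref = self._load_reference()
            tss = ref_mod.read_tss(self._path("tss.tsv"))
            flags = ref_mod.annotate_distal(ref.sites, tss,
                                            self.config.distal_threshold)
            flags.rename("distal").to_frame().to_csv(
                self._path("distal.tsv"), sep="\t")
            return ["distal.tsv"]
        self._run("distal", inputs, body)

    def _load_distal(self) -> pd.Series:
        self._require("distal", self._path("distal.tsv"))
        df = pd.read_csv(self._path("distal.tsv"), sep="\t", index_col=0)
        return df["distal"].astype("boolean")

    def _stage_loops(self) -> None:
        inputs = [self._path("loops.bedpe"), self._path("reference.bed"),
                  self._path("membership.tsv"), self._path("distal.tsv"),
                  self._path("tss.tsv")]
        self._require("simulate", inputs[0], inputs[4])
        self._require("reference", inputs[1], inputs[2])
        self._require("distal", inputs[3])

        def body() -> List[str]:
            ref = self._load_reference()
            loops = loops_mod.read_bedpe(self._path("loops.bedpe"))
            tss = ref_mod.read_tss(self._path("tss.tsv"))
            anns = loops_mod.classify_loops(loops, ref, self._load_distal(), tss)
            loops_mod.write_annotated_bedpe(anns, self._path("loops_annotated.bedpe"))
            loops_mod.summarize_loops(anns, self.config.loop_fdr) \
                .to_csv(self._path("loop_summary.tsv"), sep="\t", index=False)
            return ["loops_annotated.bedpe", "loop_summary.tsv"]
        self._run("loops", inputs, body)

    def _stage_gwas(self) -> None:
        inputs = [self._path("specific_sites.tsv"), self._path("snps.tsv"),
                  self._path("centromeres.bed"), self._path("chrom.sizes")]
        self._require("specific", inputs[0])
        self._require("simulate", *inputs[1:])

        def body() -> List[str]:
            sites = pd.read_csv(inputs[0], sep="\t", dtype={"chrom": str})
            sites = sites[sites["klass"] == "enhancer"]
            genome = self._genome()
            cfg = gwas_mod.EnrichmentConfig(
                terms=self.config.gwas_terms, window=self.config.gwas_window,
                n_perm=self.config.n_perm, z_threshold=self.config.z_threshold,
                seed=self.config.seed,
                centromeres=read_bed(inputs[2], genome=genome))
            snps = gwas_mod.read_snp_catalog(inputs[1])
            res = gwas_mod.enrichment_z(sites, snps, cfg, genome)
            res.to_csv(self._path("gwas_enrichment.tsv"), sep="\t")
            return ["gwas_enrichment.tsv"]
        self._run("gwas", inputs, body)

    def _stage_regress(self) -> None:
        inputs = [self._path("peak_manifest.tsv"), self._path("tss.tsv"),
                  self._path("expression.tsv")]
        self._require("simulate", *inputs)

        def body() -> List[str]:
            genome = self._genome()
            peaks = ref_mod.read_peak_manifest(inputs[0], genome=genome)
            tss = ref_mod.read_tss(inputs[1])
            # protein-coding autosomal gene universe
            tss = tss[(tss["biotype"] == "protein_coding")
                      & ~tss["chrom"].isin(self.config.sex_chromosomes)]
            by_sample: Dict[str, Dict[str, IntervalSet]] = {}
            for p in peaks:
                by_sample.setdefault(p.sample_id, {})[p.mark] = p.peaks
            feats = {sid: expr_mod.tss_features(
                        m["H3K4me3"], m["H3K27ac"], tss,
                        pseudocount=self.config.pseudocount)
                     for sid, m in sorted(by_sample.items())}
            expr = pd.read_csv(inputs[2], sep="\t", index_col=0)
            logexpr = expr_mod.log_tpm(expr, self.config.pseudocount)
            logexpr = logexpr.loc[logexpr.index.intersection(tss["gene_id"])]
            model = expr_mod.pooled_fit(
                feats, {c: logexpr[c] for c in logexpr.columns})
            with open(self._path("regression_model.json"), "w") as fh:
                json.dump({"a": model.a, "b1": model.b1, "b2": model.b2}, fh)
            corr = expr_mod.predict_correlate(model, feats, logexpr)
            corr.to_csv(self._path("regression_correlation.tsv"), sep="\t")
            return ["regression_model.json", "regression_correlation.tsv"]
        self._run("regress", inputs, body)

    def _stage_diff(self) -> None:
        inputs = [self._path("intensity.tsv"), self._path("groups.tsv")]
        self._require("simulate", *inputs)

        def body() -> List[str]:
            m = pd.read_csv(inputs[0], sep="\t", index_col=0)
            groups = pd.read_csv(inputs[1], sep="\t", index_col=0)["group"].to_dict()
            res = diff_mod.differential_pipeline(
                m, groups, self.config.fdr_threshold, self.config.k,
                self.config.seed, pseudocount=self.config.pseudocount)
            res.table.to_csv(self._path("differential.tsv"), sep="\t")
            if res.z_by_group is not None:
                res.z_by_group.to_csv(self._path("differential_z.tsv"), sep="\t")
            out = ["differential.tsv"]
            if res.z_by_group is not None:
                out.append("differential_z.tsv")
            return out
        self._run("diff", inputs, body)

    def _stage_cluster(self) -> None:
        inputs = [self._path("differential_z.tsv")]
        self._require("diff", *inputs)

        def body() -> List[str]:
            z = pd.read_csv(inputs[0], sep="\t", index_col=0)
            if len(z) < self.config.k:
                logger.warning("fewer significant rows than k: clustering skipped")
                pd.DataFrame(columns=["cluster"]).to_csv(
                    self._path("clusters.tsv"), sep="\t")
                return ["clusters.tsv"]
            labels, objective = diff_mod.kmeans_cluster(
                z, self.config.k, self.config.seed)
            labels.to_frame().to_csv(self._path("clusters.tsv"), sep="\t")
            logger.info("k-means objective: %.3f", objective)
            return ["clusters.tsv"]
        self._run("cluster", inputs, body)


def run_stage(stage: str, config: Optional[PipelineConfig] = None) -> None:
    """Run one named stage (or 'all') under the given configuration."""
    Pipeline(config).run_stage(stage)
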