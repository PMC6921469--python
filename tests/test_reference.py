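"""Reference-site assembly: classification, per-type intersection, merging,
membership, specificity filtering and distal annotation."""

import numpy as np
import pandas as pd
import pytest

from ecepi.intervals import GenomicInterval, IntervalSet
from ecepi.reference import (
    ClassifiedSites,
    SamplePeaks,
    annotate_distal,
    build_celltype_reference,
    build_merged_reference,
    classify_sample_sites,
    filter_specific_sites,
    read_reference,
    shared_ratio,
    write_reference,
)

from conftest import coverage_mask

GENOME = {"toy": 100_000, "chrX": 100_000}


def peaks(sample, mark, *pairs, cell_type="A", chrom="toy"):
    return SamplePeaks(sample, cell_type, mark,
                       IntervalSet([GenomicInterval(chrom, a, b) for a, b in pairs],
                                   genome=GENOME))


def iset(*pairs, chrom="toy"):
    return IntervalSet([GenomicInterval(chrom, a, b) for a, b in pairs],
                       genome=GENOME)


class TestClassify:
    def test_one_bp_overlap_makes_promoter(self):
        cls = classify_sample_sites(peaks("s", "H3K4me3", (1000, 2000)),
                                    peaks("s", "H3K27ac", (1999, 2500)))
        assert cls.promoters == iset((1000, 2000))
        assert len(cls.enhancers) == 0

    def test_k27_only_is_enhancer(self):
        cls = classify_sample_sites(peaks("s", "H3K4me3"),
                                    peaks("s", "H3K27ac", (5000, 6000)))
        assert len(cls.promoters) == 0
        assert cls.enhancers == iset((5000, 6000))

    def test_k4_only_dropped(self):
        cls = classify_sample_sites(peaks("s", "H3K4me3", (100, 200)),
                                    peaks("s", "H3K27ac"))
        assert len(cls.promoters) == 0 and len(cls.enhancers) == 0

    def test_mark_and_sample_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mark"):
            classify_sample_sites(peaks("s", "H3K27ac", (0, 10)),
                                  peaks("s", "H3K27ac", (0, 10)))
        with pytest.raises(ValueError, match="sample_id"):
            classify_sample_sites(peaks("s1", "H3K4me3", (0, 10)),
                                  peaks("s2", "H3K27ac", (0, 10)))

    def test_matches_brute_force_and_classes_disjoint(self, rng):
        for _ in range(10):
            def rand(sample, mark):
                pr = [(int(s), int(s) + int(w)) for s, w in zip(
                    rng.integers(0, 9_000, 30), rng.integers(50, 400, 30))]
                return peaks(sample, mark, *pr)
            k4, k27 = rand("s", "H3K4me3"), rand("s", "H3K27ac")
            cls = classify_sample_sites(k4, k27)
            k4n, k27n = k4.peaks, k27.peaks  # normalized by SamplePeaks
            for iv in k4n:
                hits = any(min(iv.end, o.end) - max(iv.start, o.start) >= 1
                           for o in k27n)
                got = any(iv.start == p.start and iv.end == p.end
                          for p in cls.promoters)
                assert got == hits
            for iv in k27n:
                hits = any(min(iv.end, o.end) - max(iv.start, o.start) >= 1
                           for o in k4n)
                got = any(iv.start == e.start and iv.end == e.end
                          for e in cls.enhancers)
                assert got == (not hits)
            # promoters and enhancers never share a base
            pm = coverage_mask(cls.promoters, 10_000).get("toy", np.zeros(10_000, bool))
            em = coverage_mask(cls.enhancers, 10_000).get("toy", np.zeros(10_000, bool))
            assert not (pm & em).any()


def classified(sample, proms, enhs, cell_type="A"):
    return ClassifiedSites(sample, cell_type, iset(*proms), iset(*enhs))


class TestCelltypeReference:
    def test_identical_samples_identity(self):
        s = [(1000, 2000), (5000, 5500)]
        ref = build_celltype_reference([classified("a", s, []),
                                        classified("b", s, [])])
        assert ref["promoter"] == iset(*s)

    def test_intersection(self):
        ref = build_celltype_reference([classified("a", [(0, 100)], []),
                                        classified("b", [(50, 150)], [])])
        assert ref["promoter"] == iset((50, 100))

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError):
            build_celltype_reference([])

    def test_sex_chromosomes_removed(self):
        cs = ClassifiedSites("a", "A",
                             IntervalSet([GenomicInterval("chrX", 0, 100),
                                          GenomicInterval("toy", 0, 100)],
                                         genome=GENOME),
                             IntervalSet(genome=GENOME))
        ref = build_celltype_reference([cs])
        assert ref["promoter"].chroms == ["toy"]

    def test_jittered_donors_recover_planted_cores(self, rng):
        planted = [(i * 5000 + 1000, i * 5000 + 2000) for i in range(20)]
        donors = []
        for d in range(3):
            jit = [(a + int(rng.integers(-30, 31)), b + int(rng.integers(-30, 31)))
                   for a, b in planted]
            donors.append(classified(f"d{d}", jit, []))
        ref = build_celltype_reference(donors)
        got = ref["promoter"].arrays("toy")
        assert got.shape[0] == 20
        # every recovered core lies within the planted site +/- jitter bound
        for (gs, ge), (ps, pe) in zip(got, planted):
            assert ps - 30 <= gs <= ps + 30 and pe - 30 <= ge <= pe + 30


class TestMergedReference:
    def test_single_type_all_member(self):
        ref = build_merged_reference(
            {"A": {"promoter": iset((0, 100)), "enhancer": iset((500, 600))}})
        assert len(ref.sites) == 2
        assert ref.membership.to_numpy().all()

    def test_nearby_sites_merge_with_joint_membership(self):
        ref = build_merged_reference({
            "A": {"promoter": iset((0, 100)), "enhancer": IntervalSet(genome=GENOME)},
            "B": {"promoter": iset((150, 250)), "enhancer": IntervalSet(genome=GENOME)},
        }, merge_gap=100)
        proms = ref.class_sites("promoter")
        assert len(proms) == 1
        assert proms.iloc[0]["start"] == 0 and proms.iloc[0]["end"] == 250
        assert ref.membership.iloc[0].all()

    def test_synthetic_membership_matches_planted_design(self, dataset):
        from ecepi.reference import classify_sample_sites as classify
        by_type = {}
        by_sample = {}
        for p in dataset.sample_peaks:
            by_sample.setdefault(p.sample_id, {})[p.mark] = p
        for sid, marks in by_sample.items():
            cls = classify(marks["H3K4me3"], marks["H3K27ac"])
            by_type.setdefault(marks["H3K4me3"].cell_type, []).append(cls)
        per_type = {ct: build_celltype_reference(s) for ct, s in by_type.items()}
        ref = build_merged_reference(per_type)
        assert len(ref.sites) == len(dataset.truth_sites)
        # align recovered sites to truth by class + edge proximity: the
        # merged site is a union over jittered donor peaks, so each edge may
        # sit on either side of the planted edge by at most the jitter range
        truth = dataset.truth_sites
        mem = dataset.truth_membership
        matched = 0
        for _, site in ref.sites.iterrows():
            cand = truth[(truth["klass"] == site["klass"])
                         & (truth["chrom"] == site["chrom"])
                         & ((truth["start"] - site["start"]).abs() <= 100)
                         & ((truth["end"] - site["end"]).abs() <= 100)]
            assert len(cand) == 1
            want = mem.loc[cand.iloc[0]["site_id"]]
            got = ref.membership.loc[site["site_id"]]
            assert (got[want.index] == want).all()
            matched += 1
        assert matched == len(truth)


class TestSharedRatio:
    def test_counting(self):
        ref = build_merged_reference({
            ct: {"promoter": s, "enhancer": IntervalSet(genome=GENOME)}
            for ct, s in {
                "A": iset((0, 10), (100, 110), (200, 210)),
                "B": iset((100, 110)),
            }.items()
        }, merge_gap=0)
        hist = shared_ratio(ref)["promoter"]
        assert hist.loc[1] == pytest.approx(2 / 3)
        assert hist.loc[2] == pytest.approx(1 / 3)
        assert hist.sum() == pytest.approx(1.0)

    def test_all_shared_mass_at_T(self, dataset):
        # shared-core truth sites occupy the full-membership bin by design
        from ecepi.reference import ReferenceSiteSet
        truth = dataset.truth_sites
        ref = ReferenceSiteSet(truth.rename(columns={})[
            ["site_id", "chrom", "start", "end", "klass"]],
            dataset.truth_membership, list(dataset.truth_membership.columns))
        hist = shared_ratio(ref)
        T = len(dataset.truth_membership.columns)
        n_shared_prom = dataset.design.n_shared_promoters
        n_prom = (truth["klass"] == "promoter").sum()
        assert hist["promoter"].loc[T] == pytest.approx(n_shared_prom / n_prom)


class TestSpecificityFilter:
    def _ref(self):
        return build_merged_reference({
            "A": {"promoter": iset((0, 100)),
                  "enhancer": iset((1000, 1100), (2000, 2100))}})

    def test_empty_panel_identity(self):
        ref = self._ref()
        with pytest.warns(UserWarning):
            spec = filter_specific_sites(ref, [])
        assert len(spec) == len(ref)

    def test_one_bp_overlap_removes(self):
        spec = filter_specific_sites(
            self._ref(), [peaks("E001", "H3K27ac", (1099, 1200))])
        assert "enh" not in " ".join(
            spec.sites.loc[spec.sites["start"] == 1000, "site_id"])
        assert len(spec) == 2  # promoter + other enhancer kept

    def test_exception_member_ignored(self):
        panel = [peaks("E122", "H3K27ac", (1000, 1100), (2000, 2100))]
        spec = filter_specific_sites(self._ref(), panel, exceptions=["E122"])
        assert len(spec) == 3

    def test_mark_matching(self):
        # a panel H3K4me3 peak overlapping an enhancer site removes nothing
        spec = filter_specific_sites(
            self._ref(), [peaks("E001", "H3K4me3", (1000, 1100))])
        assert len(spec) == 3
        # but the same peak over the promoter site removes the promoter only
        spec = filter_specific_sites(
            self._ref(), [peaks("E001", "H3K4me3", (50, 150))])
        assert len(spec) == 2
        assert set(spec.sites["klass"]) == {"enhancer"}

    def test_anti_monotone_in_panel_size(self, rng):
        ref = self._ref()
        p1 = [peaks("E001", "H3K27ac", (1000, 1100))]
        p2 = p1 + [peaks("E002", "H3K4me3", (0, 50))]
        assert len(filter_specific_sites(ref, p2)) <= len(
            filter_specific_sites(ref, p1))

    def test_planted_private_sites_survive_exactly(self, dataset):
        from ecepi.reference import ReferenceSiteSet
        truth = dataset.truth_sites
        ref = ReferenceSiteSet(
            truth[["site_id", "chrom", "start", "end", "klass"]],
            dataset.truth_membership, list(dataset.truth_membership.columns))
        spec = filter_specific_sites(ref, dataset.panel_peaks,
                                     exceptions=dataset.design.panel_exceptions)
        expect = set(truth.loc[~truth["panel_ubiquitous"], "site_id"])
        assert set(spec.sites["site_id"]) == expect


class TestDistal:
    def _sites(self, *rows):
        return pd.DataFrame(rows, columns=["site_id", "chrom", "start", "end"])

    def _tss(self, *rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos",
                                           "strand", "biotype"])

    def test_strictly_greater_than_threshold(self):
        sites = self._sites(("s1", "toy", 112_000, 113_000),
                            ("s2", "toy", 110_000, 110_500))
        tss = self._tss(("g", "toy", 100_000, "+", "protein_coding"))
        flags = annotate_distal(sites, tss, threshold=10_000)
        assert flags["s1"] == True  # 12 kb away
        assert flags["s2"] == False  # exactly 10 kb: not distal

    def test_no_tss_chromosome_is_missing(self):
        sites = self._sites(("s1", "other", 0, 100))
        tss = self._tss(("g", "toy", 5, "+", "protein_coding"))
        flags = annotate_distal(sites, tss)
        assert flags["s1"] is pd.NA

    def test_matches_brute_force(self, rng):
        tss_rows = [(f"g{i}", "toy", int(p), "+", "protein_coding")
                    for i, p in enumerate(rng.integers(0, 90_000, size=6))]
        tss = self._tss(*tss_rows)
        site_rows = []
        for i in range(25):
            st = int(rng.integers(0, 89_000))
            site_rows.append((f"s{i}", "toy", st, st + int(rng.integers(1, 900))))
        sites = self._sites(*site_rows)
        flags = annotate_distal(sites, tss, threshold=10_000)
        for sid, chrom, st, en in site_rows:
            brute = min(0 if st <= p < en else min(abs(p - st), abs(p - (en - 1)))
                        for p in tss["pos"])
            assert flags[sid] == (brute > 10_000)


def test_reference_io_round_trip(tmp_path, dataset):
    from ecepi.reference import ReferenceSiteSet
    truth = dataset.truth_sites
    ref = ReferenceSiteSet(
        truth[["site_id", "chrom", "start", "end", "klass"]].copy(),
        dataset.truth_membership, list(dataset.truth_membership.columns))
    bed, mem = tmp_path / "r.bed", tmp_path / "m.tsv"
    write_reference(ref, str(bed), str(mem))
    back = read_reference(str(bed), str(mem))
    assert (back.sites[["site_id", "chrom", "start", "end", "klass"]].to_numpy()
            == ref.sites[["site_id", "chrom", "start", "end", "klass"]].to_numpy()).all()
    assert back.membership.equals(ref.membership)
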