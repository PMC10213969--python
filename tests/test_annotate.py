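"""Post-hoc annotation: GTF loading, largest-overlap assignment, summation."""

import numpy as np
import pandas as pd
import pytest

import regionsift as rs
from regionsift.annotate import AnnotationParseError, UNANNOTATED, biotype_fractions
from regionsift.regions import Region, RegionSet
from conftest import make_reads


def gtf(tmp_path, lines, name="ann.gtf"):
    path = tmp_path / name
    path.write_text("".join(lines))
    return str(path)


def gtf_line(gid, start, end, kind="gene", contig="c1", biotype=None):
    attrs = f'gene_id "{gid}";'
    if biotype:
        attrs += f' gene_type "{biotype}";'
    return f"{contig}\tsrc\t{kind}\t{start}\t{end}\t.\t+\t.\t{attrs}\n"


def regions_from(spans, contig="c1"):
    return RegionSet([Region(Region.make_id(contig, s, e), contig, s, e) for s, e in spans])


class TestLoadAnnotation:
    def test_one_based_inclusive_to_half_open(self, tmp_path):
        ann = rs.load_annotation(gtf(tmp_path, [gtf_line("g1", 101, 200)]))
        assert (ann.at["g1", "start"], ann.at["g1", "end"]) == (100, 200)

    def test_non_gene_records_skipped(self, tmp_path):
        ann = rs.load_annotation(
            gtf(tmp_path, [gtf_line("g1", 1, 50), gtf_line("g1", 1, 50, kind="exon")])
        )
        assert list(ann.index) == ["g1"]

    def test_duplicate_gene_id_is_error(self, tmp_path):
        path = gtf(tmp_path, [gtf_line("g1", 1, 50), gtf_line("g1", 60, 90)])
        with pytest.raises(AnnotationParseError, match="duplicate gene_id"):
            rs.load_annotation(path)

    def test_missing_gene_id_reports_line(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("c1\tsrc\tgene\t1\t50\t.\t+\t.\tfoo \"bar\";\n")
        with pytest.raises(AnnotationParseError, match=":1"):
            rs.load_annotation(str(path))

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        with caplog.at_level("WARNING"):
            ann = rs.load_annotation(str(path))
        assert ann.empty and caplog.records

    def test_biotype_attribute(self, tmp_path):
        ann = rs.load_annotation(
            gtf(tmp_path, [gtf_line("g1", 1, 50, biotype="miRNA"), gtf_line("g2", 100, 160)])
        )
        assert ann.at["g1", "biotype"] == "miRNA"
        assert ann.at["g2", "biotype"] == "unknown"


class TestAssignRegions:
    def ann(self, tmp_path, spans):
        lines = [gtf_line(gid, s + 1, e) for gid, (s, e) in spans.items()]
        return rs.load_annotation(gtf(tmp_path, lines))

    def test_largest_overlap_wins(self, tmp_path):
        ann = self.ann(tmp_path, {"A": (0, 60), "B": (70, 200)})
        asg = rs.assign_regions(regions_from([(40, 80)]), ann)
        # overlap A = 20, overlap B = 10
        assert asg.iloc[0]["feature_id"] == "A"
        assert asg.iloc[0]["overlap_bp"] == 20

    def test_tie_breaks_to_smallest_id(self, tmp_path):
        # region [50,80): overlap 10 with both A=[0,60) and B=[70,200)
        ann = self.ann(tmp_path, {"B": (70, 200), "A": (0, 60)})
        asg = rs.assign_regions(regions_from([(50, 80)]), ann)
        assert asg.iloc[0]["feature_id"] == "A"

    def test_no_overlap_unannotated(self, tmp_path):
        ann = self.ann(tmp_path, {"A": (82, 120)})
        asg = rs.assign_regions(regions_from([(50, 80)]), ann)
        assert asg.iloc[0]["feature_id"] == UNANNOTATED

    def test_overlap_below_minimum_unannotated(self, tmp_path):
        ann = self.ann(tmp_path, {"A": (76, 120)})
        asg = rs.assign_regions(regions_from([(50, 80)]), ann,
                                rs.CountingPolicy(min_overlap=5))
        assert asg.iloc[0]["feature_id"] == UNANNOTATED  # overlap 4 < 5

    def test_every_region_assigned_once(self, tmp_path):
        ann = self.ann(tmp_path, {"A": (0, 100), "B": (200, 300)})
        regions = regions_from([(10, 40), (150, 180), (210, 260)])
        asg = rs.assign_regions(regions, ann)
        assert sorted(asg.index) == sorted(regions.ids)
        assert not asg.index.duplicated().any()


class TestSummarizeToFeatures:
    def test_region_rows_sum_to_feature(self):
        counts = pd.DataFrame(
            [[10, 20, 5], [1, 0, 2], [7, 7, 7]],
            index=["r1", "r2", "r3"], columns=["a", "b", "c"],
        )
        asg = pd.DataFrame(
            {"feature_id": ["G", "G", UNANNOTATED], "overlap_bp": [9, 9, 0],
             "biotype": ["x", "x", ""]},
            index=pd.Index(["r1", "r2", "r3"], name="region_id"),
        )
        feat, orphan = rs.summarize_to_features(counts, asg)
        assert feat.loc["G"].tolist() == [11, 20, 7]
        assert list(orphan.index) == ["r3"]

    def test_all_unannotated(self):
        counts = pd.DataFrame([[1, 2]], index=["r1"], columns=["a", "b"])
        asg = pd.DataFrame(
            {"feature_id": [UNANNOTATED], "overlap_bp": [0], "biotype": [""]},
            index=pd.Index(["r1"], name="region_id"),
        )
        feat, orphan = rs.summarize_to_features(counts, asg)
        assert feat.empty and len(orphan) == 1

    def test_missing_assignment_is_error(self):
        counts = pd.DataFrame([[1]], index=["r1"], columns=["a"])
        asg = pd.DataFrame(
            {"feature_id": [], "overlap_bp": [], "biotype": []},
            index=pd.Index([], name="region_id"),
        )
        with pytest.raises(ValueError, match="no assignment"):
            rs.summarize_to_features(counts, asg)

    def test_matches_groupby_oracle_on_random_instance(self):
        rng = np.random.default_rng(5)
        n = 40
        counts = pd.DataFrame(rng.integers(0, 30, (n, 4)),
                              index=[f"r{i}" for i in range(n)],
                              columns=list("abcd"))
        fids = rng.choice(["G1", "G2", "G3", UNANNOTATED], size=n)
        asg = pd.DataFrame({"feature_id": fids, "overlap_bp": 9, "biotype": ""},
                           index=pd.Index(counts.index, name="region_id"))
        feat, orphan = rs.summarize_to_features(counts, asg)
        for g in ["G1", "G2", "G3"]:
            expected = counts[fids == g].sum()
            if g in feat.index:
                assert (feat.loc[g] == expected).all()
            else:
                assert (fids == g).sum() == 0
        assert len(orphan) == (fids == UNANNOTATED).sum()


class TestCountFeaturesDirect:
    def test_single_read_single_gene(self, tmp_path):
        ann = rs.load_annotation(gtf(tmp_path, [gtf_line("g1", 1, 100),
                                                gtf_line("g2", 201, 300)]))
        counts = rs.count_features_direct({"s": make_reads([(10, 32)])}, ann)
        assert counts.loc["g1", "s"] == 1 and counts.loc["g2", "s"] == 0

    def test_read_spanning_two_genes_counts_both(self, tmp_path):
        ann = rs.load_annotation(gtf(tmp_path, [gtf_line("g1", 1, 20),
                                                gtf_line("g2", 26, 100)]))
        # read [10,32): overlap g1 = 10, overlap g2 = 7, both >= 5
        counts = rs.count_features_direct({"s": make_reads([(10, 32)])}, ann,
                                          rs.CountingPolicy(min_overlap=5))
        assert counts["s"].tolist() == [1, 1]

    def test_matches_bruteforce_interval_scan(self, tmp_path):
        rng = np.random.default_rng(6)
        genes = {f"g{i}": (int(s), int(s) + int(rng.integers(30, 80)))
                 for i, s in enumerate(sorted(rng.choice(900, 8, replace=False) * 1))}
        ann = rs.load_annotation(
            gtf(tmp_path, [gtf_line(g, s + 1, e) for g, (s, e) in genes.items()])
        )
        reads = [(int(s), int(s) + 22) for s in rng.integers(0, 950, 100)]
        counts = rs.count_features_direct({"s": make_reads(reads)}, ann,
                                          rs.CountingPolicy(min_overlap=5))
        for g, (s, e) in genes.items():
            brute = sum(min(e, re) - max(s, rstart) >= 5 for rstart, re in reads)
            assert counts.at[g, "s"] == brute


class TestPathEquivalence:
    def test_find_then_annotate_equals_direct_counting(self, small_experiment):
        """With deep coverage and max_gap=0 the called regions tile every
        feature, so summing region counts to genes reproduces direct read
        summarization cell for cell."""
        reads, policy = small_experiment["reads"], small_experiment["policy"]
        regions = rs.call_regions(small_experiment["track"],
                                  rs.SegmentationParams(cutoff=1, max_gap=0))
        ann = rs.load_annotation(small_experiment["gtf"])
        assignment = rs.assign_regions(regions, ann, policy)
        region_counts = rs.count_regions(regions, reads, policy)
        feat, _ = rs.summarize_to_features(region_counts, assignment)
        direct = rs.count_features_direct(reads, ann, policy)
        assert set(feat.index) == set(direct.index)
        assert feat.sort_index().equals(direct.sort_index())


class TestBiotypeFractions:
    def test_fractions_sum_to_one(self):
        counts = pd.DataFrame([[10, 10], [5, 5], [0, 10]],
                              index=["r1", "r2", "r3"], columns=["a", "b"])
        asg = pd.DataFrame(
            {"feature_id": ["G1", UNANNOTATED, "G2"], "overlap_bp": [9, 0, 9],
             "biotype": ["miRNA", "", "lncRNA"]},
            index=pd.Index(["r1", "r2", "r3"], name="region_id"),
        )
        frac = biotype_fractions(counts, asg)
        assert frac.sum() == pytest.approx(1.0)
        assert frac["unannotated"] == pytest.approx(10 / 40)
        assert frac["miRNA"] == pytest.approx(20 / 40)
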