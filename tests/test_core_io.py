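"""Interval algebra and plain-text IO."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromtraj.core_io import (
    FeatureIndex,
    GeneAnnotation,
    GenomicInterval,
    SignalTrack,
    annotate_feature,
    annotate_features,
    intersect_counts,
    merge_intervals,
    nearest_tss,
    parse_bed,
    parse_bedgraph,
    read_annotation,
    write_annotation,
    write_bed,
    write_bedgraph,
)
from conftest import random_genes, random_intervals
from oracles import intersect_oracle, merge_oracle, nearest_oracle


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 100)

    def test_length_and_midpoint(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert len(iv) == 100 and iv.midpoint == 150
        assert iv.region_id == "chr1:100-200"


class TestBedIO:
    def test_parse_roundtrip(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# comment\nchr1\t100\t200\nchr2\t0\t50\tpk1\t3.5\n")
        ivs = parse_bed(p)
        assert ivs == [GenomicInterval("chr1", 100, 200), GenomicInterval("chr2", 0, 50)]
        assert ivs[1].name == "pk1" and ivs[1].score == 3.5
        out = tmp_path / "b.bed"
        write_bed(ivs, out)
        assert parse_bed(out) == ivs

    def test_malformed_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(ValueError, match="bad.bed:1"):
            parse_bed(p)

    def test_bedgraph_roundtrip_and_bin_check(self, tmp_path):
        track = SignalTrack(data={"chr1": np.array([0.0, 2.0, 2.0, 5.0])},
                            library_total=100.0)
        p = tmp_path / "t.bedGraph"
        write_bedgraph(track, p)
        back = parse_bedgraph(p, library_total=100.0)
        np.testing.assert_array_equal(back.data["chr1"], track.data["chr1"])
        q = tmp_path / "off.bedGraph"
        q.write_text("chr1\t10\t35\t1.0\n")  # not aligned to 25-bp grid
        with pytest.raises(ValueError, match="25-bp"):
            parse_bedgraph(q)

    def test_annotation_roundtrip(self, tmp_path):
        genes = [GeneAnnotation("A", "chr1", "+", 100,
                                GenomicInterval("chr1", 100, 3000),
                                {"5utr": [(100, 200)], "exon": [(100, 500), (2500, 3000)]}),
                 GeneAnnotation("B", "chr2", "-", 999,
                                GenomicInterval("chr2", 0, 1000))]
        p = tmp_path / "ann.tsv"
        write_annotation(genes, p)
        back = read_annotation(p)
        assert [g.gene_id for g in back] == ["A", "B"]
        assert back[0].features == genes[0].features
        assert back[1].tss == 999 and back[1].strand == "-"


class TestMerge:
    def test_gap_boundary_semantics(self):
        a, b = GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400)
        assert merge_intervals([a, b], 100) == [GenomicInterval("chr1", 100, 400)]
        c = GenomicInterval("chr1", 301, 400)
        assert merge_intervals([a, c], 100) == [a, c]
        assert merge_intervals([a], 0) == [a]
        assert merge_intervals([], 5) == []

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            ivs = random_intervals(rng, int(rng.integers(1, 60)))
            gap = int(rng.integers(0, 150))
            assert merge_intervals(ivs, gap) == merge_oracle(ivs, gap)

    def test_matches_bedtools(self, tmp_path):
        if shutil.which("bedtools") is None:
            pytest.skip("bedtools unavailable")
        rng = np.random.default_rng(5)
        ivs = sorted(random_intervals(rng, 80, chroms=("chr1",)))
        bed = tmp_path / "in.bed"
        write_bed(ivs, bed)
        res = subprocess.run(["bedtools", "merge", "-d", "100", "-i", str(bed)],
                             capture_output=True, text=True, check=True)
        expected = []
        for line in res.stdout.strip().split("\n"):
            chrom, s, e = line.split("\t")
            expected.append(GenomicInterval(chrom, int(s), int(e)))
        assert merge_intervals(ivs, 100) == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3000), st.integers(1, 200)),
                    min_size=1, max_size=30),
           st.integers(0, 120))
    def test_idempotent(self, pairs, gap):
        ivs = [GenomicInterval("chrX", s, s + l) for s, l in pairs]
        once = merge_intervals(ivs, gap)
        assert merge_intervals(once, gap) == once


class TestIntersect:
    def test_examples(self):
        a = [GenomicInterval("chr1", 0, 10)]
        b = [GenomicInterval("chr1", 5, 15)]
        v = intersect_counts(a, b)
        assert (v.shared_a, v.a_only) == (1, 0)
        # half-open abutment does not overlap
        v2 = intersect_counts(a, [GenomicInterval("chr1", 10, 20)])
        assert v2.shared_a == 0 and v2.a_only == 1

    def test_rejects_internal_overlap(self):
        a = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 20)]
        with pytest.raises(ValueError, match="merge first"):
            intersect_counts(a, [GenomicInterval("chr1", 0, 5)])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            a = merge_intervals(random_intervals(rng, 50), 0)
            b = merge_intervals(random_intervals(rng, 50), 0)
            mo = int(rng.integers(1, 40))
            v = intersect_counts(a, b, min_overlap_bp=mo)
            sa, sb = intersect_oracle(a, b, min_overlap_bp=mo)
            assert (v.shared_a, v.shared_b) == (sa, sb)
            assert v.a_only + v.shared_a == len(a)
            assert v.b_only + v.shared_b == len(b)


class TestNearestTss:
    def test_inside_region_distance_zero(self):
        genes = [GeneAnnotation("g1", "chr1", "+", 1100,
                                GenomicInterval("chr1", 1100, 2100))]
        links = nearest_tss([GenomicInterval("chr1", 1000, 1200)], genes)
        assert links[0].gene_id == "g1" and links[0].distance == 0

    def test_beyond_10kb_unlinked(self):
        genes = [GeneAnnotation("g1", "chr1", "+", 20000,
                                GenomicInterval("chr1", 20000, 21000))]
        assert nearest_tss([GenomicInterval("chr1", 0, 100)], genes) == []

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(77)
        genes = random_genes(rng, 20)
        regions = random_intervals(rng, 100, span=40_000)
        links = {l.region.region_id: (l.gene_id, l.distance)
                 for l in nearest_tss(regions, genes)}
        for r in regions:
            expected = nearest_oracle(r, genes, 10_000)
            assert links.get(r.region_id) == expected


class TestFeatureAnnotation:
    @pytest.fixture()
    def genes(self):
        return [GeneAnnotation(
            "g1", "chr1", "+", 10_000, GenomicInterval("chr1", 10_000, 20_000),
            {"5utr": [(10_000, 10_200)], "exon": [(10_000, 11_000), (19_000, 20_000)],
             "3utr": [(19_800, 20_000)]})]

    def test_promoter_upstream_window(self, genes):
        # midpoint 300 bp upstream of the + strand TSS
        assert annotate_feature(GenomicInterval("chr1", 9600, 9800), genes) == "promoter"

    def test_promoter_beats_exon(self, genes):
        # midpoint 10_100: inside 5'UTR, exon AND the promoter window
        assert annotate_feature(GenomicInterval("chr1", 10_050, 10_150), genes) == "promoter"

    def test_intron_inferred_from_gene_body(self, genes):
        assert annotate_feature(GenomicInterval("chr1", 14_000, 14_200), genes) == "intron"

    def test_intergenic_far_away(self, genes):
        assert annotate_feature(GenomicInterval("chr1", 50_000, 50_100), genes) == "intergenic"

    def test_tts_window(self, genes):
        assert annotate_feature(GenomicInterval("chr1", 20_150, 20_450), genes) == "tts"

    def test_counts_sum_to_atlas_size(self, genes):
        rng = np.random.default_rng(3)
        regions = random_intervals(rng, 120, chroms=("chr1",), span=60_000)
        counts = annotate_features(regions, FeatureIndex(genes))
        assert sum(counts.values()) == len(regions)
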