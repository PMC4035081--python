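"""Candidate-site calling: block selection, clustering, classification."""
import numpy as np
import pandas as pd
import pytest

from conftest import random_orphan_table
from tglocate.errors import ParameterError
from tglocate.significance import ThresholdSet
from tglocate.sites import (
    CLEAN,
    TRANS,
    UNPAIRED,
    WITH_DELETION,
    Cluster,
    call_blocks,
    classify,
    estimate_breakpoint,
    merge_clusters,
    write_outputs,
)
from tglocate.tiss import BlockIndex, ScoreTable


def _scores(entries, lengths=None):
    lengths = lengths or {"chr1": 1_000_000, "chr2": 1_000_000}
    blocks = pd.DataFrame(entries, columns=["chrom", "block", "score"])
    return ScoreTable(blocks, BlockIndex(lengths, 1000))


def _reads(positions, chrom="chr1", strand="+"):
    rng = np.random.default_rng(0)
    df = random_orphan_table(rng, len(positions), chroms=(chrom,), max_pos=10)
    df["host_pos"] = positions
    df["host_strand"] = strand if isinstance(strand, str) else list(strand)
    df["host_mapq"] = 60
    df["tg_mapq"] = 60
    return df


class TestCallBlocks:
    def test_all_below_threshold_keeps_top_k_flagged_false(self):
        scores = _scores([("chr1", i, i + 1) for i in range(8)])
        out = call_blocks(scores, threshold=100, top_k=5)
        assert len(out) == 5
        assert not out["above_threshold"].any()
        assert set(out["score"]) == {4, 5, 6, 7, 8}

    def test_block_above_threshold_flagged_true(self):
        out = call_blocks(_scores([("chr1", 1, 2), ("chr1", 9, 50)]), threshold=10)
        assert bool(out.loc[out["block"] == 9, "above_threshold"].item()) is True

    def test_flag_partition_matches_oracle(self):
        rng = np.random.default_rng(1)
        entries = [("chr1", int(b), int(s)) for b, s in
                   zip(rng.choice(500, 60, replace=False), rng.integers(1, 30, 60))]
        scores = _scores(entries)
        out = call_blocks(scores, threshold=12, top_k=5)
        oracle_sig = {(c, b) for c, b, s in entries if s >= 12}
        got_sig = {
            (r.chrom, r.block) for r in out.itertuples() if r.above_threshold
        }
        assert got_sig == oracle_sig
        assert ((out["score"] >= 12) == out["above_threshold"]).all()

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ParameterError):
            call_blocks(_scores([("chr1", 1, 2)]), threshold=0)


class TestMergeClusters:
    def test_adjacent_blocks_merge(self):
        scores = _scores([("chr1", 97_165 % 1000, 3)], {"chr1": 100_000_000})
        blocks = pd.DataFrame(
            [("chr1", 97_165, 3), ("chr1", 97_166, 2)],
            columns=["chrom", "block", "score"],
        )
        reads = _reads([97_165_500, 97_166_200])
        index = BlockIndex({"chr1": 100_000_000}, 1000)
        clusters = merge_clusters(blocks, reads, index)
        assert len(clusters) == 1
        assert clusters[0].max_block_score == 3
        assert clusters[0].n_reads == 2

    def test_distant_blocks_stay_separate(self):
        blocks = pd.DataFrame(
            [("chr1", 100, 5), ("chr1", 111, 4)],  # ~11 kb apart
            columns=["chrom", "block", "score"],
        )
        reads = _reads([100_500, 111_500])
        index = BlockIndex({"chr1": 1_000_000}, 1000)
        clusters = merge_clusters(blocks, reads, index, max_gap=2000)
        assert len(clusters) == 2

    def test_hull_contains_every_member_read(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.integers(50_001, 53_000, size=40))
        blocks = pd.DataFrame(
            [("chr1", 50, 10), ("chr1", 51, 10), ("chr1", 52, 10)],
            columns=["chrom", "block", "score"],
        )
        reads = _reads(pos)
        index = BlockIndex({"chr1": 1_000_000}, 1000)
        (cluster,) = merge_clusters(blocks, reads, index)
        assert cluster.start <= pos.min() - 1
        assert cluster.end >= pos.max() - 1 + 100
        assert cluster.n_reads == 40

    def test_cluster_hulls_never_overlap(self):
        rng = np.random.default_rng(3)
        bl = sorted(rng.choice(300, size=25, replace=False))
        blocks = pd.DataFrame(
            [("chr1", int(b), 2) for b in bl], columns=["chrom", "block", "score"]
        )
        reads = _reads([int(b) * 1000 + 500 for b in bl])
        index = BlockIndex({"chr1": 1_000_000}, 1000)
        clusters = sorted(merge_clusters(blocks, reads, index), key=lambda c: c.start)
        for a, b in zip(clusters, clusters[1:]):
            assert a.end <= b.start


class TestClassify:
    def _index(self):
        return BlockIndex({"chr1": 1_000_000, "chr2": 1_000_000}, 1000)

    def test_compact_single_cluster_is_clean_insertion(self):
        reads = _reads(list(range(50_001, 53_901, 100)), strand="+")
        c = Cluster("chr1", 50_000, 54_000, 39, 20, 39, 0)
        (site,) = classify([c], reads, self._index(), frag_mean=3800)
        assert site.classification == CLEAN

    def test_wide_single_cluster_is_unpaired(self):
        c = Cluster("chr1", 50_000, 60_000, 5, 5, 5, 0)
        reads = _reads([51_000, 52_000, 55_000, 58_000, 59_000])
        (site,) = classify([c], reads, self._index(), frag_mean=3800)
        assert site.classification == UNPAIRED

    def test_two_linked_clusters_infer_deletion_length(self):
        left = Cluster("chr1", 96_000, 100_000, 10, 8, 0, 10)
        right = Cluster("chr1", 111_456, 115_000, 10, 8, 10, 0)
        reads = pd.concat(
            [
                _reads(list(range(96_001, 99_902, 400)), strand="-"),
                _reads(list(range(111_457, 114_958, 350)), strand="+"),
            ],
            ignore_index=True,
        )
        (site,) = classify(
            [left, right], reads, self._index(), frag_mean=3800,
            pair_distance_max=19_000, orientation="rf",
        )
        assert site.classification == WITH_DELETION
        assert site.inferred_deletion_len == 111_456 - 100_000
        assert len(site.breakpoint_intervals) == 2

    def test_clusters_on_two_chromosomes_are_trans(self):
        c1 = Cluster("chr1", 10_000, 12_000, 3, 3, 3, 0)
        c2 = Cluster("chr2", 50_000, 52_000, 3, 3, 3, 0)
        reads = pd.concat(
            [_reads([10_500, 11_000, 11_500]), _reads([50_500, 51_000, 51_500], chrom="chr2")],
            ignore_index=True,
        )
        sites = classify([c1, c2], reads, self._index(), frag_mean=3800)
        assert {s.classification for s in sites} == {TRANS}
        assert all(s.trans for s in sites)


class TestEstimateBreakpoint:
    def _index(self):
        return BlockIndex({"chr1": 1_000_000}, 1000)

    def test_plus_dominant_fr_interval_starts_at_rightmost_end(self):
        pos = [10_001, 10_201, 10_401]  # starts 10_000..10_400, ends +100
        reads = _reads(pos, strand="+")
        c = Cluster("chr1", 10_000, 10_500, 3, 3, 3, 0)
        chrom, start, end = estimate_breakpoint(c, reads, self._index(), "fr")
        assert (chrom, start, end) == ("chr1", 10_500, 11_500)

    def test_minus_dominant_fr_interval_ends_at_leftmost_start(self):
        reads = _reads([20_001, 20_201], strand="-")
        c = Cluster("chr1", 20_000, 20_300, 2, 2, 0, 2)
        chrom, start, end = estimate_breakpoint(c, reads, self._index(), "fr")
        assert (start, end) == (19_000, 20_000)

    def test_rf_orientation_swaps_strand_roles(self):
        # minus-strand rf orphans lie LEFT of the breakpoint
        reads = _reads([20_001, 20_201], strand="-")
        c = Cluster("chr1", 20_000, 20_300, 2, 2, 0, 2)
        chrom, start, end = estimate_breakpoint(c, reads, self._index(), "rf")
        assert (start, end) == (20_300, 21_300)

    def test_single_read_cluster_interval_width_is_one_block(self):
        reads = _reads([30_001], strand="+")
        c = Cluster("chr1", 30_000, 30_100, 1, 1, 1, 0)
        _, start, end = estimate_breakpoint(c, reads, self._index(), "fr")
        assert end - start == 1000

    def test_interval_intersects_or_abuts_hull(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.integers(40_001, 42_000, size=20))
        strands = np.where(rng.random(20) < 0.5, "+", "-")
        reads = _reads(pos, strand=list(strands))
        n_plus = int((strands == "+").sum())
        c = Cluster("chr1", int(pos.min() - 1), int(pos.max() + 99), 20, 5,
                    n_plus, 20 - n_plus)
        _, start, end = estimate_breakpoint(c, reads, self._index(), "fr")
        assert start <= c.end and end >= c.start


class TestWriteOutputs:
    def test_bed_round_trip_and_manifest(self, tmp_path):
        c = Cluster("chr1", 10_000, 13_900, 10, 9, 10, 0)
        from tglocate.sites import CandidateSite

        site = CandidateSite([c], CLEAN, [("chr1", 13_900, 14_900)])
        scores = _scores([("chr1", 10, 9), ("chr1", 11, 4)])
        tset = ThresholdSet({0.01: 9, 0.05: 8, 0.1: 7}, {"base_seed": 42})
        paths = write_outputs([site], scores, tset, tmp_path / "out",
                              params={"seed": 42, "alpha": 0.1})
        bed_lines = open(paths["bed"]).read().splitlines()
        assert len(bed_lines) == 1
        chrom, start, end, name, score, strand = bed_lines[0].split("\t")
        assert (chrom, int(start), int(end), name) == ("chr1", 13_900, 14_900, CLEAN)
        import json

        manifest = json.load(open(paths["manifest"]))
        assert manifest["parameters"]["seed"] == 42
        assert manifest["thresholds"]["0.1"] == 7
        report = pd.read_csv(paths["tsv"], sep="\t")
        assert report["classification"].tolist() == [CLEAN]
        bedgraph = open(paths["bedgraph"]).read().splitlines()
        assert bedgraph[0].split("\t") == ["chr1", "10000", "11000", "9"]
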