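"""Staged alignment: orphan extraction, host mapping, table building."""
import pandas as pd
import pytest

from tglocate.errors import ConsistencyError, FormatError, ParameterError
from tglocate.samio import (
    FMUNMAP,
    FPAIRED,
    FREAD1,
    FREAD2,
    FREVERSE,
    FSECONDARY,
    FUNMAP,
    AlignedRead,
    read_sam,
    sam_records_from_pairs,
    write_sam,
)
from tglocate.staged import (
    build_orphan_table,
    extract_orphans,
    map_orphans,
    read_orphan_table,
    write_orphan_table,
)
from tglocate.toymap import KmerIndex, map_batch

Q = "I" * 20
S = "ACGTACGTACGTACGTACGT"


def _pair(name, mapped1, mapped2, pos1=812, pos2=900, mapq=60):
    f1 = FPAIRED | FREAD1
    f2 = FPAIRED | FREAD2
    if not mapped1:
        f1 |= FUNMAP
        f2 |= FMUNMAP
    if not mapped2:
        f2 |= FUNMAP
        f1 |= FMUNMAP
    r1 = AlignedRead("%s" % name, f1, "transgene" if mapped1 else None,
                     pos1 if mapped1 else 0, mapq if mapped1 else 0, S, Q)
    r2 = AlignedRead("%s" % name, f2, "transgene" if mapped2 else None,
                     pos2 if mapped2 else 0, mapq if mapped2 else 0, S, Q)
    return [r1, r2]


class TestExtractOrphans:
    def test_one_mapped_mate_emits_orphan(self):
        orphans, tg_side = extract_orphans(_pair("p1", True, False))
        assert [o[0] for o in orphans] == ["p1"]
        assert tg_side["p1"].tg_pos == 812
        assert tg_side["p1"].tg_mapq == 60

    def test_both_mapped_emit_nothing(self):
        orphans, tg_side = extract_orphans(_pair("p1", True, True))
        assert orphans == [] and tg_side == {}

    def test_neither_mapped_emit_nothing(self):
        orphans, _ = extract_orphans(_pair("p1", False, False))
        assert orphans == []

    def test_secondary_records_ignored(self):
        group = _pair("p1", True, False)
        group.append(
            AlignedRead("p1", FPAIRED | FREAD1 | FSECONDARY, "transgene", 99, 0, S, Q)
        )
        orphans, tg_side = extract_orphans(group)
        assert len(orphans) == 1 and tg_side["p1"].tg_pos == 812

    def test_unsorted_stream_rejected(self):
        records = _pair("p1", True, False) + _pair("p2", True, False) + _pair("p1", True, False)
        with pytest.raises(FormatError, match="p1"):
            extract_orphans(records)

    def test_reverse_mapped_orphan_restored_to_original_orientation(self):
        # the mapped partner is reverse; the orphan is stored as-sequenced
        r1, r2 = _pair("p1", True, False)
        r1.flag |= FREVERSE
        orphans, tg_side = extract_orphans([r1, r2])
        assert orphans[0][1] == S  # unmapped mate untouched
        assert tg_side["p1"].tg_strand == "-"


class TestSamRoundTrip:
    def test_write_read_preserves_fields(self, tmp_path, tiny_host):
        from tglocate.simulate import simulate_reads

        ps = simulate_reads([(tiny_host, 1.0)], 0.05, read_len=100,
                            frag_mean=500, error_rate=0.0, seed=2)
        index = KmerIndex(tiny_host)
        r1 = map_batch(index, ps.seq1, seed=3)
        r2 = map_batch(index, ps.seq2, seed=4)
        records = list(sam_records_from_pairs(ps, r1, r2))
        path = tmp_path / "pairs.sam"
        write_sam(records, path, tiny_host.lengths)
        back = list(read_sam(path))
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert (a.name, a.flag, a.ref, a.pos, a.mapq, a.seq) == (
                b.name, b.flag, b.ref, b.pos, b.mapq, b.seq
            )


class TestMapOrphans:
    def test_external_sam_accepted_when_headers_cover_host(self, tmp_path, tiny_host):
        rec = AlignedRead("o1", 0, "chr1", 101, 60, S, Q, "20M")
        path = tmp_path / "host.sam"
        write_sam([rec], path, tiny_host.lengths)
        out = map_orphans([("o1", S, Q)], host=tiny_host, sam_path=path)
        assert out[0].pos == 101 and out[0].ref == "chr1"

    def test_external_sam_missing_chromosome_rejected(self, tmp_path, tiny_host):
        rec = AlignedRead("o1", 0, "other", 101, 60, S, Q, "20M")
        path = tmp_path / "host.sam"
        write_sam([rec], path, {"other": 10_000})
        with pytest.raises(ParameterError, match="chr1"):
            map_orphans([("o1", S, Q)], host=tiny_host, sam_path=path)

    def test_toy_route_maps_unique_orphans(self, tiny_host):
        arr = tiny_host.sequences["chr1"]
        orphans = [("o1", arr[7000:7100], "I" * 100)]
        out = map_orphans(orphans, host=tiny_host, seed=1)
        assert out[0].pos == 7001 and out[0].mapq == 60


class TestBuildOrphanTable:
    def _records(self):
        return [
            AlignedRead("a", 0, "chr1", 100, 60, S, Q, "20M"),
            AlignedRead("b", FUNMAP, None, 0, 0, S, Q),
            AlignedRead("c", FREVERSE, "chr2", 500, 0, S, Q, "20M"),
        ]

    def _tg_side(self):
        from tglocate.staged import TgSide

        return {
            "a": TgSide("transgene", 11, "+", 60),
            "b": TgSide("transgene", 22, "-", 60),
            "c": TgSide("transgene", 33, "+", 19),
        }

    def test_join_matches_dict_oracle(self):
        table = build_orphan_table(self._records(), self._tg_side())
        assert len(table) == 2
        assert table.attrs["n_unmapped"] == 1
        oracle = self._tg_side()
        for _, row in table.iterrows():
            assert row["tg_pos"] == oracle[row["name"]].tg_pos
            assert row["tg_mapq"] == oracle[row["name"]].tg_mapq
        assert list(table["host_strand"]) == ["+", "-"]

    def test_missing_name_rejected(self):
        side = self._tg_side()
        del side["a"]
        with pytest.raises(ConsistencyError, match="a"):
            build_orphan_table(self._records(), side)

    def test_tsv_round_trip(self, tmp_path):
        table = build_orphan_table(self._records(), self._tg_side())
        path = tmp_path / "orphans.tsv"
        write_orphan_table(table, path)
        back = read_orphan_table(path)
        pd.testing.assert_frame_equal(
            back[["name", "host_chrom", "host_pos", "host_mapq", "tg_pos", "tg_mapq"]],
            table[["name", "host_chrom", "host_pos", "host_mapq", "tg_pos", "tg_mapq"]],
        )


class TestPipelineConsistency:
    def test_batch_route_equals_sam_route(self, small_run):
        """The vectorized in-memory staging must agree with the SAM-file
        route built from the same mapping results."""
        from tglocate.readqc import filter_pairset

        case = small_run["case"]
        qc, _ = filter_pairset(small_run["pairset"])
        tg_index = KmerIndex(case.tg.as_genome())
        res1 = map_batch(tg_index, qc.seq1, seed=23 + 10)
        res2 = map_batch(tg_index, qc.seq2, seed=23 + 11)
        sam_records = sam_records_from_pairs(qc, res1, res2)
        orphans, tg_side = extract_orphans(sam_records)
        host_index = KmerIndex(case.host)
        host_records = map_orphans(orphans, index=host_index, seed=23 + 12)
        table_sam = build_orphan_table(host_records, tg_side)
        table_batch = small_run["table"]
        assert len(table_sam) == len(table_batch)
        key = ["name", "host_chrom", "host_pos", "host_mapq", "tg_pos", "tg_mapq"]
        pd.testing.assert_frame_equal(
            table_sam[key].sort_values("name").reset_index(drop=True),
            table_batch[key].sort_values("name").reset_index(drop=True),
            check_dtype=False,
        )

    def test_orphans_flank_the_transgene_array(self, small_run):
        """With error-free reads, every orphan pair's source fragment must
        straddle a junction on the transgenic allele: either an array/host
        boundary or an internal copy-copy junction (reads crossing those do
        not match the single-copy transgene reference, orphaning their
        fully-interior mates)."""
        case = small_run["case"]
        truth = case.truth
        tg_len = len(case.tg)
        first = tg_len - truth.first_copy_truncation
        junctions = [truth.insertion_pos]
        acc = truth.insertion_pos + first
        for _ in range(truth.copy_number):
            junctions.append(acc)
            acc += tg_len
        from tglocate.readqc import filter_pairset

        qc, _ = filter_pairset(small_run["pairset"])
        idx = small_run["orphan_idx"]
        rows = qc.truth.iloc[idx]
        assert len(rows) > 0
        assert (rows["allele"] == 0).all()  # only the transgenic allele
        for _, row in rows.iterrows():
            s, e = row["frag_start"], row["frag_start"] + row["frag_len"]
            assert any(s <= j <= e for j in junctions)

    def test_wild_type_run_yields_no_orphans(self, tiny_host, tg_construct):
        from tglocate.pipeline import SimConfig, stage_and_score
        from tglocate.simulate import simulate_reads

        ps = simulate_reads([(tiny_host, 1.0)], 2.0, read_len=100,
                            frag_mean=1000, error_rate=0.0, seed=31)
        config = SimConfig(host_len=tiny_host.total_length, repeat_fraction=0.0)
        _, table, filtered, scores, *_ = stage_and_score(
            ps, tg_construct, tiny_host, config, seed=31
        )
        assert len(table) == 0 and len(filtered) == 0
        assert scores.blocks.empty
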