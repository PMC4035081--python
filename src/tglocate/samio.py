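"""SAM records and (de)serialization through pysam.

:class:`AlignedRead` is the pipeline's in-memory view of one SAM record;
files on disk are read and written with pysam so headers, flags and
coordinates follow the SAM specification (1-based POS on disk; the rest of
the package works 0-based half-open internally and converts at this
boundary).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pysam

from . import _dna

FPAIRED, FUNMAP, FMUNMAP, FREVERSE, FMREVERSE = 0x1, 0x4, 0x8, 0x10, 0x20
FREAD1, FREAD2, FSECONDARY, FSUPPLEMENTARY = 0x40, 0x80, 0x100, 0x800


@dataclass
class AlignedRead:
    """One SAM record. ``pos`` is 1-based leftmost (0 when unmapped); ``qual``
    is the Phred+33 string as stored in SAM."""

    name: str
    flag: int
    ref: str | None
    pos: int
    mapq: int
    seq: str
    qual: str
    cigar: str | None = None

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FPAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FUNMAP)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FMUNMAP)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FREVERSE)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FREAD1)

    @property
    def is_read2(self) -> bool:
        return bool(self.flag & FREAD2)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FSECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FSUPPLEMENTARY)

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    @property
    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual]

    def original_read(self) -> tuple[str, str]:
        """(sequence, qual string) in as-sequenced orientation."""
        if self.is_reverse and not self.is_unmapped:
            return _dna.revcomp_str(self.seq), self.qual[::-1]
        return self.seq, self.qual


def make_header(ref_lengths: dict[str, int], sort_order: str = "queryname") -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": sort_order},
            "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
        }
    )


def write_sam(records: Iterable[AlignedRead], path, ref_lengths: dict[str, int]) -> None:
    header = make_header(ref_lengths)
    names = list(ref_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.name
            a.flag = rec.flag
            a.reference_id = names.index(rec.ref) if rec.ref is not None else -1
            a.reference_start = rec.pos - 1 if rec.pos > 0 else -1
            a.mapping_quality = rec.mapq
            a.query_sequence = rec.seq
            a.query_qualities = pysam.qualitystring_to_array(rec.qual)
            if rec.cigar and not rec.is_unmapped:
                a.cigarstring = rec.cigar
            out.write(a)


def read_sam(path) -> Iterator[AlignedRead]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            yield AlignedRead(
                a.query_name,
                a.flag,
                a.reference_name if a.reference_id >= 0 else None,
                (a.reference_start + 1) if a.reference_start is not None and a.reference_start >= 0 else 0,
                a.mapping_quality,
                a.query_sequence or "",
                a.qual or "",
                a.cigarstring,
            )


def sam_reference_lengths(path) -> dict[str, int]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return dict(zip(fh.references, fh.lengths))


def _oriented(seq_row: np.ndarray, qual_row: np.ndarray, reverse: bool) -> tuple[str, str]:
    if reverse:
        return (
            _dna.decode(_dna.revcomp(seq_row)),
            (qual_row[::-1] + 33).astype(np.uint8).tobytes().decode("ascii"),
        )
    return _dna.decode(seq_row), (qual_row + 33).astype(np.uint8).tobytes().decode("ascii")


def sam_records_from_pairs(pairset, res1, res2) -> Iterator[AlignedRead]:
    """Name-sorted paired SAM records from two batch mapping results."""
    ref_names = res1.ref_names
    L = pairset.read_len
    for i, name in enumerate(pairset.names):
        for mate_flag, seqs, quals, res, other in (
            (FREAD1, pairset.seq1, pairset.qual1, res1, res2),
            (FREAD2, pairset.seq2, pairset.qual2, res2, res1),
        ):
            flag = FPAIRED | mate_flag
            if not res.mapped[i]:
                flag |= FUNMAP
            elif res.is_reverse[i]:
                flag |= FREVERSE
            if not other.mapped[i]:
                flag |= FMUNMAP
            elif other.is_reverse[i]:
                flag |= FMREVERSE
            seq, qual = _oriented(seqs[i], quals[i], bool(res.mapped[i] and res.is_reverse[i]))
            yield AlignedRead(
                name,
                flag,
                ref_names[res.ref_id[i]] if res.mapped[i] else None,
                int(res.pos0[i]) + 1 if res.mapped[i] else 0,
                int(res.mapq[i]) if res.mapped[i] else 0,
                seq,
                qual,
                f"{L}M" if res.mapped[i] else None,
            )


def sam_records_from_single(reads, res) -> Iterator[AlignedRead]:
    """Single-end SAM records; ``reads`` is a list of (name, seq, qual)."""
    for i, (name, seq, qual) in enumerate(reads):
        flag = 0
        if not res.mapped[i]:
            flag |= FUNMAP
            out_seq, out_qual = seq, qual
        elif res.is_reverse[i]:
            flag |= FREVERSE
            out_seq, out_qual = _dna.revcomp_str(seq), qual[::-1]
        else:
            out_seq, out_qual = seq, qual
        yield AlignedRead(
            name,
            flag,
            res.ref_names[res.ref_id[i]] if res.mapped[i] else None,
            int(res.pos0[i]) + 1 if res.mapped[i] else 0,
            int(res.mapq[i]) if res.mapped[i] else 0,
            out_seq,
            out_qual,
            f"{len(seq)}M" if res.mapped[i] else None,
        )
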