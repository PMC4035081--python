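"""Read quality filtering prior to alignment.

A read passes when at least ``min_bases`` of its base calls have Phred
quality >= ``q_min`` (defaults: Q30 over 70 bases, tuned for 100-bp reads;
``min_frac`` offers a proportional alternative for other read lengths).
Pairs are dropped whole when either mate fails, so that no artificial
"orphans" are created by QC itself.
"""
from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from typing import Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError, ParameterError


@dataclass
class QCReport:
    n_input_pairs: int = 0
    n_kept_pairs: int = 0
    n_dropped_read1: int = 0
    n_dropped_read2: int = 0

    def as_dict(self) -> dict:
        return {
            "n_input_pairs": self.n_input_pairs,
            "n_kept_pairs": self.n_kept_pairs,
            "n_dropped_read1": self.n_dropped_read1,
            "n_dropped_read2": self.n_dropped_read2,
        }


def read_passes(
    qualities: list[int] | tuple[int, ...],
    q_min: int = 30,
    min_bases: int = 70,
    min_frac: float | None = None,
) -> bool:
    """True iff at least ``min_bases`` base calls reach ``q_min``.

    If ``min_frac`` is given it overrides ``min_bases`` with
    ``ceil(min_frac * read_len)``.
    """
    if len(qualities) == 0:
        raise ParameterError("empty quality list")
    if min_frac is not None:
        if not 0 < min_frac <= 1:
            raise ParameterError("min_frac must be in (0, 1]")
        min_bases = math.ceil(min_frac * len(qualities))
    return sum(1 for q in qualities if q >= q_min) >= min_bases


def _open(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_records(path) -> Iterator[tuple[str, str, str]]:
    """(title, sequence, phred33 quality string) triples."""
    with _open(path) as fh:
        yield from FastqGeneralIterator(fh)


def _base_name(title: str) -> str:
    name = title.split()[0]
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    return name


def _quals(qual_str: str) -> list[int]:
    return [ord(c) - 33 for c in qual_str]


def filter_fastq_pairs(
    fastq1,
    fastq2,
    out1,
    out2,
    q_min: int = 30,
    min_bases: int = 70,
    min_frac: float | None = None,
) -> QCReport:
    """Filter synchronized mate FASTQ files; a pair is kept iff both mates
    pass. Raises :class:`FormatError` at the first desynchronized record."""
    report = QCReport()
    with open(out1, "w") as o1, open(out2, "w") as o2:
        it2 = read_fastq_records(fastq2)
        for t1, s1, q1 in read_fastq_records(fastq1):
            try:
                t2, s2, q2 = next(it2)
            except StopIteration:
                raise FormatError(
                    f"mate file ended early; record {t1!r} has no partner"
                ) from None
            if _base_name(t1) != _base_name(t2):
                raise FormatError(
                    f"desynchronized mate files at {t1!r} vs {t2!r}"
                )
            report.n_input_pairs += 1
            p1 = read_passes(_quals(q1), q_min, min_bases, min_frac)
            p2 = read_passes(_quals(q2), q_min, min_bases, min_frac)
            if p1 and p2:
                report.n_kept_pairs += 1
                o1.write(f"@{t1}\n{s1}\n+\n{q1}\n")
                o2.write(f"@{t2}\n{s2}\n+\n{q2}\n")
            else:
                if not p1:
                    report.n_dropped_read1 += 1
                if not p2:
                    report.n_dropped_read2 += 1
    for extra in it2:
        raise FormatError(f"mate file has trailing record {extra[0]!r}")
    return report


def filter_pairset(pairset, q_min: int = 30, min_bases: int = 70):
    """In-memory variant over a :class:`~tglocate.simulate.ReadPairSet`;
    returns (filtered set, QCReport)."""
    import numpy as np

    ok1 = (pairset.qual1 >= q_min).sum(axis=1) >= min_bases
    ok2 = (pairset.qual2 >= q_min).sum(axis=1) >= min_bases
    keep = ok1 & ok2
    report = QCReport(
        n_input_pairs=pairset.n_pairs,
        n_kept_pairs=int(keep.sum()),
        n_dropped_read1=int((~ok1).sum()),
        n_dropped_read2=int((~ok2).sum()),
    )
    return pairset.subset(np.flatnonzero(keep)), report
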