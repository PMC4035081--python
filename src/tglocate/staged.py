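"""Staged alignment: transgene stage, orphan extraction, host stage.

Reads are first aligned to the transgene construct alone. A pair where
exactly one mate maps to the transgene yields an *orphan*: the unmapped
mate, whose eventual host-genome mapping marks the insertion neighborhood.
The mapped mate's transgene coordinates and MAPQ are kept in a side table
and joined back after the host stage into the 13-column orphan table that
the scoring stage consumes.

Orphan status is decided on primary records only; secondary and
supplementary alignments are ignored.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ParameterError
from .genome import Genome
from .samio import AlignedRead, read_sam, sam_reference_lengths
from .toymap import KmerIndex, MapResult, map_batch

log = logging.getLogger(__name__)

#: column order of the orphan table (our TSV dialect; `dtn` stays blank
#: until the scoring stage computes it)
ORPHAN_COLUMNS = [
    "name",
    "host_chrom",
    "host_pos",
    "host_strand",
    "host_mapq",
    "host_cigar",
    "tg_name",
    "tg_pos",
    "tg_strand",
    "tg_mapq",
    "read_len",
    "dtn",
    "flags_hex",
]


@dataclass
class TgSide:
    """Transgene-side mapping of an orphan's partner read."""

    tg_name: str
    tg_pos: int  # 1-based
    tg_strand: str
    tg_mapq: int


def _pair_groups(records: Iterable[AlignedRead]) -> Iterator[tuple[str, list[AlignedRead]]]:
    """Group a name-sorted stream by read name; error if a name recurs after
    a different name (i.e. the stream is not name-sorted)."""
    seen: set[str] = set()
    current: str | None = None
    group: list[AlignedRead] = []
    for rec in records:
        if rec.name != current:
            if current is not None:
                yield current, group
                seen.add(current)
            if rec.name in seen:
                raise FormatError(
                    f"SAM stream not name-sorted: {rec.name!r} reappears"
                )
            current, group = rec.name, []
        group.append(rec)
    if current is not None:
        yield current, group


def extract_orphans(
    records: Iterable[AlignedRead],
) -> tuple[list[tuple[str, str, str]], dict[str, TgSide]]:
    """From name-sorted transgene-stage SAM records, collect orphans.

    Returns ``(orphans, tg_side)`` where ``orphans`` holds ``(name, seq,
    qual)`` of each unmapped mate whose partner mapped to the transgene, in
    as-sequenced orientation, and ``tg_side`` maps name -> partner's
    transgene mapping. Pairs with both or neither mate mapped contribute
    nothing; secondary/supplementary records are ignored.
    """
    orphans: list[tuple[str, str, str]] = []
    tg_side: dict[str, TgSide] = {}
    n_missing_mate = 0
    for name, group in _pair_groups(records):
        primary = [r for r in group if not (r.is_secondary or r.is_supplementary)]
        mapped = [r for r in primary if not r.is_unmapped]
        unmapped = [r for r in primary if r.is_unmapped]
        if len(mapped) != 1 or len(primary) < 2:
            if len(mapped) == 1 and mapped[0].mate_unmapped:
                n_missing_mate += 1
            continue
        partner = mapped[0]
        orphan = unmapped[0]
        seq, qual = orphan.original_read()
        orphans.append((name, seq, qual))
        tg_side[name] = TgSide(partner.ref, partner.pos, partner.strand, partner.mapq)
    if n_missing_mate:
        log.warning(
            "%d mapped records flagged mate-unmapped had no partner record",
            n_missing_mate,
        )
    return orphans, tg_side


def write_orphans(orphans, tg_side, out_prefix) -> tuple[str, str]:
    """Write orphan FASTQ and transgene-side TSV; returns the two paths."""
    fq = f"{out_prefix}.orphans.fastq"
    ts = f"{out_prefix}.tgside.tsv"
    with open(fq, "w") as fh:
        for name, seq, qual in orphans:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    with open(ts, "w") as fh:
        fh.write("#name\ttg_name\ttg_pos\ttg_strand\ttg_mapq\n")
        for name, _, _ in orphans:
            t = tg_side[name]
            fh.write(f"{name}\t{t.tg_name}\t{t.tg_pos}\t{t.tg_strand}\t{t.tg_mapq}\n")
    return fq, ts


def read_tg_side(path) -> dict[str, TgSide]:
    tg_side: dict[str, TgSide] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            name, tg_name, tg_pos, tg_strand, tg_mapq = line.rstrip("\n").split("\t")
            tg_side[name] = TgSide(tg_name, int(tg_pos), tg_strand, int(tg_mapq))
    return tg_side


def map_orphans(
    orphans: list[tuple[str, str, str]],
    host: Genome | None = None,
    sam_path=None,
    k: int = 21,
    seed: int = 0,
    index: KmerIndex | None = None,
) -> list[AlignedRead]:
    """Map orphan reads to the host genome.

    Either with the built-in mapper (``host`` or a prebuilt ``index``), or by
    accepting an externally produced SAM (``sam_path``), whose header must
    cover every host chromosome when ``host`` is also given.
    """
    if sam_path is not None:
        if host is not None:
            refs = sam_reference_lengths(sam_path)
            missing = set(host.names) - set(refs)
            if missing:
                raise ParameterError(
                    f"external SAM header lacks host chromosomes: {sorted(missing)}"
                )
        return list(read_sam(sam_path))
    if index is None:
        if host is None:
            raise ParameterError("map_orphans needs a host genome, index, or SAM path")
        index = KmerIndex(host, k=k)
    return _toy_single(orphans, index, seed)


def _toy_single(orphans, index: KmerIndex, seed: int) -> list[AlignedRead]:
    from . import _dna
    from .samio import sam_records_from_single

    if not orphans:
        return []
    lengths = {len(s) for _, s, _ in orphans}
    records: list[AlignedRead] = []
    # group by length so each batch is rectangular
    for L in sorted(lengths):
        batch = [(n, s, q) for n, s, q in orphans if len(s) == L]
        seqs = np.vstack([_dna.encode(s) for _, s, _ in batch])
        res = map_batch(index, seqs, seed=seed)
        records.extend(sam_records_from_single(batch, res))
    return records


def build_orphan_table(
    host_records: Iterable[AlignedRead], tg_side: dict[str, TgSide]
) -> pd.DataFrame:
    """Join host-stage alignments with the transgene-side table.

    One row per *mapped* orphan; unmapped orphans are dropped and counted in
    ``df.attrs['n_unmapped']``. A mapped name absent from ``tg_side`` raises
    :class:`ConsistencyError`.
    """
    rows = []
    n_unmapped = 0
    for rec in host_records:
        if rec.is_secondary or rec.is_supplementary:
            continue
        if rec.is_unmapped:
            n_unmapped += 1
            continue
        side = tg_side.get(rec.name)
        if side is None:
            raise ConsistencyError(
                f"orphan {rec.name!r} missing from transgene-side table"
            )
        rows.append(
            (
                rec.name,
                rec.ref,
                rec.pos,
                rec.strand,
                rec.mapq,
                rec.cigar or f"{len(rec.seq)}M",
                side.tg_name,
                side.tg_pos,
                side.tg_strand,
                side.tg_mapq,
                len(rec.seq),
                np.nan,
                f"0x{rec.flag:x}",
            )
        )
    df = pd.DataFrame(rows, columns=ORPHAN_COLUMNS)
    df.attrs["n_unmapped"] = n_unmapped
    if n_unmapped:
        log.info("%d orphans did not map to the host genome", n_unmapped)
    return df


def orphan_table_from_batch(
    pairset,
    tg_res1: MapResult,
    tg_res2: MapResult,
    host_res: MapResult,
    orphan_idx: np.ndarray,
    orphan_mate: np.ndarray,
) -> pd.DataFrame:
    """Vectorized equivalent of extract + join for in-memory batches.

    ``orphan_idx`` indexes pairs with exactly one transgene-mapped mate;
    ``orphan_mate`` is 1 or 2 marking which mate is the orphan; ``host_res``
    is the host mapping of those orphans (same order).
    """
    mapped = host_res.mapped
    keep = np.flatnonzero(mapped)
    names = [pairset.names[i] for i in orphan_idx[keep]]
    partner_is_1 = orphan_mate[keep] == 2
    tg_pos = np.where(
        partner_is_1, tg_res1.pos0[orphan_idx[keep]], tg_res2.pos0[orphan_idx[keep]]
    )
    tg_rev = np.where(
        partner_is_1,
        tg_res1.is_reverse[orphan_idx[keep]],
        tg_res2.is_reverse[orphan_idx[keep]],
    )
    tg_mapq = np.where(
        partner_is_1, tg_res1.mapq[orphan_idx[keep]], tg_res2.mapq[orphan_idx[keep]]
    )
    L = pairset.read_len
    host_names = np.array(host_res.ref_names, dtype=object)
    df = pd.DataFrame(
        {
            "name": names,
            "host_chrom": host_names[host_res.ref_id[keep]],
            "host_pos": host_res.pos0[keep] + 1,
            "host_strand": np.where(host_res.is_reverse[keep], "-", "+"),
            "host_mapq": host_res.mapq[keep].astype(int),
            "host_cigar": f"{L}M",
            "tg_name": tg_res1.ref_names[0],
            "tg_pos": tg_pos + 1,
            "tg_strand": np.where(tg_rev, "-", "+"),
            "tg_mapq": tg_mapq.astype(int),
            "read_len": L,
            "dtn": np.nan,
            "flags_hex": "0x0",
        }
    )[ORPHAN_COLUMNS]
    df.attrs["n_unmapped"] = int((~mapped).sum())
    return df


def write_orphan_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ORPHAN_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", index=False, header=False, na_rep="")


def read_orphan_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment=None, names=ORPHAN_COLUMNS, skiprows=1, na_values=[""]
    )
    return df
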