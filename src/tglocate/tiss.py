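"""Distance-to-next filtering and block scoring (TISS).

The scoring scheme partitions every chromosome into fixed-length blocks
(default 1 kb) and counts, per block, the orphan reads that survive two
filters: PCR-duplicate removal via the *distance to next* (DTN) metric —
within a chromosome, each read's gap to the next read in coordinate order;
DTN = 0 marks a duplicate — and a mapping-quality floor (host and transgene
MAPQ >= 20). The per-block count is the transgene insertion site score: a
true insertion piles many distinct-coordinate orphans into one or two
blocks, while background reads scatter.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError, StateError


@dataclass(frozen=True)
class BlockIndex:
    """Fixed-length tiling of a genome; block b on chromosome c covers
    ``[b * block_len, (b + 1) * block_len)`` 0-based half-open (last block
    may be short)."""

    chrom_lengths: dict[str, int]
    block_len: int = 1000

    def __post_init__(self) -> None:
        if self.block_len <= 0:
            raise ParameterError("block_len must be > 0")
        if not self.chrom_lengths:
            raise ParameterError("no chromosomes")

    def n_blocks(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.block_len)

    @property
    def total_blocks(self) -> int:
        return sum(self.n_blocks(c) for c in self.chrom_lengths)

    def block_of(self, pos0: int) -> int:
        return pos0 // self.block_len

    def block_span(self, chrom: str, block: int) -> tuple[int, int]:
        start = block * self.block_len
        return start, min(start + self.block_len, self.chrom_lengths[chrom])

    @classmethod
    def from_genome(cls, genome, block_len: int = 1000) -> "BlockIndex":
        return cls(dict(genome.lengths), block_len)


class BlockHit(NamedTuple):
    chrom: str
    block: int
    score: int
    tied: bool = False


@dataclass
class ScoreTable:
    """Per-block read counts; zero-score blocks are omitted.

    ``blocks`` columns: chrom, block, score (sorted by chrom then block).
    """

    blocks: pd.DataFrame
    index: BlockIndex

    @property
    def total(self) -> int:
        return int(self.blocks["score"].sum())

    def max_hit(self, exclude=None) -> BlockHit | None:
        return max_score(self, exclude)

    def to_tsv(self, path) -> None:
        df = self.blocks.copy()
        df["block_start"] = df["block"] * self.index.block_len
        df["block_end"] = [
            self.index.block_span(c, b)[1]
            for c, b in zip(df["chrom"], df["block"])
        ]
        df[["chrom", "block_start", "block_end", "score"]].to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, index: BlockIndex) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t")
        blocks = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "block": df["block_start"] // index.block_len,
                "score": df["score"],
            }
        )
        return cls(blocks, index)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, block, score in self.blocks.itertuples(index=False):
                start, end = self.index.block_span(chrom, int(block))
                fh.write(f"{chrom}\t{start}\t{end}\t{int(score)}\n")


def compute_dtn(table: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``dtn`` column: per chromosome, reads sorted ascending by
    ``host_pos``; ``dtn[i] = host_pos[i+1] - host_pos[i]``, the last read per
    chromosome gets +inf. Returns the table in (chrom, pos) sort order; ties
    keep input order (stable sort), so of duplicated coordinates all but the
    last get DTN = 0."""
    if table.empty:
        out = table.copy()
        out["dtn"] = pd.Series(dtype=float)
        return out
    if table["host_pos"].isna().any():
        raise StateError("host_pos missing for some rows")
    out = table.sort_values(
        ["host_chrom", "host_pos"], kind="stable", ignore_index=True
    )
    nxt = out.groupby("host_chrom", sort=False)["host_pos"].shift(-1)
    out["dtn"] = (nxt - out["host_pos"]).fillna(np.inf)
    return out


def filter_records(table: pd.DataFrame, mapq_min: int = 20) -> pd.DataFrame:
    """Drop PCR duplicates (DTN = 0) and low-confidence mappings (host or
    transgene MAPQ < ``mapq_min``). Idempotent; after filtering, host_pos is
    strictly increasing within each chromosome."""
    if table.empty:
        return table.copy()
    if "dtn" not in table.columns or table["dtn"].isna().any():
        raise StateError("DTN must be computed before filtering")
    keep = (
        (table["dtn"] > 0)
        & (table["host_mapq"] >= mapq_min)
        & (table["tg_mapq"] >= mapq_min)
    )
    return table.loc[keep].reset_index(drop=True)


def score_blocks(
    table: pd.DataFrame,
    index: BlockIndex,
    require_containment: bool = False,
) -> ScoreTable:
    """Count retained reads per block.

    Each read is assigned to the block containing its 0-based start
    coordinate (``host_pos - 1``); with ``require_containment`` a read must
    also end within the same block (the literal strictly-within reading, at
    the price of losing straddling reads).
    """
    if table.empty:
        return ScoreTable(
            pd.DataFrame(columns=["chrom", "block", "score"]), index
        )
    start0 = table["host_pos"].to_numpy(dtype=np.int64) - 1
    for chrom in table["host_chrom"].unique():
        if chrom not in index.chrom_lengths:
            raise ConsistencyError(f"chromosome {chrom!r} not in block index")
    lens = table["host_chrom"].map(index.chrom_lengths).to_numpy(dtype=np.int64)
    bad = np.flatnonzero((start0 < 0) | (start0 >= lens))
    if bad.size:
        row = table.iloc[int(bad[0])]
        raise ConsistencyError(
            f"read {row['name']!r} at {row['host_chrom']}:{row['host_pos']} "
            "is beyond the chromosome end"
        )
    blk = start0 // index.block_len
    sub = pd.DataFrame({"chrom": table["host_chrom"], "block": blk})
    if require_containment:
        end0 = start0 + table["read_len"].to_numpy(dtype=np.int64)
        inside = end0 <= (blk + 1) * index.block_len
        sub = sub.loc[inside]
    counts = (
        sub.groupby(["chrom", "block"], sort=True)
        .size()
        .rename("score")
        .reset_index()
    )
    counts["score"] = counts["score"].astype(int)
    return ScoreTable(counts, index)


def _excluded_mask(scores: ScoreTable, exclude) -> np.ndarray:
    """Boolean mask of blocks intersecting any excluded region.

    ``exclude`` items are chromosome names or ``(chrom, start, end)``
    0-based half-open intervals.
    """
    df = scores.blocks
    mask = np.zeros(len(df), dtype=bool)
    if not exclude:
        return mask
    bl = scores.index.block_len
    for item in exclude:
        if isinstance(item, str):
            mask |= (df["chrom"] == item).to_numpy()
        else:
            chrom, start, end = item
            bstart = df["block"].to_numpy() * bl
            mask |= (
                (df["chrom"] == chrom).to_numpy()
                & (bstart < end)
                & (bstart + bl > start)
            )
    return mask


def max_score(scores: ScoreTable, exclude=None) -> BlockHit | None:
    """Highest-scoring block outside excluded regions; ties broken by
    (chrom, block) lexicographic order and flagged. None when nothing
    remains."""
    df = scores.blocks.loc[~_excluded_mask(scores, exclude)]
    if df.empty:
        return None
    top = int(df["score"].max())
    winners = df.loc[df["score"] == top].sort_values(["chrom", "block"])
    first = winners.iloc[0]
    return BlockHit(str(first["chrom"]), int(first["block"]), top, len(winners) > 1)
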