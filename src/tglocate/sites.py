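"""From significant blocks to candidate insertion sites.

Cluster geometry carries the biological reading: one compact cluster of
orphan reads (spanning about one library fragment length) marks a clean
insertion; two clusters in close proximity on one chromosome mark an
insertion with a host-genome deletion between the breakpoints (or,
indistinguishably without PCR, two closely linked insertions); significant
clusters on multiple chromosomes are reported as trans candidates
(potential translocations or multiple integrations).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, StateError
from .tiss import BlockIndex, ScoreTable

CLEAN = "clean_insertion"
WITH_DELETION = "insertion_with_deletion"
UNPAIRED = "unpaired"
TRANS = "trans_candidate"


@dataclass
class Cluster:
    """A run of significant blocks plus the member reads they contain."""

    chrom: str
    start: int  # 0-based half-open hull of member read coordinates
    end: int
    n_reads: int
    max_block_score: int
    n_plus: int
    n_minus: int
    blocks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError("cluster end must exceed start")
        if self.n_reads != self.n_plus + self.n_minus or self.n_reads < 1:
            raise ParameterError("strand counts must sum to n_reads >= 1")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class CandidateSite:
    """One called insertion event (1 cluster, or 2 paired clusters)."""

    clusters: list[Cluster]
    classification: str
    breakpoint_intervals: list[tuple[str, int, int]]
    inferred_deletion_len: int = 0
    trans: bool = False
    note: str = ""

    @property
    def chrom(self) -> str:
        return self.clusters[0].chrom

    @property
    def max_block_score(self) -> int:
        return max(c.max_block_score for c in self.clusters)


def call_blocks(scores: ScoreTable, threshold: int, top_k: int = 5) -> pd.DataFrame:
    """Blocks with score >= threshold, united with the global top-K blocks,
    each flagged ``above_threshold`` — top hits are worth inspecting even
    below the genome-wide threshold."""
    if threshold < 1:
        raise ParameterError("threshold must be >= 1")
    df = scores.blocks.copy()
    if df.empty:
        return df.assign(above_threshold=pd.Series(dtype=bool))
    df = df.sort_values(
        ["score", "chrom", "block"], ascending=[False, True, True], ignore_index=True
    )
    significant = df["score"] >= threshold
    in_top = np.zeros(len(df), dtype=bool)
    in_top[: min(top_k, len(df))] = True
    out = df.loc[significant | in_top].copy()
    out["above_threshold"] = out["score"] >= threshold
    return out.sort_values(["chrom", "block"], ignore_index=True)


def merge_clusters(
    blocks: pd.DataFrame,
    reads: pd.DataFrame,
    index: BlockIndex,
    max_gap: int | None = None,
) -> list[Cluster]:
    """Merge same-chromosome significant blocks separated by <= ``max_gap``
    (default 2 x block_len) and attach their member reads.

    The cluster hull is the min/max coordinate span of member reads. Reads
    in sub-threshold blocks immediately flanking a run (within ``max_gap``
    of the block-member hull) are also attached — they are part of the same
    read pile and sharpen hulls and breakpoint/deletion estimates — with
    the reach clamped at the midpoint toward the neighboring run so that
    hulls can never overlap. A block holding no read at all falls back to
    its own bounds (only possible with externally edited inputs).
    """
    if max_gap is None:
        max_gap = 2 * index.block_len
    bl = index.block_len
    clusters: list[Cluster] = []
    if blocks.empty:
        return clusters
    start0 = reads["host_pos"].to_numpy(dtype=np.int64) - 1
    read_block = start0 // bl
    for chrom, sub in blocks.groupby("chrom", sort=True):
        bs = np.sort(sub["block"].to_numpy(dtype=np.int64))
        runs: list[list[int]] = [[int(bs[0])]]
        for b in bs[1:]:
            # inner gap between block intervals
            gap = (int(b) - runs[-1][-1] - 1) * bl
            if gap <= max_gap:
                runs[-1].append(int(b))
            else:
                runs.append([int(b)])
        on_chrom = (reads["host_chrom"] == chrom).to_numpy()
        for ri, run in enumerate(runs):
            member = on_chrom & np.isin(read_block, run)
            if member.any():
                hull_lo = int(start0[member].min())
                hull_hi = int(start0[member].max()) + 1
                lo_bound = (
                    (runs[ri - 1][-1] + 1) * bl + (run[0] * bl - (runs[ri - 1][-1] + 1) * bl) // 2
                    if ri > 0
                    else 0
                )
                hi_bound = (
                    (run[-1] + 1) * bl + (runs[ri + 1][0] * bl - (run[-1] + 1) * bl) // 2
                    if ri + 1 < len(runs)
                    else index.chrom_lengths[chrom]
                )
                lo = max(hull_lo - max_gap, lo_bound)
                hi = min(hull_hi + max_gap, hi_bound)
                member = member | (on_chrom & (start0 >= lo) & (start0 < hi))
            sub_reads = reads.loc[member]
            scores_in_run = sub.loc[sub["block"].isin(run), "score"]
            if len(sub_reads):
                hull_lo = int(start0[member].min())
                hull_hi = int(
                    (start0[member] + sub_reads["read_len"].to_numpy()).max()
                )
                n_plus = int((sub_reads["host_strand"] == "+").sum())
                n_minus = int((sub_reads["host_strand"] == "-").sum())
                n_reads = len(sub_reads)
            else:
                hull_lo, hull_hi = run[0] * bl, (run[-1] + 1) * bl
                n_plus, n_minus, n_reads = 1, 0, 1
            clusters.append(
                Cluster(
                    str(chrom),
                    hull_lo,
                    hull_hi,
                    n_reads,
                    int(scores_in_run.max()),
                    n_plus,
                    n_minus,
                    run,
                )
            )
    return clusters


def estimate_breakpoint(
    cluster: Cluster,
    reads: pd.DataFrame,
    index: BlockIndex,
    orientation: str = "fr",
    inner_edge: str | None = None,
) -> tuple[str, int, int]:
    """Strand-aware breakpoint interval for one cluster.

    For an fr (inward-facing) library, plus-strand orphans lie upstream of
    the breakpoint: when they dominate, the interval starts at the rightmost
    plus-read end and extends one block; minus-dominant clusters mirror
    this. For an rf (outward-facing mate-pair) library the strand roles are
    swapped, because the mate emitted at the fragment start carries the
    minus strand under the rf convention. Balanced clusters fall back to a
    one-block window around a hull edge (the edge facing the paired cluster
    when known, else the right hull edge).
    """
    if cluster.n_reads < 1:
        raise StateError("empty cluster")
    if orientation not in ("fr", "rf"):
        raise ParameterError("orientation must be 'fr' or 'rf'")
    bl = index.block_len
    on = (
        (reads["host_chrom"] == cluster.chrom)
        & (reads["host_pos"] - 1 >= cluster.start)
        & (reads["host_pos"] - 1 < cluster.end)
    )
    sub = reads.loc[on]
    if sub.empty:
        edge = cluster.end
        return cluster.chrom, max(0, edge - bl), edge + bl
    start0 = sub["host_pos"].to_numpy(dtype=np.int64) - 1
    strands = sub["host_strand"].to_numpy()
    rl = sub["read_len"].to_numpy(dtype=np.int64)
    n_plus = int((strands == "+").sum())
    n_minus = int((strands == "-").sum())
    # strand whose reads sit upstream (left) of the breakpoint
    upstream = "+" if orientation == "fr" else "-"
    downstream = "-" if orientation == "fr" else "+"
    n_up = n_plus if upstream == "+" else n_minus
    n_down = cluster.n_reads - n_up
    if n_up > n_down:
        p = int((start0 + rl)[strands == upstream].max())
        return cluster.chrom, p, p + bl
    if n_down > n_up:
        q = int(start0[strands == downstream].min())
        return cluster.chrom, max(0, q - bl), q
    edge = cluster.start if inner_edge == "left" else cluster.end
    return cluster.chrom, max(0, edge - bl), edge + bl


def classify(
    clusters: list[Cluster],
    reads: pd.DataFrame,
    index: BlockIndex,
    frag_mean: int,
    pair_distance_max: int | None = None,
    orientation: str = "fr",
) -> list[CandidateSite]:
    """Turn clusters into candidate sites.

    Two clusters on one chromosome whose inner-edge gap is at most
    ``pair_distance_max`` (default 5 x frag_mean, the scale set by closely
    linked validated insertions ~11.5 kb apart under a ~3.8 kb library)
    become one insertion-with-deletion candidate whose inferred deletion
    length is the inner gap. A lone cluster is a clean insertion when its
    span is at most 1.5 x frag_mean, else unpaired. When more than one
    chromosome carries clusters, lone-cluster candidates are reported as
    trans candidates and every site carries ``trans=True``.
    """
    if pair_distance_max is None:
        pair_distance_max = 5 * frag_mean
    by_chrom: dict[str, list[Cluster]] = {}
    for c in sorted(clusters, key=lambda c: (c.chrom, c.start)):
        by_chrom.setdefault(c.chrom, []).append(c)
    multi_chrom = len(by_chrom) > 1
    sites: list[CandidateSite] = []
    for chrom, cl in by_chrom.items():
        i = 0
        while i < len(cl):
            paired = False
            if i + 1 < len(cl):
                gap = cl[i + 1].start - cl[i].end
                if gap <= pair_distance_max:
                    left, right = cl[i], cl[i + 1]
                    bp_left = estimate_breakpoint(
                        left, reads, index, orientation, inner_edge="right"
                    )
                    bp_right = estimate_breakpoint(
                        right, reads, index, orientation, inner_edge="left"
                    )
                    sites.append(
                        CandidateSite(
                            [left, right],
                            WITH_DELETION,
                            [bp_left, bp_right],
                            inferred_deletion_len=max(0, gap),
                            trans=multi_chrom,
                            note=(
                                "two linked clusters: one insertion with a host "
                                "deletion, or two closely linked insertions"
                            ),
                        )
                    )
                    i += 2
                    paired = True
            if not paired:
                c = cl[i]
                if multi_chrom:
                    label = TRANS
                    note = "significant clusters occur on multiple chromosomes"
                elif c.span <= 1.5 * frag_mean:
                    label, note = CLEAN, ""
                else:
                    label, note = UNPAIRED, "cluster span exceeds library fragment scale"
                sites.append(
                    CandidateSite(
                        [c],
                        label,
                        [estimate_breakpoint(c, reads, index, orientation)],
                        trans=multi_chrom,
                        note=note,
                    )
                )
                i += 1
    return sites


def write_outputs(
    candidates: list[CandidateSite],
    scores: ScoreTable,
    thresholds,
    out_prefix,
    params: dict | None = None,
) -> dict[str, str]:
    """Write BED (breakpoint intervals), TSV report, BEDGRAPH score track
    and a JSON run manifest; returns the paths."""
    paths = {
        "bed": f"{out_prefix}.candidates.bed",
        "tsv": f"{out_prefix}.candidates.tsv",
        "bedgraph": f"{out_prefix}.scores.bedgraph",
        "manifest": f"{out_prefix}.manifest.json",
    }
    with open(paths["bed"], "w") as fh:
        for site in candidates:
            for chrom, start, end in site.breakpoint_intervals:
                fh.write(
                    f"{chrom}\t{start}\t{end}\t{site.classification}\t"
                    f"{min(site.max_block_score, 1000)}\t.\n"
                )
    rows = []
    for site in candidates:
        for ci, cluster in enumerate(site.clusters):
            chrom, bs, be = site.breakpoint_intervals[min(ci, len(site.breakpoint_intervals) - 1)]
            rows.append(
                {
                    "classification": site.classification,
                    "chrom": cluster.chrom,
                    "cluster_start": cluster.start,
                    "cluster_end": cluster.end,
                    "n_reads": cluster.n_reads,
                    "n_plus": cluster.n_plus,
                    "n_minus": cluster.n_minus,
                    "max_block_score": cluster.max_block_score,
                    "breakpoint_start": bs,
                    "breakpoint_end": be,
                    "inferred_deletion_len": site.inferred_deletion_len,
                    "trans": site.trans,
                    "note": site.note,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "classification",
            "chrom",
            "cluster_start",
            "cluster_end",
            "n_reads",
            "n_plus",
            "n_minus",
            "max_block_score",
            "breakpoint_start",
            "breakpoint_end",
            "inferred_deletion_len",
            "trans",
            "note",
        ],
    ).to_csv(paths["tsv"], sep="\t", index=False)
    scores.to_bedgraph(paths["bedgraph"])
    from . import __version__

    manifest = {
        "version": __version__,
        "parameters": params or {},
        "thresholds": (
            {str(a): int(v) for a, v in thresholds.thresholds.items()}
            if thresholds is not None
            else None
        ),
        "n_candidates": len(candidates),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
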