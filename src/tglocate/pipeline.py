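"""End-to-end orchestration: simulate -> QC -> staged alignment -> score ->
thresholds -> call.

These functions are what the CLI, the test harness and the coverage
comparison drive; everything runs in memory on batch arrays, with the same
operations the file-based interface exposes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genome import Genome, TransgeneConstruct
from .readqc import QCReport, filter_pairset
from .significance import ThresholdSet, null_distribution, thresholds, uniform_background
from .simulate import (
    ReadPairSet,
    SimTruth,
    hemizygous_alleles,
    make_host_genome,
    make_transgenic_genome,
    simulate_reads,
)
from .sites import CandidateSite, classify, call_blocks, merge_clusters
from .staged import orphan_table_from_batch
from .tiss import BlockIndex, ScoreTable, compute_dtn, filter_records, score_blocks
from .toymap import KmerIndex, map_batch


@dataclass
class SimConfig:
    """Study conditions for one synthetic transgenic-genome experiment.

    Defaults emulate the motivating use case scaled to desk size: a
    repeat-containing host, a 15-kb transgene inserted as a 5-copy tandem
    array with a truncated first copy, hemizygous genotype, and a ~3.8-kb
    rf mate-pair library at 10-fold coverage.
    """

    host_len: int = 10_000_000
    n_chroms: int = 1
    repeat_fraction: float = 0.2
    repeat_unit_len: int = 6000
    tg_len: int = 15_000
    insertion_chrom: str = "chr1"
    insertion_pos: int | None = None  # default: middle of the chromosome
    copy_number: int = 5
    host_deletion_len: int = 0
    first_copy_truncation: int = 2000
    zygosity: str = "hemizygous"
    coverage: float = 10.0
    read_len: int = 100
    frag_mean: int = 3800
    frag_sd: float | None = None
    orientation: str = "rf"
    error_rate: float = 0.001
    low_quality_read_fraction: float = 0.05
    block_len: int = 1000
    mapq_min: int = 20
    k: int = 21


@dataclass
class SimCase:
    host: Genome
    tg: TransgeneConstruct
    transgenic: Genome
    truth: SimTruth
    config: SimConfig


@dataclass
class PipelineResult:
    qc_report: QCReport
    n_pairs_in: int
    orphan_table: pd.DataFrame
    filtered: pd.DataFrame
    scores: ScoreTable
    threshold_set: ThresholdSet | None
    candidates: list[CandidateSite]
    counts: dict


def build_case(config: SimConfig, seed: int) -> SimCase:
    """Host genome, transgene and transgenic allele with recorded truth."""
    host = make_host_genome(
        config.n_chroms,
        config.host_len,
        config.repeat_fraction,
        config.repeat_unit_len,
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    from . import _dna

    tg = TransgeneConstruct(
        _dna.decode(_dna.from_codes(_dna.random_codes(rng, config.tg_len))),
        "transgene",
    )
    pos = (
        config.insertion_pos
        if config.insertion_pos is not None
        else config.host_len // 2
    )
    truth = SimTruth(
        config.insertion_chrom,
        pos,
        config.copy_number,
        config.host_deletion_len,
        config.first_copy_truncation,
        config.zygosity,
    )
    transgenic = make_transgenic_genome(host, tg, truth)
    return SimCase(host, tg, transgenic, truth, config)


def simulate_case_reads(case: SimCase, seed: int, coverage: float | None = None) -> ReadPairSet:
    cfg = case.config
    if cfg.zygosity == "hemizygous":
        alleles = hemizygous_alleles(case.transgenic, case.host)
    else:
        alleles = [(case.transgenic, 1.0)]
    return simulate_reads(
        alleles,
        coverage if coverage is not None else cfg.coverage,
        read_len=cfg.read_len,
        frag_mean=cfg.frag_mean,
        frag_sd=cfg.frag_sd,
        orientation=cfg.orientation,
        error_rate=cfg.error_rate,
        seed=seed,
        low_quality_read_fraction=cfg.low_quality_read_fraction,
    )


def stage_and_score(
    pairset: ReadPairSet,
    tg: TransgeneConstruct,
    host: Genome,
    config: SimConfig,
    seed: int,
    host_index: KmerIndex | None = None,
    apply_qc: bool = True,
) -> tuple[QCReport, pd.DataFrame, pd.DataFrame, ScoreTable, np.ndarray, np.ndarray]:
    """QC, transgene stage, orphan extraction, host stage, DTN/filter/score.

    Returns (qc_report, orphan_table, filtered_table, scores, orphan_idx,
    orphan_mate)."""
    if apply_qc:
        qc, report = filter_pairset(pairset)
    else:
        qc, report = pairset, QCReport(pairset.n_pairs, pairset.n_pairs, 0, 0)
    tg_index = KmerIndex(tg.as_genome(), k=config.k)
    res1 = map_batch(tg_index, qc.seq1, seed=seed + 10)
    res2 = map_batch(tg_index, qc.seq2, seed=seed + 11)
    orphan_mask = res1.mapped ^ res2.mapped
    orphan_idx = np.flatnonzero(orphan_mask)
    orphan_mate = np.where(res1.mapped[orphan_idx], 2, 1)
    L = qc.read_len
    orphan_seqs = np.empty((len(orphan_idx), L), dtype=np.uint8)
    m2 = orphan_mate == 2
    orphan_seqs[m2] = qc.seq2[orphan_idx[m2]]
    orphan_seqs[~m2] = qc.seq1[orphan_idx[~m2]]
    if host_index is None:
        host_index = KmerIndex(host, k=config.k)
    if len(orphan_idx):
        host_res = map_batch(host_index, orphan_seqs, seed=seed + 12)
        table = orphan_table_from_batch(qc, res1, res2, host_res, orphan_idx, orphan_mate)
    else:
        from .staged import ORPHAN_COLUMNS

        table = pd.DataFrame(columns=ORPHAN_COLUMNS)
        table.attrs["n_unmapped"] = 0
    filtered = filter_records(compute_dtn(table), mapq_min=config.mapq_min)
    index = BlockIndex.from_genome(host, config.block_len)
    scores = score_blocks(filtered, index)
    return report, table, filtered, scores, orphan_idx, orphan_mate


def run_pipeline(
    pairset: ReadPairSet,
    tg: TransgeneConstruct,
    host: Genome,
    config: SimConfig,
    seed: int,
    alpha: float = 0.10,
    n_reps: int = 20,
    reads_per_rep: int = 10_000,
    compute_thresholds: bool = True,
    exclude=None,
    host_index: KmerIndex | None = None,
) -> PipelineResult:
    """The full caller: orphan scoring plus randomization thresholds and
    candidate classification.

    Thresholds are calibrated from a uniform wild-type background of the
    host genome, scaled to ``reads_per_rep`` reads per replicate.
    """
    report, table, filtered, scores, *_ = stage_and_score(
        pairset, tg, host, config, seed, host_index=host_index
    )
    index = scores.index
    tset = None
    threshold = 1
    if compute_thresholds:
        bg = uniform_background(index, max(3 * reads_per_rep, 1000), seed=seed + 20)
        null = null_distribution(
            bg, index, n_reps=n_reps, reads_per_rep=reads_per_rep,
            base_seed=seed + 21, mapq_min=config.mapq_min,
        )
        tset = thresholds(null)
        threshold = tset.threshold(alpha)
    candidates: list[CandidateSite] = []
    if not scores.blocks.empty:
        blocks = call_blocks(scores, threshold)
        if exclude:
            from .tiss import _excluded_mask

            blocks = blocks.loc[
                ~_excluded_mask(ScoreTable(blocks, index), exclude)
            ].reset_index(drop=True)
        sig = blocks.loc[blocks["above_threshold"]]
        use = sig if not sig.empty else blocks
        clusters = merge_clusters(use, filtered, index)
        candidates = classify(
            clusters,
            filtered,
            index,
            frag_mean=config.frag_mean,
            orientation=config.orientation,
        )
    counts = {
        "n_pairs_in": pairset.n_pairs,
        "n_pairs_qc": report.n_kept_pairs,
        "n_orphans": len(table),
        "n_orphans_unmapped": table.attrs.get("n_unmapped", 0),
        "n_retained": len(filtered),
    }
    return PipelineResult(
        report, pairset.n_pairs, table, filtered, scores, tset, candidates, counts
    )


def simulate_and_run(
    config: SimConfig, seed: int, alpha: float = 0.10, **kwargs
) -> tuple[SimCase, ReadPairSet, PipelineResult]:
    case = build_case(config, seed)
    pairset = simulate_case_reads(case, seed + 5)
    result = run_pipeline(
        pairset, case.tg, case.host, config, seed, alpha=alpha, **kwargs
    )
    return case, pairset, result


def informative_read_count(
    filtered: pd.DataFrame, truth: SimTruth, frag_mean: int
) -> int:
    """Retained orphan reads whose host coordinate lies within one library
    fragment length of either breakpoint — the reads that actually carry
    insertion-site information."""
    lo = truth.insertion_pos - frag_mean
    hi = truth.right_breakpoint + frag_mean
    pos0 = filtered["host_pos"] - 1
    return int(
        (
            (filtered["host_chrom"] == truth.chrom) & (pos0 >= lo) & (pos0 < hi)
        ).sum()
    )


def top_candidate_error(
    result: PipelineResult, truth: SimTruth, frag_mean: int
) -> tuple[int | None, bool]:
    """Distance (bp) between the top candidate's breakpoint interval and the
    true left breakpoint, and whether the interval widened by ``frag_mean``
    contains it. None when nothing was called."""
    if not result.candidates:
        return None, False
    top = max(result.candidates, key=lambda s: s.max_block_score)
    best_d = None
    contained = False
    for chrom, start, end in top.breakpoint_intervals:
        if chrom != truth.chrom:
            continue
        for target in (truth.insertion_pos, truth.right_breakpoint):
            if start - frag_mean <= target < end + frag_mean:
                contained = True
            d = 0 if start <= target < end else min(abs(target - start), abs(target - end + 1))
            best_d = d if best_d is None else min(best_d, d)
    return best_d, contained


def downsample_pairset(
    pairset: ReadPairSet, target_cov: float, genome_len: float, seed: int
) -> ReadPairSet:
    """Uniformly keep pairs to reach ``target_cov`` over ``genome_len``."""
    n_keep = int(round(target_cov * genome_len / (2 * pairset.read_len)))
    if n_keep > pairset.n_pairs:
        raise ParameterError("target coverage exceeds simulated coverage")
    rng = np.random.default_rng(seed)
    keys = rng.random(pairset.n_pairs)
    keep = np.sort(np.argpartition(keys, min(n_keep, pairset.n_pairs - 1))[:n_keep])
    return pairset.subset(keep)


def compare_coverage(
    config: SimConfig,
    coverages: list[float] = (5.0, 10.0, 15.0),
    replicates: int = 3,
    base_seed: int = 0,
    alpha: float = 0.10,
) -> pd.DataFrame:
    """Downsampling harness: simulate each replicate once at max coverage,
    downsample to each target, run the full caller, and record whether the
    top hit is the true site — the mate-pair vs coverage trade-off study."""
    top_cov = max(coverages)
    rows = []
    for rep in range(replicates):
        seed = base_seed + 1000 * rep
        case = build_case(config, base_seed)  # same genome across replicates
        full = simulate_case_reads(case, seed + 5, coverage=top_cov)
        genome_len = 0.5 * (case.host.total_length + case.transgenic.total_length)
        host_index = KmerIndex(case.host, k=config.k)
        for cov in coverages:
            sub = downsample_pairset(full, cov, genome_len, seed + 7)
            result = run_pipeline(
                sub, case.tg, case.host, config, seed,
                alpha=alpha, host_index=host_index,
            )
            hit = result.scores.max_hit()
            dist, contained = top_candidate_error(result, case.truth, config.frag_mean)
            rows.append(
                {
                    "replicate": rep,
                    "coverage": cov,
                    "max_score": hit.score if hit else 0,
                    "top_chrom": hit.chrom if hit else "",
                    "top_block": hit.block if hit else -1,
                    "threshold": (
                        result.threshold_set.threshold(alpha)
                        if result.threshold_set
                        else np.nan
                    ),
                    "true_site_top": contained,
                    "informative_reads": informative_read_count(
                        result.filtered, case.truth, config.frag_mean
                    ),
                }
            )
    return pd.DataFrame(rows)
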