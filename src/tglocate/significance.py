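"""Genome-wide significance by randomization, and coverage downsampling.

The null asks: with no transgene at all, how large a block score does the
genome-wide maximum reach by chance? Replicate subsamples of a background
(host-mapped, orphan-free) read table are pushed through the same DTN /
MAPQ / block-scoring path as real data; the empirical quantiles of the
per-replicate maxima give the score thresholds at genome-wide alpha 0.01,
0.05 and 0.10.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParameterError
from .tiss import BlockIndex, compute_dtn, filter_records, score_blocks

DEFAULT_QUANTILES = (0.99, 0.95, 0.90)


@dataclass
class NullDistribution:
    """Per-replicate maximum block scores under the no-transgene null."""

    maxima: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maxima = np.asarray(self.maxima)
        if len(self.maxima) == 0:
            raise ParameterError("empty null distribution")


@dataclass
class ThresholdSet:
    """Score thresholds keyed by genome-wide alpha, with provenance."""

    thresholds: dict[float, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        alphas = sorted(self.thresholds)
        values = [self.thresholds[a] for a in alphas]
        if any(v2 > v1 for v1, v2 in zip(values, values[1:])):
            raise ParameterError("thresholds must be non-increasing in alpha")

    def threshold(self, alpha: float) -> int:
        if alpha not in self.thresholds:
            raise ParameterError(
                f"no threshold at alpha={alpha}; have {sorted(self.thresholds)}"
            )
        return self.thresholds[alpha]

    def to_json(self, path) -> None:
        payload = {
            "thresholds": {str(a): int(v) for a, v in sorted(self.thresholds.items())},
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            {float(a): int(v) for a, v in payload["thresholds"].items()},
            payload.get("provenance", {}),
        )


def subsample(records, n: int, seed: int):
    """Uniform sample of ``min(n, total)`` records without replacement,
    deterministic per seed.

    DataFrames are sampled with a vectorized random-key draw (equivalent in
    distribution to reservoir sampling); arbitrary iterables use single-pass
    reservoir sampling. Output preserves source order.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(records, pd.DataFrame):
        total = len(records)
        if n >= total:
            return records.copy()
        keys = rng.random(total)
        keep = np.sort(np.argpartition(keys, n)[:n])
        return records.iloc[keep].reset_index(drop=True)
    # reservoir (algorithm R) over a stream of unknown length
    reservoir: list = []
    replaced: list[int] = []
    for i, rec in enumerate(records):
        if i < n:
            reservoir.append(rec)
            replaced.append(i)
        else:
            j = int(rng.integers(0, i + 1))
            if j < n:
                reservoir[j] = rec
                replaced[j] = i
    order = np.argsort(replaced, kind="stable")
    return [reservoir[i] for i in order]


def null_distribution(
    background: pd.DataFrame,
    index: BlockIndex,
    n_reps: int = 100,
    reads_per_rep: int = 100_000,
    base_seed: int = 0,
    mapq_min: int = 20,
) -> NullDistribution:
    """Randomization null: per replicate r (seed ``base_seed + r``),
    subsample ``reads_per_rep`` background reads, compute DTN, filter, score
    blocks, and record the genome-wide maximum score."""
    if background.empty:
        raise ParameterError("background table is empty")
    if len(background) < reads_per_rep:
        warnings.warn(
            f"background has only {len(background)} reads (< {reads_per_rep}); "
            "each replicate will sample all of them",
            stacklevel=2,
        )
    maxima = np.zeros(n_reps, dtype=np.int64)
    seeds = [base_seed + r for r in range(n_reps)]
    for r, s in enumerate(seeds):
        sub = subsample(background, reads_per_rep, seed=s)
        filtered = filter_records(compute_dtn(sub), mapq_min=mapq_min)
        hit = score_blocks(filtered, index).max_hit()
        maxima[r] = hit.score if hit is not None else 0
    return NullDistribution(
        maxima,
        provenance={
            "n_reps": n_reps,
            "reads_per_rep": reads_per_rep,
            "base_seed": base_seed,
            "seeds": seeds,
            "mapq_min": mapq_min,
            "block_len": index.block_len,
        },
    )


def thresholds(
    null: NullDistribution, quantiles: Iterable[float] = DEFAULT_QUANTILES
) -> ThresholdSet:
    """Nearest-rank empirical quantiles of the null maxima.

    threshold(alpha = 1 - q) is the ceil(q * n)-th order statistic.
    """
    values = np.sort(null.maxima)
    n = len(values)
    out: dict[float, int] = {}
    for q in quantiles:
        if not 0 < q < 1:
            raise ParameterError(f"quantile {q} outside (0, 1)")
        rank = int(np.ceil(q * n))
        out[round(1.0 - q, 10)] = int(values[rank - 1])
    return ThresholdSet(out, provenance=dict(null.provenance, quantiles=list(quantiles)))


def uniform_background(
    index: BlockIndex, n_reads: int, seed: int, read_len: int = 100, mapq: int = 60
) -> pd.DataFrame:
    """Orphan-table-like background of reads placed uniformly on the genome:
    the idealized wild-type (no transgene, no homology) host-mapped read
    set used to calibrate thresholds in simulation."""
    if n_reads <= 0:
        raise ParameterError("n_reads must be > 0")
    rng = np.random.default_rng(seed)
    chroms = list(index.chrom_lengths)
    lens = np.array([index.chrom_lengths[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=n_reads, p=lens / lens.sum())
    pos = rng.integers(1, lens[ci].astype(np.int64) + 1)
    df = pd.DataFrame(
        {
            "name": [f"bg:{i:07d}" for i in range(n_reads)],
            "host_chrom": np.array(chroms, dtype=object)[ci],
            "host_pos": pos,
            "host_strand": np.where(rng.random(n_reads) < 0.5, "+", "-"),
            "host_mapq": mapq,
            "host_cigar": f"{read_len}M",
            "tg_name": "none",
            "tg_pos": 1,
            "tg_strand": "+",
            "tg_mapq": mapq,
            "read_len": read_len,
            "dtn": np.nan,
            "flags_hex": "0x0",
        }
    )
    return df


def downsample_to_coverage(
    fastq1,
    fastq2,
    out1,
    out2,
    target_cov: float,
    read_len: int,
    genome_len: int,
    seed: int = 0,
) -> int:
    """Keep ``round(target_cov * genome_len / (2 * read_len))`` pairs,
    sampled uniformly with mates kept together. Returns pairs written;
    errors if the target exceeds the measured source coverage."""
    from .readqc import read_fastq_records

    r1 = list(read_fastq_records(fastq1))
    r2 = list(read_fastq_records(fastq2))
    if len(r1) != len(r2):
        raise ParameterError("mate FASTQ files differ in record count")
    n_source = len(r1)
    source_cov = n_source * 2 * read_len / genome_len
    if target_cov > source_cov + 1e-9:
        raise ParameterError(
            f"target coverage {target_cov}X exceeds source coverage "
            f"{source_cov:.2f}X"
        )
    n_keep = int(round(target_cov * genome_len / (2 * read_len)))
    rng = np.random.default_rng(seed)
    keys = rng.random(n_source)
    keep = np.sort(np.argpartition(keys, min(n_keep, n_source - 1))[:n_keep])
    with open(out1, "w") as o1, open(out2, "w") as o2:
        for i in keep:
            t, s, q = r1[i]
            o1.write(f"@{t}\n{s}\n+\n{q}\n")
            t, s, q = r2[i]
            o2.write(f"@{t}\n{s}\n+\n{q}\n")
    return n_keep
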