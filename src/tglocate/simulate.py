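"""Synthetic transgenic genomes and sequencing reads with known truth.

The generator emulates the data a transgene-mapping experiment produces:

* a host genome with a tunable fraction of repeat-unit copies (so that
  multi-mapping reads arise near insertion sites, as they do around the
  LINE-rich loci where transgenes tend to land),
* a transgenic allele carrying a tandem multi-copy transgene array, with
  optional truncation of the first copy and optional deletion of host
  sequence at the integration site,
* mate-pair (rf, ~3.8 kb fragments) or paired-end (fr, ~210 bp fragments)
  read pairs at a requested fold coverage, from a hemizygous (50/50
  transgenic/wild-type) or homozygous allele mixture,
* a sidecar truth table recording every pair's source allele, fragment and
  per-mate coordinates, so downstream calls can be scored against truth.

All randomness flows through one :class:`numpy.random.Generator`; a fixed
seed gives byte-identical FASTA/FASTQ/TSV output.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from . import _dna
from .errors import ParameterError
from .genome import Genome, TransgeneConstruct

ZYGOSITIES = ("hemizygous", "homozygous")


@dataclass
class SimTruth:
    """Ground truth of one simulated transgene integration event.

    ``insertion_pos`` is the 0-based host coordinate of the left breakpoint:
    host bases ``[insertion_pos, insertion_pos + host_deletion_len)`` are
    replaced by the transgene array on the transgenic allele.
    """

    chrom: str
    insertion_pos: int
    copy_number: int = 1
    host_deletion_len: int = 0
    first_copy_truncation: int = 0
    zygosity: str = "hemizygous"

    def validate(self, host: Genome, tg: TransgeneConstruct) -> None:
        if self.chrom not in host.sequences:
            raise ParameterError(f"unknown chromosome {self.chrom!r}")
        if self.copy_number < 1:
            raise ParameterError("copy_number must be >= 1")
        if self.host_deletion_len < 0 or self.first_copy_truncation < 0:
            raise ParameterError("deletion/truncation must be >= 0")
        if self.insertion_pos < 0:
            raise ParameterError("insertion_pos must be >= 0")
        L = len(host.sequences[self.chrom])
        if self.insertion_pos + self.host_deletion_len > L:
            raise ParameterError(
                f"insertion_pos + host_deletion_len exceeds length of {self.chrom}"
            )
        if self.first_copy_truncation >= len(tg):
            raise ParameterError("first_copy_truncation must be < transgene length")
        if self.zygosity not in ZYGOSITIES:
            raise ParameterError(f"zygosity must be one of {ZYGOSITIES}")

    @property
    def right_breakpoint(self) -> int:
        """0-based host coordinate of the right breakpoint."""
        return self.insertion_pos + self.host_deletion_len

    def array_length(self, tg: TransgeneConstruct) -> int:
        return self.copy_number * len(tg) - self.first_copy_truncation


def make_host_genome(
    n_chroms: int,
    chrom_len: int,
    repeat_fraction: float,
    repeat_unit_len: int = 6000,
    seed: int = 0,
    mutation_rate: float = 0.01,
) -> Genome:
    """Random host genome with a controlled repeat content.

    Approximately ``repeat_fraction`` of each chromosome is tiled with
    non-overlapping, lightly mutated (``mutation_rate`` substitutions) copies
    of one shared repeat unit, so reads from those regions multi-map. The
    placement log is kept on ``Genome.repeat_intervals``.
    """
    if n_chroms < 1 or chrom_len <= 0 or repeat_unit_len <= 0:
        raise ParameterError("n_chroms, chrom_len and repeat_unit_len must be positive")
    if not 0.0 <= repeat_fraction <= 1.0:
        raise ParameterError("repeat_fraction must be in [0, 1]")
    if chrom_len < 10 * repeat_unit_len:
        raise ParameterError("chrom_len must be at least 10 x repeat_unit_len")

    rng = np.random.default_rng(seed)
    unit = _dna.random_codes(rng, repeat_unit_len)
    sequences: dict[str, str] = {}
    intervals: dict[str, list[tuple[int, int]]] = {}
    for ci in range(n_chroms):
        name = f"chr{ci + 1}"
        codes = _dna.random_codes(rng, chrom_len)
        placed: list[tuple[int, int]] = []
        n_units = int(round(repeat_fraction * chrom_len / repeat_unit_len))
        if n_units:
            occupied = np.zeros(chrom_len, dtype=bool)
            attempts = 0
            max_attempts = 50 * n_units + 100
            while len(placed) < n_units and attempts < max_attempts:
                attempts += 1
                start = int(rng.integers(0, chrom_len - repeat_unit_len + 1))
                if occupied[start : start + repeat_unit_len].any():
                    continue
                copy = _dna.mutate_codes(rng, unit, mutation_rate)
                codes[start : start + repeat_unit_len] = copy
                occupied[start : start + repeat_unit_len] = True
                placed.append((start, start + repeat_unit_len))
        sequences[name] = _dna.decode(_dna.from_codes(codes))
        intervals[name] = sorted(placed)
    return Genome(sequences, repeat_intervals=intervals)


def make_transgenic_genome(
    host: Genome, tg: TransgeneConstruct, truth: SimTruth
) -> Genome:
    """The transgenic allele: host with the transgene array spliced in.

    ``host[:pos] + truncated-first-copy + (copy_number - 1) full copies +
    host[pos + deletion:]`` on ``truth.chrom``; other chromosomes unchanged.
    """
    truth.validate(host, tg)
    chrom_seq = host.sequences[truth.chrom]
    array = tg.sequence[truth.first_copy_truncation :] + tg.sequence * (
        truth.copy_number - 1
    )
    new_seq = (
        chrom_seq[: truth.insertion_pos]
        + array
        + chrom_seq[truth.right_breakpoint :]
    )
    sequences = dict(host.sequences)
    sequences[truth.chrom] = new_seq
    return Genome(sequences)


def theoretical_coverage(n_reads: int, read_len: int, genome_len: int) -> float:
    """Raw fold coverage ``n_reads * read_len / genome_len``."""
    if n_reads < 0 or read_len <= 0:
        raise ParameterError("n_reads must be >= 0 and read_len > 0")
    if genome_len <= 0:
        raise ParameterError("genome_len must be > 0")
    return n_reads * read_len / genome_len


@dataclass
class ReadPair:
    """One simulated pair, mate sequences in original (as-sequenced) order."""

    name: str
    seq1: str
    seq2: str
    qual1: list[int]
    qual2: list[int]
    orientation: str
    fragment_len: int


@dataclass
class ReadPairSet:
    """Batch container for simulated pairs.

    ``seq1``/``seq2`` are (n, read_len) uint8 ASCII arrays; ``qual1``/``qual2``
    hold integer Phred scores. ``truth`` has one row per pair with the source
    allele, fragment coordinates, and each mate's 0-based leftmost mapping
    coordinate and strand on its source allele.
    """

    names: list[str]
    seq1: np.ndarray
    seq2: np.ndarray
    qual1: np.ndarray
    qual2: np.ndarray
    truth: pd.DataFrame
    orientation: str
    read_len: int

    @property
    def n_pairs(self) -> int:
        return len(self.names)

    def pairs(self) -> Iterator[ReadPair]:
        for i, name in enumerate(self.names):
            yield ReadPair(
                name,
                _dna.decode(self.seq1[i]),
                _dna.decode(self.seq2[i]),
                self.qual1[i].tolist(),
                self.qual2[i].tolist(),
                self.orientation,
                int(self.truth["frag_len"].iat[i]),
            )

    def subset(self, idx: np.ndarray) -> "ReadPairSet":
        idx = np.asarray(idx)
        return ReadPairSet(
            [self.names[i] for i in idx],
            self.seq1[idx],
            self.seq2[idx],
            self.qual1[idx],
            self.qual2[idx],
            self.truth.iloc[idx].reset_index(drop=True),
            self.orientation,
            self.read_len,
        )

    def to_fastq(self, path1, path2) -> None:
        _write_fastq(path1, self.names, self.seq1, self.qual1, "/1")
        _write_fastq(path2, self.names, self.seq2, self.qual2, "/2")

    def truth_to_tsv(self, path) -> None:
        self.truth.assign(name=self.names).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_fastq(cls, path1, path2, orientation: str = "fr") -> "ReadPairSet":
        from .readqc import read_fastq_records

        r1 = list(read_fastq_records(path1))
        r2 = list(read_fastq_records(path2))
        if len(r1) != len(r2):
            raise ParameterError("FASTQ mate files differ in record count")
        names = [_strip_mate_suffix(t) for t, _, _ in r1]
        L = max((len(s) for _, s, _ in r1 + r2), default=0)
        n = len(r1)
        seq1 = np.full((n, L), ord("N"), dtype=np.uint8)
        seq2 = np.full((n, L), ord("N"), dtype=np.uint8)
        q1 = np.zeros((n, L), dtype=np.uint8)
        q2 = np.zeros((n, L), dtype=np.uint8)
        for i in range(n):
            for arr, qarr, (_, s, q) in ((seq1, q1, r1[i]), (seq2, q2, r2[i])):
                arr[i, : len(s)] = _dna.encode(s)
                qarr[i, : len(q)] = np.frombuffer(q.encode(), np.uint8) - 33
        truth = pd.DataFrame(index=range(n)).assign(frag_len=L)
        return cls(names, seq1, seq2, q1, q2, truth, orientation, L)


def _strip_mate_suffix(title: str) -> str:
    name = title.split()[0]
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    return name


def _write_fastq(path, names, seqs, quals, suffix: str) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(names):
            fh.write(
                f"@{name}{suffix}\n{_dna.decode(seqs[i])}\n+\n"
                f"{(quals[i] + 33).astype(np.uint8).tobytes().decode('ascii')}\n"
            )


def _two_state_qualities(
    rng: np.random.Generator,
    n_reads: int,
    read_len: int,
    low_read_fraction: float,
    switch_prob: float = 0.002,
) -> np.ndarray:
    """Per-base Phred scores from a sticky two-state chain.

    Reads start in the low state (~Q20) with probability
    ``low_read_fraction``, otherwise high (~Q38); the state persists along the
    read with switch probability ``switch_prob`` per base, plus +/-2 jitter.
    Low-start reads almost always fail the Q30-over-70-bases rule, high-start
    reads almost always pass (an early switch to the low state occasionally
    fails one), so the QC filter is exercised on both sides.
    """
    start_low = rng.random(n_reads) < low_read_fraction
    switches = rng.random((n_reads, read_len - 1)) < switch_prob
    parity = np.cumsum(switches, axis=1) % 2
    low = np.concatenate(
        [start_low[:, None], start_low[:, None] ^ parity.astype(bool)], axis=1
    )
    q = np.where(low, 20, 38) + rng.integers(-2, 3, size=(n_reads, read_len))
    return q.astype(np.uint8)


def simulate_reads(
    alleles: list[tuple[Genome, float]],
    coverage: float,
    read_len: int = 100,
    frag_mean: int = 3800,
    frag_sd: float | None = None,
    orientation: str = "rf",
    error_rate: float = 0.001,
    seed: int = 0,
    low_quality_read_fraction: float = 0.05,
    name_prefix: str = "sim",
) -> ReadPairSet:
    """Simulate read pairs from a weighted allele mixture.

    The pair count is ``round(coverage * total_len / (2 * read_len))`` where
    ``total_len`` is the weight-averaged allele length. Fragment lengths are
    drawn from a normal(``frag_mean``, ``frag_sd``) truncated to
    ``[read_len, frag_mean + 4 * frag_sd]``.

    Orientation conventions (fragment ``[s, s + f)`` on the source allele):

    * ``fr`` (paired-end): mate1 is the forward read at the fragment start,
      mate2 the reverse-complemented read at the fragment end — inward-facing.
    * ``rf`` (mate-pair, circularized-junction protocol): mate1 is the
      reverse-complemented read at the fragment start (maps on the minus
      strand), mate2 the forward read at the fragment end — outward-facing.
    """
    if coverage <= 0:
        raise ParameterError("coverage must be > 0")
    if not alleles:
        raise ParameterError("at least one allele required")
    if orientation not in ("fr", "rf"):
        raise ParameterError("orientation must be 'fr' or 'rf'")
    weights = np.array([w for _, w in alleles], dtype=float)
    if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
        raise ParameterError("allele weights must be >= 0 and sum to 1")
    if frag_mean <= read_len:
        raise ParameterError("frag_mean must exceed read_len")
    if frag_sd is None:
        frag_sd = 0.05 * frag_mean

    rng = np.random.default_rng(seed)
    total_len = sum(w * g.total_length for g, w in alleles)
    n_pairs = int(round(coverage * total_len / (2 * read_len)))
    if n_pairs == 0:
        raise ParameterError("requested coverage yields zero pairs")

    allele_idx = rng.choice(len(alleles), size=n_pairs, p=weights)
    chrom_idx = np.zeros(n_pairs, dtype=np.int64)
    for ai, (g, _) in enumerate(alleles):
        mask = allele_idx == ai
        if not mask.any():
            continue
        lens = np.array([len(s) for s in g.sequences.values()], dtype=float)
        chrom_idx[mask] = rng.choice(len(lens), size=int(mask.sum()), p=lens / lens.sum())

    lo, hi = read_len, frag_mean + 4 * frag_sd
    a, b = (lo - frag_mean) / frag_sd, (hi - frag_mean) / frag_sd
    frag = np.rint(
        stats.truncnorm.rvs(a, b, loc=frag_mean, scale=frag_sd, size=n_pairs, random_state=rng)
    ).astype(np.int64)

    chrom_lens = np.empty(n_pairs, dtype=np.int64)
    for ai, (g, _) in enumerate(alleles):
        names = g.names
        for ci, name in enumerate(names):
            m = (allele_idx == ai) & (chrom_idx == ci)
            if m.any():
                chrom_lens[m] = len(g.sequences[name])
    frag = np.minimum(frag, chrom_lens)
    starts = rng.integers(0, chrom_lens - frag + 1)

    seq1 = np.empty((n_pairs, read_len), dtype=np.uint8)
    seq2 = np.empty((n_pairs, read_len), dtype=np.uint8)
    offsets = np.arange(read_len)
    for ai, (g, _) in enumerate(alleles):
        for ci, name in enumerate(g.names):
            m = (allele_idx == ai) & (chrom_idx == ci)
            if not m.any():
                continue
            arr = g.encoded(name)
            w1 = starts[m, None] + offsets
            w2 = (starts[m] + frag[m] - read_len)[:, None] + offsets
            s1, s2 = arr[w1], arr[w2]
            if orientation == "fr":
                seq1[m], seq2[m] = s1, _dna.revcomp(s2)
            else:  # rf: outward-facing
                seq1[m], seq2[m] = _dna.revcomp(s1), s2
    # per-mate truth: leftmost 0-based mapping coordinate and strand
    start1, start2 = starts, starts + frag - read_len
    if orientation == "fr":
        strand1 = np.full(n_pairs, "+")
        strand2 = np.full(n_pairs, "-")
    else:
        strand1 = np.full(n_pairs, "-")
        strand2 = np.full(n_pairs, "+")

    if error_rate > 0:
        for s in (seq1, seq2):
            codes = _dna.to_codes(s)
            codes = _dna.mutate_codes(rng, codes, error_rate)
            s[:] = _dna.from_codes(codes)

    qual1 = _two_state_qualities(rng, n_pairs, read_len, low_quality_read_fraction)
    qual2 = _two_state_qualities(rng, n_pairs, read_len, low_quality_read_fraction)

    names = [f"{name_prefix}:{i:08d}" for i in range(n_pairs)]
    chrom_names = np.empty(n_pairs, dtype=object)
    for ai, (g, _) in enumerate(alleles):
        for ci, name in enumerate(g.names):
            m = (allele_idx == ai) & (chrom_idx == ci)
            if m.any():
                chrom_names[m] = name
    truth = pd.DataFrame(
        {
            "allele": allele_idx,
            "chrom": chrom_names,
            "frag_start": starts,
            "frag_len": frag,
            "start1": start1,
            "strand1": strand1,
            "start2": start2,
            "strand2": strand2,
        }
    )
    return ReadPairSet(names, seq1, seq2, qual1, qual2, truth, orientation, read_len)


def hemizygous_alleles(transgenic: Genome, wild_type: Genome) -> list[tuple[Genome, float]]:
    """50/50 transgenic / wild-type mixture, the hemizygous genotype."""
    return [(transgenic, 0.5), (wild_type, 0.5)]
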