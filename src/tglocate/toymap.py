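"""A deliberately simple seed-and-extend read mapper.

The pipeline normally consumes SAM from a production aligner; this mapper
exists so that simulations, tests and the end-to-end harness run with no
external binary. It does exact k-mer seeding (a few fixed offsets per read,
both strands) followed by full-length ungapped extension allowing up to
``ceil(0.05 * read_len)`` mismatches. MAPQ is binary: 60 for a unique best
location, 0 for ties (one reported at random, seeded); no location sets the
unmapped flag. Downstream filtering only thresholds MAPQ at 20, so the
binary scale is sufficient and transparent.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _dna
from .errors import ParameterError
from .genome import Genome


@dataclass
class MapResult:
    """Batch single-end mapping result (parallel arrays, one slot per read)."""

    ref_names: list[str]
    mapped: np.ndarray  # bool
    ref_id: np.ndarray  # int32, -1 when unmapped
    pos0: np.ndarray  # int64, 0-based leftmost, -1 when unmapped
    is_reverse: np.ndarray  # bool
    mapq: np.ndarray  # uint8
    nm: np.ndarray  # int16 mismatch count, -1 when unmapped

    @property
    def n(self) -> int:
        return len(self.mapped)


class KmerIndex:
    """Sorted exact k-mer (2-bit packed) index over a genome's forward strand."""

    def __init__(self, genome: Genome, k: int = 21):
        if k < 4 or k > 31:
            raise ParameterError("k must be in [4, 31]")
        if genome.total_length == 0:
            raise ParameterError("empty reference")
        self.k = k
        self.genome = genome
        self.ref_names = genome.names
        self.ref_codes: list[np.ndarray] = []
        hashes, poss, cids = [], [], []
        for ci, name in enumerate(self.ref_names):
            codes = _dna.to_codes(genome.encoded(name))
            self.ref_codes.append(codes)
            L = len(codes)
            if L < k:
                continue
            n = L - k + 1
            h = np.zeros(n, dtype=np.uint64)
            for j in range(k):
                h = h * np.uint64(4) + codes[j : j + n].astype(np.uint64)
            bad = np.concatenate([[0], np.cumsum(codes > 3)])
            valid = (bad[k:] - bad[:-k]) == 0
            hashes.append(h[valid])
            poss.append(np.flatnonzero(valid).astype(np.int64))
            cids.append(np.full(int(valid.sum()), ci, dtype=np.int32))
        if not hashes:
            raise ParameterError("reference shorter than k")
        h = np.concatenate(hashes)
        order = np.argsort(h, kind="stable")
        self._hash = h[order]
        self._pos = np.concatenate(poss)[order]
        self._cid = np.concatenate(cids)[order]
        self.ref_lengths = [len(c) for c in self.ref_codes]

    def hash_windows(self, codes2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pack each row's first k codes; returns (hashes, validity)."""
        k = self.k
        h = np.zeros(codes2d.shape[0], dtype=np.uint64)
        for j in range(k):
            h = h * np.uint64(4) + codes2d[:, j].astype(np.uint64)
        valid = (codes2d[:, :k] <= 3).all(axis=1)
        return h, valid

    def lookup(self, hashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._hash, hashes, side="left")
        hi = np.searchsorted(self._hash, hashes, side="right")
        return lo, hi

    def entries(self, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        return self._cid[lo:hi], self._pos[lo:hi]


def map_batch(
    index: KmerIndex,
    seqs: np.ndarray,
    seed: int = 0,
    max_mismatch_frac: float = 0.05,
    max_candidates: int = 100,
) -> MapResult:
    """Map a batch of equal-length reads (uint8 ASCII, shape (n, L)).

    Reads with no seed hit anywhere are rejected in bulk, so mapping a large
    library against a small reference (the transgene stage) costs little.
    """
    n, L = seqs.shape
    k = index.k
    if L < k:
        raise ParameterError("read length shorter than seed length k")
    rng = np.random.default_rng(seed)
    maxmm = math.ceil(max_mismatch_frac * L)

    fwd = _dna.to_codes(seqs)
    rc = _dna.CODE_COMP[fwd][:, ::-1]
    offsets = sorted({0, (L - k) // 2, L - k})

    # seed pass: record (read, lo, hi, offset, rev) for every hit
    hit_lists: dict[int, list[tuple[int, int, int, bool]]] = {}
    for rev, codes in ((False, fwd), (True, rc)):
        for off in offsets:
            h, valid = index.hash_windows(codes[:, off : off + k])
            lo, hi = index.lookup(h)
            has = (hi > lo) & valid
            for r in np.flatnonzero(has):
                hit_lists.setdefault(int(r), []).append(
                    (int(lo[r]), int(hi[r]), off, rev)
                )

    mapped = np.zeros(n, dtype=bool)
    ref_id = np.full(n, -1, dtype=np.int32)
    pos0 = np.full(n, -1, dtype=np.int64)
    is_rev = np.zeros(n, dtype=bool)
    mapq = np.zeros(n, dtype=np.uint8)
    nm = np.full(n, -1, dtype=np.int16)

    for r in sorted(hit_lists):
        seen: set[tuple[int, int, bool]] = set()
        best_nm = maxmm + 1
        best: list[tuple[int, int, bool, int]] = []
        capped = False
        for lo, hi, off, rev in hit_lists[r]:
            cids, poss = index.entries(lo, hi)
            for cid, p in zip(cids, poss):
                start = int(p) - off
                if start < 0 or start + L > index.ref_lengths[cid]:
                    continue
                key = (int(cid), start, rev)
                if key in seen:
                    continue
                if len(seen) >= max_candidates:
                    capped = True
                    break
                seen.add(key)
                read_codes = rc[r] if rev else fwd[r]
                mism = int(
                    np.count_nonzero(index.ref_codes[cid][start : start + L] != read_codes)
                )
                if mism < best_nm:
                    best_nm = mism
                    best = [(int(cid), start, rev, mism)]
                elif mism == best_nm:
                    best.append((int(cid), start, rev, mism))
            if capped:
                break
        if best_nm > maxmm or not best:
            continue
        if len(best) == 1 and not capped:
            cid, start, rev, mism = best[0]
            q = 60
        else:
            best.sort()
            cid, start, rev, mism = best[int(rng.integers(0, len(best)))]
            q = 0
        mapped[r] = True
        ref_id[r] = cid
        pos0[r] = start
        is_rev[r] = rev
        mapq[r] = q
        nm[r] = mism
    return MapResult(index.ref_names, mapped, ref_id, pos0, is_rev, mapq, nm)


def toy_map(reads, reference: Genome, k: int = 21, seed: int = 0):
    """Spec-level convenience wrapper producing SAM-style records.

    ``reads`` is either a :class:`~tglocate.simulate.ReadPairSet` (paired
    flags emitted, name-sorted output) or an iterable of ``(name, seq,
    qual_str)`` single-end tuples.
    """
    from .samio import sam_records_from_pairs, sam_records_from_single
    from .simulate import ReadPairSet

    index = KmerIndex(reference, k=k)
    if isinstance(reads, ReadPairSet):
        r1 = map_batch(index, reads.seq1, seed=seed)
        r2 = map_batch(index, reads.seq2, seed=seed + 1)
        return list(sam_records_from_pairs(reads, r1, r2))
    reads = list(reads)
    if not reads:
        return []
    L = len(reads[0][1])
    if any(len(s) != L for _, s, _ in reads):
        raise ParameterError("toy_map batch requires equal-length reads")
    seqs = np.vstack([_dna.encode(s) for _, s, _ in reads])
    res = map_batch(index, seqs, seed=seed)
    return list(sam_records_from_single(reads, res))
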