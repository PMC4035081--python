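"""Reference containers: host genomes and transgene constructs.

A :class:`Genome` is a plain mapping of chromosome name to uppercase DNA
string, with FASTA round-tripping through Biopython. The simulator attaches
its repeat-placement log so tests can audit repeat content directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _dna
from .errors import ParameterError

_ALPHABET = frozenset("ACGTN")


@dataclass
class Genome:
    """A set of named chromosomes.

    Parameters
    ----------
    sequences
        Mapping chromosome name -> uppercase DNA string (A/C/G/T/N).
    repeat_intervals
        Optional per-chromosome log of [start, end) intervals covered by
        placed repeat-unit copies (filled by the simulator).
    """

    sequences: dict[str, str]
    repeat_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    _encoded: dict[str, np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ParameterError("genome has no chromosomes")
        for name, seq in self.sequences.items():
            if not name:
                raise ParameterError("empty chromosome name")
            if not seq:
                raise ParameterError(f"chromosome {name!r} has zero length")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ParameterError(
                    f"chromosome {name!r} contains non-DNA characters {sorted(bad)!r}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def encoded(self, chrom: str) -> np.ndarray:
        """Chromosome as a cached uint8 ASCII array."""
        arr = self._encoded.get(chrom)
        if arr is None:
            arr = _dna.encode(self.sequences[chrom])
            self._encoded[chrom] = arr
        return arr

    def write_fasta(self, path, width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)

    @classmethod
    def read_fasta(cls, path) -> "Genome":
        seqs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(seqs)

    def write_sizes(self, path) -> None:
        """Two-column chrom\\tlength file (UCSC genome-sizes style)."""
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f"{name}\t{len(seq)}\n")

    @staticmethod
    def read_sizes(path) -> dict[str, int]:
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                name, length = line.split()[:2]
                sizes[name] = int(length)
        return sizes


@dataclass
class TransgeneConstruct:
    """The exogenous construct: the in-silico reconstructed sequence that the
    first alignment stage uses as its reference."""

    sequence: str
    label: str = "transgene"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParameterError("transgene sequence is empty")
        if not self.label:
            raise ParameterError("transgene label is empty")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def as_genome(self) -> Genome:
        """Single-sequence reference for the transgene alignment stage."""
        return Genome({self.label: self.sequence})

    @classmethod
    def read_fasta(cls, path) -> "TransgeneConstruct":
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise ParameterError(f"no sequences in {path}")
        return cls(str(recs[0].seq).upper(), recs[0].id)

    def write_fasta(self, path) -> None:
        self.as_genome().write_fasta(path)
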