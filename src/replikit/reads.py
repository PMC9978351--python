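"""In-memory container for short-read batches plus FASTQ round-tripping.

A :class:`ReadSet` keeps all reads of one file in three parallel numpy
structures (base codes, qualities, lengths) so that trimming and mapping can
run vectorised / jit-compiled over the whole batch.  Rows are left-aligned;
columns past ``lengths[i]`` are padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import PHRED_OFFSET, decode, encode, string_to_quals


@dataclass
class ReadSet:
    codes: np.ndarray          # (n, Lmax) uint8 base codes
    quals: np.ndarray          # (n, Lmax) uint8 Phred scores
    lengths: np.ndarray        # (n,) int32
    names: list[str] = field(default_factory=list)
    terminal_clipped: bool = False   # set once the fixed terminal clip ran

    def __post_init__(self) -> None:
        if self.codes.shape != self.quals.shape:
            raise ValueError("codes and quals shapes differ")
        if len(self.lengths) != self.codes.shape[0]:
            raise ValueError("lengths does not match number of rows")
        if not self.names:
            self.names = [f"read{i}" for i in range(len(self.lengths))]

    def __len__(self) -> int:
        return int(self.codes.shape[0])

    def sequence(self, i: int) -> str:
        return decode(self.codes[i, : self.lengths[i]])

    def quality(self, i: int) -> np.ndarray:
        return self.quals[i, : self.lengths[i]]

    def subset(self, idx: np.ndarray) -> "ReadSet":
        idx = np.asarray(idx)
        return ReadSet(
            self.codes[idx].copy(),
            self.quals[idx].copy(),
            self.lengths[idx].copy(),
            [self.names[i] for i in idx],
            terminal_clipped=self.terminal_clipped,
        )

    @classmethod
    def from_records(cls, records: list[tuple[str, str, str]]) -> "ReadSet":
        """Build from (name, sequence, quality-string) triples."""
        n = len(records)
        lmax = max((len(s) for _, s, _ in records), default=0)
        codes = np.full((n, lmax), 4, dtype=np.uint8)
        quals = np.zeros((n, lmax), dtype=np.uint8)
        lengths = np.zeros(n, dtype=np.int32)
        names = []
        for i, (name, seq, qual) in enumerate(records):
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {i} ({name}): "
                    f"sequence and quality lengths differ"
                )
            codes[i, : len(seq)] = encode(seq)
            quals[i, : len(qual)] = string_to_quals(qual)
            lengths[i] = len(seq)
            names.append(name)
        return cls(codes, quals, lengths, names)


def read_fastq(path) -> ReadSet:
    with open(path) as fh:
        records = [(name.split()[0], seq, qual) for name, seq, qual in FastqGeneralIterator(fh)]
    return ReadSet.from_records(records)


def write_fastq(reads: ReadSet, path) -> None:
    offset = PHRED_OFFSET
    with open(path, "w") as fh:
        for i in range(len(reads)):
            n = reads.lengths[i]
            seq = decode(reads.codes[i, :n])
            qual = (reads.quals[i, :n] + offset).tobytes().decode("ascii")
            fh.write(f"@{reads.names[i]}\n{seq}\n+\n{qual}\n")
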