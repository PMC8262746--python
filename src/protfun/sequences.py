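"""Protein sequence reading and one-hot encoding.

Sequences are one-hot encoded over the 20 standard residues plus a single
"unknown" bucket (``X``) that absorbs ambiguity codes and nonstandard
symbols; sequences longer than ``max_len`` are truncated and shorter ones
are right-padded with all-zero position vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, NamedTuple

import numpy as np
from Bio import SeqIO

from .errors import FormatError

#: 20 standard residues (alphabetical) + unknown bucket.
DEFAULT_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
DEFAULT_MAX_LEN = 2000


class SequenceRecord(NamedTuple):
    identifier: str
    sequence: str


def read_fasta(stream: IO[str] | str) -> list[SequenceRecord]:
    """Read a FASTA file into records, in file order.

    Sequences are uppercased and a terminal ``*`` stop symbol is stripped.
    Duplicate identifiers and empty sequences are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(stream, "fasta"):
        seq = str(entry.seq).upper().rstrip("*")
        if entry.id in seen:
            raise FormatError(f"duplicate sequence identifier {entry.id!r}")
        if not seq:
            raise FormatError(f"record {entry.id!r} has an empty sequence")
        seen.add(entry.id)
        records.append(SequenceRecord(entry.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], stream: IO[str],
                width: int = 60) -> None:
    for rec in records:
        stream.write(f">{rec.identifier}\n")
        for i in range(0, len(rec.sequence), width):
            stream.write(rec.sequence[i:i + width] + "\n")


@dataclass
class EncodedBatch:
    """One-hot encoded sequences: ``matrix[i, pos, residue]`` ∈ {0, 1}.

    Rows beyond a sequence's (possibly truncated) length are all-zero
    padding, so each position vector sums to 1 or 0.
    """

    identifiers: list[str]
    matrix: np.ndarray  # (n, max_len, len(alphabet)) float32
    alphabet: str
    max_len: int

    def __len__(self) -> int:
        return len(self.identifiers)


def encode_batch(records: Iterable[SequenceRecord],
                 max_len: int = DEFAULT_MAX_LEN,
                 alphabet: str = DEFAULT_ALPHABET) -> EncodedBatch:
    """Encode records into a ``(n, max_len, |alphabet|)`` one-hot tensor.

    Residues outside the alphabet map to its last symbol (the unknown
    bucket).  Encoding is deterministic and order-preserving.
    """
    records = list(records)
    index = {aa: i for i, aa in enumerate(alphabet)}
    unknown = len(alphabet) - 1
    matrix = np.zeros((len(records), max_len, len(alphabet)), dtype=np.float32)
    for row, rec in enumerate(records):
        for pos, aa in enumerate(rec.sequence[:max_len]):
            matrix[row, pos, index.get(aa, unknown)] = 1.0
    return EncodedBatch(
        identifiers=[r.identifier for r in records],
        matrix=matrix,
        alphabet=alphabet,
        max_len=max_len,
    )
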