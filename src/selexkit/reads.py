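"""The RoundReads container: one selection round's variable regions."""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import seq


@dataclass
class RoundReads:
    """Extracted variable-region sequences for one SELEX round.

    All sequences are plain ACGT and share one length L (the randomized
    region of the library design, 40 nt by default).
    """

    round_index: int
    sequences: list[str]
    condition_label: str = ""
    source: str = "unknown"
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.round_index < 0:
            raise ValueError("round_index must be >= 0")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        if not self.sequences:
            raise ValueError("no sequences")
        return len(self.sequences[0])

    def codes(self) -> np.ndarray:
        """(n, L) base-code matrix; validated ACGT, cached."""
        if self._codes is None or self._codes.shape[0] != len(self.sequences):
            self._codes = seq.encode_matrix(self.sequences)
        return self._codes

    @classmethod
    def from_codes(cls, codes: np.ndarray, round_index: int,
                   condition_label: str = "", source: str = "simulated") -> "RoundReads":
        sequences = [seq.decode(row) for row in codes]
        obj = cls(round_index=round_index, sequences=sequences,
                  condition_label=condition_label, source=source)
        obj._codes = np.asarray(codes, dtype=np.uint8)
        return obj

    def write_fasta(self, path: str | Path) -> None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for i, s in enumerate(self.sequences):
                fh.write(f">r{self.round_index}_read{i}\n{s}\n")

    @classmethod
    def read_fasta(cls, path: str | Path, round_index: int,
                   condition_label: str = "") -> "RoundReads":
        from Bio import SeqIO

        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            sequences = [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")]
        return cls(round_index=round_index, sequences=sequences,
                   condition_label=condition_label, source=str(path))
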