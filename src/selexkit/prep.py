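"""Raw FASTQ -> clean variable regions.

Mirrors the filtering a SELEX-seq run goes through before counting:
records flagged by the sequencer's chastity filter (the Y/N field of a
CASAVA 1.8 header) are discarded, reads matching a contaminant (e.g.
phiX spike-in) are removed, and the fixed flank/barcode context is
stripped to leave the 40-nt randomized region. Contaminant screening is
done by shared exact words: a read is a contaminant hit if any window of
length ``contaminant_screen_word_length`` (default 25) also occurs in
the contaminant sequence on either strand — for error-free reads this is
equivalent to zero-mismatch mapping of reads contained in the
contaminant, without requiring an aligner.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

from . import seq
from .reads import RoundReads

DROP_REASONS = ("casava_filter", "too_short", "flank_not_found",
                "ambiguous_base", "contaminant")


@dataclass
class PrepConfig:
    left_flank: str = ""
    right_flank: str = ""
    variable_length: int = 40
    max_flank_mismatches: int = 0
    drop_filter_flagged: bool = True
    contaminant_screen_word_length: int = 25

    def __post_init__(self) -> None:
        if self.variable_length <= 0:
            raise ValueError("variable_length must be positive")
        if self.max_flank_mismatches < 0:
            raise ValueError("max_flank_mismatches must be >= 0")
        if self.contaminant_screen_word_length < 1:
            raise ValueError("contaminant_screen_word_length must be >= 1")


@dataclass
class PrepReport:
    n_input: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=lambda: {r: 0 for r in DROP_REASONS})

    def drop(self, reason: str) -> None:
        self.dropped[reason] += 1

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def to_tsv(self, path: str | Path, label: str = "") -> None:
        with open(path, "w") as fh:
            fh.write("label\treason\tcount\n")
            fh.write(f"{label}\tinput\t{self.n_input}\n")
            fh.write(f"{label}\tkept\t{self.n_kept}\n")
            for reason in DROP_REASONS:
                fh.write(f"{label}\t{reason}\t{self.dropped[reason]}\n")


class ExtractionError(ValueError):
    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


def casava_filter_flagged(description: str) -> bool:
    """True if a CASAVA-1.8 header marks the read as failing the chastity
    filter (second colon-field of the part after the first space is "Y")."""
    parts = description.split(None, 1)
    if len(parts) < 2:
        return False
    fields = parts[1].split(":")
    return len(fields) >= 2 and fields[1] == "Y"


def _find_flank(read: str, flank: str, budget: int) -> int:
    """Leftmost start of ``flank`` in ``read`` with <= budget mismatches; -1
    if absent."""
    if budget == 0:
        return read.find(flank)
    m = len(flank)
    for start in range(len(read) - m + 1):
        mism = 0
        for a, b in zip(read[start:start + m], flank):
            if a != b:
                mism += 1
                if mism > budget:
                    break
        else:
            return start
    return -1


def extract_variable_region(record_sequence: str, config: PrepConfig) -> str:
    """Return the L bases following the left flank (0-based half-open).

    With empty flanks the first L bases are returned. Raises
    ExtractionError with reason "too_short" or "flank_not_found".
    """
    read = record_sequence.upper()
    L = config.variable_length
    flank = config.left_flank.upper()
    if len(read) < len(flank) + L:
        raise ExtractionError("too_short", f"read of length {len(read)} cannot "
                              f"contain flank ({len(flank)}) + {L} nt")
    if not flank:
        return read[:L]
    pos = _find_flank(read, flank, config.max_flank_mismatches)
    if pos < 0 or pos + len(flank) + L > len(read):
        raise ExtractionError("flank_not_found",
                              "left flank not found within mismatch budget")
    start = pos + len(flank)
    return read[start:start + L]


def load_contaminant_words(fasta_path: str | Path, word_length: int) -> set[str]:
    """All length-w words of the contaminant sequences, both strands."""
    from Bio import SeqIO

    path = Path(fasta_path)
    opener = gzip.open if path.suffix == ".gz" else open
    words: set[str] = set()
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            s = str(rec.seq).upper()
            for strand in (s, seq.revcomp(s)):
                for i in range(len(strand) - word_length + 1):
                    words.add(strand[i:i + word_length])
    return words


def _is_contaminant(region: str, words: set[str], w: int) -> bool:
    return any(region[i:i + w] in words for i in range(len(region) - w + 1))


def parse_fastq(path: str | Path):
    """Yield (description, sequence) pairs from a FASTQ(.gz) file."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.description, str(rec.seq)


def filter_reads(records, config: PrepConfig,
                 contaminant_fasta: str | Path | None = None,
                 round_index: int = 0, condition_label: str = "",
                 source: str = "filtered") -> tuple[RoundReads, PrepReport]:
    """Filter + extract a round's reads.

    ``records`` is a FASTQ path or an iterable of (description, sequence)
    pairs. Order of checks per record: CASAVA filter flag, flank-anchored
    extraction, ambiguous-base check, contaminant screen. The report
    conserves counts: input == kept + sum(dropped per reason).
    """
    if isinstance(records, (str, Path)):
        source = str(records)
        records = parse_fastq(records)
    contaminant_words: set[str] | None = None
    w = config.contaminant_screen_word_length
    if contaminant_fasta is not None:
        contaminant_words = load_contaminant_words(contaminant_fasta, w)

    report = PrepReport()
    kept: list[str] = []
    for description, sequence in records:
        report.n_input += 1
        if config.drop_filter_flagged and casava_filter_flagged(description):
            report.drop("casava_filter")
            continue
        try:
            region = extract_variable_region(sequence, config)
        except ExtractionError as exc:
            report.drop(exc.reason)
            continue
        if any(c not in "ACGT" for c in region):
            report.drop("ambiguous_base")
            continue
        if contaminant_words and _is_contaminant(region, contaminant_words, w):
            report.drop("contaminant")
            continue
        kept.append(region)
    report.n_kept = len(kept)
    out = RoundReads(round_index=round_index, sequences=kept,
                     condition_label=condition_label, source=source)
    return out, report
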