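"""Low-level DNA sequence utilities.

Every k-mer of length ``k`` is identified with its 2-bit packed integer
index: ``A=0, C=1, G=2, T=3``, most significant digit first, so that the
numeric order of indices equals the lexicographic order of words. Dense
numpy arrays indexed by these integers are the workhorse representation
for the ~1.05 million 10-mers the pipeline tracks.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_CODE_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)

# IUPAC degenerate alphabet -> set of base codes
IUPAC_CODES: dict[str, frozenset[int]] = {
    "A": frozenset({0}), "C": frozenset({1}), "G": frozenset({2}), "T": frozenset({3}),
    "R": frozenset({0, 2}), "Y": frozenset({1, 3}), "S": frozenset({1, 2}),
    "W": frozenset({0, 3}), "K": frozenset({2, 3}), "M": frozenset({0, 1}),
    "B": frozenset({1, 2, 3}), "D": frozenset({0, 2, 3}), "H": frozenset({0, 1, 3}),
    "V": frozenset({0, 1, 2}), "N": frozenset({0, 1, 2, 3}),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# byte-level translation table for fast reverse complement of ACGT strings
_RC_TABLE = bytes.maketrans(b"ACGT", b"TGCA")

# byte -> code lookup (255 marks non-ACGT)
_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_TO_CODE.items():
    _BYTE_TO_CODE[ord(_b)] = _c


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_RC_TABLE)[::-1]


def iupac_revcomp(pattern: str) -> str:
    """Reverse complement of a degenerate (IUPAC) pattern."""
    try:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in pattern {pattern!r}") from exc


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code vector; reject other characters."""
    codes = _BYTE_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.size and codes.max() > 3:
        bad = seq[int(np.argmax(codes > 3))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[np.asarray(codes, dtype=np.intp)].tobytes().decode()


def encode_matrix(seqs: list[str]) -> np.ndarray:
    """Encode equal-length ACGT strings as an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must all have equal length")
    raw = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), L)
    codes = _BYTE_TO_CODE[raw]
    if codes.max(initial=0) > 3:
        i, j = np.argwhere(codes > 3)[0]
        raise ValueError(f"non-ACGT character {seqs[i][j]!r} in sequence {i}")
    return codes


def word_to_index(word: str) -> int:
    idx = 0
    for c in word:
        try:
            idx = idx * 4 + _BASE_TO_CODE[c]
        except KeyError as exc:
            raise ValueError(f"non-ACGT character {c!r} in word {word!r}") from exc
    return idx


def index_to_word(idx: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append(BASES[idx & 3])
        idx >>= 2
    return "".join(reversed(chars))


def indices_to_words(idx: np.ndarray, k: int) -> list[str]:
    idx = np.asarray(idx, dtype=np.int64)
    out = np.empty((idx.size, k), dtype=np.uint8)
    for j in range(k):
        out[:, k - 1 - j] = _CODE_TO_BASE[(idx >> (2 * j)) & 3]
    return [row.tobytes().decode() for row in out]


def window_indices(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed indices of all length-k windows.

    ``codes`` is an (n, L) matrix (or length-L vector) of base codes; the
    result has shape (n, L-k+1) (or (L-k+1,)).
    """
    codes = np.asarray(codes)
    single = codes.ndim == 1
    if single:
        codes = codes[None, :]
    L = codes.shape[1]
    if k < 1 or k > L:
        raise ValueError(f"k={k} incompatible with read length {L}")
    base = codes.astype(np.int64)
    n_windows = L - k + 1
    idx = np.empty((codes.shape[0], n_windows), dtype=np.int64)
    # rolling 2-bit hash: O(L) vector ops instead of an (n, L-k+1, k) blowup
    cur = np.zeros(codes.shape[0], dtype=np.int64)
    for j in range(k):
        cur = cur * 4 + base[:, j]
    idx[:, 0] = cur
    mask = 4 ** (k - 1) - 1
    for j in range(1, n_windows):
        cur = ((cur & mask) << 2) | base[:, j + k - 1]
        idx[:, j] = cur
    return idx[0] if single else idx


def revcomp_index(idx: np.ndarray | int, k: int):
    """Packed index of the reverse complement, vectorized."""
    scalar = np.isscalar(idx)
    idx = np.asarray(idx, dtype=np.int64)
    rc = np.zeros_like(idx)
    for t in range(k):
        digit = (idx >> (2 * (k - 1 - t))) & 3
        rc += (3 - digit) << (2 * t)
    return int(rc) if scalar else rc


def canonical_index(idx: np.ndarray | int, k: int):
    """Lexicographically smaller of a word index and its reverse complement."""
    rc = revcomp_index(idx, k)
    if np.isscalar(idx):
        return min(int(idx), rc)
    return np.minimum(np.asarray(idx, dtype=np.int64), rc)


def pattern_mask(pattern: str) -> np.ndarray:
    """Boolean mask over all 4^k indices matching a degenerate IUPAC pattern."""
    k = len(pattern)
    n = 4 ** k
    mask = np.ones(n, dtype=bool)
    idx = np.arange(n, dtype=np.int64)
    for j, letter in enumerate(pattern.upper()):
        try:
            allowed = IUPAC_CODES[letter]
        except KeyError as exc:
            raise ValueError(f"non-IUPAC character {letter!r} in pattern") from exc
        if len(allowed) == 4:
            continue
        digit = (idx >> (2 * (k - 1 - j))) & 3
        mask &= np.isin(digit, list(allowed))
    return mask
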