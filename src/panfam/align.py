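"""Affine-gap pairwise protein alignment (Gotoh dynamic programming).

One DP engine serves both alignment modes the pipeline needs: Smith–Waterman
local alignment for the homology scan (a self-contained stand-in for a BLASTp
search) and Needleman–Wunsch global alignment for the whole-protein coverage
and identity computations of the duplicate-pair rule. Scoring defaults to
BLOSUM62 with gap open 11 / extend 1 (a gap of length L costs open + L·extend).

The fill is numba-compiled; traceback is plain Python with a deterministic
move preference (diagonal, then vertical, then horizontal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

logger = logging.getLogger("panfam")

NEG_INF = -1e30

_BLOSUM62 = None
_ALPHABET: str | None = None
_warned_residues: set[str] = set()


def _blosum62() -> tuple[np.ndarray, str]:
    global _BLOSUM62, _ALPHABET
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        _ALPHABET = str(mat.alphabet)
        _BLOSUM62 = np.asarray(mat, dtype=np.float64)
    return _BLOSUM62, _ALPHABET


def substitution_matrix(scoring=None) -> tuple[np.ndarray, str]:
    """Resolve ``scoring`` into (matrix, alphabet).

    ``None`` -> BLOSUM62; a ``(match, mismatch)`` pair -> simple scoring over
    the 20 residues + X; otherwise a Biopython substitution matrix.
    """
    if scoring is None:
        return _blosum62()
    if isinstance(scoring, tuple) and len(scoring) == 2:
        match, mismatch = scoring
        alphabet = "ACDEFGHIKLMNPQRSTVWYX"
        n = len(alphabet)
        mat = np.full((n, n), float(mismatch))
        np.fill_diagonal(mat, float(match))
        return mat, alphabet
    return np.asarray(scoring, dtype=np.float64), str(scoring.alphabet)


def encode(seq: str, alphabet: str) -> np.ndarray:
    """Encode residues as alphabet indices; unknown residues become X (logged once)."""
    x = alphabet.index("X") if "X" in alphabet else 0
    idx = {c: i for i, c in enumerate(alphabet)}
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        j = idx.get(ch)
        if j is None:
            if ch not in _warned_residues:
                _warned_residues.add(ch)
                logger.warning("alignment: residue %r not in scoring table, treated as X", ch)
            j = x
        out[i] = j
    return out


@njit(cache=True)
def _gotoh_fill(a, b, sub, gap_open, gap_ext, local):  # pragma: no cover (numba)
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), NEG_INF)  # gap in b (vertical)
    if not local:
        for j in range(1, m + 1):
            E[0, j] = -(gap_open + gap_ext * j)
            H[0, j] = E[0, j]
        for i in range(1, n + 1):
            F[i, 0] = -(gap_open + gap_ext * i)
            H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open - gap_ext, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_ext, F[i - 1, j] - gap_ext)
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            h = max(h, E[i, j])
            h = max(h, F[i, j])
            if local and h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


@dataclass
class Alignment:
    """A pairwise alignment: aligned strings with '-' gaps plus summary stats.

    ``identity`` is the fraction of identical residue pairs over columns where
    both sequences have a residue; spans are 1-based inclusive."""

    score: float
    aligned_a: str
    aligned_b: str
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    query_id: str = ""
    subject_id: str = ""

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def aligned_pairs(self) -> int:
        return sum(1 for x, y in zip(self.aligned_a, self.aligned_b)
                   if x != "-" and y != "-")

    @property
    def identity(self) -> float:
        pairs = self.aligned_pairs
        if pairs == 0:
            return 0.0
        same = sum(1 for x, y in zip(self.aligned_a, self.aligned_b)
                   if x == y and x != "-")
        return same / pairs


def _traceback(a, b, seq_a, seq_b, H, E, F, sub, gap_open, gap_ext,
               i, j, local) -> tuple[str, str, int, int]:
    out_a, out_b = [], []
    state = "H"
    while i > 0 or j > 0:
        if local and state == "H" and H[i, j] == 0.0:
            break
        if state == "H":
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]:
                out_a.append(seq_a[i - 1])
                out_b.append(seq_b[j - 1])
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            elif j > 0 and H[i, j] == E[i, j]:
                state = "E"
            else:  # global boundary rows/cols
                state = "F" if j == 0 else "E"
        elif state == "F":
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            if F[i, j] == H[i - 1, j] - gap_open - gap_ext or i == 1:
                state = "H"
            i -= 1
        else:  # E
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            if E[i, j] == H[i, j - 1] - gap_open - gap_ext or j == 1:
                state = "H"
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j


def smith_waterman(a: str, b: str, scoring=None, gap_open: float = 11.0,
                   gap_extend: float = 1.0) -> Alignment:
    """Optimal local alignment of two protein sequences.

    Returns the highest-scoring local alignment; among co-optimal end cells
    the one with the smallest (i, j) is taken, and traceback prefers
    diagonal > vertical > horizontal moves, so the result is deterministic.
    An all-negative scoring landscape yields the empty alignment with score 0.
    """
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty sequences")
    sub, alphabet = substitution_matrix(scoring)
    ea, eb = encode(a, alphabet), encode(b, alphabet)
    H, E, F = _gotoh_fill(ea, eb, sub, float(gap_open), float(gap_extend), True)
    best = np.unravel_index(int(np.argmax(H)), H.shape)
    score = float(H[best])
    if score <= 0.0:
        return Alignment(0.0, "", "", (0, 0), (0, 0))
    sa, sb, i0, j0 = _traceback(ea, eb, a, b, H, E, F, sub, gap_open, gap_extend,
                                int(best[0]), int(best[1]), True)
    return Alignment(score, sa, sb, (i0 + 1, int(best[0])), (j0 + 1, int(best[1])))


def needleman_wunsch(a: str, b: str, scoring=None, gap_open: float = 11.0,
                     gap_extend: float = 1.0) -> Alignment:
    """Optimal global alignment of two protein sequences (affine gaps)."""
    if not a or not b:
        raise ValueError("needleman_wunsch requires non-empty sequences")
    sub, alphabet = substitution_matrix(scoring)
    ea, eb = encode(a, alphabet), encode(b, alphabet)
    H, E, F = _gotoh_fill(ea, eb, sub, float(gap_open), float(gap_extend), False)
    sa, sb, _, _ = _traceback(ea, eb, a, b, H, E, F, sub, gap_open, gap_extend,
                              len(a), len(b), False)
    return Alignment(float(H[len(a), len(b)]), sa, sb, (1, len(a)), (1, len(b)))


def local_score(a: str, b: str, scoring=None, gap_open: float = 11.0,
                gap_extend: float = 1.0) -> float:
    """Score-only Smith–Waterman (skips traceback)."""
    sub, alphabet = substitution_matrix(scoring)
    H, _, _ = _gotoh_fill(encode(a, alphabet), encode(b, alphabet), sub,
                          float(gap_open), float(gap_extend), True)
    return float(H.max())
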