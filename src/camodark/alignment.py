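"""Affine-gap pairwise alignment (Gotoh algorithm).

Two modes are provided:

``local``
    Smith-Waterman-style local alignment; used to compare camouflaged
    region copies and to measure percent identity.
``fit``
    Glocal alignment: the whole query must align, against any substring
    of the subject.  Used to realign extracted reads to the
    representative region so that a variant near a read end is not
    silently clipped away.

A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the open
penalty is charged on the first gap column, extension on each further
column).  The inner loop is vectorised over the subject with numpy; the
within-row horizontal-gap recurrence is solved as a running-maximum
prefix scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["ScoringScheme", "Alignment", "align", "percent_identity"]

_NEG = -1e18
_TOL = 1e-6


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and affine gap penalties."""

    match: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


@dataclass
class Alignment:
    """Result of a pairwise alignment.

    ``columns`` lists (query_index, subject_index) pairs in order; a
    ``None`` on either side marks a gap column in that sequence.
    """

    score: float
    query: str
    subject: str
    columns: list[tuple[Optional[int], Optional[int]]] = field(default_factory=list)

    @property
    def query_start(self) -> int:
        idx = [q for q, _ in self.columns if q is not None]
        return idx[0] if idx else 0

    @property
    def query_end(self) -> int:
        idx = [q for q, _ in self.columns if q is not None]
        return idx[-1] + 1 if idx else 0

    @property
    def subject_start(self) -> int:
        idx = [s for _, s in self.columns if s is not None]
        return idx[0] if idx else 0

    @property
    def subject_end(self) -> int:
        idx = [s for _, s in self.columns if s is not None]
        return idx[-1] + 1 if idx else 0

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def n_matches(self) -> int:
        return sum(
            1
            for q, s in self.columns
            if q is not None and s is not None and self.query[q] == self.subject[s]
        )

    def cigar(self) -> list[tuple[str, int]]:
        """Query-relative CIGAR over the aligned span (M/I/D ops)."""
        ops: list[tuple[str, int]] = []
        for q, s in self.columns:
            op = "M" if q is not None and s is not None else ("I" if s is None else "D")
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + 1)
            else:
                ops.append((op, 1))
        return ops


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def align(
    query: str,
    subject: str,
    scoring: ScoringScheme = ScoringScheme(),
    mode: str = "local",
) -> Alignment:
    """Optimal affine-gap alignment of ``query`` against ``subject``.

    ``N`` never matches anything (so masked reference stretches cannot
    attract alignments).
    """
    if mode not in ("local", "fit"):
        raise ValueError(f"unknown mode {mode!r}")
    if not query or not subject:
        raise ValueError("sequences must be nonempty")
    local = mode == "local"
    m, n = len(query), len(subject)
    a = _codes(query)
    b = _codes(subject)
    match, mism = scoring.match, scoring.mismatch
    go, ge = scoring.gap_open, scoring.gap_extend
    n_code = ord("N")

    H = np.full((m + 1, n + 1), _NEG)
    E = np.full((m + 1, n + 1), _NEG)  # gap in query (consumes subject)
    F = np.full((m + 1, n + 1), _NEG)  # gap in subject (consumes query)
    H[0, :] = 0.0
    if local:
        H[:, 0] = 0.0
    else:
        H[1:, 0] = go + np.arange(m) * ge
        F[1:, 0] = H[1:, 0]

    t_idx = np.arange(n)
    for i in range(1, m + 1):
        qc = a[i - 1]
        sub = np.where((b == qc) & (b != n_code) & (qc != n_code), match, mism)
        Fi = np.maximum(F[i - 1] + ge, H[i - 1] + go)
        diag = H[i - 1, :-1] + sub
        Gh = np.maximum(diag, Fi[1:])  # row values excluding the E component
        if local:
            Gh = np.maximum(Gh, 0.0)
        # E[j] = max over t < j of Gh_full[t] + go + (j-1-t)*ge, via prefix max
        gh_full = np.empty(n)
        gh_full[0] = H[i, 0] if local else Fi[0]
        gh_full[1:] = Gh[:-1]
        run = np.maximum.accumulate(gh_full - t_idx * ge)
        Ei = np.empty(n + 1)
        Ei[0] = _NEG
        Ei[1:] = go + t_idx * ge + run
        Hi = np.maximum(Gh, Ei[1:])
        F[i] = Fi
        E[i] = Ei
        H[i, 1:] = Hi
        H[i, 0] = 0.0 if local else Fi[0]

    if local:
        i, j = np.unravel_index(int(np.argmax(H)), H.shape)
        score = float(H[i, j])
        if score <= 0:
            return Alignment(0.0, query, subject, [])
    else:
        j = int(np.argmax(H[m, :]))
        i = m
        score = float(H[m, j])

    # traceback
    cols: list[tuple[Optional[int], Optional[int]]] = []
    state = "H"
    while True:
        if state == "H":
            if local and H[i, j] <= _TOL and H[i, j] >= -_TOL:
                break
            if not local and i == 0:
                break
            if i > 0 and j > 0:
                qc, sc = a[i - 1], b[j - 1]
                s = match if (qc == sc and qc != n_code) else mism
                if abs(H[i, j] - (H[i - 1, j - 1] + s)) < _TOL:
                    cols.append((i - 1, j - 1))
                    i -= 1
                    j -= 1
                    continue
            if abs(H[i, j] - E[i, j]) < _TOL:
                state = "E"
                continue
            if abs(H[i, j] - F[i, j]) < _TOL:
                state = "F"
                continue
            raise AssertionError("traceback failed")  # pragma: no cover
        elif state == "E":
            cols.append((None, j - 1))
            if abs(E[i, j] - (E[i, j - 1] + ge)) < _TOL:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            cols.append((i - 1, None))
            if abs(F[i, j] - (F[i - 1, j] + ge)) < _TOL:
                i -= 1
            else:
                i -= 1
                state = "H"
    cols.reverse()
    return Alignment(score, query, subject, cols)


def percent_identity(aln: Alignment) -> float:
    """Identity over alignment columns, gap columns included (BLAT-like)."""
    if aln.n_columns == 0:
        return 0.0
    return 100.0 * aln.n_matches / aln.n_columns
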