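"""Global pairwise alignment with affine gaps (Gotoh three-state recursion).

This is a NEEDLE-equivalent global aligner: by default it uses the EMBOSS
DNA scoring (match +5, mismatch -4, gap open 10, gap extend 0.5) and
penalizes end gaps.  A gap of length L costs ``gap_open + gap_extend * L``.

The recursion keeps three state matrices:

* ``M``  - a[i-1] aligned to b[j-1] (match/substitution),
* ``Ix`` - a[i-1] aligned to a gap (deletion from a),
* ``Iy`` - b[j-1] aligned to a gap (insertion in b, relative to a).

Rows are computed with numpy; the horizontal state ``Iy`` (which depends on
cells to its left in the same row) is vectorised with a running-maximum
identity: ``Iy[i][j] = max_{k<j}(max(M,Ix)[i][k] + ge*k) - go - ge*j``.

Traceback tie-breaking is fixed (prefer match/substitution, then deletion,
then insertion) so alignments are bit-reproducible.  All default scores are
dyadic rationals, so the float arithmetic is exact.

:func:`exhaustive_score` is a deliberately naive reference implementation
(plain recursion over (i, j, last-operation)) used to validate the DP on
small inputs; it is exponential without memoisation and must not be used on
long sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

NEG = -1.0e30  # effective -infinity
_TIE = 1e-9


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and affine gap penalties.

    A gap run of length L is charged ``gap_open + gap_extend * L``.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class IndelEvent:
    """A coalesced insertion or deletion in reference coordinates.

    For deletions ``anchor`` is the reference coordinate of the first deleted
    base; for insertions it is the inter-base reference index between the
    flanking reference columns.
    """

    kind: str  # "insertion" | "deletion"
    anchor: int
    length: int
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")


@dataclass(frozen=True)
class PairwiseAlignment:
    """An optimal global alignment of ``a`` and ``b``.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings; removing the
    gaps reproduces the inputs, and no column is a gap in both rows.
    """

    aligned_a: str
    aligned_b: str
    score: float
    scheme: ScoringScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")

    @property
    def a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def b(self) -> str:
        return self.aligned_b.replace("-", "")

    def ops(self) -> list[tuple[str, int]]:
        """Run-length operation list over
        {match, substitution, deletion, insertion}."""
        out: list[tuple[str, int]] = []
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-":
                op = "insertion"
            elif cb == "-":
                op = "deletion"
            elif ca == cb:
                op = "match"
            else:
                op = "substitution"
            if out and out[-1][0] == op:
                out[-1] = (op, out[-1][1] + 1)
            else:
                out.append((op, 1))
        return out

    def score_from_ops(self) -> float:
        """Recompute the score from the operation list (invariant check)."""
        s = self.scheme
        total = 0.0
        for op, n in self.ops():
            if op == "match":
                total += s.match * n
            elif op == "substitution":
                total += s.mismatch * n
            else:
                total -= s.gap_open + s.gap_extend * n
        return total

    def identity(self) -> float:
        """Gap-excluded identity: matches / columns aligned in both rows."""
        both = matches = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != "-" and cb != "-":
                both += 1
                matches += ca == cb
        return matches / both if both else 0.0

    def ref_coverage(self) -> tuple[int, int]:
        """Half-open reference-coordinate span covered by bases of ``b``."""
        ref = 0
        lo, hi = None, None
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != "-":
                if cb != "-":
                    if lo is None:
                        lo = ref
                    hi = ref + 1
                ref += 1
        if lo is None:
            return (0, 0)
        return (lo, hi)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def global_align(
    a: str,
    b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    free_end_gaps: bool = False,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of ``a`` and ``b``.

    With ``free_end_gaps=True`` leading and trailing gaps in either row are
    unpenalized (overlap-style alignment, used e.g. to place a short donor
    inside a longer amplicon); the returned score then excludes end gaps.

    Raises
    ------
    ValueError
        If either sequence is empty.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    n, m = len(a), len(b)
    go, ge = scheme.gap_open, scheme.gap_extend
    a_arr, b_arr = _encode(a), _encode(b)

    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    jj = np.arange(1, m + 1, dtype=float)
    ii = np.arange(1, n + 1, dtype=float)
    Iy[0, 1:] = 0.0 if free_end_gaps else -(go + ge * jj)
    Ix[1:, 0] = 0.0 if free_end_gaps else -(go + ge * ii)

    k_ext = ge * np.arange(m + 1, dtype=float)
    open_cost = go + ge
    for i in range(1, n + 1):
        s = np.where(b_arr == a_arr[i - 1], scheme.match, scheme.mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]), Iy[i - 1, :-1])
        M[i, 1:] = prev_best + s
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) - open_cost,
            Ix[i - 1, 1:] - ge,
        )
        u = np.maximum(M[i, :], Ix[i, :]) + k_ext
        Iy[i, 1:] = np.maximum.accumulate(u[:-1]) - go - ge * jj

    end_i, end_j, state = _pick_end(M, Ix, Iy, n, m, free_end_gaps)
    score = (M, Ix, Iy)[state][end_i, end_j]
    col_a, col_b = _traceback(a, b, M, Ix, Iy, scheme, end_i, end_j, state)
    # Pad free trailing end gaps.
    if end_i < n:
        col_a.append(a[end_i:])
        col_b.append("-" * (n - end_i))
    if end_j < m:
        col_a.append("-" * (m - end_j))
        col_b.append(b[end_j:])
    return PairwiseAlignment("".join(col_a), "".join(col_b), float(score), scheme)


def _pick_end(M, Ix, Iy, n, m, free_end_gaps):
    """End cell and state; ties prefer (n, m), larger i+j, then M > Ix > Iy."""
    if not free_end_gaps:
        cells = [(n, m)]
    else:
        cells = [(n, m)]
        cells += [(i, m) for i in range(n - 1, 0, -1)]
        cells += [(n, j) for j in range(m - 1, 0, -1)]
        cells.sort(key=lambda c: (c != (n, m), -(c[0] + c[1])))
    best = NEG
    pick = (n, m, 0)
    for i, j in cells:
        for state, mat in enumerate((M, Ix, Iy)):
            v = mat[i, j]
            if v > best + _TIE:
                best = v
                pick = (i, j, state)
    return pick


def _traceback(a, b, M, Ix, Iy, scheme, i, j, state):
    go, ge = scheme.gap_open, scheme.gap_extend
    open_cost = go + ge
    col_a: list[str] = []
    col_b: list[str] = []

    def argbest(vals):
        top = max(vals)
        for k, v in enumerate(vals):
            if v > top - _TIE:
                return k
        return 0  # pragma: no cover

    while i > 0 or j > 0:
        if j == 0:
            state = 1
        elif i == 0:
            state = 2
        if state == 0:  # match/substitution
            col_a.append(a[i - 1])
            col_b.append(b[j - 1])
            state = argbest((M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]))
            i -= 1
            j -= 1
        elif state == 1:  # deletion from a (gap in b)
            col_a.append(a[i - 1])
            col_b.append("-")
            if j > 0:
                state = argbest(
                    (
                        M[i - 1, j] - open_cost,
                        Ix[i - 1, j] - ge,
                        Iy[i - 1, j] - open_cost,
                    )
                )
            i -= 1
        else:  # insertion in b (gap in a)
            col_a.append("-")
            col_b.append(b[j - 1])
            if i > 0:
                state = argbest(
                    (
                        M[i, j - 1] - open_cost,
                        Ix[i, j - 1] - open_cost,
                        Iy[i, j - 1] - ge,
                    )
                )
            j -= 1
    col_a.reverse()
    col_b.reverse()
    return col_a, col_b


def extract_events(
    aln: PairwiseAlignment,
) -> tuple[list[IndelEvent], list[tuple[int, str]]]:
    """Coalesced indel events and substitutions in reference coordinates.

    The reference is ``aln.aligned_a``.  Adjacent gap columns in one row merge
    into a single event; an insertion's anchor is the inter-base index between
    its flanking reference columns; substitutions are reported as
    ``(ref_coord, read_base)``.
    """
    indels: list[IndelEvent] = []
    subs: list[tuple[int, str]] = []
    ref = 0
    run_kind: str | None = None
    run_start = 0
    run_len = 0
    run_seq: list[str] = []

    def flush():
        nonlocal run_kind, run_len, run_seq
        if run_kind is not None:
            indels.append(
                IndelEvent(run_kind, run_start, run_len, "".join(run_seq))
            )
        run_kind, run_len, run_seq = None, 0, []

    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca == "-":
            if run_kind != "insertion":
                flush()
                run_kind, run_start = "insertion", ref
            run_len += 1
            run_seq.append(cb)
        elif cb == "-":
            if run_kind != "deletion":
                flush()
                run_kind, run_start = "deletion", ref
            run_len += 1
            ref += 1
        else:
            flush()
            if ca != cb:
                subs.append((ref, cb))
            ref += 1
    flush()
    return indels, subs


def exhaustive_score(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Optimal global alignment score by plain recursion over all alignments.

    Reference implementation for validating :func:`global_align` on short
    sequences (memoised on (i, j, last-operation); end gaps penalized).
    """
    s = scheme

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        out = NEG
        if i < len(a) and j < len(b):
            sub = s.match if a[i] == b[j] else s.mismatch
            out = max(out, sub + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = s.gap_extend + (0.0 if last == "X" else s.gap_open)
            out = max(out, -cost + best(i + 1, j, "X"))
        if j < len(b):
            cost = s.gap_extend + (0.0 if last == "Y" else s.gap_open)
            out = max(out, -cost + best(i, j + 1, "Y"))
        return out

    result = best(0, 0, "M")
    best.cache_clear()
    return result
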