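"""Global pairwise and progressive multiple alignment for near-identical haplotypes.

The aligner is a Needleman–Wunsch/Gotoh affine-gap DP (first gap base costs
``gap_open``, each further base ``gap_extend``) with a fixed traceback tie
order (diagonal > up > left) so alignments are bit-reproducible.  The MSA is
classic progressive alignment: UPGMA guide tree on a shared-8-mer distance,
profile–profile merges with the pairwise scheme, and "once a gap, always a
gap" propagation.  The DP inner loops are numba-compiled so a ~2.8 kb
amplicon with dozens of rows aligns in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "Alignment",
    "AlignedPair",
    "SplicedCDS",
    "pairwise_align",
    "progressive_msa",
    "spliced_cds",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 4}

# state codes used in the DP pointer matrices
_M, _X, _Y = 0, 1, 2


@dataclass(frozen=True)
class AlignedPair:
    a: str
    b: str
    score: float


@dataclass
class Alignment:
    """A column-indexed MSA over {A,C,G,T,-}.

    Invariants: all rows equal length; degapping row *i* returns input *i*;
    no all-gap column.
    """

    ids: list[str]
    rows: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows have unequal length")
        self._index = {rid: i for i, rid in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, row_id: str) -> str:
        return self.rows[self._index[row_id]]

    def has_row(self, row_id: str) -> bool:
        return row_id in self._index

    def ref_to_col(self, ref_id: str) -> list[int]:
        """Map ungapped positions (0-based) of row *ref_id* to column indices."""
        cols = [i for i, c in enumerate(self.row(ref_id)) if c != "-"]
        return cols

    def as_array(self, rows: list[str] | None = None) -> np.ndarray:
        """Rows as a uint8 matrix of base indices (A,C,G,T=0..3, gap/N=4)."""
        which = self.rows if rows is None else [self.row(r) for r in rows]
        out = np.empty((len(which), self.width), dtype=np.uint8)
        for i, r in enumerate(which):
            out[i] = [_BASE_INDEX[c] for c in r]
        return out


@njit(cache=False)
def _gotoh(sub, gap_open, gap_extend):  # pragma: no cover - exercised via wrapper
    n, m = sub.shape
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # ends with gap in B ("up": consumes A)
    Y = np.full((n + 1, m + 1), NEG)  # ends with gap in A ("left": consumes B)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        pX[i, 0] = _X if i > 1 else _M
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        pY[0, j] = _Y if j > 1 else _M
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state: predecessor preference M > X > Y
            best = M[i - 1, j - 1]
            arg = _M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                arg = _X
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                arg = _Y
            M[i, j] = best + sub[i - 1, j - 1]
            pM[i, j] = arg
            # gap-in-B state
            best = M[i - 1, j] + gap_open
            arg = _M
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                arg = _X
            if Y[i - 1, j] + gap_open > best:
                best = Y[i - 1, j] + gap_open
                arg = _Y
            X[i, j] = best
            pX[i, j] = arg
            # gap-in-A state
            best = M[i, j - 1] + gap_open
            arg = _M
            if X[i, j - 1] + gap_open > best:
                best = X[i, j - 1] + gap_open
                arg = _X
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                arg = _Y
            Y[i, j] = best
            pY[i, j] = arg
    return M, X, Y, pM, pX, pY


def _traceback(M, X, Y, pM, pX, pY) -> tuple[list[int], list[int], float]:
    """Walk the pointer matrices back to index traces (-1 marks a gap)."""
    n = M.shape[0] - 1
    m = M.shape[1] - 1
    # final state preference: diagonal > up > left
    state, score = _M, M[n, m]
    if X[n, m] > score:
        state, score = _X, X[n, m]
    if Y[n, m] > score:
        state, score = _Y, Y[n, m]
    ai: list[int] = []
    bi: list[int] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _M:
            ai.append(i - 1)
            bi.append(j - 1)
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == _X:
            ai.append(i - 1)
            bi.append(-1)
            state = pX[i, j]
            i -= 1
        else:
            ai.append(-1)
            bi.append(j - 1)
            state = pY[i, j]
            j -= 1
    ai.reverse()
    bi.reverse()
    return ai, bi, float(score)


def _align_traces(
    sub: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[list[int], list[int], float]:
    M, X, Y, pM, pX, pY = _gotoh(sub, float(gap_open), float(gap_extend))
    return _traceback(M, X, Y, pM, pX, pY)


def pairwise_align(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> AlignedPair:
    """Optimal global alignment of two sequences under the affine scheme.

    A gap of length k costs ``gap_open + (k-1)*gap_extend``.  Traceback ties
    resolve diagonal > up > left, so the result is deterministic.
    """
    if not a or not b:
        raise ValueError("pairwise_align requires non-empty sequences")
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], float(match), float(mismatch))
    ai, bi, score = _align_traces(sub, gap_open, gap_extend)
    a_aln = "".join(a[i] if i >= 0 else "-" for i in ai)
    b_aln = "".join(b[j] if j >= 0 else "-" for j in bi)
    return AlignedPair(a_aln, b_aln, score)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _kmer_distance(a: str, b: str, k: int = 8) -> float:
    """1 minus the Sørensen fraction of shared k-mers; adequate at ~99% identity."""
    k = max(1, min(k, len(a), len(b)))
    ka, kb = _kmer_set(a, k), _kmer_set(b, k)
    if not ka or not kb:
        return 1.0
    return 1.0 - 2.0 * len(ka & kb) / (len(ka) + len(kb))


def _upgma_order(dist: np.ndarray) -> list[tuple[int, int]]:
    """UPGMA merge schedule over a condensed distance matrix.

    Returns a list of (i, j) cluster-index merges; clusters are numbered
    0..n-1 for leaves, then n, n+1, ... for internal merges.  Ties break on
    the smallest (i, j) pair, making the guide tree deterministic.
    """
    n = dist.shape[0]
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster -> size
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist[i, j])
    merges: list[tuple[int, int]] = []
    nxt = n
    while len(active) > 1:
        (i, j), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        si, sj = active.pop(i), active.pop(j)
        merges.append((i, j))
        for k in list(active):
            a = d.pop((min(i, k), max(i, k)))
            b = d.pop((min(j, k), max(j, k)))
            d[(min(nxt, k), max(nxt, k))] = (a * si + b * sj) / (si + sj)
        d.pop((i, j), None)
        active[nxt] = si + sj
        nxt += 1
    return merges


@dataclass
class _Profile:
    ids: list[str]
    rows: list[str]

    def counts(self) -> np.ndarray:
        w = len(self.rows[0])
        c = np.zeros((w, 5), dtype=np.float64)
        for r in self.rows:
            for i, ch in enumerate(r):
                c[i, _BASE_INDEX[ch]] += 1.0
        return c


def _merge_profiles(
    pa: _Profile,
    pb: _Profile,
    smat: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> _Profile:
    ca = pa.counts()
    cb = pb.counts()
    na, nb = len(pa.rows), len(pb.rows)
    # column-pair score: average substitution score over non-gap char pairs;
    # gap characters inside a profile score 0 against everything
    sub = (ca[:, :4] @ smat @ cb[:, :4].T) / (na * nb)
    ai, bi, _ = _align_traces(sub, gap_open, gap_extend)
    rows_a = [
        "".join(r[i] if i >= 0 else "-" for i in ai) for r in pa.rows
    ]
    rows_b = [
        "".join(r[j] if j >= 0 else "-" for j in bi) for r in pb.rows
    ]
    return _Profile(pa.ids + pb.ids, rows_a + rows_b)


def progressive_msa(
    seqs: list[tuple[str, str]],
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    k: int = 8,
) -> Alignment:
    """Progressive MSA of (id, sequence) pairs.

    Guide order is UPGMA on the shared-k-mer distance; profiles are merged
    with the pairwise affine scheme and gaps propagate.  Deterministic for a
    fixed input order and parameters.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa requires at least 2 sequences")
    ids = [s[0] for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(seqs[i][1], seqs[j][1], k)
    smat = np.full((4, 4), float(mismatch))
    np.fill_diagonal(smat, float(match))
    profiles: dict[int, _Profile] = {
        i: _Profile([seqs[i][0]], [seqs[i][1]]) for i in range(n)
    }
    nxt = n
    for i, j in _upgma_order(dist):
        profiles[nxt] = _merge_profiles(
            profiles.pop(i), profiles.pop(j), smat, gap_open, gap_extend
        )
        nxt += 1
    final = profiles.popitem()[1]
    # restore input row order
    order = {rid: k_ for k_, rid in enumerate(ids)}
    pairs = sorted(zip(final.ids, final.rows), key=lambda p: order[p[0]])
    aln = Alignment([p[0] for p in pairs], [p[1] for p in pairs])
    assert all(
        any(c != "-" for c in col) for col in zip(*aln.rows)
    ), "all-gap column in MSA"
    return aln


@dataclass(frozen=True)
class SplicedCDS:
    """Coding sequence spliced out of an alignment row.

    ``frameshift`` is set when the degapped CDS length is not a multiple of
    three; such haplotypes are excluded from translation-based analyses.
    """

    hap_id: str
    seq: str
    frameshift: bool


def spliced_cds(
    aln: Alignment,
    row_id: str,
    exons: list[tuple[int, int]],
    ref_id: str,
) -> SplicedCDS:
    """Splice the coding sequence of *row_id* using exon coordinates given on
    the ungapped reference row (0-based half-open), then drop gaps.

    Columns inserted relative to the reference are not part of any exon and
    are excluded.
    """
    ref_cols = aln.ref_to_col(ref_id)
    row = aln.row(row_id)
    chars: list[str] = []
    for start, end in exons:
        for pos in range(start, end):
            c = row[ref_cols[pos]]
            if c != "-":
                chars.append(c)
    seq = "".join(chars)
    return SplicedCDS(row_id, seq, frameshift=(len(seq) % 3 != 0))
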