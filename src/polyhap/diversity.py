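"""Sequence-diversity statistics: haplotype diversity and its variance
(Nei 1987 estimators), nucleotide diversity, and sliding-window diversity.

All per-site statistics use complete deletion: any alignment column
containing a gap (within the analyzed row subset) is excluded before
counting.  At the ~99% identity typical of within-gene haplotypes no
multiple-hit correction is applied; a Jukes–Cantor correction would not move
the reported figures at printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .alignment import Alignment

__all__ = [
    "DiversityReport",
    "haplotype_diversity",
    "hd_variance",
    "nucleotide_diversity",
    "sliding_pi",
    "diversity_report",
]


@dataclass(frozen=True)
class DiversityReport:
    """The per-group diversity summary: sample size n, haplotype count Hn,
    segregating sites S, mutation total Eta, haplotype diversity Hd with
    variance Hv, nucleotide diversity Pi, and the analyzed (gap-free) site
    count."""

    n: int
    Hn: int
    S: int
    Eta: int
    Hd: float
    Hv: float
    Pi: float
    analyzed_sites: int


def _freqs(counts: list[int] | np.ndarray) -> tuple[np.ndarray, int]:
    c = np.asarray(counts, dtype=float)
    if (c <= 0).any():
        raise ValueError("haplotype counts must be positive")
    n = int(c.sum())
    if n < 2:
        raise ValueError("need total sample size >= 2")
    return c / n, n


def haplotype_diversity(counts: list[int]) -> float:
    """Nei's haplotype (gene) diversity: Hd = n(1 - sum p_i^2)/(n - 1).

    Evaluated as (n^2 - sum c_i^2) / (n(n-1)) on the raw counts, which is
    exact in floating point for the closed-form cases (all singletons -> 1,
    a single class -> 0).
    """
    _, n = _freqs(counts)  # validation
    sum_sq = sum(int(c) * int(c) for c in counts)
    return (n * n - sum_sq) / (n * (n - 1))


def hd_variance(counts: list[int]) -> float:
    """Sampling variance of Hd (Nei 1987):

    Hv = (2/(n(n-1))) * { 2(n-2) [sum p_i^3 - (sum p_i^2)^2]
                          + sum p_i^2 - (sum p_i^2)^2 }
    """
    p, n = _freqs(counts)
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    return (2.0 / (n * (n - 1))) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)


def _subset_matrix(aln: Alignment, rows: list[str] | None) -> np.ndarray:
    mat = aln.as_array(rows)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    return mat


def _pi_on(mat: np.ndarray) -> tuple[float | None, int]:
    """(Pi, analyzed sites) on a base-index matrix; gap columns excluded."""
    keep = (mat != 4).all(axis=0)
    m = int(keep.sum())
    if m == 0:
        return None, 0
    sub = mat[:, keep]
    n = sub.shape[0]
    total = 0
    for i, j in combinations(range(n), 2):
        total += int((sub[i] != sub[j]).sum())
    n_pairs = n * (n - 1) // 2
    return total / n_pairs / m, m


def nucleotide_diversity(aln: Alignment, rows: list[str] | None = None) -> float | None:
    """Average pairwise differences per analyzed (gap-free) site.

    Pi = [sum_{i<j} k_ij] / C(n,2) / m.  Returns None when no gap-free
    column exists (undefined).
    """
    pi, _ = _pi_on(_subset_matrix(aln, rows))
    return pi


def sliding_pi(
    aln: Alignment,
    window: int = 100,
    step: int = 25,
    rows: list[str] | None = None,
) -> list[tuple[int, float | None]]:
    """Windowed Pi over alignment columns.

    Windows are [start, start+window) in alignment columns, advancing by
    ``step``; gap columns are excluded within each window.  Returns
    (1-based midpoint column, Pi) per window; Pi is None for windows with no
    analyzed site.
    """
    if not (0 < step <= window <= aln.width):
        raise ValueError("require 0 < step <= window <= alignment width")
    mat = _subset_matrix(aln, rows)
    out: list[tuple[int, float | None]] = []
    for start in range(0, aln.width - window + 1, step):
        pi, _ = _pi_on(mat[:, start : start + window])
        out.append((start + (window + 1) // 2, pi))
    return out


def diversity_report(
    aln: Alignment,
    counts: list[int],
    S: int,
    eta: int,
    rows: list[str] | None = None,
) -> DiversityReport:
    """Assemble the standard report for one sequence group.

    ``counts`` are the haplotype frequency counts defining the sample (one
    count per distinct haplotype — weight each haplotype once, or by its
    carriage, per the caller's sampling convention).
    """
    mat = _subset_matrix(aln, rows)
    pi, m = _pi_on(mat)
    return DiversityReport(
        n=int(sum(counts)),
        Hn=len(counts),
        S=S,
        Eta=eta,
        Hd=haplotype_diversity(counts),
        Hv=hd_variance(counts),
        Pi=float("nan") if pi is None else pi,
        analyzed_sites=m,
    )
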