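"""Confirmed-haplotype calling from clone sequences, and clone-coverage math.

A haplotype is confirmed when two or more assemblies (clones) with byte-
identical sequences are observed, pooled across accessions.  The module also
answers the planning question "how many successful assemblies per accession
guarantee seeing every haplotype of a p-ploid at least twice?" with an exact
binomial tail computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

__all__ = [
    "Haplotype",
    "NoHaplotypesError",
    "merge_read_pair",
    "call_haplotypes",
    "required_clones",
    "haplotype_presence_matrix",
    "PresenceSummary",
]

logger = logging.getLogger(__name__)


class NoHaplotypesError(ValueError):
    """Raised when no clone group survives filtering and the support rule."""


@dataclass
class Haplotype:
    """A confirmed haplotype: one distinct sequence with its clone support."""

    hap_id: str
    seq: str
    support: dict[str, int]  # accession -> clone count
    total_support: int = field(init=False)

    def __post_init__(self) -> None:
        self.total_support = sum(self.support.values())
        if "N" in self.seq:
            raise ValueError(f"{self.hap_id}: haplotype sequence contains N")

    @property
    def accessions(self) -> set[str]:
        return set(self.support)


def merge_read_pair(fwd: str, rev: str, min_overlap: int = 6) -> str | None:
    """Merge two same-orientation reads over an exact suffix/prefix overlap.

    Returns the merged sequence for the longest exact overlap of at least
    ``min_overlap`` bases, the containing read when one read is wholly
    contained in the other (a 100%-identity full overlap), or None when no
    such overlap exists.  No-merge is a value, not an error.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if rev in fwd:
        return fwd
    if fwd in rev:
        return rev
    max_k = min(len(fwd), len(rev))
    for k in range(max_k, min_overlap - 1, -1):
        if fwd[-k:] == rev[:k]:
            return fwd + rev[k:]
    return None


def call_haplotypes(
    clones: dict[str, list[tuple[str, str]]] | dict[str, list[str]],
    min_support: int = 2,
) -> tuple[list[Haplotype], pd.DataFrame]:
    """Group clone sequences by exact identity, pooled across accessions.

    Clones containing N are dropped (with a logged count) before grouping.
    Groups whose pooled support falls below ``min_support`` are discarded.
    Haplotype ids HAP1, HAP2, ... are assigned in order of decreasing total
    support, ties broken lexicographically by sequence.

    Returns the haplotype list and the accession x haplotype clone-count
    table.  Raises :class:`NoHaplotypesError` if nothing survives.
    """
    counts: dict[str, dict[str, int]] = {}
    n_filtered = 0
    n_total = 0
    for acc in sorted(clones):
        for item in clones[acc]:
            seq = item[1] if isinstance(item, tuple) else item
            n_total += 1
            if "N" in seq:
                n_filtered += 1
                continue
            counts.setdefault(seq, {}).setdefault(acc, 0)
            counts[seq][acc] += 1
    if n_filtered:
        logger.info("filtered %d/%d clones containing N", n_filtered, n_total)
    confirmed = {
        seq: sup
        for seq, sup in counts.items()
        if sum(sup.values()) >= min_support
    }
    if not confirmed:
        raise NoHaplotypesError(
            f"no haplotype reaches min_support={min_support} "
            f"({n_total} clones, {n_filtered} filtered)"
        )
    ordered = sorted(
        confirmed.items(), key=lambda kv: (-sum(kv[1].values()), kv[0])
    )
    haplotypes = [
        Haplotype(hap_id=f"HAP{i}", seq=seq, support=dict(sup))
        for i, (seq, sup) in enumerate(ordered, start=1)
    ]
    accs = sorted(clones)
    table = pd.DataFrame(
        {h.hap_id: [h.support.get(a, 0) for a in accs] for h in haplotypes},
        index=pd.Index(accs, name="accession"),
    )
    return haplotypes, table


def required_clones(ploidy: int, min_copies: int = 2, confidence: float = 0.95) -> int:
    """Smallest clone count c with P[Binomial(c, 1/ploidy) >= min_copies] >= confidence.

    This is the number of successful assemblies needed per accession so that
    even the rarest haplotype of a ``ploidy``-plex locus (sampled with
    probability 1/ploidy per clone) is seen at least ``min_copies`` times
    with the stated confidence — e.g. 56 assemblies for a 12-ploid at the
    see-it-twice, 95% level.
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    p = 1.0 / ploidy
    c = min_copies
    while True:
        # P[X >= min_copies] = sf(min_copies - 1)
        if stats.binom.sf(min_copies - 1, c, p) >= confidence:
            return c
        c += 1


@dataclass
class PresenceSummary:
    """Presence/absence matrix plus per-accession and per-group summaries."""

    presence: pd.DataFrame  # accessions x hap_ids, 0/1
    per_accession_counts: pd.Series
    group_specific: dict[str, list[str]]
    shared: list[str]


def haplotype_presence_matrix(
    haplotypes: list[Haplotype],
    accessions: list[str],
    groups: dict[str, str] | None = None,
) -> PresenceSummary:
    """Binary accession x haplotype matrix with group-specific haplotype lists.

    ``groups`` maps accession to a group label (e.g. HS/LS); a haplotype is
    group-specific when all of its carriers fall in one group, otherwise it
    is listed as shared.
    """
    hap_ids = [h.hap_id for h in haplotypes]
    presence = pd.DataFrame(
        0, index=pd.Index(accessions, name="accession"), columns=hap_ids
    )
    for h in haplotypes:
        for acc in h.accessions:
            if acc in presence.index:
                presence.loc[acc, h.hap_id] = 1
    per_acc = presence.sum(axis=1)
    group_specific: dict[str, list[str]] = {}
    shared: list[str] = []
    if groups:
        for h in haplotypes:
            labels = {groups[a] for a in h.accessions if a in groups}
            if len(labels) == 1:
                group_specific.setdefault(labels.pop(), []).append(h.hap_id)
            elif len(labels) > 1:
                shared.append(h.hap_id)
    return PresenceSummary(presence, per_acc, group_specific, shared)
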