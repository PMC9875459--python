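"""Variant catalogue from the haplotype MSA.

SNP sites are scored on gap-free columns only (complete deletion); alignment
columns containing gaps are routed to InDel event calling, where each maximal
gap run against the designated reference row is one event.  Also provides
transition/transversion classification, SNP density, degenerate splice-motif
scanning (e.g. the YNYYRAY branch-point motif), and protein-type grouping of
haplotypes by their translated coding sequence.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .alignment import Alignment
from .synthetic import GeneTemplate

__all__ = [
    "VariantSite",
    "IndelEvent",
    "ProteinType",
    "classify_substitution",
    "segregating_sites",
    "indel_events",
    "snp_density",
    "scan_motif",
    "protein_types",
]

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class VariantSite:
    """One polymorphic alignment column (1-based)."""

    column: int
    kind: str  # "SNP" (INDEL columns are reported as IndelEvent)
    ref_state: str
    alleles: tuple[tuple[str, int], ...]  # (state, count), count-desc
    ts_tv: str | None  # set only for biallelic SNPs
    region: str = ""


@dataclass(frozen=True)
class IndelEvent:
    """A maximal insertion/deletion run polarized against the reference row."""

    start_column: int  # 1-based alignment column of the first affected column
    length: int
    polarity: str  # "insertion" | "deletion" relative to the reference
    inserted_seq: str  # empty for deletions
    carriers: tuple[str, ...]


@dataclass(frozen=True)
class ProteinType:
    type_id: str
    protein: str
    members: tuple[str, ...]


def classify_substitution(a: str, b: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs transversion."""
    if a == b:
        raise ValueError(f"not a substitution: {a!r} == {b!r}")
    pair = {a, b}
    if not pair <= (_PURINES | _PYRIMIDINES):
        raise ValueError(f"non-base input: {a!r}, {b!r}")
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def _region_lookup(
    aln: Alignment, ref_id: str, template: GeneTemplate
) -> dict[int, str]:
    """Alignment column -> region label, via the ungapped reference row."""
    cols = aln.ref_to_col(ref_id)
    return {col: template.region_of(pos) for pos, col in enumerate(cols)}


def segregating_sites(
    aln: Alignment,
    ref_id: str | None = None,
    template: GeneTemplate | None = None,
) -> tuple[list[VariantSite], int, int]:
    """Catalogue SNP sites and return (sites, S, Eta).

    Gap-containing columns are excluded (complete deletion) — they belong to
    :func:`indel_events`.  S counts columns with >= 2 states; Eta adds
    (distinct states - 1) per such column.  ``ref_state`` is taken from the
    designated reference row (default: first row); ts/tv is classified for
    biallelic sites only.
    """
    ref_id = ref_id if ref_id is not None else aln.ids[0]
    regions = (
        _region_lookup(aln, ref_id, template) if template is not None else {}
    )
    ref_row = aln.row(ref_id)
    sites: list[VariantSite] = []
    S = 0
    eta = 0
    for col in range(aln.width):
        states = [r[col] for r in aln.rows]
        if "-" in states:
            continue
        counts = Counter(states)
        if len(counts) < 2:
            continue
        S += 1
        eta += len(counts) - 1
        alleles = tuple(
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )
        if len(counts) == 2:
            a, b = counts.keys()
            ts_tv = classify_substitution(a, b)
        else:
            ts_tv = None
        sites.append(
            VariantSite(
                column=col + 1,
                kind="SNP",
                ref_state=ref_row[col],
                alleles=alleles,
                ts_tv=ts_tv,
                region=regions.get(col, ""),
            )
        )
    return sites, S, eta


def indel_events(aln: Alignment, reference_row_id: str) -> list[IndelEvent]:
    """Call InDel events as maximal gap runs polarized against the reference.

    For each non-reference row: a maximal run of row-gaps over reference
    bases is one deletion; a maximal run of row-bases over reference gaps is
    one insertion.  Events identical in (start, length, polarity, inserted
    sequence) merge across carriers.
    """
    ref = aln.row(reference_row_id)
    events: dict[tuple, set[str]] = {}
    for rid in aln.ids:
        if rid == reference_row_id:
            continue
        row = aln.row(rid)
        col = 0
        w = aln.width
        while col < w:
            if row[col] == "-" and ref[col] != "-":
                start = col
                while col < w and row[col] == "-" and ref[col] != "-":
                    col += 1
                key = (start + 1, col - start, "deletion", "")
                events.setdefault(key, set()).add(rid)
            elif row[col] != "-" and ref[col] == "-":
                start = col
                while col < w and row[col] != "-" and ref[col] == "-":
                    col += 1
                ins = row[start:col]
                key = (start + 1, col - start, "insertion", ins)
                events.setdefault(key, set()).add(rid)
            else:
                col += 1
    return [
        IndelEvent(
            start_column=k[0],
            length=k[1],
            polarity=k[2],
            inserted_seq=k[3],
            carriers=tuple(sorted(car)),
        )
        for k, car in sorted(events.items())
    ]


def snp_density(analyzed_length: int, n_snp: int) -> float | None:
    """Base pairs per SNP (None when there are no SNPs: density undefined)."""
    if n_snp == 0:
        return None
    return analyzed_length / n_snp


def _expand_code(code: str) -> frozenset[str]:
    try:
        return frozenset(ambiguous_dna_values[code])
    except KeyError:
        raise ValueError(f"invalid degenerate nucleotide code {code!r}") from None


def scan_motif(
    seq: str,
    motif: str = "YNYYRAY",
    regions: list[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Scan for a degenerate-code motif, optionally restricted to regions.

    ``regions`` are 0-based half-open intervals on *seq* (e.g. intron
    coordinates); matches must lie fully inside a region.  Returns
    (region_index, offset-within-region) for every — possibly overlapping —
    match.  Without regions the whole sequence is region 0.
    """
    allowed = [_expand_code(c) for c in motif.upper()]
    m = len(allowed)
    if regions is None:
        regions = [(0, len(seq))]
    hits: list[tuple[int, int]] = []
    for ri, (start, end) in enumerate(regions):
        for off in range(start, end - m + 1):
            if all(seq[off + i] in allowed[i] for i in range(m)):
                hits.append((ri, off - start))
    return hits


def protein_types(cds_map: dict[str, str]) -> list[ProteinType]:
    """Group haplotypes by the amino-acid sequence of their CDS.

    Translation uses the standard genetic code; a trailing stop is stripped
    and haplotypes with an internal stop codon are excluded with a logged
    warning.  Types are ordered by member count (desc), ties by smallest
    member id, and labelled P1, P2, ...
    """
    proteins: dict[str, str] = {}
    for hap_id, cds in cds_map.items():
        if len(cds) % 3 != 0:
            logger.warning("%s: CDS length not divisible by 3, excluded", hap_id)
            continue
        aa = str(Seq(cds).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            logger.warning("%s: internal stop codon, excluded", hap_id)
            continue
        proteins[hap_id] = aa
    groups: dict[str, list[str]] = {}
    for hap_id, aa in proteins.items():
        groups.setdefault(aa, []).append(hap_id)
    ordered = sorted(
        groups.items(), key=lambda kv: (-len(kv[1]), sorted(kv[1])[0])
    )
    return [
        ProteinType(type_id=f"P{i}", protein=aa, members=tuple(sorted(members)))
        for i, (aa, members) in enumerate(ordered, start=1)
    ]
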