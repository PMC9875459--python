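"""Synthetic amplicon study generator with a fully known truth.

Emulates the data-generating process of a cloned-amplicon haplotype survey of
a multi-copy gene in a highly polyploid crop: a ~2.8 kb gene template with
8 exons / 7 introns, a few dozen near-identical haplotypes carrying planted
SNPs (transition-biased, ~44:23) and rare intronic InDels including one large
(277 bp) insertion, ploidy-limited haplotype assignments across accessions,
error-bearing clone sequences (substitution errors at ~0.09% per base, ~20%
clone dropout), and additive-dosage trait values with Gaussian noise.

Everything is driven by explicit seeds and records its ground truth in
:class:`SimulationTruth`, so every downstream stage can be tested for exact
or statistical recovery without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneTemplate",
    "PlantedVariant",
    "SimulationTruth",
    "DEFAULT_EXON_LENGTHS",
    "DEFAULT_INTRON_LENGTHS",
    "make_template",
    "plant_haplotypes",
    "assign_to_accessions",
    "simulate_clones",
    "simulate_traits",
]

# Default gene shape: 8 exons + 7 introns totalling 2,824 bp, spliced CDS
# length divisible by 3 (1,254 bp = 418 codons).
DEFAULT_EXON_LENGTHS = (120, 150, 180, 210, 150, 120, 180, 144)
DEFAULT_INTRON_LENGTHS = (200, 250, 220, 230, 210, 240, 220)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass(frozen=True)
class GeneTemplate:
    """Reference amplicon with exon annotation (0-based half-open intervals)."""

    seq: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        last = 0
        for s, e in self.exons:
            if not (last <= s < e <= len(self.seq)):
                raise ValueError("exon intervals must be sorted, non-overlapping, in range")
            last = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1, s2))
        return tuple(out)

    @property
    def spliced(self) -> str:
        return "".join(self.seq[s:e] for s, e in self.exons)

    def region_of(self, pos: int) -> str:
        """Human-readable region label (``exon k`` / ``intron k``, 1-based)."""
        for k, (s, e) in enumerate(self.exons, start=1):
            if s <= pos < e:
                return f"exon {k}"
        for k, (s, e) in enumerate(self.introns, start=1):
            if s <= pos < e:
                return f"intron {k}"
        return "flank"


@dataclass(frozen=True)
class PlantedVariant:
    """A planted mutation, in template coordinates (0-based).

    ``kind`` is SNP / INS / DEL; for insertions ``alt`` holds the inserted
    sequence and ``pos`` the insertion point (before template base ``pos``);
    for deletions ``ref`` holds the deleted bases starting at ``pos``.
    """

    pos: int
    kind: str
    ref: str
    alt: str
    carriers: tuple[str, ...]
    ts_tv: str | None = None
    region: str = ""


@dataclass
class SimulationTruth:
    template: GeneTemplate
    hap_ids: list[str]
    hap_seqs: dict[str, str]
    variants: list[PlantedVariant]
    seed: int
    assignment: dict[str, list[str]] = field(default_factory=dict)
    causal_sites: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.0


def make_template(
    seed: int,
    exon_lengths: tuple[int, ...] = DEFAULT_EXON_LENGTHS,
    intron_lengths: tuple[int, ...] = DEFAULT_INTRON_LENGTHS,
    gc: float = 0.5,
) -> GeneTemplate:
    """Generate a random gene template with the given exon/intron structure.

    The spliced reading frame is kept free of internal stop codons (any stop
    arising from the random draw has its third base rewritten to C).
    Deterministic for a fixed seed.
    """
    if any(l <= 0 for l in exon_lengths + intron_lengths):
        raise ValueError("exon/intron lengths must be positive")
    if len(exon_lengths) != len(intron_lengths) + 1:
        raise ValueError("need exactly one more exon than introns")
    if sum(exon_lengths) % 3 != 0:
        raise ValueError("total exon length must be divisible by 3")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    for i, el in enumerate(exon_lengths):
        exon = "".join(rng.choice(list(_BASES), size=el, p=p))
        pieces.append(exon)
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lengths):
            il = intron_lengths[i]
            pieces.append("".join(rng.choice(list(_BASES), size=il, p=p)))
            pos += il
    seq = list("".join(pieces))
    # genomic positions of spliced bases, for stop-codon repair
    spliced_pos = [i for s, e in exons for i in range(s, e)]
    for c in range(0, len(spliced_pos) - 3, 3):  # keep terminal codon free
        codon = "".join(seq[spliced_pos[c + k]] for k in range(3))
        if codon in _STOPS:
            seq[spliced_pos[c + 2]] = "C"
    return GeneTemplate("".join(seq), tuple(exons))


def _codon_context(template: GeneTemplate, pos: int) -> tuple[int, int] | None:
    """(spliced codon start index, offset in codon) for an exonic position."""
    offset = 0
    for s, e in template.exons:
        if s <= pos < e:
            sp = offset + (pos - s)
            return (sp // 3) * 3, sp % 3
        offset += e - s
    return None


def _creates_stop(template: GeneTemplate, pos: int, alt: str) -> bool:
    ctx = _codon_context(template, pos)
    if ctx is None:
        return False
    start, off = ctx
    spliced = template.spliced
    codon = list(spliced[start : start + 3])
    if len(codon) < 3:
        return False
    codon[off] = alt
    return "".join(codon) in _STOPS


def plant_haplotypes(
    template: GeneTemplate,
    n_hap: int = 39,
    n_snp: int = 67,
    n_indel: int = 6,
    tstv: float = 44 / 23,
    indel_len_range: tuple[int, int] = (6, 30),
    seed: int = 0,
    p_extra_carrier: float = 0.08,
    large_insertion: tuple[int, int, int] | None = (277, 3, 3),
) -> tuple[list[tuple[str, str]], SimulationTruth]:
    """Plant SNPs and intronic InDels on the template and derive haplotypes.

    Haplotype ``H1`` is the template itself (the designated reference).  The
    transition count is fixed to ``round(n_snp * tstv / (1 + tstv))`` so the
    default composition matches the 44:23 transition:transversion shape
    exactly; placements and transversion targets are random.  InDels are
    intronic only; ``large_insertion=(length, intron, n_carriers)`` plants one
    large insertion (default 277 bp in the 3rd intron, 3 carriers).  SNP
    positions avoid InDel footprints, and exonic SNPs avoid creating stop
    codons, so error-free recovery of the catalogue is exact.
    """
    if n_hap < 2:
        raise ValueError("n_hap must be >= 2")
    if n_snp + n_indel < n_hap - 1:
        raise ValueError("need at least n_hap - 1 variants for distinct haplotypes")
    rng = np.random.default_rng(seed)
    introns = template.introns
    L = len(template.seq)
    non_ref = [f"H{i}" for i in range(2, n_hap + 1)]
    hap_ids = ["H1"] + non_ref

    # ---- indels (intronic) -------------------------------------------------
    # two exclusion sets: `footprints` keeps SNPs a few bases clear of indel
    # edges (alignment slide ambiguity); `indel_space` keeps indels apart by
    # their own length so distinct events never interleave in the MSA
    footprints: set[int] = set()
    indel_space: set[int] = set()
    indels: list[dict] = []

    def _reserve(pos: int, del_len: int, indel_len: int) -> bool:
        # separation margin grows with the event length but is capped: the
        # aligner only interleaves events whose gap regions nearly touch
        margin = min(indel_len, 36) + 4
        zone = range(pos - margin, pos + del_len + margin)
        if any(p in indel_space for p in zone):
            return False
        indel_space.update(zone)
        footprints.update(range(pos - 4, pos + del_len + 4))
        return True

    n_made = 0
    if large_insertion is not None and n_indel >= 1 and introns:
        length, intron_no, n_car = large_insertion
        s, e = introns[min(intron_no - 1, len(introns) - 1)]
        for _ in range(1000):
            pos = int(rng.integers(s + 1, e))
            if _reserve(pos, 0, length):
                break
        ins_seq = "".join(rng.choice(list(_BASES), size=length))
        indels.append({"pos": pos, "kind": "INS", "ref": "", "alt": ins_seq,
                       "n_forced_carriers": n_car})
        n_made = 1
    attempts = 0
    while n_made < n_indel:
        attempts += 1
        if attempts > 2000:
            raise ValueError(
                "could not place the requested indels: not enough intron space"
            )
        kind = "INS" if rng.random() < 0.5 else "DEL"
        length = int(rng.integers(indel_len_range[0], indel_len_range[1] + 1))
        s, e = introns[int(rng.integers(0, len(introns)))]
        if kind == "DEL":
            if e - s <= length + 2:
                continue
            pos = int(rng.integers(s + 1, e - length))
            if not _reserve(pos, length, length):
                continue
            indels.append({"pos": pos, "kind": "DEL",
                           "ref": template.seq[pos : pos + length], "alt": ""})
        else:
            pos = int(rng.integers(s + 1, e))
            if not _reserve(pos, 0, length):
                continue
            ins_seq = "".join(rng.choice(list(_BASES), size=length))
            indels.append({"pos": pos, "kind": "INS", "ref": "", "alt": ins_seq})
        n_made += 1

    # ---- SNPs --------------------------------------------------------------
    pool = [p for p in range(L) if p not in footprints]
    n_ts = int(round(n_snp * tstv / (1.0 + tstv)))
    labels = ["transition"] * n_ts + ["transversion"] * (n_snp - n_ts)
    rng.shuffle(labels)
    snps: list[dict] = []
    if n_snp > len(pool):
        raise ValueError("more variants than available positions")
    pool_arr = list(rng.permutation(pool))
    for label in labels:
        while True:
            if not pool_arr:
                raise ValueError("more variants than available positions")
            pos = int(pool_arr.pop())
            ref = template.seq[pos]
            if label == "transition":
                alt = _TRANSITION[ref]
                if _creates_stop(template, pos, alt):
                    continue
            else:
                options = [b for b in _TRANSVERSIONS[ref]
                           if not _creates_stop(template, pos, b)]
                if not options:
                    continue
                alt = str(rng.choice(options))
            snps.append({"pos": pos, "kind": "SNP", "ref": ref, "alt": alt,
                         "ts_tv": label})
            break

    # ---- carrier assignment ------------------------------------------------
    raw = snps + indels
    order = list(rng.permutation(len(raw)))
    primaries = [non_ref[i % len(non_ref)] for i in range(len(raw))]
    carriers: list[set[str]] = [set() for _ in raw]
    for slot, vi in enumerate(order):
        carriers[vi].add(primaries[slot])
    for vi in range(len(raw)):
        extras = rng.random(len(non_ref)) < p_extra_carrier
        for h, hit in zip(non_ref, extras):
            if hit:
                carriers[vi].add(h)
        forced = raw[vi].get("n_forced_carriers")
        if forced:
            others = [h for h in non_ref if h not in carriers[vi]]
            rng.shuffle(others)
            while len(carriers[vi]) < forced and others:
                carriers[vi].add(others.pop())

    # enforce pairwise-distinct haplotypes: strip an extra (never a primary)
    # from one member of any colliding pair
    primary_of = {vi: primaries[slot] for slot, vi in enumerate(order)}
    for _ in range(1000):
        sets = {h: frozenset(vi for vi in range(len(raw)) if h in carriers[vi])
                for h in non_ref}
        seen: dict[frozenset, str] = {}
        collision = None
        for h in non_ref:
            if sets[h] in seen:
                collision = (seen[sets[h]], h)
                break
            seen[sets[h]] = h
        if collision is None:
            break
        _, h2 = collision
        for vi in sorted(sets[h2]):
            if primary_of[vi] != h2:
                carriers[vi].discard(h2)
                break
        else:  # pragma: no cover - cannot happen: every hap has a primary
            raise RuntimeError("could not separate duplicate haplotypes")

    variants = [
        PlantedVariant(
            pos=v["pos"], kind=v["kind"], ref=v.get("ref", ""), alt=v.get("alt", ""),
            carriers=tuple(sorted(carriers[vi])),
            ts_tv=v.get("ts_tv"), region=template.region_of(v["pos"]),
        )
        for vi, v in enumerate(raw)
    ]
    variants.sort(key=lambda v: (v.pos, v.kind))

    hap_seqs: dict[str, str] = {"H1": template.seq}
    for h in non_ref:
        mine = sorted(
            (v for v in variants if h in v.carriers),
            key=lambda v: v.pos, reverse=True,
        )
        seq = template.seq
        for v in mine:
            if v.kind == "SNP":
                seq = seq[: v.pos] + v.alt + seq[v.pos + 1 :]
            elif v.kind == "DEL":
                seq = seq[: v.pos] + seq[v.pos + len(v.ref) :]
            else:
                seq = seq[: v.pos] + v.alt + seq[v.pos :]
        hap_seqs[h] = seq

    truth = SimulationTruth(
        template=template, hap_ids=hap_ids, hap_seqs=hap_seqs,
        variants=variants, seed=seed,
    )
    return [(h, hap_seqs[h]) for h in hap_ids], truth


def assign_to_accessions(
    hap_ids: list[str],
    n_acc: int = 18,
    ploidy: int = 12,
    shared_fraction: float = 0.3,
    seed: int = 0,
    cover_all: bool = True,
) -> dict[str, list[str]]:
    """Assign 1..ploidy distinct haplotypes to each accession.

    ``shared_fraction`` is the per-slot probability of drawing a haplotype
    already carried by another accession rather than a fresh one; 0 with
    enough haplotypes yields pairwise-disjoint accessions.  With
    ``cover_all`` every haplotype ends up in at least one accession (the
    simulated population is exactly the planted haplotype set).
    """
    if n_acc < 1:
        raise ValueError("n_acc must be >= 1")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    rng = np.random.default_rng(seed)
    unused = list(rng.permutation(hap_ids))
    used: list[str] = []
    assignment: dict[str, list[str]] = {}
    for a in range(1, n_acc + 1):
        acc = f"ACC{a:02d}"
        k = int(rng.integers(1, ploidy + 1))
        mine: list[str] = []
        for _ in range(k):
            cand_used = [h for h in used if h not in mine]
            if (rng.random() < shared_fraction and cand_used) or not unused:
                if not cand_used:
                    break
                mine.append(cand_used[int(rng.integers(0, len(cand_used)))])
            else:
                mine.append(unused.pop())
        for h in mine:
            if h not in used:
                used.append(h)
        assignment[acc] = mine
    if cover_all:
        for h in list(unused):
            open_accs = [a for a, v in assignment.items() if len(v) < ploidy]
            if not open_accs:
                raise ValueError("cannot cover all haplotypes within ploidy limits")
            acc = open_accs[int(rng.integers(0, len(open_accs)))]
            assignment[acc].append(h)
            unused.remove(h)
    return assignment


def simulate_clones(
    assignment: dict[str, list[str]],
    hap_seqs: dict[str, str],
    clones_per_acc: int = 60,
    error_rate: float = 0.0009,
    dropout: float = 0.2,
    seed: int = 0,
) -> dict[str, list[tuple[str, str]]]:
    """Simulate full-length clone sequences per accession.

    Each clone copies one of the accession's haplotypes with i.i.d. per-base
    substitution errors; a ``dropout`` fraction of clones fails (sequencing /
    assembly loss).  Source haplotypes are sampled by shuffled round-robin
    over the assigned set, so with ``clones_per_acc >= 2*ploidy`` and no
    dropout every assigned haplotype is drawn at least twice.
    """
    if not (0.0 <= error_rate <= 1.0 and 0.0 <= dropout <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, list[tuple[str, str]]] = {}
    for acc in sorted(assignment):
        haps = assignment[acc]
        reps = math.ceil(clones_per_acc / len(haps))
        sources = (list(haps) * reps)[:clones_per_acc]
        rng.shuffle(sources)
        clones: list[tuple[str, str]] = []
        for k, h in enumerate(sources, start=1):
            if rng.random() < dropout:
                continue
            seq = hap_seqs[h]
            n_err = rng.binomial(len(seq), error_rate)
            if n_err:
                s = list(seq)
                for p in rng.choice(len(seq), size=n_err, replace=False):
                    s[p] = str(rng.choice([b for b in _BASES if b != s[p]]))
                seq = "".join(s)
            clones.append((f"{acc}|clone{k}", seq))
        out[acc] = clones
    return out


def simulate_traits(
    truth: SimulationTruth,
    assignment: dict[str, list[str]],
    causal_sites: dict[int, float] | None = None,
    baseline: float = 14.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    trait: str = "sucrose",
) -> pd.DataFrame:
    """Simulate an accession trait table under an additive dosage model.

    ``causal_sites`` maps indices into ``truth.variants`` to per-copy effects;
    an accession's trait is baseline + sum over causal variants of
    effect x (number of carried haplotypes carrying the variant) + Gaussian
    noise.  Accessions are labelled HS/LS by splitting at the median genetic
    value (ties broken by the noisy value), giving the ANOVA stage a
    two-group design.
    """
    causal_sites = causal_sites or {}
    for vi in causal_sites:
        if not (0 <= vi < len(truth.variants)):
            raise ValueError(f"causal site index {vi} outside planted variants")
    rng = np.random.default_rng(seed)
    rows = []
    for acc in sorted(assignment):
        genetic = 0.0
        for vi, eff in causal_sites.items():
            car = set(truth.variants[vi].carriers)
            dosage = sum(1 for h in assignment[acc] if h in car)
            genetic += eff * dosage
        value = baseline + genetic + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append({"accession": acc, "genetic": genetic, "value": value})
    df = pd.DataFrame(rows)
    order = df.sort_values(["genetic", "value"], kind="mergesort").reset_index(drop=True)
    cut = len(order) // 2
    ls_accs = set(order["accession"].iloc[:cut])
    out = pd.DataFrame(
        {
            "accession": df["accession"],
            "group": ["LS" if a in ls_accs else "HS" for a in df["accession"]],
            "brix": np.nan,
            "sucrose": np.nan,
            "fiber": np.nan,
            "reducing_sugar": np.nan,
        }
    )
    out[trait] = df["value"].clip(lower=0.0).values
    truth.assignment = dict(assignment)
    truth.causal_sites = dict(causal_sites)
    truth.noise_sd = noise_sd
    return out
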