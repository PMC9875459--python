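"""Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction, and selection calls.

Synonymous/nonsynonymous site counts use the classical unweighted NG86
scheme: each codon position contributes the fraction of its single-base
changes that are synonymous, with changes to stop codons excluded from the
denominator.  Between two codons differing at 2–3 positions the observed
differences are averaged over all mutational pathways that avoid stop-codon
intermediates (equal weights; if every pathway is blocked, the unweighted
average over all pathways is used and flagged).  Proportions are corrected
with d = -(3/4) ln(1 - (4/3) p); Ka/Ks > 1, = 1, < 1 map to positive,
neutral, and purifying selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "KaKsResult",
    "ng86_sites",
    "ng86_pair",
    "classify_selection",
    "kaks_matrix",
    "positive_selection_summary",
]

_BASES = "ACGT"
_STOPS = frozenset(standard_dna_table.stop_codons)
_AA = dict(standard_dna_table.forward_table)


def _translate(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop codon."""
    return _AA.get(codon)


@dataclass
class KaKsResult:
    """NG86 counts and corrected rates for one sequence pair.

    ``flags`` records degeneracies: 'all_pathways_blocked' (some codon pair
    had only stop-passing pathways), 'ks_saturated' / 'ka_saturated' (p >=
    3/4, Jukes–Cantor correction undefined — the rate is None).
    """

    hap_a: str
    hap_b: str
    syn_sites: float
    nonsyn_sites: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    Ks: float | None
    Ka: float | None
    ratio: float | None
    selection_class: str = "undefined"
    n_codons: int = 0
    flags: list[str] = field(default_factory=list)


def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position, the fraction of the three single-base changes that are
    synonymous (changes to stop codons are dropped from the denominator);
    the two counts always sum to 3.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(c not in _BASES for c in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = _translate(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    syn = 0.0
    for i in range(3):
        n_syn = 0
        n_valid = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            aa2 = _translate(mut)
            if aa2 is None:
                continue
            n_valid += 1
            if aa2 == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


def _pathways(c1: str, c2: str) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """(syn, nonsyn) step counts per mutational pathway from c1 to c2.

    Returns (valid_pathways, all_pathways); a pathway is valid when no
    intermediate codon is a stop.  Endpoints are assumed to be sense codons.
    """
    valid: list[tuple[float, float]] = []
    everything: list[tuple[float, float]] = []

    def walk(cur: str, syn: float, non: float, blocked: bool) -> None:
        diff = [i for i in range(3) if cur[i] != c2[i]]
        if not diff:
            everything.append((syn, non))
            if not blocked:
                valid.append((syn, non))
            return
        for i in diff:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            aa_cur, aa_nxt = _translate(cur), _translate(nxt)
            step_blocked = blocked or (aa_nxt is None and nxt != c2)
            if aa_cur is not None and aa_nxt is not None and aa_cur == aa_nxt:
                walk(nxt, syn + 1.0, non, step_blocked)
            else:
                walk(nxt, syn, non + 1.0, step_blocked or aa_nxt is None)

    walk(c1, 0.0, 0.0, False)
    return valid, everything


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_pair(cds_a: str, cds_b: str, hap_a: str = "a", hap_b: str = "b") -> KaKsResult:
    """NG86 Ka/Ks between two in-frame coding sequences of equal length.

    Codons containing a gap or N in either sequence are dropped pairwise;
    terminal (or stray) stop codons are skipped.  Site counts are averaged
    over both sequences.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS length mismatch")
    if len(cds_a) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    syn_a = syn_b = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    flags: list[str] = []
    for k in range(0, len(cds_a), 3):
        ca, cb = cds_a[k : k + 3], cds_b[k : k + 3]
        if any(ch not in _BASES for ch in ca + cb):
            continue  # gapped / ambiguous codon: dropped pairwise
        if ca in _STOPS or cb in _STOPS:
            continue
        n_codons += 1
        syn_a += ng86_sites(ca)[0]
        syn_b += ng86_sites(cb)[0]
        if ca != cb:
            valid, everything = _pathways(ca, cb)
            paths = valid if valid else everything
            if not valid:
                flags.append("all_pathways_blocked")
            s = sum(p[0] for p in paths) / len(paths)
            n = sum(p[1] for p in paths) / len(paths)
            Sd += s
            Nd += n
    S_bar = (syn_a + syn_b) / 2.0
    N_bar = 3.0 * n_codons - S_bar
    pS = Sd / S_bar if S_bar > 0 else None
    pN = Nd / N_bar if N_bar > 0 else None
    Ks = _jc(pS) if pS is not None else None
    Ka = _jc(pN) if pN is not None else None
    if pS is not None and pS >= 0.75:
        flags.append("ks_saturated")
    if pN is not None and pN >= 0.75:
        flags.append("ka_saturated")
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    res = KaKsResult(
        hap_a=hap_a, hap_b=hap_b,
        syn_sites=S_bar, nonsyn_sites=N_bar,
        Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
        ratio=ratio, n_codons=n_codons, flags=flags,
    )
    res.selection_class = classify_selection(res)
    return res


def classify_selection(result: KaKsResult, tol: float = 1e-9) -> str:
    """identical / positive / purifying / neutral / undefined from Ka vs Ks."""
    if result.Sd == 0.0 and result.Nd == 0.0:
        return "identical"
    if result.Ka is None or result.Ks is None:
        return "undefined"
    if result.Ka > result.Ks + tol:
        return "positive"
    if result.Ka < result.Ks - tol:
        return "purifying"
    return "neutral"


def kaks_matrix(
    cds_map: dict[str, str],
    reference_ids: list[str],
) -> tuple[dict[str, dict[str, KaKsResult]], pd.DataFrame, pd.DataFrame]:
    """Per-reference Ka/Ks vectors plus the full pairwise Ka and Ks matrices.

    ``reference_ids`` are typically the two ancestral haplotypes; each gets a
    vector of results against every other haplotype.  The matrices are
    symmetric with zero diagonal (None where the correction is undefined).
    """
    for ref in reference_ids:
        if ref not in cds_map:
            raise KeyError(f"reference id {ref!r} not among CDS set")
    ids = sorted(cds_map)
    ka = pd.DataFrame(0.0, index=ids, columns=ids, dtype=object)
    ks = pd.DataFrame(0.0, index=ids, columns=ids, dtype=object)
    cache: dict[tuple[str, str], KaKsResult] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            res = ng86_pair(cds_map[a], cds_map[b], a, b)
            cache[(a, b)] = cache[(b, a)] = res
            ka.loc[a, b] = ka.loc[b, a] = res.Ka
            ks.loc[a, b] = ks.loc[b, a] = res.Ks
    vectors = {
        ref: {h: cache[(ref, h)] for h in ids if h != ref}
        for ref in reference_ids
    }
    return vectors, ka, ks


def positive_selection_summary(
    vector: dict[str, KaKsResult],
    carriage: dict[str, list[str]],
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-accession counts of carried positively selected haplotypes.

    ``vector`` is one reference's result vector; ``carriage`` maps accession
    to its haplotype list; ``groups`` optionally labels accessions (HS/LS)
    so group averages can be compared.
    """
    positive = {h for h, r in vector.items() if r.selection_class == "positive"}
    rows = []
    for acc in sorted(carriage):
        n_pos = sum(1 for h in carriage[acc] if h in positive)
        rows.append(
            {
                "accession": acc,
                "group": (groups or {}).get(acc, ""),
                "n_positive": n_pos,
            }
        )
    return pd.DataFrame(rows)
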