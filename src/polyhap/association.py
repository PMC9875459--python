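"""Mutation encoding, site-by-trait correlation, group means, and one-way ANOVA.

The encoding maps each (reference, observed) state pair at a variant site to
a fixed numeric code that distinguishes the mutation category: C-T
transitions 0.5, A-G 0.555; transversions C-A 7, C-G 7.777, T-A 70, T-G
70.777; insertions 900, deletions 900.999; identity 0.  The codes are an
arbitrary but category-distinguishing metric, used exactly as published in
the procedure this reproduces; a one-hot mode is available for
methodological comparison.  Observations are (accession, haplotype)
carriage pairs with the accession's traits attached, or per-accession code
averages in ``per_accession`` mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import Alignment
from .variation import IndelEvent, VariantSite

__all__ = [
    "DEFAULT_ENCODING",
    "CorrelationResult",
    "AnovaResult",
    "encode_site",
    "encode_matrix",
    "site_trait_correlation",
    "group_anova",
    "group_means",
]

#: Category -> code.  Keys for substitutions are unordered base pairs.
DEFAULT_ENCODING: dict[frozenset[str] | str, float] = {
    frozenset("CT"): 0.5,
    frozenset("AG"): 0.555,
    frozenset("CA"): 7.0,
    frozenset("CG"): 7.777,
    frozenset("TA"): 70.0,
    frozenset("TG"): 70.777,
    "insertion": 900.0,
    "deletion": 900.999,
}


@dataclass(frozen=True)
class CorrelationResult:
    site: int
    trait: str
    r: float | None
    p: float | None
    flag: str  # significant-positive | significant-negative | ns | undefined
    n: int


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way decomposition; F = (Sq_between/df_between)/(Sq_within/df_within)."""

    Sq_between: float
    Sq_within: float
    df_between: int
    df_within: int
    Mse_between: float
    Mse_within: float
    F: float | None
    p: float | None


def encode_site(
    ref_state: str,
    obs_state: str,
    scheme: dict | None = None,
) -> float:
    """Numeric code for an observed state against the reference state.

    States are bases, or the markers 'INS' / 'DEL' for indel alleles.
    Symmetric in base order; identity encodes as 0.
    """
    scheme = scheme if scheme is not None else DEFAULT_ENCODING
    if ref_state == obs_state:
        return 0.0
    if obs_state == "INS":
        return scheme["insertion"]
    if obs_state == "DEL" or obs_state == "-":
        return scheme["deletion"]
    key = frozenset((ref_state, obs_state))
    if key not in scheme:
        raise KeyError(f"no code for state pair ({ref_state!r}, {obs_state!r})")
    return scheme[key]


def encode_matrix(
    aln: Alignment,
    snp_sites: list[VariantSite],
    events: list[IndelEvent],
    reference_id: str,
    carriage: dict[str, list[str]],
    scheme: dict | None = None,
    one_hot: bool = False,
) -> pd.DataFrame:
    """Code matrix over (accession, haplotype) observations x variant sites.

    Rows: one per carriage pair, indexed (accession, hap_id).  Columns:
    SNP sites in alignment order, then InDel events in positional order,
    labelled 1..k (the "variant site number" axis).  The reference
    haplotype's rows are all zero by construction.

    ``one_hot`` replaces the numeric category codes with 0/1
    mutation-presence indicators (same columns), for comparing results
    against the published arbitrary-code metric.
    """
    if not aln.has_row(reference_id):
        raise KeyError(f"reference {reference_id!r} not in alignment")
    cols: list[tuple[str, object]] = [("SNP", s) for s in snp_sites]
    cols += [("INDEL", e) for e in sorted(events, key=lambda e: (e.start_column, e.length))]
    index = [
        (acc, hap)
        for acc in sorted(carriage)
        for hap in sorted(carriage[acc])
    ]
    data = np.zeros((len(index), len(cols)))
    ref_row = aln.row(reference_id)
    for j, (kind, obj) in enumerate(cols):
        if kind == "SNP":
            col = obj.column - 1
            ref_state = ref_row[col]
            for i, (_, hap) in enumerate(index):
                obs = aln.row(hap)[col]
                data[i, j] = encode_site(ref_state, obs, scheme)
        else:
            code = encode_site("", "INS" if obj.polarity == "insertion" else "DEL",
                               scheme)
            carriers = set(obj.carriers)
            for i, (_, hap) in enumerate(index):
                data[i, j] = code if hap in carriers else 0.0
    if one_hot:
        data = (data != 0.0).astype(float)
    return pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(index, names=["accession", "hap_id"]),
        columns=pd.RangeIndex(1, len(cols) + 1, name="site"),
    )


def site_trait_correlation(
    matrix: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float = 0.01,
    per_accession: bool = False,
    bh_correct: bool = False,
    trait_columns: tuple[str, ...] = ("brix", "sucrose", "fiber", "reducing_sugar"),
) -> list[CorrelationResult]:
    """Pearson correlation of each variant-site code column with each trait.

    Traits join observations by accession; missing trait values drop
    pairwise.  ``per_accession`` first averages codes over each accession's
    haplotypes so every accession is a single observation.  Zero-variance
    site columns are flagged undefined.  Significance is two-sided from the
    t-transform with n-2 df; |r| direction plus p < alpha sets the flag.
    With ``bh_correct`` flags use Benjamini–Hochberg-adjusted p-values
    (raw p is still reported); the default applies no correction.
    """
    if per_accession:
        matrix = matrix.groupby(level="accession").mean()
        acc_of = list(matrix.index)
    else:
        acc_of = [ix[0] for ix in matrix.index]
    tdf = traits.set_index("accession")
    results: list[CorrelationResult] = []
    for trait in trait_columns:
        if trait not in tdf.columns or tdf[trait].dropna().empty:
            continue
        y_all = np.array(
            [tdf[trait].get(a, np.nan) for a in acc_of], dtype=float
        )
        for site in matrix.columns:
            x_all = matrix[site].to_numpy(dtype=float)
            keep = ~np.isnan(y_all)
            x, y = x_all[keep], y_all[keep]
            n = len(x)
            if n < 3:
                raise ValueError(
                    f"fewer than 3 paired observations for trait {trait!r}"
                )
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                results.append(
                    CorrelationResult(int(site), trait, None, None, "undefined", n)
                )
                continue
            r, p = stats.pearsonr(x, y)
            if p < alpha:
                flag = "significant-positive" if r > 0 else "significant-negative"
            else:
                flag = "ns"
            results.append(CorrelationResult(int(site), trait, float(r), float(p), flag, n))
    if bh_correct:
        defined = [i for i, c in enumerate(results) if c.p is not None]
        adjusted = stats.false_discovery_control(
            [results[i].p for i in defined], method="bh"
        )
        for i, p_adj in zip(defined, adjusted):
            c = results[i]
            if p_adj < alpha:
                flag = "significant-positive" if c.r > 0 else "significant-negative"
            else:
                flag = "ns"
            results[i] = CorrelationResult(c.site, c.trait, c.r, c.p, flag, c.n)
    return results


def group_anova(values: "pd.Series | list[float]", groups: "pd.Series | list[str]") -> AnovaResult:
    """One-way ANOVA over labelled values (classical decomposition).

    Sq_between = sum_g n_g (mean_g - grand)^2; df = (groups-1, n-groups);
    p from the F distribution.  All-identical values leave F undefined.
    """
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(groups)
    keep = ~np.isnan(vals)
    vals, labs = vals[keep], labs[keep]
    uniq = sorted(set(labs.tolist()))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    n = len(vals)
    if n <= len(uniq):
        raise ValueError("need at least one group with >= 2 values")
    grand = vals.mean()
    sq_between = 0.0
    sq_within = 0.0
    for g in uniq:
        gv = vals[labs == g]
        if gv.size == 0:
            raise ValueError(f"group {g!r} is empty")
        sq_between += gv.size * (gv.mean() - grand) ** 2
        sq_within += float(((gv - gv.mean()) ** 2).sum())
    df_b = len(uniq) - 1
    df_w = n - len(uniq)
    mse_b = sq_between / df_b
    mse_w = sq_within / df_w
    if mse_w == 0.0:
        F = None if sq_between == 0.0 else float("inf")
        p = None if F is None else 0.0
    else:
        F = mse_b / mse_w
        p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(
        Sq_between=float(sq_between),
        Sq_within=float(sq_within),
        df_between=df_b,
        df_within=df_w,
        Mse_between=float(mse_b),
        Mse_within=float(mse_w),
        F=None if F is None else float(F),
        p=p,
    )


def group_means(traits: pd.DataFrame, group: str, trait: str = "sucrose") -> float:
    """Arithmetic group mean of a trait, reported to 2 decimals."""
    sel = traits.loc[traits["group"] == group, trait].dropna()
    if sel.empty:
        raise ValueError(f"no values for trait {trait!r} in group {group!r}")
    return round(float(sel.mean()), 2)
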