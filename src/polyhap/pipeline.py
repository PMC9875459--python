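"""End-to-end orchestration: simulate -> call -> align -> variants ->
diversity -> Ka/Ks -> network -> associate, as one seeded, reproducible run.

A single seed drives all stochastic stages through independent derived
substreams (numpy SeedSequence spawning), so any stage can be rerun in
isolation and a whole run is byte-reproducible for a fixed seed + config.
Stage decisions (filtered clones, frameshift exclusions, undefined
correlations) go to the stderr log; the machine-readable run report contains
only deterministic content.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as aln_mod
from . import association, diversity, haplotyping, network, selection, synthetic, variation
from .io_core import RunConfig, SequenceRecord, write_fasta, write_tsv

__all__ = ["SimulationParams", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class SimulationParams:
    """Study-scale defaults: a 2,824 bp amplicon with 39 haplotypes carrying
    67 SNPs + 6 InDels (44:23 ts:tv), 18 accessions of ploidy <= 12, 60
    clones per accession with 0.09% per-base error and 20% dropout, and
    three positive-effect causal variants on the sucrose trait."""

    n_hap: int = 39
    n_snp: int = 67
    n_indel: int = 6
    tstv: float = 44 / 23
    n_acc: int = 18
    ploidy: int = 12
    shared_fraction: float = 0.3
    clones_per_acc: int = 60
    error_rate: float = 0.0009
    dropout: float = 0.2
    exon_lengths: tuple[int, ...] = synthetic.DEFAULT_EXON_LENGTHS
    intron_lengths: tuple[int, ...] = synthetic.DEFAULT_INTRON_LENGTHS
    causal_sites: dict[int, float] | None = None  # auto-picked when None
    n_causal: int = 3
    causal_effect: float = 0.8
    baseline: float = 14.0
    noise_sd: float = 0.5
    large_insertion: tuple[int, int, int] | None = (277, 3, 3)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % 2**31)
            for c in np.random.SeedSequence(seed).spawn(n)]


def _auto_causal(truth: synthetic.SimulationTruth, params: SimulationParams,
                 seed: int) -> dict[int, float]:
    """Pick the SNP variants with the most carriers as causal, positive effects."""
    rng = np.random.default_rng(seed)
    snp_idx = [i for i, v in enumerate(truth.variants) if v.kind == "SNP"]
    snp_idx.sort(key=lambda i: (-len(truth.variants[i].carriers), i))
    chosen = snp_idx[: params.n_causal]
    rng.shuffle(chosen)
    return {i: params.causal_effect for i in chosen}


def run_all(
    config: RunConfig,
    params: SimulationParams | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full simulated-study pipeline and write all stage outputs.

    Returns the run report (also written as ``report.json``): per-stage
    record counts, diversity statistics, selection and association
    summaries, plus the seed and a config echo.
    """
    params = params or SimulationParams()
    out = Path(out_dir) if out_dir is not None else config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    s_template, s_plant, s_assign, s_clone, s_trait, s_causal = _child_seeds(
        config.seed, 6
    )

    # ---- simulate ----------------------------------------------------------
    logger.info("stage simulate")
    template = synthetic.make_template(
        s_template, params.exon_lengths, params.intron_lengths
    )
    haps, truth = synthetic.plant_haplotypes(
        template, n_hap=params.n_hap, n_snp=params.n_snp, n_indel=params.n_indel,
        tstv=params.tstv, seed=s_plant, large_insertion=params.large_insertion,
    )
    assignment = synthetic.assign_to_accessions(
        truth.hap_ids, n_acc=params.n_acc, ploidy=params.ploidy,
        shared_fraction=params.shared_fraction, seed=s_assign,
    )
    clones = synthetic.simulate_clones(
        assignment, truth.hap_seqs, clones_per_acc=params.clones_per_acc,
        error_rate=params.error_rate, dropout=params.dropout, seed=s_clone,
    )
    causal = (params.causal_sites if params.causal_sites is not None
              else _auto_causal(truth, params, s_causal))
    traits = synthetic.simulate_traits(
        truth, assignment, causal, baseline=params.baseline,
        noise_sd=params.noise_sd, seed=s_trait,
    )
    traits.to_csv(out / "traits.csv", index=False)
    n_clones = sum(len(v) for v in clones.values())

    # ---- haplotype calling -------------------------------------------------
    logger.info("stage call-haplotypes")
    called, count_table = haplotyping.call_haplotypes(clones, config.min_support)
    write_fasta(
        [SequenceRecord(
            id=f"{h.hap_id}|{h.total_support}|{','.join(sorted(h.accessions))}",
            seq=h.seq) for h in called],
        out / "haplotypes.fasta",
    )
    count_table.to_csv(out / "support_matrix.tsv", sep="\t")
    carriage = {
        acc: [hap for hap in count_table.columns if count_table.loc[acc, hap] > 0]
        for acc in count_table.index
    }
    freq = {h.hap_id: len(h.accessions) for h in called}

    # ---- alignment ---------------------------------------------------------
    logger.info("stage align")
    ref_id = next((h.hap_id for h in called if h.seq == template.seq), None)
    rows = [(h.hap_id, h.seq) for h in called]
    if ref_id is None:
        ref_id = "REF"
        rows.append((ref_id, template.seq))
    aln = aln_mod.progressive_msa(rows)
    with open(out / "msa.fasta", "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")

    # ---- variant catalogue -------------------------------------------------
    logger.info("stage variants")
    sites, S, eta = variation.segregating_sites(aln, ref_id, template)
    events = variation.indel_events(aln, ref_id)
    density = variation.snp_density(len(template.seq), len(sites))
    write_tsv(
        pd.DataFrame(
            [{"column": s.column, "kind": s.kind, "ref": s.ref_state,
              "alleles": ";".join(f"{a}:{c}" for a, c in s.alleles),
              "ts_tv": s.ts_tv or "NA", "region": s.region} for s in sites]
        ),
        out / "variants.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [{"start_column": e.start_column, "length": e.length,
              "polarity": e.polarity, "inserted_seq": e.inserted_seq,
              "carriers": ",".join(e.carriers)} for e in events]
        ),
        out / "indel_events.tsv",
    )
    cds_map: dict[str, str] = {}
    n_frameshift = 0
    for rid in aln.ids:
        spl = aln_mod.spliced_cds(aln, rid, list(template.exons), ref_id)
        if spl.frameshift:
            n_frameshift += 1
            logger.warning("%s: frameshifted CDS, excluded from translation", rid)
        else:
            cds_map[rid] = spl.seq
    ptypes = variation.protein_types(cds_map)

    # ---- diversity ---------------------------------------------------------
    logger.info("stage diversity")
    group_of = dict(zip(traits["accession"], traits["group"]))
    reports: dict[str, diversity.DiversityReport] = {}
    windows: dict[str, list] = {}

    def _group_report(label: str, accs: list[str]) -> None:
        hap_set = sorted({h for a in accs for h in carriage.get(a, [])})
        if len(hap_set) < 2:
            logger.info("group %s has <2 haplotypes; diversity skipped", label)
            return
        counts = [sum(1 for a in accs if h in carriage.get(a, [])) for h in hap_set]
        sub = aln_mod.Alignment(hap_set, [aln.row(h) for h in hap_set])
        _, S_g, eta_g = variation.segregating_sites(sub, hap_set[0])
        reports[label] = diversity.diversity_report(sub, counts, S_g, eta_g)
        win = min(config.window, sub.width)
        step = min(config.step, win)
        windows[label] = diversity.sliding_pi(sub, win, step)

    all_accs = list(count_table.index)
    _group_report("total", all_accs)
    _group_report("HS", [a for a in all_accs if group_of.get(a) == "HS"])
    _group_report("LS", [a for a in all_accs if group_of.get(a) == "LS"])
    write_tsv(
        pd.DataFrame([{"group": g, **asdict(r)} for g, r in reports.items()]),
        out / "diversity.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [{"group": g, "midpoint_column": c, "pi": p}
             for g, rows_ in windows.items() for c, p in rows_]
        ),
        out / "pi_windows.tsv",
    )

    # ---- selection ---------------------------------------------------------
    logger.info("stage kaks")
    ref2 = None
    steps_from_ref = {}
    for rid in aln.ids:
        if rid != ref_id:
            steps_from_ref[rid] = network.pairwise_steps(ref_id, rid, aln, events)
    if steps_from_ref:
        ref2 = max(sorted(steps_from_ref), key=lambda r: steps_from_ref[r])
    refs = [r for r in (ref_id, ref2) if r is not None and r in cds_map]
    vectors, ka_mat, ks_mat = selection.kaks_matrix(cds_map, refs)
    kaks_rows = [
        {"reference": ref, "hap_id": h, "Ka": r.Ka, "Ks": r.Ks,
         "ratio": r.ratio, "class": r.selection_class}
        for ref, vec in vectors.items() for h, r in sorted(vec.items())
    ]
    write_tsv(pd.DataFrame(kaks_rows), out / "kaks.tsv")
    pos_summary = selection.positive_selection_summary(
        vectors[refs[0]], carriage, group_of
    ) if refs else pd.DataFrame()
    if not pos_summary.empty:
        write_tsv(pos_summary, out / "positive_selection.tsv")

    # ---- network -----------------------------------------------------------
    logger.info("stage network")
    dist = network.step_matrix(aln, list(aln.ids), events)
    G = network.build_msn(dist, freq)
    H = network.insert_inferred_nodes(G)
    center = network.central_haplotype(H)
    write_tsv(
        pd.DataFrame(
            [{"u": u, "v": v, "steps": d["steps"],
              "u_type": H.nodes[u]["kind"], "v_type": H.nodes[v]["kind"]}
             for u, v, d in sorted(H.edges(data=True))]
        ),
        out / "network_edges.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [{"id": n, "kind": d["kind"], "frequency": d["frequency"]}
             for n, d in sorted(H.nodes(data=True))]
        ),
        out / "network_nodes.tsv",
    )

    # ---- association -------------------------------------------------------
    logger.info("stage associate")
    enc = association.encode_matrix(aln, sites, events, ref_id, carriage)
    enc.to_csv(out / "encoded.tsv", sep="\t")
    corr = association.site_trait_correlation(enc, traits, alpha=config.alpha)
    write_tsv(pd.DataFrame([asdict(c) for c in corr]), out / "correlations.tsv")
    sig_per_trait: dict[str, int] = {}
    for c in corr:
        if c.flag.startswith("significant"):
            sig_per_trait[c.trait] = sig_per_trait.get(c.trait, 0) + 1
    anova_rows = []
    for trait in ("brix", "sucrose", "fiber", "reducing_sugar"):
        sel_df = traits[traits["group"].isin(["HS", "LS"])][["group", trait]].dropna()
        if sel_df.empty or sel_df["group"].nunique() < 2:
            continue
        res = association.group_anova(sel_df[trait], sel_df["group"])
        anova_rows.append({"trait": trait, **asdict(res)})
    if anova_rows:
        write_tsv(pd.DataFrame(anova_rows), out / "anova.tsv")

    # ---- report ------------------------------------------------------------
    pos_by_group = {}
    if not pos_summary.empty:
        hs_ls = pos_summary[pos_summary["group"].isin(["HS", "LS"])]
        pos_by_group = {
            g: float(v) for g, v in hs_ls.groupby("group")["n_positive"].mean().items()
        }
    report = {
        "seed": config.seed,
        "config": {
            "min_support": config.min_support,
            "confidence": config.confidence,
            "window": config.window,
            "step": config.step,
            "alpha": config.alpha,
        },
        "clones_in": n_clones,
        "clones_filtered_N": 0,
        "haplotypes_called": len(called),
        "Hn": len(called),
        "S": S,
        "Eta": eta,
        "snp_sites": len(sites),
        "indel_events": len(events),
        "snp_density_bp": density,
        "frameshift_excluded": n_frameshift,
        "protein_types": len(ptypes),
        "central_haplotype": center,
        "backbone_steps": G.graph["backbone_weight"],
        "positive_selection_mean_per_group": pos_by_group,
        "significant_sites_per_trait": sig_per_trait,
        "diversity": {g: asdict(r) for g, r in reports.items()},
    }
    # cross-stage consistency
    assert report["Hn"] == len(called) == len(carriage and count_table.columns)
    assert report["snp_sites"] == len(sites)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
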