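import numpy as np
import pytest

from polyhap import synthetic
from polyhap.synthetic import (
    assign_to_accessions,
    make_template,
    plant_haplotypes,
    simulate_clones,
    simulate_traits,
)

STOPS = {"TAA", "TAG", "TGA"}


class TestMakeTemplate:
    def test_default_shape_is_study_scale(self):
        t = make_template(0)
        assert len(t.seq) == 2824
        assert len(t.exons) == 8 and len(t.introns) == 7
        assert len(t.spliced) % 3 == 0

    def test_length_additivity(self):
        t = make_template(0, exon_lengths=(100, 100, 100), intron_lengths=(100, 100))
        assert len(t.seq) == 500

    def test_deterministic_for_fixed_seed(self):
        assert make_template(5).seq == make_template(5).seq
        assert make_template(5).seq != make_template(6).seq

    def test_spliced_frame_has_no_internal_stop(self):
        for seed in range(5):
            s = make_template(seed).spliced
            assert all(s[i : i + 3] not in STOPS for i in range(0, len(s) - 3, 3))

    def test_rejects_frame_breaking_exons(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            make_template(0, exon_lengths=(100, 100), intron_lengths=(50,))


class TestPlantHaplotypes:
    def test_minimal_case_two_haplotypes_one_snp(self):
        t = make_template(1, exon_lengths=(30, 30), intron_lengths=(40,))
        haps, truth = plant_haplotypes(
            t, n_hap=2, n_snp=1, n_indel=0, seed=2, large_insertion=None
        )
        assert len(haps) == 2
        (a, sa), (b, sb) = haps
        assert sa != sb and len(sa) == len(sb)
        assert sum(x != y for x, y in zip(sa, sb)) == 1
        assert sa == t.seq  # first haplotype is the reference

    def test_deterministic_truth(self):
        t = make_template(1)
        _, t1 = plant_haplotypes(t, seed=9)
        _, t2 = plant_haplotypes(t, seed=9)
        assert t1.hap_seqs == t2.hap_seqs
        assert t1.variants == t2.variants

    def test_extreme_tstv_plants_only_transitions(self):
        t = make_template(1)
        _, truth = plant_haplotypes(
            t, n_hap=10, n_snp=100, n_indel=0, tstv=1e9, seed=3,
            large_insertion=None,
        )
        assert all(v.ts_tv == "transition" for v in truth.variants)

    def test_default_composition_matches_study_counts(self):
        t = make_template(1)
        _, truth = plant_haplotypes(t, seed=4)
        kinds = [v.kind for v in truth.variants]
        assert kinds.count("SNP") == 67
        assert len(truth.variants) - kinds.count("SNP") == 6
        ts = sum(1 for v in truth.variants if v.ts_tv == "transition")
        tv = sum(1 for v in truth.variants if v.ts_tv == "transversion")
        assert (ts, tv) == (44, 23)

    def test_planted_ts_tv_labels_match_reclassification(self):
        from polyhap.variation import classify_substitution

        t = make_template(2)
        _, truth = plant_haplotypes(t, seed=5)
        for v in truth.variants:
            if v.kind == "SNP":
                assert classify_substitution(v.ref, v.alt) == v.ts_tv

    def test_every_variant_has_a_carrier_and_haplotypes_distinct(self):
        t = make_template(3)
        haps, truth = plant_haplotypes(t, seed=6)
        assert all(v.carriers for v in truth.variants)
        seqs = [s for _, s in haps]
        assert len(set(seqs)) == len(seqs)

    def test_indels_are_intronic(self):
        t = make_template(1)
        _, truth = plant_haplotypes(t, seed=7)
        for v in truth.variants:
            if v.kind != "SNP":
                assert v.region.startswith("intron")

    def test_too_many_variants_rejected(self):
        t = make_template(1, exon_lengths=(9,), intron_lengths=())
        with pytest.raises(ValueError, match="positions"):
            plant_haplotypes(t, n_hap=2, n_snp=50, n_indel=0, seed=0,
                             large_insertion=None)


class TestAssignToAccessions:
    def test_ploidy_one_gives_single_haplotype_each(self):
        ids = [f"H{i}" for i in range(1, 30)]
        a = assign_to_accessions(ids, n_acc=10, ploidy=1, seed=0, cover_all=False)
        assert all(len(v) == 1 for v in a.values())

    def test_cover_all_beyond_capacity_rejected(self):
        ids = [f"H{i}" for i in range(1, 30)]
        with pytest.raises(ValueError, match="cover"):
            assign_to_accessions(ids, n_acc=10, ploidy=1, seed=0, cover_all=True)

    def test_zero_sharing_with_enough_haplotypes_is_disjoint(self):
        ids = [f"H{i}" for i in range(1, 200)]
        a = assign_to_accessions(
            ids, n_acc=6, ploidy=4, shared_fraction=0.0, seed=1, cover_all=False
        )
        seen = [h for v in a.values() for h in v]
        assert len(seen) == len(set(seen))

    def test_default_counts_within_ploidy_and_all_covered(self):
        ids = [f"H{i}" for i in range(1, 40)]
        a = assign_to_accessions(ids, seed=2)
        assert all(1 <= len(v) <= 12 for v in a.values())
        assert {h for v in a.values() for h in v} == set(ids)

    def test_within_accession_haplotypes_distinct(self):
        ids = [f"H{i}" for i in range(1, 40)]
        a = assign_to_accessions(ids, shared_fraction=0.8, seed=3)
        assert all(len(v) == len(set(v)) for v in a.values())


class TestSimulateClones:
    def _setup(self):
        t = make_template(1, exon_lengths=(60, 60), intron_lengths=(80,))
        haps, truth = plant_haplotypes(
            t, n_hap=4, n_snp=6, n_indel=0, seed=2, large_insertion=None
        )
        assignment = {"ACC01": ["H1", "H2"], "ACC02": ["H3", "H4"]}
        return truth, assignment

    def test_error_free_clones_copy_their_haplotype(self):
        truth, assignment = self._setup()
        clones = simulate_clones(assignment, truth.hap_seqs, clones_per_acc=8,
                                 error_rate=0.0, dropout=0.0, seed=3)
        hap_seqs = set(truth.hap_seqs.values())
        for acc, recs in clones.items():
            assert len(recs) == 8
            assert all(seq in hap_seqs for _, seq in recs)

    def test_round_robin_covers_every_assigned_haplotype_twice(self):
        truth, assignment = self._setup()
        clones = simulate_clones(assignment, truth.hap_seqs, clones_per_acc=4,
                                 error_rate=0.0, dropout=0.0, seed=4)
        for acc, haps in assignment.items():
            counts = {truth.hap_seqs[h]: 0 for h in haps}
            for _, seq in clones[acc]:
                counts[seq] += 1
            assert all(c >= 2 for c in counts.values())

    def test_full_dropout_yields_no_clones(self):
        truth, assignment = self._setup()
        clones = simulate_clones(assignment, truth.hap_seqs, dropout=1.0, seed=5)
        assert all(len(v) == 0 for v in clones.values())

    def test_error_rate_monte_carlo_mean(self):
        # expected errors/clone = L * rate; at the study's 0.09% over 2,824 bp
        # that is ~2.54 — checked at matching L*rate on a smaller template
        t = make_template(8, exon_lengths=(282, 282), intron_lengths=(282,))
        seq = {"H1": t.seq}
        assignment = {"ACC01": ["H1"]}
        rate = 0.003  # L * rate = 2.54 on an 846 bp template
        clones = simulate_clones(assignment, seq, clones_per_acc=600,
                                 error_rate=rate, dropout=0.0, seed=6)
        diffs = [
            sum(a != b for a, b in zip(s, t.seq)) for _, s in clones["ACC01"]
        ]
        assert np.mean(diffs) == pytest.approx(len(t.seq) * rate, rel=0.15)


class TestSimulateTraits:
    def _truth(self):
        t = make_template(1, exon_lengths=(60, 60), intron_lengths=(80,))
        _, truth = plant_haplotypes(
            t, n_hap=4, n_snp=6, n_indel=0, seed=2, large_insertion=None
        )
        return truth

    def test_no_noise_no_causal_gives_baseline_everywhere(self):
        truth = self._truth()
        assignment = {"ACC01": ["H1"], "ACC02": ["H2", "H3"]}
        tr = simulate_traits(truth, assignment, {}, baseline=14.0, noise_sd=0.0,
                             seed=1)
        assert (tr["sucrose"] == 14.0).all()

    def test_additive_dosage_effect_is_linear(self):
        truth = self._truth()
        vi = 0
        carriers = set(truth.variants[vi].carriers)
        non = [h for h in truth.hap_ids if h not in carriers]
        carrier_hap = next(iter(carriers))
        assignment = {
            "ACC01": [non[0]],                      # dosage 0
            "ACC02": [carrier_hap],                 # dosage 1
            "ACC03": [carrier_hap, non[0]],         # dosage 1
        }
        tr = simulate_traits(truth, assignment, {vi: 2.0}, baseline=10.0,
                             noise_sd=0.0, seed=1).set_index("accession")
        assert tr.loc["ACC02", "sucrose"] - tr.loc["ACC01", "sucrose"] == 2.0
        assert tr.loc["ACC03", "sucrose"] == tr.loc["ACC02", "sucrose"]

    def test_groups_split_by_genetic_value(self):
        truth = self._truth()
        vi = 0
        carriers = set(truth.variants[vi].carriers)
        non = [h for h in truth.hap_ids if h not in carriers]
        carrier_hap = next(iter(carriers))
        assignment = {f"A{i}": [carrier_hap] for i in range(3)}
        assignment |= {f"B{i}": [non[0]] for i in range(3)}
        tr = simulate_traits(truth, assignment, {vi: 3.0}, noise_sd=0.01, seed=2)
        by = tr.set_index("accession")["group"]
        assert all(by[f"A{i}"] == "HS" for i in range(3))
        assert all(by[f"B{i}"] == "LS" for i in range(3))


class TestDeterminism:
    def test_clone_simulation_is_byte_identical_under_fixed_seed(self):
        t = make_template(7, exon_lengths=(60, 60), intron_lengths=(80,))
        haps, truth = plant_haplotypes(
            t, n_hap=4, n_snp=6, n_indel=1, seed=2, large_insertion=None
        )
        a = assign_to_accessions(truth.hap_ids, n_acc=4, ploidy=3, seed=3)
        c1 = simulate_clones(a, truth.hap_seqs, seed=4)
        c2 = simulate_clones(a, truth.hap_seqs, seed=4)
        assert c1 == c2
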