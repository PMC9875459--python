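import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyhap.alignment import Alignment
from polyhap.association import (
    DEFAULT_ENCODING,
    encode_matrix,
    encode_site,
    group_anova,
    group_means,
    site_trait_correlation,
)
from polyhap.variation import indel_events, segregating_sites


class TestEncodeSite:
    @pytest.mark.parametrize(
        "ref, obs, code",
        [
            ("C", "T", 0.5),
            ("A", "G", 0.555),
            ("C", "A", 7.0),
            ("C", "G", 7.777),
            ("T", "A", 70.0),
            ("T", "G", 70.777),
            ("A", "A", 0.0),
            ("G", "INS", 900.0),
            ("G", "DEL", 900.999),
        ],
    )
    def test_category_codes(self, ref, obs, code):
        assert encode_site(ref, obs) == code

    def test_symmetry_over_all_base_pairs(self):
        for a in "ACGT":
            for b in "ACGT":
                if a != b:
                    assert encode_site(a, b) == encode_site(b, a)

    def test_codes_pairwise_distinct(self):
        assert len(set(DEFAULT_ENCODING.values())) == len(DEFAULT_ENCODING)

    def test_unknown_pair_rejected(self):
        with pytest.raises(KeyError):
            encode_site("A", "Z")


class TestEncodeMatrix:
    def _setup(self):
        ref = "ACGTACGTAC"
        snp = "ATGTACGTAC"  # C->T at column 2
        dele = "ACGTA---AC"
        aln = Alignment(["ref", "snp", "del"], [ref, snp, dele])
        sites, _, _ = segregating_sites(aln, "ref")
        events = indel_events(aln, "ref")
        return aln, sites, events

    def test_reference_rows_are_all_zero(self):
        aln, sites, events = self._setup()
        m = encode_matrix(aln, sites, events, "ref",
                          {"a1": ["ref", "snp"], "a2": ["del"]})
        assert (m.loc[("a1", "ref")] == 0).all()

    def test_snp_and_indel_codes_placed_by_carrier(self):
        aln, sites, events = self._setup()
        m = encode_matrix(aln, sites, events, "ref",
                          {"a1": ["ref", "snp"], "a2": ["del"]})
        assert m.shape == (3, 2)  # 1 SNP column + 1 deletion event
        assert m.loc[("a1", "snp"), 1] == 0.5
        assert m.loc[("a2", "del"), 2] == 900.999
        assert m.loc[("a1", "snp"), 2] == 0.0

    def test_column_count_is_snp_sites_plus_indel_events(self, small_study):
        aln = small_study["aln"]
        ref_id = small_study["ref_id"]
        sites, _, _ = segregating_sites(aln, ref_id)
        events = indel_events(aln, ref_id)
        carriage = {
            acc: [h for h in small_study["table"].columns
                  if small_study["table"].loc[acc, h] > 0]
            for acc in small_study["table"].index
        }
        m = encode_matrix(aln, sites, events, ref_id, carriage)
        assert m.shape[1] == len(sites) + len(events)

    def test_nonzero_pattern_matches_planted_carriage(self, small_study):
        truth = small_study["truth"]
        aln = small_study["aln"]
        ref_id = small_study["ref_id"]
        called = small_study["called"]
        sites, _, _ = segregating_sites(aln, ref_id)
        events = indel_events(aln, ref_id)
        hap_of_seq = {h.seq: h.hap_id for h in called}
        carriage = {
            acc: sorted({hap_of_seq[truth.hap_seqs[h]] for h in haps})
            for acc, haps in small_study["assignment"].items()
        }
        m = encode_matrix(aln, sites, events, ref_id, carriage)
        called_of = {h: hap_of_seq[truth.hap_seqs[h]] for h in truth.hap_ids}
        n_variants_of = {
            called_of[h]: sum(1 for v in truth.variants if h in v.carriers)
            for h in truth.hap_ids
        }
        for (acc, hap), row in m.iterrows():
            assert (row != 0).sum() == n_variants_of[hap]

    def test_missing_reference_rejected(self):
        aln, sites, events = self._setup()
        with pytest.raises(KeyError):
            encode_matrix(aln, sites, events, "nope", {"a": ["ref"]})

    def test_one_hot_mode_is_binary_with_same_support(self):
        aln, sites, events = self._setup()
        carriage = {"a1": ["ref", "snp"], "a2": ["del"]}
        coded = encode_matrix(aln, sites, events, "ref", carriage)
        binary = encode_matrix(aln, sites, events, "ref", carriage, one_hot=True)
        assert set(np.unique(binary.values)) <= {0.0, 1.0}
        assert ((coded.values != 0) == (binary.values != 0)).all()


class TestSiteTraitCorrelation:
    def _matrix(self, codes):
        idx = pd.MultiIndex.from_tuples(
            [(f"A{i}", "h") for i in range(len(codes))],
            names=["accession", "hap_id"],
        )
        return pd.DataFrame({1: codes}, index=idx)

    def _traits(self, values):
        return pd.DataFrame(
            {
                "accession": [f"A{i}" for i in range(len(values))],
                "group": ["HS"] * len(values),
                "brix": np.nan,
                "sucrose": values,
                "fiber": np.nan,
                "reducing_sugar": np.nan,
            }
        )

    def test_perfect_proportionality_is_significant_positive(self):
        codes = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5]
        res = site_trait_correlation(self._matrix(codes),
                                     self._traits([10 + 2 * c for c in codes]))
        hit = res[0]
        assert hit.r == pytest.approx(1.0)
        assert hit.flag == "significant-positive"

    def test_negative_effect_flagged_with_sign(self):
        codes = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5]
        res = site_trait_correlation(self._matrix(codes),
                                     self._traits([10 - 3 * c for c in codes]))
        assert res[0].flag == "significant-negative"

    def test_constant_column_is_undefined_not_error(self):
        res = site_trait_correlation(self._matrix([1.0] * 5),
                                     self._traits([1, 2, 3, 4, 5]))
        assert res[0].flag == "undefined"

    def test_missing_traits_dropped_pairwise(self):
        codes = [0.0, 1.0, 2.0, 3.0, 4.0]
        traits = self._traits([1, 2, 3, 4, 5])
        traits.loc[0, "sucrose"] = np.nan
        res = site_trait_correlation(self._matrix(codes), traits)
        assert res[0].n == 4

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            site_trait_correlation(self._matrix([0.0, 1.0]), self._traits([1, 2]))

    def test_bh_correction_only_tightens_flags(self):
        codes = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 1.2, 0.3]
        traits = self._traits([10 + 2 * c + 0.01 * i for i, c in enumerate(codes)])
        m = self._matrix(codes)
        m[2] = [0.1, 2.0, 0.4, 1.1, 0.2, 1.9, 0.8, 0.1]  # unrelated column
        raw = site_trait_correlation(m, traits, alpha=0.01)
        adj = site_trait_correlation(m, traits, alpha=0.01, bh_correct=True)
        raw_sig = {(c.site, c.trait) for c in raw if c.flag.startswith("significant")}
        adj_sig = {(c.site, c.trait) for c in adj if c.flag.startswith("significant")}
        assert adj_sig <= raw_sig  # BH can only remove discoveries here

    def test_per_accession_mode_averages_codes(self):
        idx = pd.MultiIndex.from_tuples(
            [("A0", "h1"), ("A0", "h2"), ("A1", "h1"), ("A2", "h3"), ("A3", "h4")],
            names=["accession", "hap_id"],
        )
        m = pd.DataFrame({1: [0.0, 1.0, 1.0, 2.0, 3.0]}, index=idx)
        traits = self._traits([10.5, 11.0, 12.0, 13.0])
        res = site_trait_correlation(m, traits, per_accession=True)
        # A0 averages to 0.5 -> perfectly linear with the trait
        assert res[0].r == pytest.approx(1.0)


class TestGroupAnova:
    def test_reproduces_published_brix_decomposition(self, traits):
        sel = traits[traits["group"].isin(["HS", "LS"])]
        res = group_anova(sel["brix"], sel["group"])
        assert res.Sq_between == pytest.approx(54.139, abs=5e-4)
        assert (res.df_between, res.df_within) == (1, 11)
        assert res.F == pytest.approx(40.257, abs=5e-4)
        assert res.p < 0.01

    def test_identical_group_means_give_zero_f(self):
        res = group_anova([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"])
        assert res.F == 0.0

    def test_all_identical_values_leave_f_undefined(self):
        res = group_anova([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert res.F is None

    def test_sum_of_squares_additivity_on_random_inputs(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            vals = rng.normal(size=n)
            labs = rng.choice(["x", "y", "z"], size=n)
            if len(set(labs)) < 2 or n <= len(set(labs)):
                continue
            res = group_anova(vals, labs)
            total = float(((vals - vals.mean()) ** 2).sum())
            assert res.Sq_between + res.Sq_within == pytest.approx(total)

    def test_matches_scipy_f_oneway(self, rng):
        a, b, c = rng.normal(size=8), rng.normal(1, 1, size=6), rng.normal(size=5)
        res = group_anova(
            np.concatenate([a, b, c]),
            ["a"] * 8 + ["b"] * 6 + ["c"] * 5,
        )
        F, p = stats.f_oneway(a, b, c)
        assert res.F == pytest.approx(F)
        assert res.p == pytest.approx(p)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            group_anova([1.0, 2.0], ["a", "a"])


class TestGroupMeans:
    def test_published_sucrose_means(self, traits):
        assert group_means(traits, "HS", "sucrose") == 15.90
        assert group_means(traits, "LS", "sucrose") == 13.04

    def test_single_value_is_itself(self, traits):
        assert group_means(traits, "CK", "sucrose") == 13.07

    def test_empty_group_rejected(self, traits):
        with pytest.raises(ValueError):
            group_means(traits, "NOPE", "sucrose")

    def test_missing_values_excluded(self, traits):
        # ancestral group: India1 sucrose is missing and must not count
        val = group_means(traits, "ANCESTRAL", "sucrose")
        assert val == round((15.2 + 12.34 + 12.13) / 3, 2)
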