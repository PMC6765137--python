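import numpy as np
import pandas as pd
import pytest

from longasv.mockeval import (StrainReference, genomic_abundance,
                              integral_ratio_check, normalized_ratios,
                              profile_errors, rarefy, replicate_concordance,
                              assess_accuracy)

from conftest import qread


class TestGenomicAbundance:
    def test_three_to_one_ratios(self):
        # 5 alleles at 3:1:1:1:1 over a 7-copy genome
        assert genomic_abundance([300, 100, 100, 100, 100], 7) == 100

    def test_single_allele(self):
        assert genomic_abundance([40], 10) == 4

    def test_zero_abundance(self):
        assert genomic_abundance([0], 4) == 0

    def test_invalid_copy_number(self):
        with pytest.raises(ValueError):
            genomic_abundance([10], 0)


class TestNormalizedRatios:
    def test_integral_pattern(self):
        r = normalized_ratios([300, 100, 100, 100, 100], 100)
        assert r.tolist() == [3, 1, 1, 1, 1]

    def test_scale_invariance(self):
        a = np.array([300.0, 100.0, 50.0])
        r1 = normalized_ratios(a, genomic_abundance(a, 9))
        r2 = normalized_ratios(a * 7, genomic_abundance(a * 7, 9))
        assert np.allclose(r1, r2)

    def test_zero_genome_error(self):
        with pytest.raises(ValueError):
            normalized_ratios([1.0], 0.0)


class TestIntegralRatioCheck:
    @pytest.mark.parametrize("ratio,nearest,passes", [
        (1.15, 1, True),
        (1.45, 1, False),
        (0.1, 0, False),  # copies must be >= 1
        (2.2, 2, True),
    ])
    def test_examples(self, ratio, nearest, passes):
        r = integral_ratio_check(ratio)
        assert r["nearest"] == nearest and r["pass"] == passes

    def test_composition_recovers_copies(self):
        copies = [4, 2, 1, 1]
        g = 37.0
        abunds = [c * g for c in copies]
        ratios = normalized_ratios(abunds, genomic_abundance(abunds, 8))
        assert [integral_ratio_check(r)["nearest"] for r in ratios] == copies
        assert all(integral_ratio_check(r)["deviation"] < 1e-9
                   for r in ratios)


class TestAssessAccuracy:
    def setup_method(self):
        self.ref = StrainReference(
            "strainX", (("AAAA", 2), ("CCCC", 1)), 3)

    def test_exact_match(self):
        df = assess_accuracy({"AAAA": 200, "CCCC": 100},
                             {"AAAA": "strainX", "CCCC": "strainX"},
                             {"strainX": self.ref})
        assert set(df["verdict"]) == {"exact"}

    def test_integral_ratio_supported(self):
        df = assess_accuracy({"AAAA": 200, "GGGG": 100},
                             {"AAAA": "strainX", "GGGG": "strainX"},
                             {"strainX": self.ref})
        assert df.set_index("sequence").loc["GGGG", "verdict"] == "supported"

    def test_unsupported_singleton_bin(self):
        ref1 = StrainReference("s1", (("AAAA", 1),), 1)
        df = assess_accuracy({"GGGG": 160}, {"GGGG": "s1"}, {"s1": ref1})
        assert df["verdict"].iloc[0] == "unsupported"

    def test_unassigned_reported(self):
        df = assess_accuracy({"TTTT": 5}, {}, {})
        assert df["verdict"].iloc[0] == "unsupported"
        assert df["reason"].iloc[0] == "unassigned"


class TestProfileErrors:
    def test_identical_read_zero_tallies(self, rng):
        t = "".join(rng.choice(list("ACGT"), 200))
        prof = profile_errors([qread(t)], [t])
        assert prof.aggregate_rates()["total"] == 0.0

    def test_single_insertion_recorded(self, rng):
        t = "".join(rng.choice(list("ACGT"), 200))
        q = np.full(201, 93)
        q[50] = 37
        ins = "A" if t[50] != "A" else "C"
        read = qread(t[:50] + ins + t[50:], q=q)
        prof = profile_errors([read], [t])
        assert prof.insertions == {(51, 37): 1}
        assert not prof.substitutions and not prof.deletions

    def test_single_deletion_no_quality(self, rng):
        t = "".join(rng.choice(list("ACGT"), 200))
        read = qread(t[:80] + t[81:])
        prof = profile_errors([read], [t])
        assert prof.deletions == {81: 1}

    def test_best_truth_chosen(self, rng):
        t1 = "".join(rng.choice(list("ACGT"), 150))
        t2 = "".join(rng.choice(list("ACGT"), 150))
        prof = profile_errors([qread(t1), qread(t2)], [t1, t2])
        assert prof.aggregate_rates()["total"] == 0.0

    def test_recovers_generator_rates(self):
        # closure with the read simulator at elevated rates for power
        from longasv.simulate import (CommunitySpec, QualityModel,
                                      make_alleles, simulate_reads)
        from longasv.seqio import remove_primers
        refs = make_alleles(1, [[1]], seed=2, length=600)
        rates = {"substitution": 2e-3, "insertion": 4e-3, "deletion": 4e-3}
        spec = CommunitySpec(strains=refs, proportions=[1.0], rates=rates,
                             chimera_fraction=0.0, seed=9)
        reads, truth = simulate_reads(spec, 400)
        oriented, _ = remove_primers(reads)
        prof = profile_errors(oriented, [refs[0].alleles[0][0]])
        got = prof.aggregate_rates()
        n = prof.total_ref_bases
        for key in rates:
            se = np.sqrt(rates[key] * (1 - rates[key]) / n)
            assert abs(got[key] - rates[key]) <= 3 * se, key


class TestRarefy:
    def test_identity_at_full_depth(self):
        c = [5, 10, 0, 3]
        assert rarefy(c, 18, seed=1).tolist() == c

    def test_sum_and_reproducibility(self):
        c = np.arange(1, 40)
        r1 = rarefy(c, 300, seed=7)
        r2 = rarefy(c, 300, seed=7)
        assert r1.sum() == 300
        assert (r1 == r2).all()
        assert (r1 <= c).all()

    def test_depth_exceeds_total(self):
        with pytest.raises(ValueError):
            rarefy([3, 4], 100, seed=0)

    def test_preserves_expected_proportions(self):
        counts = np.array([5000, 2500, 1500, 800, 200])
        p = counts / counts.sum()
        depth = 1000
        sums = np.zeros(len(counts))
        n_seeds = 200
        for s in range(n_seeds):
            sums += rarefy(counts, depth, seed=s)
        mean_prop = sums / (n_seeds * depth)
        se = np.sqrt(p * (1 - p) / (n_seeds * depth))
        assert (np.abs(mean_prop - p) <= 3 * se + 1e-12).all()


class TestReplicateConcordance:
    def test_identical_tables(self):
        t = pd.DataFrame({"X": [10, 0], "Y": [5, 8]}, index=["s1", "s2"])
        r = replicate_concordance(t, t.copy())
        assert r["a_only"] == r["b_only"] == 0
        assert r["pearson_r"] == pytest.approx(1.0)

    def test_doubled_abundances_still_correlated(self):
        t = pd.DataFrame({"X": [10, 2], "Y": [5, 8]}, index=["s1", "s2"])
        r = replicate_concordance(t, t * 2)
        assert r["shared"] == 4 and r["pearson_r"] == pytest.approx(1.0)

    def test_disjoint_asvs(self):
        a = pd.DataFrame({"X": [10]}, index=["s1"])
        b = pd.DataFrame({"Y": [10]}, index=["s1"])
        r = replicate_concordance(a, b)
        assert r["shared"] == 0 and r["a_only"] == 1 and r["b_only"] == 1

    def test_disjoint_samples_error(self):
        a = pd.DataFrame({"X": [10]}, index=["s1"])
        b = pd.DataFrame({"X": [10]}, index=["s2"])
        with pytest.raises(ValueError):
            replicate_concordance(a, b)
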