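import math

import numpy as np
import pytest

from longasv.denoise import (DEFAULT_OMEGA_A, UniqueSequence,
                             abundance_pvalue, compute_lambda, dereplicate,
                             make_asv_table, run_dada)
from longasv.errormodel import N_QUAL, ErrorModel

from conftest import qread


def uniform_model(self_rate=0.999, indel_rate=1e-3):
    err = (1.0 - self_rate) / 3.0
    rates = np.full((4, 4, N_QUAL), err)
    for t in range(4):
        rates[t, t, :] = self_rate
    return ErrorModel(rates, indel_rate=indel_rate)


class TestDereplicate:
    def test_abundance_sorting(self):
        reads = [qread("ACGT", rid=f"a{i}") for i in range(3)] + \
                [qread("ACGG", rid="b0")]
        uniq = dereplicate(reads)
        assert [(u.sequence, u.abundance) for u in uniq] == \
            [("ACGT", 3), ("ACGG", 1)]

    def test_mean_quality_profile(self):
        reads = [qread("ACGT", q=[20, 20, 20, 20]),
                 qread("ACGT", q=[40, 20, 20, 20])]
        uniq = dereplicate(reads)
        assert uniq[0].quality_profile[0] == 30

    def test_empty(self):
        assert dereplicate([]) == []

    def test_abundance_tie_broken_lexically(self):
        reads = [qread("TTTT"), qread("AAAA")]
        assert [u.sequence for u in dereplicate(reads)] == ["AAAA", "TTTT"]


class TestComputeLambda:
    def test_self_lambda_closed_form(self):
        s = 0.999
        m = uniform_model(self_rate=s)
        L = 40
        u = UniqueSequence("ACGT" * 10, 5, np.full(L, 93.0))
        lam = compute_lambda(u, u.sequence, None, m)
        assert lam == pytest.approx(s ** L, rel=1e-9)

    def test_single_mismatch_scales_by_rate_ratio(self):
        m = uniform_model(self_rate=0.999)
        center = "A" * 30
        member_seq = "A" * 10 + "C" + "A" * 19
        u = UniqueSequence(member_seq, 2, np.full(30, 93.0))
        uc = UniqueSequence(center, 9, np.full(30, 93.0))
        lam_mm = compute_lambda(u, center, None, m)
        lam_self = compute_lambda(uc, center, None, m)
        ratio = m.rates[0, 1, 93] / m.rates[0, 0, 93]
        assert lam_mm / lam_self == pytest.approx(ratio, rel=1e-9)

    def test_error_column_quality_monotonicity(self):
        # higher quality at the error position -> smaller lambda
        rates = np.full((4, 4, N_QUAL), 1e-3)
        for t in range(4):
            rates[t, t, :] = 0.997
        for q in range(N_QUAL):  # strictly decreasing error rates in q
            rates[:, :, q] = np.where(np.eye(4, dtype=bool),
                                      0.997, 1e-3 * 10 ** (-q / 50))
        m = ErrorModel(rates)
        center = "A" * 20
        lams = []
        for q_err in (10, 40, 80):
            qs = np.full(20, 93.0)
            qs[5] = q_err
            u = UniqueSequence("A" * 5 + "G" + "A" * 14, 2, qs)
            lams.append(compute_lambda(u, center, None, m))
        assert lams[0] > lams[1] > lams[2]


class TestAbundancePvalue:
    def test_conditioning_at_singleton(self):
        assert abundance_pvalue(1e-6, 100, 1) == 1.0

    def test_matches_direct_series(self):
        # mu = 1, a = 10 against explicit series summation
        lam, n = 0.01, 100
        mu = n * lam
        num = math.fsum(
            math.exp(-mu + k * math.log(mu) - math.lgamma(k + 1))
            for k in range(10, 200))
        expected = num / (1 - math.exp(-mu))
        assert abundance_pvalue(lam, n, 10) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_nonincreasing_in_abundance(self):
        ps = [abundance_pvalue(0.002, 1000, a) for a in range(1, 30)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            abundance_pvalue(0.0, 10, 2)
        with pytest.raises(ValueError):
            abundance_pvalue(0.5, 1, 5)


class TestRunDada:
    def test_error_free_limit(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 120)) for _ in range(3)]
        reads = [qread(s, rid=f"r{i}{j}") for i, s in enumerate(seqs)
                 for j in range(10 + 5 * i)]
        uniq = dereplicate(reads)
        res = run_dada(uniq, uniform_model())
        assert sorted(res.asvs) == sorted(
            (s, 10 + 5 * i) for i, s in enumerate(seqs))

    def test_omega_zero_single_partition(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(3)]
        reads = [qread(s, rid=f"r{i}{j}") for i, s in enumerate(seqs)
                 for j in range(5)]
        res = run_dada(dereplicate(reads), uniform_model(), omega_a=0.0)
        assert len(res.partitions) == 1

    def test_conservation_and_self_consistency(self, rng):
        base = "".join(rng.choice(list("ACGT"), 150))
        reads = [qread(base, rid=f"r{i}") for i in range(50)]
        # sprinkle singleton error reads
        for i in range(10):
            pos = int(rng.integers(150))
            mutated = base[:pos] + "ACGT"[int(rng.integers(4))] + base[pos + 1:]
            reads.append(qread(mutated, rid=f"e{i}"))
        res = run_dada(dereplicate(reads), uniform_model())
        assert sum(ab for _, ab in res.asvs) == len(reads)
        inputs = {r.nucleotides for r in reads}
        assert all(seq in inputs for seq, _ in res.asvs)

    def test_singletons_never_promoted(self, rng):
        base = "".join(rng.choice(list("ACGT"), 100))
        far = "".join(rng.choice(list("ACGT"), 100))
        reads = [qread(base, rid=f"r{i}") for i in range(20)] + \
            [qread(far, rid="s1")]
        res = run_dada(dereplicate(reads), uniform_model())
        assert len(res.asvs) == 1

    def test_deterministic(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 90)) for _ in range(4)]
        reads = [qread(s, rid=f"r{i}{j}") for i, s in enumerate(seqs)
                 for j in range(4)]
        r1 = run_dada(dereplicate(reads), uniform_model())
        r2 = run_dada(dereplicate(reads), uniform_model())
        assert r1.asvs == r2.asvs
        assert (r1.assignment == r2.assignment).all()

    def test_one_mismatch_pair_resolved(self, small_community):
        # two sequences differing at few positions, both well-populated
        from longasv.simulate import (CommunitySpec, QualityModel,
                                      simulate_reads)
        from longasv.seqio import remove_primers
        spec = CommunitySpec(
            strains=[small_community[0]], proportions=[1.0],
            quality=QualityModel(), chimera_fraction=0.0, seed=3)
        reads, _ = simulate_reads(spec, 1200)
        oriented, _ = remove_primers(reads)
        res = run_dada(dereplicate(oriented), uniform_model(0.9995))
        truth = {s for s, _ in small_community[0].alleles}
        assert {s for s, _ in res.asvs} == truth


class TestAsvTable:
    def test_single_sample(self):
        t = make_asv_table({"s1": {"X" * 20: 10, "Y" * 20: 5}})
        assert t.shape == (1, 2)
        assert t.iloc[0].tolist() == [10, 5]

    def test_shared_asv_merged(self):
        t = make_asv_table({"s1": {"XX": 10}, "s2": {"XX": 3, "YY": 1}})
        assert t.shape == (2, 2)
        assert t.loc["s1", "XX"] == 10 and t.loc["s2", "XX"] == 3
        assert t.loc["s1", "YY"] == 0

    def test_empty(self):
        t = make_asv_table({})
        assert t.shape == (0, 0)

    def test_column_order_total_abundance_then_lex(self):
        t = make_asv_table({"s1": {"B": 5, "A": 5, "C": 9}})
        assert list(t.columns) == ["C", "A", "B"]
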