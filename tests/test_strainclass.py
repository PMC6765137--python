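import numpy as np
import pytest

from longasv.seqio import reverse_complement
from longasv.strainclass import (HitTable, V3V4_PRIMERS, bin_strains,
                                 consensus_classify, extract_subregion)


class TestBinStrains:
    def test_three_one_pattern(self):
        bins, unbinned = bin_strains(
            {"a": 300, "b": 100, "c": 100, "d": 100, "e": 100},
            copy_number=7)
        assert unbinned == [] and len(bins) == 1
        assert bins[0].copies == [3, 1, 1, 1, 1]
        assert bins[0].genome_unit == pytest.approx(100, rel=0.05)

    def test_two_one_pattern(self):
        bins, _ = bin_strains(
            {"a": 200, "b": 100, "c": 100, "d": 100, "e": 100, "f": 100},
            copy_number=7)
        assert len(bins) == 1 and bins[0].copies == [2, 1, 1, 1, 1, 1]

    def test_two_strains_at_separated_scales(self):
        ab = {f"hi{i}": 1000.0 for i in range(7)}
        ab.update({f"lo{i}": 10.0 for i in range(7)})
        bins, unbinned = bin_strains(ab, copy_number=7)
        assert unbinned == [] and len(bins) == 2
        assert all(b.copies == [1] * 7 for b in bins)
        members = [set(b.members) for b in bins]
        assert {f"hi{i}" for i in range(7)} in members
        assert {f"lo{i}" for i in range(7)} in members

    def test_noisy_abundances_still_recovered(self, rng):
        true = [3, 1, 1, 1, 1]
        g = 140.0
        ab = {f"a{i}": c * g * (1 + rng.normal(0, 0.03)) for i, c in
              enumerate(true)}
        bins, _ = bin_strains(ab, copy_number=7)
        assert len(bins) == 1 and bins[0].copies == sorted(true, reverse=True)

    @pytest.mark.parametrize("seed", range(8))
    def test_exhaustive_small_case_oracle(self, seed):
        # exact integral abundances: the generating assignment must be
        # recovered (<= 8 ASVs, copies summing to <= 12)
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        budget = int(rng.integers(n, 13))
        copies = np.ones(n, dtype=int)
        for _ in range(budget - n):
            copies[rng.integers(n)] += 1
        g = float(rng.uniform(50, 500))
        ab = {f"x{i}": float(c * g) for i, c in enumerate(copies)}
        bins, unbinned = bin_strains(ab, copy_number=int(copies.sum()))
        assert unbinned == [] and len(bins) == 1
        got = {aid: k for aid, (_, k) in bins[0].members.items()}
        assert got == {f"x{i}": int(c) for i, c in enumerate(copies)}


class TestConsensusClassify:
    def _table(self):
        # 14 top accessions: 12 annotated O157:H7, 2 with no serotype
        hits = {f"asv{i}": {f"acc{j}" for j in range(14)} for i in range(4)}
        hits["asv0"].add("stray")  # lower-occurrence accession
        meta = {f"acc{j}": {"serotype": "O157:H7"} for j in range(12)}
        meta["acc12"] = {}
        meta["acc13"] = {}
        return HitTable(hits=hits, metadata=meta)

    def test_missing_metadata_ignored(self):
        r = consensus_classify(self._table(), "serotype")
        assert r["classification"] == "O157:H7"
        assert r["supporting_accessions"] == 14

    def test_all_missing_unclassified(self):
        t = HitTable(hits={"a": {"x", "y"}}, metadata={})
        assert consensus_classify(t, "serotype")["classification"] == \
            "unclassified"

    def test_conflict_ambiguous(self):
        t = HitTable(hits={"a": {"x", "y"}},
                     metadata={"x": {"st": "A"}, "y": {"st": "B"}})
        assert consensus_classify(t, "st")["classification"] == "ambiguous"

    def test_invariant_to_ordering_and_duplication(self):
        t1 = self._table()
        items = list(t1.hits.items())[::-1]
        t2 = HitTable(hits=dict(items), metadata=t1.metadata)
        # duplicating an identical hit set does not change the consensus
        t3 = HitTable(hits={**t1.hits, "asv_dup": set(t1.hits["asv0"])},
                      metadata=t1.metadata)
        r1, r2, r3 = (consensus_classify(t, "serotype")
                      for t in (t1, t2, t3))
        assert r1["classification"] == r2["classification"] == \
            r3["classification"]

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            consensus_classify(HitTable(hits={}), "f")

    def test_empty_accession_set_rejected(self):
        with pytest.raises(ValueError):
            HitTable(hits={"a": set()})


class TestHitTableIO:
    def test_from_tsv(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("asv_id\taccession\tserotype\n"
                     "asv1\tacc1\tO157:H7\n"
                     "asv1\tacc2\t\n"
                     "asv2\tacc1\tO157:H7\n")
        t = HitTable.from_tsv(p)
        assert t.hits == {"asv1": {"acc1", "acc2"}, "asv2": {"acc1"}}
        assert t.metadata["acc1"]["serotype"] == "O157:H7"
        assert "serotype" not in t.metadata.get("acc2", {})
        r = consensus_classify(t, "serotype")
        assert r["classification"] == "O157:H7"


class TestExtractSubregion:
    fwd, rev = V3V4_PRIMERS

    def test_constructed_sequence(self, rng):
        region = "".join(rng.choice(list("ACGT"), 400))
        seq = ("GG" + "CCTACGGGAGGCAGCAG" + region
               + reverse_complement("GACTACAAGGGTATCTAATCC") + "TT")
        assert extract_subregion(seq, self.fwd, self.rev) == region

    def test_absent_primer_returns_none(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        assert extract_subregion(seq, self.fwd, self.rev) is None

    def test_alleles_identical_inside_region_collapse(self, rng):
        region = "".join(rng.choice(list("ACGT"), 300))
        mid = ("CCTACGGGTGGCTGCAG" + region
               + reverse_complement("GACTACACGGGTATCTAATCC"))
        a1 = "AAAA" + mid + "GGGG"
        a2 = "TTTT" + mid + "CCCC"  # differs only outside the region
        assert extract_subregion(a1, self.fwd, self.rev) == \
            extract_subregion(a2, self.fwd, self.rev) == region
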