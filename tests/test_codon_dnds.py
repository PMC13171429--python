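import math

import numpy as np
import pytest

from oracles import brute_ng86
from vertitrace import codon_dnds
from vertitrace.codon_dnds import (
    CodonAlignment,
    backtranslate,
    codon_site_counts,
    genetic_code,
    ng86_pair,
    pairwise_matrix,
)
from vertitrace.seqio import SeqSet

SENSE = sorted(c for c, aa in genetic_code(1).items() if aa != "*")


def random_codon_rows(rng, n_codons, gap_prob=0.05, mutate_prob=0.3):
    """Two aligned codon rows sharing most columns, with gaps and multi-hit columns."""
    r1, r2 = [], []
    for _ in range(n_codons):
        if rng.random() < gap_prob:
            r1.append("---")
            r2.append(SENSE[rng.integers(len(SENSE))])
            continue
        c = SENSE[rng.integers(len(SENSE))]
        r1.append(c)
        r2.append(SENSE[rng.integers(len(SENSE))] if rng.random() < mutate_prob else c)
    return "".join(r1), "".join(r2)


class TestBacktranslate:
    def test_gap_insertion(self):
        prot = SeqSet([("a", "M-K")], alphabet="aa")
        cds = SeqSet([("a", "ATGAAA")])
        aln = backtranslate(prot, cds)
        assert aln.rows[0] == "ATG---AAA"

    def test_terminal_stop_stripped(self):
        prot = SeqSet([("a", "MK")], alphabet="aa")
        cds = SeqSet([("a", "ATGAAATAA")])
        aln = backtranslate(prot, cds)
        assert aln.rows[0] == "ATGAAA"

    def test_translation_mismatch_reports_position(self):
        prot = SeqSet([("a", "MK")], alphabet="aa")
        cds = SeqSet([("a", "ATGAGA")])  # translates MR
        with pytest.raises(ValueError, match="position 2"):
            backtranslate(prot, cds)

    def test_partially_gapped_codon_rejected(self):
        with pytest.raises(ValueError, match="partially gapped"):
            CodonAlignment(ids=["a"], rows=["AT-AAA"])


class TestSiteCounts:
    def test_phe_one_third_synonymous(self):
        s, n = codon_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_met_zero_synonymous(self):
        s, n = codon_site_counts("ATG")
        assert s == 0.0 and n == 3.0

    def test_sites_sum_to_three_for_all_sense_codons(self):
        for codon in SENSE:
            s, n = codon_site_counts(codon)
            assert s + n == pytest.approx(3.0)
            assert 0.0 <= s <= 3.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_site_counts("TAA")


class TestNg86Pair:
    def test_identical_rows_filtered(self):
        row = "ATGAAATTT"
        p = ng86_pair(row, row)
        assert p.Sd == p.Nd == 0.0
        assert p.status == "filtered_dN0_or_dS0"

    def test_multihit_pathway_average(self):
        # TTT->GTT->GTA: 1 nonsyn + 1 syn; TTT->TTA->GTA: 2 nonsyn
        p = ng86_pair("TTT", "GTA")
        assert p.Nd == pytest.approx(1.5)
        assert p.Sd == pytest.approx(0.5)

    def test_single_syn_and_nonsyn_difference_status_ok(self):
        r1 = "".join(["ATG", "AAA", "TTT"] + ["GGC"] * 97)
        r2 = "".join(["ATG", "AAG", "TTC"] + ["GGC"] * 96 + ["AGC"])
        p = ng86_pair(r1, r2)
        assert p.dS > 0 and p.dN > 0 and p.status == "ok"
        ref = brute_ng86(r1, r2)
        assert p.omega == pytest.approx(ref["omega"], abs=1e-12)

    def test_undefined_ps0_distinct_from_filtered(self):
        # one nonsynonymous difference only -> pS = 0, ratio undefined
        p = ng86_pair("ATGAAA", "ATGAGA")
        assert p.pS == 0 and p.pN > 0
        assert p.status == "undefined_pS0"

    def test_symmetry_all_fields(self, rng):
        for _ in range(20):
            r1, r2 = random_codon_rows(rng, 30)
            a, b = ng86_pair(r1, r2), ng86_pair(r2, r1)
            for f in ("S", "N", "Sd", "Nd", "pS", "pN", "dS", "dN", "omega"):
                x, y = getattr(a, f), getattr(b, f)
                assert (x is None and y is None) or x == pytest.approx(y)
            assert a.status == b.status

    def test_site_conservation_invariant(self, rng):
        """Sum of per-column averaged site fractions equals the S total."""
        r1, r2 = random_codon_rows(rng, 40, gap_prob=0.0, mutate_prob=0.1)
        p = ng86_pair(r1, r2)
        table = genetic_code(1)
        expected_S = 0.0
        for i in range(0, len(r1), 3):
            c1, c2 = r1[i : i + 3], r2[i : i + 3]
            if table.get(c1, "*") == "*" or table.get(c2, "*") == "*":
                continue
            if codon_dnds._pathway_differences(c1, c2, table) is None:
                continue
            expected_S += (
                codon_site_counts(c1)[0] + codon_site_counts(c2)[0]
            ) / 2.0
        assert p.S == pytest.approx(expected_S)

    def test_jc_correction_small_p_limit(self):
        for p in (1e-6, 1e-5, 1e-4):
            d = codon_dnds._jc(p)
            assert d == pytest.approx(p, rel=1e-3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ng86_pair("ATG", "ATGAAA")


class TestPairwiseMatrix:
    def test_identical_rows_all_filtered(self):
        aln = CodonAlignment(ids=list("abc"), rows=["ATGAAATTT"] * 3)
        m = pairwise_matrix(aln)
        assert len(m.pairs) == 3
        assert m.retained_omegas == []

    def test_pair_count(self):
        rows = ["ATGAAA", "ATGAAG", "ATGACG", "ATGCCA", "ATGCCG"]
        m = pairwise_matrix(CodonAlignment(ids=list("abcde"), rows=rows))
        assert len(m.pairs) == 5 * 4 // 2

    def test_retained_mean_matches_oracle(self, rng):
        rows = []
        base, _ = random_codon_rows(rng, 25, gap_prob=0.0, mutate_prob=0.0)
        for _ in range(4):
            _, mutated = random_codon_rows(rng, 25, gap_prob=0.0, mutate_prob=0.15)
            # splice: mutate base columns instead for a related family
            row = "".join(
                mutated[i : i + 3] if rng.random() < 0.5 else base[i : i + 3]
                for i in range(0, len(base), 3)
            )
            rows.append(row)
        m = pairwise_matrix(CodonAlignment(ids=[f"s{i}" for i in range(4)], rows=rows))
        expected = [
            brute_ng86(rows[i], rows[j])["omega"]
            for i in range(4)
            for j in range(i + 1, 4)
            if brute_ng86(rows[i], rows[j])["status"] == "ok"
        ]
        if expected:
            assert np.mean(m.retained_omegas) == pytest.approx(np.mean(expected))
        else:
            assert m.retained_omegas == []
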