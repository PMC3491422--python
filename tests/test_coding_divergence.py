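"""Protein alignment, back-translation and Nei-Gojobori dN/dS."""

from __future__ import annotations

import math
import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from markdiv.coding_divergence import (CodonAlignment, SequenceInputError,
                                       align_proteins, backtranslate,
                                       filter_estimates, jukes_cantor,
                                       nei_gojobori)
from markdiv.coding_divergence import (STATUS_HIGH_KS, STATUS_INVALID_KS,
                                       STATUS_OK)
from oracles import affine_dp_score, oracle_ng86

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestAlignProteins:
    def test_identical_sequences_score_diagonal(self):
        pa = align_proteins("MKV", "MKV")
        assert pa.aligned_a == pa.aligned_b == "MKV"
        assert pa.score == sum(BLOSUM62[c, c] for c in "MKV")

    def test_known_pair_matches_dp_oracle(self):
        pa = align_proteins("HEAGAWGHEE", "PAWHEAE")
        assert pa.score == affine_dp_score("HEAGAWGHEE", "PAWHEAE",
                                           BLOSUM62, 10.0, 0.5)

    def test_free_end_gaps(self):
        pa = align_proteins("A", "AAAA")
        assert pa.score == BLOSUM62["A", "A"]

    def test_score_matches_oracle_on_random_pairs(self):
        # the acceptance property: DP oracle agreement for all lengths <= 12
        rng = np.random.default_rng(2024)
        for _ in range(150):
            la, lb = rng.integers(1, 13, size=2)
            a = "".join(rng.choice(list(AA20), size=la))
            b = "".join(rng.choice(list(AA20), size=lb))
            pa = align_proteins(a, b)
            expected = affine_dp_score(a, b, BLOSUM62, 10.0, 0.5)
            assert pa.score == pytest.approx(expected), (a, b)

    def test_alignment_recovers_inputs(self):
        pa = align_proteins("MKVLHE", "MKHE")
        assert pa.aligned_a.replace("-", "") == "MKVLHE"
        assert pa.aligned_b.replace("-", "") == "MKHE"
        assert len(pa.aligned_a) == len(pa.aligned_b)

    def test_input_validation(self):
        with pytest.raises(SequenceInputError):
            align_proteins("", "MK")
        with pytest.raises(SequenceInputError):
            align_proteins("MK", "M9")
        with pytest.raises(SequenceInputError):
            align_proteins("MK", "MK", gap_open=-1.0)


class TestBacktranslate:
    def test_simple_mapping(self):
        pa = align_proteins("MK", "MK")
        ca = backtranslate(pa, "ATGAAA", "ATGAAG")
        assert ca.aligned_cds_a == "ATGAAA"
        assert ca.aligned_cds_b == "ATGAAG"

    def test_gap_expansion_to_codon_gaps(self):
        from markdiv.coding_divergence import ProteinAlignment

        pa = ProteinAlignment(aligned_a="M-K", aligned_b="MVK", score=0.0)
        ca = backtranslate(pa, "ATGAAA", "ATGGTTAAA")
        assert ca.aligned_cds_a == "ATG---AAA"
        assert ca.aligned_cds_b == "ATGGTTAAA"

    def test_aligner_output_roundtrips_through_backtranslate(self):
        pa = align_proteins("MVK", "MK")
        ca = backtranslate(pa, "ATGGTTAAA", "ATGAAA")
        assert ca.aligned_cds_a.replace("-", "") == "ATGGTTAAA"
        assert ca.aligned_cds_b.replace("-", "") == "ATGAAA"
        assert len(ca.aligned_cds_a) % 3 == 0

    def test_terminal_stop_trimmed(self):
        pa = align_proteins("MK", "MK")
        ca = backtranslate(pa, "ATGAAATAA", "ATGAAG")
        assert ca.aligned_cds_a == "ATGAAA"

    def test_length_mismatch_raises(self):
        pa = align_proteins("MK", "MK")
        with pytest.raises(SequenceInputError):
            backtranslate(pa, "ATGAAAA", "ATGAAG")

    def test_translation_mismatch_raises(self):
        pa = align_proteins("MK", "MK")
        with pytest.raises(SequenceInputError, match="translates"):
            backtranslate(pa, "ATGCCC", "ATGAAA")  # CCC is Pro, not Lys


class TestNeiGojobori:
    def test_identical_sequences(self):
        est = nei_gojobori(CodonAlignment("p", "ATGAAA", "ATGAAA"))
        assert est.n_diffs == est.s_diffs == 0
        assert est.dn == est.ds == 0.0
        assert est.status == STATUS_OK

    def test_leu_phe_single_codon(self):
        # hand-derived per NG86 rules: TTT vs TTA
        est = nei_gojobori(CodonAlignment("p", "TTT", "TTA"))
        assert est.s_sites == pytest.approx(0.5)
        assert est.n_sites == pytest.approx(2.5)
        assert est.n_diffs == 1 and est.s_diffs == 0
        assert est.ds == 0.0
        assert est.dn == pytest.approx(0.5716, abs=1e-4)

    def test_synonymous_third_position(self):
        est = nei_gojobori(CodonAlignment("p", "GTT", "GTA"))
        assert est.s_diffs == 1 and est.n_diffs == 0
        assert est.dn == 0.0

    def test_exhaustive_single_codon_oracle(self):
        # every sense-codon pair against the enumeration oracle
        table = CodonTable.unambiguous_dna_by_id[1]
        sense = sorted(table.forward_table)
        for ca in sense[::3]:           # stride keeps runtime modest; all codons
            for cb in sense:            # appear on at least one side
                est = nei_gojobori(CodonAlignment("p", ca, cb))
                ref = oracle_ng86(ca, cb)
                assert est.s_sites == pytest.approx(ref["S"]), (ca, cb)
                assert est.s_diffs == pytest.approx(ref["Sd"]), (ca, cb)
                assert est.n_diffs == pytest.approx(ref["Nd"]), (ca, cb)

    def test_matches_reference_implementation_on_multicodon_cds(self):
        # independent cross-check against Bio.codonalign NG86
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        # restricted to codons without stop-codon neighbors and <=1 difference
        # per codon: there the reference's conventions (it averages orderings
        # through stops and scores mutations-to-stop as nonsynonymous sites)
        # provably coincide with the stop-excluding convention used here
        rng = np.random.default_rng(5)
        table = CodonTable.unambiguous_dna_by_id[1]
        sense = sorted(table.forward_table)

        def neighbors(c):
            return [c[:k] + b + c[k + 1:] for k in range(3) for b in "ACGT"
                    if b != c[k]]

        safe = [c for c in sense
                if not any(n in table.stop_codons for n in neighbors(c))]
        for _ in range(10):
            codons1 = list(rng.choice(safe, size=40))
            codons2 = []
            for c in codons1:
                if rng.random() < 0.4:
                    alts = [a for a in neighbors(c) if a in safe]
                    c = alts[int(rng.integers(len(alts)))]
                codons2.append(c)
            c1, c2 = "".join(codons1), "".join(codons2)
            est = nei_gojobori(CodonAlignment("p", c1, c2))
            dn_ref, ds_ref = cal_dn_ds(CodonSeq(c1), CodonSeq(c2), method="NG86")
            assert est.dn == pytest.approx(dn_ref, abs=1e-6)
            assert est.ds == pytest.approx(ds_ref, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        table = CodonTable.unambiguous_dna_by_id[1]
        sense = sorted(table.forward_table)
        for _ in range(20):
            c1 = "".join(rng.choice(sense, size=10))
            c2 = "".join(rng.choice(sense, size=10))
            e12 = nei_gojobori(CodonAlignment("p", c1, c2))
            e21 = nei_gojobori(CodonAlignment("p", c2, c1))
            for f in ("n_sites", "s_sites", "n_diffs", "s_diffs", "dn", "ds"):
                assert getattr(e12, f) == pytest.approx(getattr(e21, f))

    def test_site_conservation(self):
        # N + S == 3 * comparable codons, including gapped/ambiguous columns
        rng = np.random.default_rng(11)
        table = CodonTable.unambiguous_dna_by_id[1]
        sense = sorted(table.forward_table)
        for _ in range(20):
            n = int(rng.integers(3, 20))
            c1 = list(rng.choice(sense, size=n))
            c2 = list(rng.choice(sense, size=n))
            if rng.random() < 0.5:
                k = int(rng.integers(n))
                c1[k] = "---"
                c2[k] = "---" if rng.random() < 0.5 else c2[k]
            if rng.random() < 0.5:
                k = int(rng.integers(n))
                c2[k] = "ANT"
            est = nei_gojobori(CodonAlignment("p", "".join(c1), "".join(c2)))
            assert est.n_sites + est.s_sites == pytest.approx(3 * est.n_codons, abs=1e-9)

    def test_no_comparable_codons_raises(self):
        with pytest.raises(SequenceInputError):
            nei_gojobori(CodonAlignment("p", "---", "ATG"))

    def test_saturation_flagged_not_raised(self):
        # maximally different codons drive p_n past 0.75
        est = nei_gojobori(CodonAlignment(
            "p", "AAAAAAAAAAAA", "TTTTTTTTTTTT"))
        assert est.status == "undefined_saturation"
        assert est.dn is None


class TestJukesCantor:
    def test_values(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.4) == pytest.approx(-0.75 * math.log(1 - 4 * 0.4 / 3))
        assert jukes_cantor(0.75) is None
        with pytest.raises(ValueError):
            jukes_cantor(-0.1)


class TestFilterEstimates:
    def _estimate(self, ds, dn=0.1):
        from markdiv.coding_divergence import DivergenceEstimate
        return DivergenceEstimate(pair_id="p", n_sites=100, s_sites=50,
                                  n_diffs=5, s_diffs=5, p_n=0.05, p_s=0.1,
                                  dn=dn, ds=ds, n_codons=50)

    def test_partition_and_reasons(self):
        ests = [self._estimate(0.5), self._estimate(6.0), self._estimate(None)]
        kept, discarded = filter_estimates(ests, ks_max=5.0)
        assert [e.ds for e in kept] == [0.5]
        assert kept[0].status == STATUS_OK
        reasons = {e.status for e in discarded}
        assert reasons == {STATUS_HIGH_KS, STATUS_INVALID_KS}

    def test_boundary_kept(self):
        kept, discarded = filter_estimates([self._estimate(5.0)], ks_max=5.0)
        assert kept and not discarded
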