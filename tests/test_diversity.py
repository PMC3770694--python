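"""Nucleotide diversity, calibration and NG86 Ka/Ks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tyrscan import diversity as dv
from tyrscan.exceptions import FrameError, JCDomainError, SampleSizeError
from tyrscan.io import STANDARD_CODON_TABLE, RegionInterval

from conftest import make_alignment


class TestPi:
    def test_identical_sequences_zero(self):
        aln = make_alignment(["ACGT" * 25] * 2)
        res = dv.nucleotide_diversity(aln)
        assert res.pi_raw == 0 == res.pi_jc

    def test_one_difference_in_100bp(self):
        a = "A" * 100
        b = "A" * 99 + "G"
        res = dv.nucleotide_diversity(make_alignment([a, b]))
        assert res.pi_raw == pytest.approx(0.01)
        assert res.pi_jc == pytest.approx(0.010067, abs=1e-6)

    def test_needs_two_chromosomes(self):
        with pytest.raises(SampleSizeError):
            dv.nucleotide_diversity(make_alignment(["ACGT"]))

    def test_jc_domain_error(self):
        with pytest.raises(JCDomainError):
            dv.jc_correct(0.8)

    def test_jc_converges_to_raw_for_small_p(self):
        for p in (0.001, 0.003, 0.0049):
            assert dv.jc_correct(p) / p == pytest.approx(1.0, abs=0.01)

    @given(st.integers(0, 10**6))
    @settings(max_examples=15, deadline=None)
    def test_region_pis_recombine_to_whole(self, seed):
        """Site-weighted average of per-region pi equals whole-alignment pi."""
        rng = np.random.default_rng(seed)
        seqs = rng.choice(list("ACGT"), p=[0.85, 0.05, 0.05, 0.05],
                          size=(6, 60))
        regions = [RegionInterval(0, 20, "5'flank"),
                   RegionInterval(20, 50, "intron_1"),
                   RegionInterval(50, 60, "3'flank")]
        aln = make_alignment(["".join(r) for r in seqs], regions=regions)
        whole = dv.nucleotide_diversity(aln)
        num = den = 0.0
        for iv in regions:
            cols = aln.columns_for_region(iv.label)
            r = dv.nucleotide_diversity(aln, columns=cols)
            num += r.pi_raw * r.n_sites
            den += r.n_sites
        assert num / den == pytest.approx(whole.pi_raw, rel=1e-12)


class TestSlidingWindows:
    def _aln(self, seqs):
        L = len(seqs[0])
        return make_alignment(seqs, regions=[RegionInterval(0, L, "5'flank")])

    def test_constant_alignment_all_zero(self):
        res = dv.sliding_window_pi(self._aln(["A" * 3000] * 4),
                                   window_bp=1500, step_bp=375)
        vals = [r.pi_raw for r in res if not r.missing]
        assert vals and all(v == 0 for v in vals)

    def test_variation_localised_to_one_window(self):
        a = "A" * 3000
        b = "A" * 100 + "G" * 5 + "A" * 2895      # variation only in cols 100-104
        res = dv.sliding_window_pi(self._aln([a, b]),
                                   window_bp=500, step_bp=500)
        nonzero = [r for r in res if not r.missing and r.pi_raw > 0]
        assert len(nonzero) == 1
        assert nonzero[0].window == (0, 500)

    def test_sparse_windows_reported_missing(self):
        aln = make_alignment(["ACGT" * 10] * 3,
                             regions=[RegionInterval(0, 40, "5'flank")])
        res = dv.sliding_window_pi(aln, window_bp=8, step_bp=8, min_sites=10)
        assert all(r.missing for r in res)


class TestCalibration:
    def test_printed_divergence_gives_three_e_minus_eight(self):
        cal = dv.calibrate_mutation_rate(0.01447, 7e6, 29)
        assert cal.mu_per_site_per_gen == pytest.approx(3.0e-8, rel=0.005)

    def test_zero_divergence(self):
        assert dv.calibrate_mutation_rate(0.0).mu_per_site_per_gen == 0

    def test_closed_form_case(self):
        cal = dv.calibrate_mutation_rate(0.02, 1e7, 25)
        assert cal.mu_per_site_per_gen == pytest.approx(2.5e-8)

    def test_consensus_tie_broken_toward_outgroup(self):
        aln = make_alignment(["AAAA", "AAAG"], outgroup="AAAG")
        cons = dv.human_consensus(aln)
        assert cons[3] == "G"


def brute_force_pathways(c1, c2, table=STANDARD_CODON_TABLE):
    """Independent oracle: DFS over substitution orderings."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    aa = table.forward_table.get
    paths = []

    def walk(cur, remaining, syn, non, blocked):
        if not remaining:
            paths.append((blocked, syn, non))
            return
        for i in remaining:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            a1, a2 = aa(cur, "*"), aa(nxt, "*")
            s = syn + (1 if (a1 == a2 and a1 != "*") else 0)
            n = non + (0 if (a1 == a2 and a1 != "*") else 1)
            walk(nxt, [j for j in remaining if j != i], s, n,
                 blocked or (a2 == "*" and nxt != c2))

    walk(c1, diff, 0, 0, False)
    ok = [(s, n) for b, s, n in paths if not b] or \
         [(s, n) for _, s, n in paths]
    return (sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok))


class TestNeiGojobori:
    def test_identical_sequences_undefined_ratio(self):
        res = dv.nei_gojobori_kaks("ATGAAA", "ATGAAA")
        assert res.Ka == res.Ks == 0 and res.ratio is None

    def test_atg_site_counts(self):
        res = dv.nei_gojobori_kaks("ATG", "ATG")
        assert res.N_sites == pytest.approx(3.0)
        assert res.S_sites == pytest.approx(0.0)

    def test_site_counts_sum_to_sequence_length(self):
        a = "ATGAAACCCGGGTTTCTGGAGCATAAGGCA"
        b = "ATGAAACCAGGGTTTCTAGAGCATAAGGCA"
        res = dv.nei_gojobori_kaks(a, b)
        assert res.N_sites + res.S_sites == pytest.approx(len(a))
        assert res.Sd + res.Nd == pytest.approx(2.0)

    def test_printed_rates_give_ratio(self):
        res = dv.KaKsResult(Ka=0.0018, Ks=0.0114, N_sites=0, S_sites=0,
                            Nd=0, Sd=0)
        assert res.ratio == pytest.approx(0.158, abs=5e-4)

    def test_internal_stop_raises(self):
        with pytest.raises(FrameError):
            dv.nei_gojobori_kaks("TAAAAA", "TAAAAG")

    @pytest.mark.parametrize("c1,c2", [
        ("ATG", "ATA"), ("TTT", "GGG"), ("TGG", "TGT"),
        ("AAA", "GGG"), ("CGA", "AGG"), ("TCA", "ACT"),
    ])
    def test_pathway_counts_match_brute_force(self, c1, c2):
        sd, nd = dv._pathway_counts(c1, c2, STANDARD_CODON_TABLE)
        sd_o, nd_o = brute_force_pathways(c1, c2)
        assert sd == pytest.approx(sd_o)
        assert nd == pytest.approx(nd_o)

    def test_divergence_pipeline_on_synthetic_coding(self, rng):
        """End-to-end Ka/Ks on a pair of mutated coding sequences keeps the
        difference counts equal to the number of differing codon positions."""
        codons = [c for c in map("".join, itertools.product("ACGT", repeat=3))
                  if STANDARD_CODON_TABLE.forward_table.get(c)]
        seq = "".join(rng.choice(codons, size=60))
        seq2 = list(seq)
        mutated = rng.choice(len(seq2), size=8, replace=False)
        for i in mutated:
            choices = [b for b in "ACGT" if b != seq2[i]]
            seq2[i] = rng.choice(choices)
        try:
            res = dv.nei_gojobori_kaks(seq, "".join(seq2))
        except FrameError:
            return                      # mutation created an internal stop
        assert res.Sd + res.Nd == pytest.approx(
            sum(a != b for a, b in zip(seq, seq2)))
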