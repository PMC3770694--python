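"""EHH machinery, F_ST, d_i and the window/bin/rank scan."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tyrscan import selscan as ss
from tyrscan.exceptions import ConfigError

from conftest import make_panel


class TestEhh:
    def test_identical_carriers_full_homozygosity(self):
        geno = np.zeros((6, 9), dtype=np.int8)
        geno[:3, 4] = 1                       # derived carriers identical rows
        curve = ss.ehh(make_panel(geno), core_snp=4, core_allele=1,
                       direction="right")
        assert (curve.ehh == 1.0).all()

    def test_two_carriers_split_at_first_flanking_snp(self):
        geno = np.zeros((4, 3), dtype=np.int8)
        geno[:2, 1] = 1                       # carriers of the core
        geno[0, 2] = 1                        # they differ at the next SNP
        curve = ss.ehh(make_panel(geno), core_snp=1, core_allele=1,
                       direction="right")
        assert curve.ehh[0] == 1.0 and curve.ehh[1] == 0.0

    def test_four_carrier_hand_enumeration(self):
        # carriers extended one SNP each side: haplotypes AB, AB, Ab, aB
        # (A/a = left SNP allele, B/b = right SNP allele)
        left = [1, 1, 1, 0]
        right = [1, 1, 0, 1]
        geno = np.column_stack([left, [1] * 4, right]).astype(np.int8)
        panel = make_panel(geno)
        r = ss.ehh(panel, 1, 1, "right")
        l = ss.ehh(panel, 1, 1, "left")
        # right: groups {AB,AB,aB}x{Ab}? pairs identical over [core,right]:
        # B carriers {0,1,3} -> C(3,2)=3 pairs of 6
        assert r.ehh[1] == pytest.approx(3 / 6)
        # left: A carriers {0,1,2} -> 3 of 6
        assert l.ehh[1] == pytest.approx(3 / 6)

    def test_single_carrier_returns_none(self):
        geno = np.zeros((4, 3), dtype=np.int8)
        geno[0, 1] = 1
        assert ss.ehh(make_panel(geno), 1, 1, "right") is None

    def test_ehh_non_increasing_outward(self, neutral_panel):
        daf = neutral_panel.daf()
        cores = np.flatnonzero((daf > 0.2) & (daf < 0.8))[:20]
        for core in cores:
            for direction in ("left", "right"):
                c = ss.ehh(neutral_panel, int(core), 1, direction)
                if c is None or len(c.ehh) < 2:
                    continue
                assert c.ehh[0] == 1.0
                assert (np.diff(c.ehh) <= 1e-12).all()


class TestIhs:
    def test_symmetric_classes_give_zero(self):
        # ancestral and derived carriers with mirrored haplotype structure
        block = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        geno = np.hstack([
            np.vstack([block, block]),
            np.array([[1]] * 4 + [[0]] * 4, dtype=np.int8),   # core
            np.vstack([block, block]),
        ])
        scores = ss.ihs(make_panel(geno), min_daf=0.0, max_daf=1.0)
        core = scores[2]
        assert not core.unscored_reason
        assert core.unstandardized == pytest.approx(0.0, abs=1e-12)

    def test_gap_rule_flags_unscored(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 2, size=(30, 40)).astype(np.int8)
        pos = np.arange(40) * 1000
        pos[25:] += 300_000                  # > 200 kb assembly gap
        panel = make_panel(geno, pos_bp=pos + 1)
        scores = ss.ihs(panel, snps=[24])
        assert scores[0].unscored_reason in ("edge-or-gap", "zero-ihh")

    def test_ihh_integration_refinement_stable(self, neutral_panel):
        """Halving the integration grid spacing by linear interpolation of
        the decay curve changes iHH by < 1% (trapezoid refinement
        stability on the interpolated map)."""
        from tyrscan.selscan import _integrate_ihh
        daf = neutral_panel.daf()
        band = np.flatnonzero((daf > 0.4) & (daf < 0.6))
        cores = band[np.argsort(np.abs(band - neutral_panel.n_snps // 2))][:5]
        checked = 0
        for core in cores:
            curve = ss.ehh(neutral_panel, int(core), 1, "right")
            if curve is None or len(curve.ehh) < 4:
                continue
            x, y = curve.pos_cM, curve.ehh
            base = _integrate_ihh(x, y)
            xm = (x[:-1] + x[1:]) / 2
            xf = np.sort(np.concatenate([x, xm]))
            yf = np.interp(xf, x, y)
            fine = _integrate_ihh(xf, yf)
            if base > 0:
                assert fine == pytest.approx(base, rel=0.01)
                checked += 1
        assert checked >= 3


class TestXpehh:
    def test_identity_panels_give_zero(self, neutral_panel):
        scores = ss.xpehh(neutral_panel, neutral_panel, normalize=False,
                          snps=list(range(0, neutral_panel.n_snps, 7)))
        vals = [s.standardized for s in scores if not s.unscored_reason]
        assert vals and max(abs(v) for v in vals) == 0.0

    def test_swapping_panels_negates_scores(self, neutral_panel):
        half = neutral_panel.n_haps // 2
        a = make_panel(neutral_panel.geno[:half],
                       pos_bp=neutral_panel.pos_bp)
        b = make_panel(neutral_panel.geno[half:],
                       pos_bp=neutral_panel.pos_bp)
        snps = list(range(5, neutral_panel.n_snps - 5, 11))
        ab = ss.xpehh(a, b, normalize=False, snps=snps)
        ba = ss.xpehh(b, a, normalize=False, snps=snps)
        for x, y in zip(ab, ba):
            if x.unscored_reason or y.unscored_reason:
                continue
            assert x.standardized == pytest.approx(-y.standardized)

    def test_mismatched_snp_sets_rejected(self, neutral_panel):
        other = neutral_panel.subset_snps(np.arange(neutral_panel.n_snps - 1))
        with pytest.raises(ConfigError):
            ss.xpehh(neutral_panel, other)


class TestWcFst:
    def _panel(self, p1, p2, n1=200, n2=200):
        g = np.zeros((n1 + n2, 1), dtype=np.int8)
        g[:int(p1 * n1), 0] = 1
        g[n1:n1 + int(p2 * n2), 0] = 1
        return make_panel(g, pops=["a"] * n1 + ["b"] * n2)

    def test_fixed_alternate_alleles_approach_one(self):
        theta = ss.wc_fst(self._panel(1.0, 0.0), "a", "b")[0]
        assert theta == pytest.approx(1.0, abs=1e-9)

    def test_equal_frequencies_nonpositive_in_expectation(self, rng):
        vals = []
        for _ in range(200):
            g = (rng.random((40, 1)) < 0.3).astype(np.int8)
            panel = make_panel(g, pops=["a"] * 20 + ["b"] * 20)
            v = ss.wc_fst(panel, "a", "b")[0]
            if not np.isnan(v):
                vals.append(v)
        assert np.mean(vals) < 0.02

    def test_textbook_formula_case(self):
        theta = ss.wc_fst(self._panel(0.2, 0.8, 50, 50), "a", "b")[0]
        # independent evaluation of the 1984 estimator
        n1 = n2 = 50.0
        p1, p2, r = 0.2, 0.8, 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar)**2 + n2 * (p2 - pbar)**2) / ((r - 1) * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
        assert theta == pytest.approx(a / (a + b), abs=1e-12)

    def test_monomorphic_pair_undefined(self):
        g = np.zeros((20, 1), dtype=np.int8)
        panel = make_panel(g, pops=["a"] * 10 + ["b"] * 10)
        assert np.isnan(ss.wc_fst(panel, "a", "b")[0])


class TestDi:
    def _three_pop_panel(self, rng, n_snps=120):
        freqs = rng.uniform(0.1, 0.9, size=(3, n_snps))
        rows = []
        pops = []
        for k, pop in enumerate(["A", "B", "C"]):
            rows.append((rng.random((30, n_snps)) < freqs[k]))
            pops += [pop] * 30
        return make_panel(np.vstack(rows).astype(np.int8), pops=pops)

    def test_di_matches_direct_standardisation(self, rng):
        panel = self._three_pop_panel(rng)
        scores = ss.di_statistic(panel, "A")
        # direct recomputation from pairwise F_ST series
        expected = np.zeros(panel.n_snps)
        for other in ("B", "C"):
            fst = ss.wc_fst(panel, "A", other)
            z = (fst - np.nanmean(fst)) / np.nanstd(fst)
            expected += np.nan_to_num(z)
        got = np.array([s.di for s in scores])
        assert np.allclose(got, expected, atol=1e-9)

    def test_window_mean_di_near_zero(self, rng):
        panel = self._three_pop_panel(rng, n_snps=400)
        scores = ss.di_statistic(panel, "B")
        assert abs(np.mean([s.di for s in scores])) < 0.1

    def test_degenerate_pair_rejected(self):
        g = np.tile(np.array([[0], [1]], dtype=np.int8), (15, 1))
        panel = make_panel(g, pops=["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        with pytest.raises(ConfigError):
            ss.di_statistic(panel, "A")

    def test_needs_three_populations(self):
        panel = make_panel(np.zeros((4, 2), dtype=np.int8),
                           pops=["A", "A", "B", "B"])
        with pytest.raises(ConfigError):
            ss.di_statistic(panel, "A")


class TestWindowize:
    def _frame(self, rng, n=400, span=2_000_000):
        return pd.DataFrame(dict(
            chrom="1", pos_bp=np.sort(rng.integers(0, span, n)),
            value=rng.normal(size=n)))

    def test_all_below_two_gives_zero_fraction_everywhere(self, rng):
        df = self._frame(rng)
        df["value"] = rng.uniform(-1.5, 1.5, len(df))
        wins = ss.windowize(df, bin_size=20, summary="frac_gt2")
        assert all(w.value == 0 for w in wins)
        assert all(w.percentile_rank == 1.0 for w in wins)

    def test_strict_maximum_attains_rank_one(self, rng):
        df = self._frame(rng)
        wins = ss.windowize(df, bin_size=20, summary="max")
        for b in {w.bin for w in wins}:
            grp = [w for w in wins if w.bin == b]
            top = max(grp, key=lambda w: w.value)
            assert top.percentile_rank == 1.0

    def test_bin_is_floor_of_snp_count(self, rng):
        wins = ss.windowize(self._frame(rng), bin_size=15, summary="mean")
        assert all(w.bin == w.n_snps // 15 for w in wins)

    def test_ranks_invariant_under_monotone_transform(self, rng):
        df = self._frame(rng)
        wins = ss.windowize(df, bin_size=20, summary="max")
        df2 = df.assign(value=np.exp(df["value"]))
        wins2 = ss.windowize(df2, bin_size=20, summary="max")
        # exp is monotone: same windows, same ranks
        assert [w.percentile_rank for w in wins] == \
               [w.percentile_rank for w in wins2]

    def test_focal_window_recentred_on_gene_midpoint(self, rng):
        df = self._frame(rng)
        fw = ss.focal_window(df, "1", center_bp=1_000_000, bin_size=20,
                             summary="mean")
        assert (fw.start, fw.end) == (900_000, 1_100_000)
        assert 0 <= fw.percentile_rank <= 1
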