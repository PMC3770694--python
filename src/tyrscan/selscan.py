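"""Haplotype-homozygosity scans, differentiation statistics and the
200-kb window / SNP-count bin / percentile-rank genome-scan machinery.

EHH(x) is the probability that two random distinct haplotypes carrying the
core allele are identical over [core, x].  iHS integrates EHH over genetic
distance separately for ancestral and derived cores (iHH_A, iHH_D) and
takes ln(iHH_A / iHH_D), standardised within derived-allele-frequency bins
and then z-normalised per chromosome.  XP-EHH integrates over all
haplotypes of each of two populations and takes ln(iHH_focal / iHH_ref).
d_i sums, over the other populations, the genome-standardised pairwise
Weir-Cockerham F_ST of the focal population.

Scan results are summarised in non-overlapping 200-kb windows anchored at
position 0 of each chromosome, binned by SNP count (floor(n/bin_size)), and
ranked by the fraction of same-bin windows with a value <= their own (ties
counted <=, so the maximum attains rank 1.0).  The focal-gene window is
re-centred on the gene midpoint and ranked against the same-bin windows of
the anchored genome-wide grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import HaplotypePanel

__all__ = [
    "EhhCurve", "CoreScore", "WindowScore", "ehh", "ihs", "xpehh",
    "wc_fst", "di_statistic", "windowize", "focal_window",
]

EHH_CUTOFF = 0.05
MAX_GAP_BP = 200_000


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EhhCurve:
    snp_indices: np.ndarray     # panel SNP indices, core first
    pos_cM: np.ndarray
    ehh: np.ndarray             # EHH at each SNP, 1.0 at the core


def _n_pairs(k):
    return k * (k - 1) / 2.0


def _ehh_walk(geno: np.ndarray, snp_order: np.ndarray, masks: list[np.ndarray],
              cutoff: float = EHH_CUTOFF, track_all: bool = False):
    """Walk outward over ``snp_order`` refining the haplotype partition.

    ``masks``: boolean haplotype sets to track (e.g. derived carriers,
    ancestral carriers, or whole populations).  Returns (curves, decayed):
    per-set EHH arrays (the 1.0 at the core itself is prepended by the
    caller) and whether the stopping rule was met before the SNPs ran out.
    The walk stops when every tracked set has EHH < cutoff, or — with
    ``track_all`` — when the pooled set drops below cutoff.
    """
    n_sets = len(masks)
    n_haps = geno.shape[0]
    sizes = [int(m.sum()) for m in masks]
    pair_norm = [_n_pairs(k) for k in sizes]
    gid = np.zeros(n_haps, dtype=np.intp)
    n_groups = 1
    pooled = np.zeros(n_haps, dtype=bool)
    for m in masks:
        pooled |= m
    pooled_pairs = _n_pairs(int(pooled.sum()))
    out = [[] for _ in range(n_sets)]
    for j in snp_order:
        col = geno[:, j]
        # missing calls form their own allele class (break homozygosity
        # against both real alleles)
        code = np.where(col == 1, 1, np.where(col == 0, 0, 2))
        wide = gid * 3 + code
        # recompact group ids without sorting (ids stay < 3 * n_groups)
        occupied = np.bincount(wide, minlength=3 * n_groups) > 0
        remap = np.cumsum(occupied) - 1
        gid = remap[wide]
        n_groups = int(remap[-1]) + 1
        ehh_vals = []
        for m, norm in zip(masks, pair_norm):
            if norm == 0:
                ehh_vals.append(0.0)
                continue
            counts = np.bincount(gid[m], minlength=n_groups)
            ehh_vals.append(float(_n_pairs(counts).sum() / norm))
        for s in range(n_sets):
            out[s].append(ehh_vals[s])
        if track_all:
            counts_all = np.bincount(gid[pooled], minlength=n_groups)
            pooled_ehh = (_n_pairs(counts_all).sum() / pooled_pairs
                          if pooled_pairs else 0.0)
            if pooled_ehh < cutoff:
                return [np.asarray(o) for o in out], True
        elif all(v < cutoff for v in ehh_vals):
            return [np.asarray(o) for o in out], True
    return [np.asarray(o) for o in out], False


def ehh(panel: HaplotypePanel, core_snp: int, core_allele: int,
        direction: str) -> EhhCurve | None:
    """EHH decay curve from a core SNP in one direction ('left'/'right').

    Returns None when fewer than 2 haplotypes carry ``core_allele``.
    Missing genotypes count as a private allele (they break homozygosity).
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    chrom = panel.chrom[core_snp]
    on_chrom = np.flatnonzero(panel.chrom == chrom)
    k = int(np.searchsorted(on_chrom, core_snp))
    order = on_chrom[k + 1:] if direction == "right" else on_chrom[:k][::-1]
    carriers = panel.geno[:, core_snp] == core_allele
    if carriers.sum() < 2:
        return None
    curves, _ = _ehh_walk(panel.geno, order, [carriers])
    vals = curves[0]
    m = len(vals)
    return EhhCurve(
        snp_indices=np.concatenate([[core_snp], order[:m]]),
        pos_cM=np.concatenate([[panel.pos_cM[core_snp]],
                               panel.pos_cM[order[:m]]]),
        ehh=np.concatenate([[1.0], vals]))


def _integrate_ihh(pos_cM: np.ndarray, vals: np.ndarray) -> float:
    """Trapezoid integral of an EHH curve over |cM|, truncated at the
    cutoff crossing (linear interpolation to EHH = cutoff)."""
    x = np.abs(pos_cM - pos_cM[0])
    area = 0.0
    for i in range(1, len(vals)):
        lo, hi = vals[i - 1], vals[i]
        dx = x[i] - x[i - 1]
        if hi >= EHH_CUTOFF:
            area += 0.5 * (lo + hi) * dx
        else:
            if lo <= EHH_CUTOFF:
                break
            frac = (lo - EHH_CUTOFF) / (lo - hi)
            area += 0.5 * (lo + EHH_CUTOFF) * dx * frac
            break
    return area


@dataclass
class CoreScore:
    snp_id: str
    chrom: str
    pos_bp: int
    daf: float
    ihh_a: float = math.nan
    ihh_d: float = math.nan
    unstandardized: float = math.nan
    standardized: float = math.nan
    unscored_reason: str = ""


def _directional_curves(panel, core, masks, track_all=False):
    """EHH curves (both directions) for the haplotype sets in ``masks``.

    Returns (curves_left, curves_right, ok) where ok is False when the walk
    hit a chromosome edge or a > MAX_GAP_BP assembly gap before decaying
    below the cutoff.
    """
    chrom = panel.chrom[core]
    on_chrom = np.flatnonzero(panel.chrom == chrom)
    k = int(np.searchsorted(on_chrom, core))
    results = []
    for direction in ("left", "right"):
        order = on_chrom[:k][::-1] if direction == "left" else on_chrom[k + 1:]
        curves, decayed = _ehh_walk(panel.geno, order, masks,
                                    track_all=track_all)
        if not decayed:          # chromosome edge before the EHH cutoff
            return None, None, False
        m = len(curves[0]) if curves else 0
        idx = np.concatenate([[core], order[:m]]).astype(int)
        # gap rule: consecutive SNPs > MAX_GAP_BP apart
        gaps = np.abs(np.diff(panel.pos_bp[idx]))
        if (gaps > MAX_GAP_BP).any():
            return None, None, False
        pos = panel.pos_cM[idx]
        results.append([
            (pos, np.concatenate([[1.0], c])) for c in curves])
    return results[0], results[1], True


def _ihh_both(curve_pair):
    (pos_l, vals_l), (pos_r, vals_r) = curve_pair
    return _integrate_ihh(pos_l, vals_l) + _integrate_ihh(pos_r, vals_r)


def ihs(panel: HaplotypePanel, min_daf: float = 0.05,
        max_daf: float = 0.95, n_daf_bins: int = 50,
        standardize_order: str = "bins-then-chromosome",
        snps=None) -> list[CoreScore]:
    """Integrated haplotype score per SNP of a polarised, phased panel.

    Scores SNPs with derived-allele frequency in [min_daf, max_daf];
    unstandardised iHS = ln(iHH_ancestral / iHH_derived).  Standardisation:
    within ``n_daf_bins`` equal-width DAF bins, then a z-normalisation per
    chromosome (``standardize_order='chromosome-then-bins'`` swaps the two).
    SNPs whose EHH never decays below the cutoff before a chromosome edge or
    a > 200 kb gap are flagged unscored.
    """
    daf = panel.daf()
    which = range(panel.n_snps) if snps is None else np.atleast_1d(snps)
    scores: list[CoreScore] = []
    for j in which:
        sc = CoreScore(snp_id=panel.snp_ids[j], chrom=str(panel.chrom[j]),
                       pos_bp=int(panel.pos_bp[j]), daf=float(daf[j]))
        if not (min_daf <= daf[j] <= max_daf):
            sc.unscored_reason = "daf"
            scores.append(sc)
            continue
        derived = panel.geno[:, j] == 1
        ancestral = panel.geno[:, j] == 0
        if derived.sum() < 2 or ancestral.sum() < 2:
            sc.unscored_reason = "carriers"
            scores.append(sc)
            continue
        left, right, ok = _directional_curves(panel, j, [ancestral, derived])
        if not ok:
            sc.unscored_reason = "edge-or-gap"
            scores.append(sc)
            continue
        ihh_a = _ihh_both((left[0], right[0]))
        ihh_d = _ihh_both((left[1], right[1]))
        if ihh_a <= 0 or ihh_d <= 0:
            sc.unscored_reason = "zero-ihh"
            scores.append(sc)
            continue
        sc.ihh_a, sc.ihh_d = ihh_a, ihh_d
        sc.unstandardized = math.log(ihh_a / ihh_d)
        scores.append(sc)
    _standardize(scores, daf_bins=n_daf_bins, order=standardize_order)
    return scores


def _zscore(vals):
    mu = np.nanmean(vals)
    sd = np.nanstd(vals)
    return (vals - mu) / sd if sd > 0 else vals - mu


def _standardize(scores: list[CoreScore], daf_bins: int | None,
                 order: str = "bins-then-chromosome"):
    scored = [s for s in scores if not s.unscored_reason]
    if not scored:
        return
    vals = np.array([s.unstandardized for s in scored])

    def by_daf(v):
        bins = np.clip((np.array([s.daf for s in scored]) * daf_bins).astype(int),
                       0, daf_bins - 1)
        out = v.copy()
        for b in np.unique(bins):
            m = bins == b
            out[m] = _zscore(v[m])
        return out

    def by_chrom(v):
        chroms = np.array([s.chrom for s in scored])
        out = v.copy()
        for c in np.unique(chroms):
            m = chroms == c
            out[m] = _zscore(v[m])
        return out

    if daf_bins is None:
        vals = by_chrom(vals)
    elif order == "bins-then-chromosome":
        vals = by_chrom(by_daf(vals))
    elif order == "chromosome-then-bins":
        vals = by_daf(by_chrom(vals))
    else:
        raise ValueError(f"unknown standardize order {order!r}")
    for s, v in zip(scored, vals):
        s.standardized = float(v)


def xpehh(panel_focal: HaplotypePanel, panel_reference: HaplotypePanel,
          normalize: bool = True, snps=None) -> list[CoreScore]:
    """Cross-population EHH score per shared SNP.

    iHH is integrated over *all* haplotypes of each population (not
    allele-partitioned); the walk stops when the pooled two-population EHH
    drops below the cutoff; score = ln(iHH_focal / iHH_ref), z-normalised
    per chromosome when ``normalize``.
    """
    if panel_focal.n_snps != panel_reference.n_snps or \
            (panel_focal.pos_bp != panel_reference.pos_bp).any():
        raise ConfigError("panels must share their SNP set")
    merged = HaplotypePanel(
        hap_ids=panel_focal.hap_ids + panel_reference.hap_ids,
        pop_labels=(["focal"] * panel_focal.n_haps +
                    ["ref"] * panel_reference.n_haps),
        geno=np.vstack([panel_focal.geno, panel_reference.geno]),
        pos_bp=panel_focal.pos_bp, pos_cM=panel_focal.pos_cM,
        chrom=panel_focal.chrom, snp_ids=list(panel_focal.snp_ids))
    focal_mask = np.array([p == "focal" for p in merged.pop_labels])
    ref_mask = ~focal_mask
    daf = panel_focal.daf()
    which = range(merged.n_snps) if snps is None else np.atleast_1d(snps)
    scores: list[CoreScore] = []
    for j in which:
        sc = CoreScore(snp_id=merged.snp_ids[j], chrom=str(merged.chrom[j]),
                       pos_bp=int(merged.pos_bp[j]), daf=float(daf[j]))
        left, right, ok = _directional_curves(
            merged, j, [focal_mask, ref_mask], track_all=True)
        if not ok:
            sc.unscored_reason = "edge-or-gap"
            scores.append(sc)
            continue
        ihh_f = _ihh_both((left[0], right[0]))
        ihh_r = _ihh_both((left[1], right[1]))
        if ihh_r <= 0 or ihh_f <= 0:
            sc.unscored_reason = "zero-ihh"
            scores.append(sc)
            continue
        sc.ihh_a, sc.ihh_d = ihh_f, ihh_r       # focal, reference integrals
        sc.unstandardized = math.log(ihh_f / ihh_r)
        scores.append(sc)
    if normalize:
        _standardize(scores, daf_bins=None)
    else:
        for s in scores:
            if not s.unscored_reason:
                s.standardized = s.unstandardized
    return scores


# ---------------------------------------------------------------------------
# F_ST and d_i
# ---------------------------------------------------------------------------

def wc_fst(panel: HaplotypePanel, pop_a: str, pop_b: str,
           snps=None) -> np.ndarray:
    """Weir-Cockerham (1984) theta per SNP between two populations.

    Computed from haploid allele counts (r = 2 samples); monomorphic SNPs
    across both populations are NaN.  Negative estimates are retained.
    """
    idx = np.arange(panel.n_snps) if snps is None else np.atleast_1d(snps)
    out = np.full(len(idx), np.nan)
    masks = [np.array([p == pop for p in panel.pop_labels])
             for pop in (pop_a, pop_b)]
    g = panel.geno[:, idx]
    ns, ps = [], []
    for m in masks:
        sub = g[m]
        called = sub != -1
        n_i = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(sub == 1, 1, 0).sum(axis=0) / np.maximum(n_i, 1)
        ns.append(n_i)
        ps.append(p_i)
    n1, n2 = ns
    p1, p2 = ps
    valid = (n1 >= 2) & (n2 >= 2)
    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar)**2 + n2 * (p2 - p_bar)**2) / ((r - 1) * n_bar)
        # haploid data: no heterozygosity term (h_bar = 0)
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2)
                             / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2)
        theta = a / (a + b)
    poly = (p_bar > 0) & (p_bar < 1)
    out[valid & poly] = theta[valid & poly]
    return out


@dataclass
class DiScore:
    snp_id: str
    chrom: str
    pos_bp: int
    di: float
    n_pairs: int


def di_statistic(panel: HaplotypePanel, focal_pop: str,
                 snps=None) -> list[DiScore]:
    """Locus-specific differentiation d_i for ``focal_pop``.

    For each other population j, pairwise F_ST values are standardised by
    their genome-wide (all scored SNPs) mean and SD, and summed over j.
    SNPs with an undefined F_ST for some pair drop that pair from their sum.
    """
    pops = sorted(set(panel.pop_labels))
    if len(pops) < 3:
        raise ConfigError("d_i needs >= 3 populations")
    others = [p for p in pops if p != focal_pop]
    if len(others) == len(pops):
        raise ConfigError(f"unknown focal population {focal_pop!r}")
    idx = np.arange(panel.n_snps) if snps is None else np.atleast_1d(snps)
    z = np.zeros((len(others), len(idx)))
    defined = np.zeros_like(z, dtype=bool)
    for k, other in enumerate(others):
        fst = wc_fst(panel, focal_pop, other, snps=idx)
        ok = ~np.isnan(fst)
        mu, sd = np.nanmean(fst), np.nanstd(fst)
        if not np.isfinite(sd) or sd == 0:
            raise ConfigError(f"degenerate F_ST distribution for pair "
                              f"({focal_pop}, {other})")
        z[k, ok] = (fst[ok] - mu) / sd
        defined[k] = ok
    out = []
    for col, j in enumerate(idx):
        used = defined[:, col]
        out.append(DiScore(snp_id=panel.snp_ids[j], chrom=str(panel.chrom[j]),
                           pos_bp=int(panel.pos_bp[j]),
                           di=float(z[used, col].sum()),
                           n_pairs=int(used.sum())))
    return out


# ---------------------------------------------------------------------------
# Windows, bins, percentile ranks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowScore:
    chrom: str
    start: int                 # half-open [start, end)
    end: int
    n_snps: int
    bin: int
    value: float
    percentile_rank: float = math.nan


_SUMMARIES = {
    "max": lambda v: float(np.nanmax(v)),
    "mean": lambda v: float(np.nanmean(v)),
    "frac_gt2": lambda v: float(np.mean(np.abs(v[~np.isnan(v)]) > 2))
    if (~np.isnan(v)).any() else math.nan,
}


def _scores_frame(scores) -> pd.DataFrame:
    if isinstance(scores, pd.DataFrame):
        return scores
    rows = []
    for s in scores:
        val = getattr(s, "standardized", None)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            val = getattr(s, "di", math.nan)
        rows.append(dict(chrom=s.chrom, pos_bp=s.pos_bp, value=val))
    return pd.DataFrame(rows)


def windowize(scores, window_bp: int = 200_000, bin_size: int = 20,
              summary: str = "max") -> list[WindowScore]:
    """Non-overlapping windows from position 0 of each chromosome.

    ``scores``: CoreScore/DiScore list or a DataFrame with columns
    chrom, pos_bp, value.  Windows with zero SNPs are excluded; ``bin`` =
    floor(n_snps / bin_size); ``percentile_rank`` = fraction of same-bin
    windows (genome-wide) whose summary value is <= the window's own.
    """
    if summary not in _SUMMARIES:
        raise ValueError(f"summary must be one of {sorted(_SUMMARIES)}")
    df = _scores_frame(scores).dropna(subset=["value"])
    agg = _SUMMARIES[summary]
    windows: list[WindowScore] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        w = (sub["pos_bp"].to_numpy() // window_bp).astype(int)
        for widx in np.unique(w):
            vals = sub["value"].to_numpy()[w == widx]
            windows.append(WindowScore(
                chrom=str(chrom), start=int(widx) * window_bp,
                end=(int(widx) + 1) * window_bp, n_snps=len(vals),
                bin=len(vals) // bin_size, value=agg(vals)))
    return _attach_ranks(windows)


def _attach_ranks(windows: list[WindowScore]) -> list[WindowScore]:
    out = []
    by_bin: dict[int, list[float]] = {}
    for w in windows:
        by_bin.setdefault(w.bin, []).append(w.value)
    for w in windows:
        vals = np.asarray(by_bin[w.bin])
        rank = float((vals <= w.value).sum() / len(vals))
        out.append(WindowScore(chrom=w.chrom, start=w.start, end=w.end,
                               n_snps=w.n_snps, bin=w.bin, value=w.value,
                               percentile_rank=rank))
    return out


def focal_window(scores, chrom: str, center_bp: int,
                 window_bp: int = 200_000, bin_size: int = 20,
                 summary: str = "max") -> WindowScore:
    """Score + rank of the window re-centred on a focal gene's midpoint.

    The focal window [center - w/2, center + w/2) is summarised like any
    other window and ranked against the *anchored* genome-wide windows of
    the same SNP-count bin.
    """
    df = _scores_frame(scores).dropna(subset=["value"])
    genome = windowize(df, window_bp=window_bp, bin_size=bin_size,
                       summary=summary)
    start = int(center_bp - window_bp // 2)
    end = start + window_bp
    sub = df[(df["chrom"] == chrom) & (df["pos_bp"] >= start)
             & (df["pos_bp"] < end)]
    if sub.empty:
        raise ValueError("focal window contains no scored SNPs")
    value = _SUMMARIES[summary](sub["value"].to_numpy())
    b = len(sub) // bin_size
    same_bin = np.asarray([w.value for w in genome if w.bin == b])
    if same_bin.size == 0:
        rank = math.nan
    else:
        rank = float((same_bin <= value).sum() / same_bin.size)
    return WindowScore(chrom=str(chrom), start=start, end=end,
                       n_snps=len(sub), bin=b, value=value,
                       percentile_rank=rank)
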