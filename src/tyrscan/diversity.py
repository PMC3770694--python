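"""Nucleotide diversity, divergence, mutation-rate calibration and Ka/Ks.

Diversity is the mean number of pairwise nucleotide differences per site
(pi), optionally Jukes-Cantor corrected:  pi_JC = -(3/4) ln(1 - (4/3) pi).
Divergence between the sample consensus and an outgroup calibrates the local
per-generation mutation rate given a species split time and a generation
time:  mu = d * g / (2 T).  Coding constraint is summarised by the
Nei-Gojobori (1986) Ka/Ks with equal-weight minimal-pathway averaging and
Jukes-Cantor correction of the proportions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import FrameError, JCDomainError, SampleSizeError
from .io import Alignment, STANDARD_CODON_TABLE, VALID_BASES

__all__ = [
    "DiversityResult", "RateCalibration", "KaKsResult",
    "jc_correct", "nucleotide_diversity", "sliding_window_pi",
    "human_consensus", "jc_divergence", "calibrate_mutation_rate",
    "nei_gojobori_kaks",
]


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityResult:
    pi_raw: float
    pi_jc: float
    n_sites: int
    n_chroms: int
    region: str = ""
    window: tuple[int, int] | None = None   # half-open, rel-to-first-codon bp
    population: str = ""

    @property
    def missing(self) -> bool:
        return math.isnan(self.pi_raw)


@dataclass(frozen=True)
class RateCalibration:
    divergence_d: float
    T_split_years: float
    gen_time_years: float
    mu_per_site_per_gen: float


@dataclass(frozen=True)
class KaKsResult:
    Ka: float
    Ks: float
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float

    @property
    def ratio(self) -> float | None:
        """Ka/Ks; undefined (None) when Ks == 0."""
        if self.Ks <= 0:
            return None
        return self.Ka / self.Ks


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------

def jc_correct(p: float) -> float:
    """Jukes-Cantor distance from a raw proportion of differences."""
    if p < 0:
        raise ValueError("negative difference proportion")
    if p >= 0.75:
        raise JCDomainError(f"p={p} outside Jukes-Cantor domain [0, 3/4)")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _pairwise_diffs_per_column(seqs: np.ndarray) -> np.ndarray:
    """Per column: number of chromosome pairs that differ (complete data)."""
    n = seqs.shape[0]
    total_pairs = n * (n - 1) // 2
    same = np.zeros(seqs.shape[1], dtype=np.int64)
    for base in VALID_BASES:
        counts = (seqs == base).sum(axis=0)
        same += counts * (counts - 1) // 2
    return total_pairs - same


def nucleotide_diversity(aln: Alignment, columns=None, population=None,
                         region="") -> DiversityResult:
    """Mean pairwise differences per site over the analyzable columns.

    ``columns`` restricts the calculation (e.g. a region or a window); the
    complete-deletion mask is applied on top of it.
    """
    sub = aln.subset_samples(population=population) if population else aln
    n = sub.n_samples
    if n < 2:
        raise SampleSizeError("nucleotide diversity needs >= 2 chromosomes")
    mask = sub.analyzable
    if columns is not None:
        sel = np.zeros(sub.length, dtype=bool)
        sel[np.asarray(columns)] = True
        mask = mask & sel
    cols = np.flatnonzero(mask)
    if cols.size == 0:
        raise ValueError("no analyzable columns selected")
    diffs = _pairwise_diffs_per_column(sub.seqs[:, cols])
    total_pairs = n * (n - 1) / 2
    pi_raw = float(diffs.sum() / total_pairs / cols.size)
    return DiversityResult(pi_raw=pi_raw, pi_jc=jc_correct(pi_raw),
                           n_sites=int(cols.size), n_chroms=n, region=region,
                           population=population or "all")


def sliding_window_pi(aln: Alignment, window_bp=1500, step_bp=375,
                      by_population=False, min_sites=10) -> list[DiversityResult]:
    """Sliding-window pi profile anchored on relative-to-first-codon coordinates.

    Windows are half-open ``[start, start + window_bp)`` starting at the
    5'-most annotated column and advancing by ``step_bp``; the final partial
    window is reported with its actual site count.  Windows with fewer than
    ``min_sites`` analyzable columns are reported as missing (NaN pi).
    """
    if not (window_bp >= step_bp > 0):
        raise ValueError("need window >= step > 0")
    rel = aln.rel_pos
    pops = sorted(set(aln.pop_labels)) if by_population else [None]
    results: list[DiversityResult] = []
    start = int(rel[0])
    stop = int(rel[-1]) + 1
    for pop in pops:
        sub = aln.subset_samples(population=pop) if pop else aln
        mask = sub.analyzable
        for w0 in range(start, stop, step_bp):
            w1 = w0 + window_bp
            in_win = (rel >= w0) & (rel < w1)
            cols = np.flatnonzero(in_win & mask)
            if cols.size < min_sites:
                results.append(DiversityResult(
                    pi_raw=float("nan"), pi_jc=float("nan"),
                    n_sites=int(cols.size), n_chroms=sub.n_samples,
                    window=(w0, w1), population=pop or "all"))
                continue
            res = nucleotide_diversity(sub, columns=cols)
            results.append(DiversityResult(
                pi_raw=res.pi_raw, pi_jc=res.pi_jc, n_sites=res.n_sites,
                n_chroms=res.n_chroms, window=(w0, w1), population=pop or "all"))
            if w1 >= stop:
                break
    return results


# ---------------------------------------------------------------------------
# divergence and calibration
# ---------------------------------------------------------------------------

def human_consensus(aln: Alignment, columns=None) -> np.ndarray:
    """Column-wise majority allele over the sample rows.

    Frequency ties are broken toward the outgroup allele when the outgroup
    carries one of the tied alleles, otherwise alphabetically.
    """
    cols = np.arange(aln.length) if columns is None else np.asarray(columns)
    cons = np.empty(cols.size, dtype="U1")
    for k, col in enumerate(cols):
        alleles, counts = np.unique(aln.seqs[:, col], return_counts=True)
        best = counts.max()
        tied = sorted(alleles[counts == best])
        pick = tied[0]
        if len(tied) > 1 and aln.outgroup is not None \
                and aln.outgroup[col] in tied:
            pick = aln.outgroup[col]
        cons[k] = pick
    return cons


def jc_divergence(aln: Alignment, columns=None) -> float:
    """JC-corrected divergence between the sample consensus and the outgroup."""
    if aln.outgroup is None:
        raise ValueError("alignment has no outgroup")
    mask = aln.analyzable & np.isin(aln.outgroup, list(VALID_BASES))
    if columns is not None:
        sel = np.zeros(aln.length, dtype=bool)
        sel[np.asarray(columns)] = True
        mask &= sel
    cols = np.flatnonzero(mask)
    cons = human_consensus(aln, columns=cols)
    p = float((cons != aln.outgroup[cols]).mean())
    return jc_correct(p)


def calibrate_mutation_rate(divergence_d: float, T_split_years: float = 7e6,
                            gen_time_years: float = 29.0) -> RateCalibration:
    """Per-site per-generation mutation rate from interspecies divergence.

    The divergence ``d`` accrues along the two branches separating the
    species, i.e. over ``2 T / g`` generations, so ``mu = d g / (2 T)``.
    """
    if divergence_d < 0 or T_split_years <= 0 or gen_time_years <= 0:
        raise ValueError("divergence must be >= 0 and times > 0")
    mu = divergence_d * gen_time_years / (2.0 * T_split_years)
    return RateCalibration(divergence_d=divergence_d,
                           T_split_years=T_split_years,
                           gen_time_years=gen_time_years,
                           mu_per_site_per_gen=mu)


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986
# ---------------------------------------------------------------------------

def _codon_aa(codon: str, table) -> str:
    return table.forward_table.get(codon, "*")


def _syn_fraction(codon: str, table) -> np.ndarray:
    """Per position: fraction of the 3 possible changes that are synonymous.

    Changes producing stop codons count as nonsynonymous (standard NG86 site
    counting).
    """
    aa = _codon_aa(codon, table)
    frac = np.zeros(3)
    for i in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if _codon_aa(mut, table) == aa and aa != "*":
                syn += 1
        frac[i] = syn / 3.0
    return frac


def _pathway_counts(c1: str, c2: str, table) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over all minimal mutational pathways that avoid stop
    codons (all pathways used if every one passes through a stop)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            steps.append((cur, nxt))
            if _codon_aa(nxt, table) == "*" and nxt != c2:
                through_stop = True
            cur = nxt
        paths.append((through_stop, steps))
    usable = [steps for stop, steps in paths if not stop] or \
             [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if _codon_aa(a, table) == _codon_aa(b, table) \
                    and _codon_aa(a, table) != "*":
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def nei_gojobori_kaks(coding_seq_a: str, coding_seq_b: str,
                      codon_table=STANDARD_CODON_TABLE) -> KaKsResult:
    """NG86 Ka/Ks between two in-frame coding sequences.

    Synonymous/nonsynonymous site counts are averaged over the two
    sequences; differences are averaged over all minimal mutational pathways
    (stop-codon pathways excluded); the proportions ``pd`` are Jukes-Cantor
    corrected to rates.
    """
    a, b = coding_seq_a.upper(), coding_seq_b.upper()
    if len(a) != len(b):
        raise FrameError("sequences differ in length")
    if len(a) % 3:
        raise FrameError("length not divisible by 3")
    codons_a = [a[i:i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i:i + 3] for i in range(0, len(b), 3)]
    for name, codons in (("first", codons_a[:-1]), ("second", codons_b[:-1])):
        if any(_codon_aa(c, codon_table) == "*" for c in codons):
            raise FrameError(f"internal stop codon in {name} sequence")
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        s_a = _syn_fraction(ca, codon_table).sum()
        s_b = _syn_fraction(cb, codon_table).sum()
        S += (s_a + s_b) / 2.0
        N += 3.0 - (s_a + s_b) / 2.0
        sd, nd = _pathway_counts(ca, cb, codon_table)
        Sd += sd
        Nd += nd
    Ks = jc_correct(Sd / S) if S > 0 and Sd > 0 else 0.0
    Ka = jc_correct(Nd / N) if N > 0 and Nd > 0 else 0.0
    return KaKsResult(Ka=Ka, Ks=Ks, N_sites=N, S_sites=S, Nd=Nd, Sd=Sd)
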