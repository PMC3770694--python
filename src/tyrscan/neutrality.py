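"""Tajima's D with simulation-based significance, Bonferroni, and AMOVA.

Tajima's D contrasts two estimators of the population mutation parameter:
the mean pairwise difference (pi) and the segregating-site count scaled by
a1 = sum 1/i.  D = (pi - S/a1) / sqrt(e1 S + e2 S (S-1)) with the 1989
variance constants.  Significance is empirical, from two nulls:

* the equilibrium null — constant size, no recombination, conditioned on the
  observed S (mutations dropped proportionally to branch length), matching
  the classical fixed-S convention;
* the demography-aware null — the configurable coalescent with
  recombination (:mod:`tyrscan.coalsim`), with America and Oceania proxied
  by the Asian history.

Both report a two-sided empirical p = 2 min(P(D_sim <= D_obs),
P(D_sim >= D_obs)) capped at 1; with zero exceedances the value is reported
as an upper bound "< 2/n_sims".

AMOVA partitions pairwise nucleotide-difference variance among/within
subpopulations of one regional group; F_ST significance comes from label
permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coalsim import DemographicModel, simulate_fixed_s, simulate_neutral_sfs_stats
from .exceptions import SampleSizeError
from .io import Alignment, VALID_BASES

__all__ = [
    "TajimaResult", "EmpiricalP", "AmovaResult", "tajima_constants",
    "tajimas_d", "tajimas_d_from_counts", "empirical_p", "p_value_basic",
    "p_value_bestfit", "bonferroni", "amova_within",
]


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of the D variance for sample size ``n``."""
    if n < 2:
        raise SampleSizeError("Tajima constants need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


@dataclass(frozen=True)
class TajimaResult:
    D: float | None               # None when S == 0 (undefined, not zero)
    S: int
    pi_total: float               # mean pairwise differences per sequence
    n: int

    @property
    def defined(self) -> bool:
        return self.D is not None


def tajimas_d_from_counts(S: int, pi_total: float, n: int) -> TajimaResult:
    """D from precomputed S and pi (the workhorse for simulation nulls)."""
    if n < 4:
        raise SampleSizeError("Tajima's D needs n >= 4 chromosomes")
    if S == 0:
        return TajimaResult(D=None, S=0, pi_total=pi_total, n=n)
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    D = (pi_total - S / k["a1"]) / math.sqrt(var)
    return TajimaResult(D=D, S=S, pi_total=pi_total, n=n)


def _seg_stats_from_alignment(aln: Alignment, population=None):
    sub = aln.subset_samples(population=population) if population else aln
    n = sub.n_samples
    cols = np.flatnonzero(sub.analyzable)
    S = 0
    pi_sum = 0.0
    pairs = n * (n - 1) / 2
    n_multi = 0
    for col in cols:
        alleles, counts = np.unique(sub.seqs[:, col], return_counts=True)
        if len(alleles) < 2:
            continue
        if len(alleles) > 2:
            n_multi += 1          # excluded from S (biallelic framing)
            continue
        S += 1
        pi_sum += counts[0] * counts[1] / pairs
    if n_multi:
        import logging
        logging.getLogger(__name__).info(
            "tajimas_d: %d multiallelic columns excluded", n_multi)
    return S, pi_sum, n


def _seg_stats_from_geno(geno: np.ndarray):
    geno = np.asarray(geno)
    n = geno.shape[0]
    c = geno.sum(axis=0)
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    pairs = n * (n - 1) / 2
    pi = float((c[seg] * (n - c[seg])).sum() / pairs)
    return S, pi, n


def tajimas_d(geno_or_aln, population=None) -> TajimaResult:
    """Tajima's D for an :class:`Alignment` (optionally one population) or a
    0/1 haplotype matrix."""
    if isinstance(geno_or_aln, Alignment):
        S, pi, n = _seg_stats_from_alignment(geno_or_aln, population)
    else:
        S, pi, n = _seg_stats_from_geno(geno_or_aln)
    return tajimas_d_from_counts(S, pi, n)


# ---------------------------------------------------------------------------
# Empirical p-values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmpiricalP:
    """Two-sided empirical p-value; a bound when no simulated exceedance."""

    value: float
    n_sims: int
    is_upper_bound: bool = False

    def __str__(self):
        return (f"<{self.value:.1e}" if self.is_upper_bound
                else f"{self.value:.3g}")

    def __float__(self):
        return self.value


def empirical_p(observed: float, null: np.ndarray) -> EmpiricalP:
    """2 * min(lower tail, upper tail) over a simulated null sample."""
    null = np.asarray([d for d in null if d is not None and not math.isnan(d)])
    m = len(null)
    if m == 0:
        raise ValueError("empty null distribution")
    lo = int((null <= observed).sum())
    hi = int((null >= observed).sum())
    least = min(lo, hi)
    if least == 0:
        return EmpiricalP(value=2.0 / m, n_sims=m, is_upper_bound=True)
    return EmpiricalP(value=min(1.0, 2.0 * least / m), n_sims=m)


def p_value_basic(observed_D: float, n: int, S: int, n_sims: int = 10_000,
                  seed: int = 0) -> EmpiricalP:
    """Equilibrium fixed-S null: constant size, no recombination.

    Each replicate draws a standard coalescent genealogy for ``n``
    chromosomes and places exactly ``S`` mutations on it; D is recomputed on
    the replicate and the observed value is located in the simulated
    distribution (two-sided).
    """
    if observed_D is None:
        raise ValueError("observed D undefined (S = 0)")
    rng = np.random.default_rng(seed)
    null = np.empty(n_sims)
    for i in range(n_sims):
        rep = simulate_fixed_s(n, S, seed=int(rng.integers(1, 2**31 - 1)))
        res = tajimas_d(rep.geno)
        null[i] = res.D if res.defined else 0.0
    return empirical_p(observed_D, null)


def simulate_bestfit_null_d(model: DemographicModel, seq_len: float,
                            samples, n_sims: int, seed: int,
                            population: str | None = None) -> np.ndarray:
    """Simulated D distribution under the configured demography."""
    stats = simulate_neutral_sfs_stats(model, seq_len, seed, samples, n_sims,
                                       population=population)
    out = []
    for S, pi, n in stats:
        res = tajimas_d_from_counts(S, pi, n)
        if res.defined:
            out.append(res.D)
    return np.asarray(out)


def p_value_bestfit(observed_D: float, model: DemographicModel,
                    seq_len: float, samples, n_sims: int = 10_000,
                    seed: int = 0, population: str | None = None,
                    null: np.ndarray | None = None) -> EmpiricalP:
    """Demography-aware null with recombination (best-fit style model).

    ``samples`` maps simulated population name -> chromosome count and must
    include the population whose D is being tested (populations without a
    calibrated history are run under their proxy model, e.g. the Asian one).
    A precomputed ``null`` D sample may be supplied to amortise simulations
    across tests.
    """
    if observed_D is None:
        raise ValueError("observed D undefined (S = 0)")
    if isinstance(samples, dict):
        known = set(model.population_names)
        for p in samples:
            if p not in known:
                raise KeyError(f"model lacks sampled population {p!r}")
    if null is None:
        null = simulate_bestfit_null_d(model, seq_len, samples, n_sims, seed,
                                       population=population)
    return empirical_p(observed_D, null)


def bonferroni(p_values, n_tests: int = 6, alpha: float = 0.05):
    """Per-value flags at the raw and Bonferroni-corrected thresholds."""
    out = []
    for p in p_values:
        p = float(p)
        if not (0 < p <= 1):
            raise ValueError(f"p-value {p} outside (0, 1]")
        out.append(dict(p=p, significant_raw=p < alpha,
                        significant_bonferroni=p < alpha / n_tests))
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmovaResult:
    F_ST: float
    sigma2_among: float
    sigma2_within: float
    p_perm: float
    n_perms: int
    n_chroms: int
    n_subpops: int


def _distance_matrix(seqs: np.ndarray, analyzable: np.ndarray) -> np.ndarray:
    """Pairwise nucleotide-difference counts over analyzable columns."""
    cols = np.flatnonzero(analyzable)
    sub = seqs[:, cols]
    n = sub.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1:] = (sub[i + 1:] != sub[i]).sum(axis=1)
    return d + d.T


def _fst_from_distances(d: np.ndarray, labels: np.ndarray):
    """One-level AMOVA variance components from a matrix of pairwise
    nucleotide differences (Excoffier convention: SSD = sum d_ij / n)."""
    N = len(labels)
    groups = np.unique(labels)
    P = len(groups)
    iu = np.triu_indices(N, 1)
    ssd_total = d[iu].sum() / N
    ssd_within = 0.0
    sizes = []
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sizes.append(len(idx))
        if len(idx) > 1:
            sub = d[np.ix_(idx, idx)]
            ssd_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssd_among = ssd_total - ssd_within
    sizes = np.asarray(sizes, dtype=float)
    df_among, df_within = P - 1, N - P
    sigma_w = ssd_within / df_within if df_within > 0 else 0.0
    n_bar = (N - (sizes**2).sum() / N) / df_among
    sigma_a = (ssd_among / df_among - sigma_w) / n_bar
    denom = sigma_a + sigma_w
    fst = sigma_a / denom if denom > 0 else 0.0
    return fst, sigma_a, sigma_w


def amova_within(aln: Alignment, group: str | None, subpop_labels,
                 n_perms: int = 1000, seed: int = 0) -> AmovaResult:
    """Within-group AMOVA F_ST with permutation significance.

    ``group`` selects one regional group of the alignment (None = all rows);
    ``subpop_labels`` assigns each selected chromosome to a subpopulation.
    Subpopulations with fewer than 2 chromosomes are dropped with a warning.
    p = (1 + #{perm F_ST >= observed}) / (1 + n_perms).
    """
    sub = aln.subset_samples(population=group) if group else aln
    labels = np.asarray(list(subpop_labels), dtype=object)
    if len(labels) != sub.n_samples:
        raise ValueError("subpop_labels length must match selected chromosomes")
    keep = np.ones(len(labels), dtype=bool)
    for g in np.unique(labels):
        idx = labels == g
        if idx.sum() < 2:
            import logging
            logging.getLogger(__name__).warning(
                "amova: subpopulation %r has <2 chromosomes; dropped", g)
            keep &= ~idx
    labels = labels[keep]
    seq_idx = np.flatnonzero(keep)
    if len(np.unique(labels)) < 2:
        raise SampleSizeError("AMOVA needs >= 2 subpopulations of size >= 2")
    d = _distance_matrix(sub.seqs[seq_idx], sub.analyzable)
    fst, sa, sw = _fst_from_distances(d, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perms):
        perm = rng.permutation(labels)
        f, _, _ = _fst_from_distances(d, perm)
        if f >= fst:
            hits += 1
    p = (1 + hits) / (1 + n_perms)
    return AmovaResult(F_ST=fst, sigma2_among=sa, sigma2_within=sw,
                       p_perm=p, n_perms=n_perms, n_chroms=len(labels),
                       n_subpops=len(np.unique(labels)))
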