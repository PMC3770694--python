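"""Calibration and validation studies for the simulator and the scans.

Each function runs a self-contained Monte-Carlo study against an analytic
expectation or a statistical property (closed-form coalescent moments,
probability-integral-transform uniformity of empirical p-values, z-score
calibration of standardised iHS, detection power on sweep fixtures,
type-I error of the window/bin/percentile genome scan, exact-interval
coverage, the recombination lower bound) and returns a plain dict of the
quantities measured.  The test suite asserts on these dicts; the
acceptance script reports them.

Study sizes are chosen so each check completes in minutes on one core
while keeping its Monte-Carlo error band meaningful; the methods note
records the sizes and the rescaling argument for the sweep fixture.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from . import coalsim, haplonet, neutrality, selscan

__all__ = [
    "closed_form_neutral_checks", "fixed_s_bias_check",
    "bestfit_null_uniformity", "ihs_standardization_check",
    "sweep_power_study", "scan_type_i_error",
    "clopper_pearson_coverage", "rmin_bound_check",
]


# ---------------------------------------------------------------------------
# Coalescent closed forms
# ---------------------------------------------------------------------------

def closed_form_neutral_checks(seed: int = 1, n_reps: int = 2000,
                               N: float = 20_000, mu: float = 1e-7,
                               seq_len: float = 1_000, n: int = 10) -> dict:
    """E[pi] = theta, E[S] = theta a1(n), E[TMRCA] = 2(1 - 1/n) N.

    ``N`` is in chromosomes; theta = 2 N mu L is the per-locus pairwise
    expectation.  Returns means, expectations and standard errors.
    """
    rng = np.random.default_rng(seed)
    model = coalsim.DemographicModel.constant(N, mutation_rate=mu,
                                              recombination_rate=0.0)
    pis, Ss, ts = [], [], []
    for _ in range(n_reps):
        rep = coalsim.simulate_neutral(model, seq_len,
                                       seed=int(rng.integers(1, 2**31 - 1)),
                                       samples=n)
        pis.append(rep.pairwise_diversity())
        Ss.append(rep.n_sites)
        ts.append(rep.tmrca)
    theta = 2 * N * mu * seq_len
    a1 = sum(1.0 / i for i in range(1, n))
    out = dict(theta=theta, n_reps=n_reps)
    for key, vals, expect in (("pi", pis, theta), ("S", Ss, theta * a1),
                              ("tmrca", ts, 2 * (1 - 1 / n) * N)):
        vals = np.asarray(vals, dtype=float)
        out[f"mean_{key}"] = float(vals.mean())
        out[f"expected_{key}"] = float(expect)
        out[f"se_{key}"] = float(vals.std(ddof=1) / math.sqrt(n_reps))
    return out


def fixed_s_bias_check(seed: int = 2, n_reps: int = 10_000, n: int = 20,
                       S: int = 20) -> dict:
    """Mean Tajima's D under the equilibrium fixed-S null (slightly < 0)."""
    rng = np.random.default_rng(seed)
    ds = np.empty(n_reps)
    for i in range(n_reps):
        rep = coalsim.simulate_fixed_s(n, S,
                                       seed=int(rng.integers(1, 2**31 - 1)))
        ds[i] = neutrality.tajimas_d(rep.geno).D
    return dict(mean_D=float(ds.mean()),
                se_D=float(ds.std(ddof=1) / math.sqrt(n_reps)),
                n_reps=n_reps)


# ---------------------------------------------------------------------------
# Demography-aware null: probability integral transform
# ---------------------------------------------------------------------------

def bestfit_null_uniformity(seed: int = 3, n_null: int = 999,
                            n_obs: int = 200, seq_len: float = 5_000,
                            n_chroms: int = 32) -> dict:
    """p-values of null-drawn D against the null itself are ~ uniform."""
    model = coalsim.load_best_fit_model()
    samples = {"EUR": n_chroms}
    null = neutrality.simulate_bestfit_null_d(model, seq_len, samples,
                                              n_null, seed)
    obs = neutrality.simulate_bestfit_null_d(model, seq_len, samples,
                                             n_obs, seed + 1_000_003)
    ps = [neutrality.p_value_bestfit(d, model, seq_len, samples,
                                     null=null).value for d in obs]
    ks = stats.kstest(ps, "uniform")
    return dict(ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
                n_null=len(null), n_obs=len(obs))


# ---------------------------------------------------------------------------
# iHS standardisation
# ---------------------------------------------------------------------------

def ihs_standardization_check(seed: int = 4, seq_len: float = 5_000_000,
                              n_chroms: int = 120, min_bin: int = 50) -> dict:
    """Per-DAF-bin mean/SD of standardised iHS on a large neutral panel."""
    model = coalsim.DemographicModel.constant(
        20_000, mutation_rate=1e-8, recombination_rate=1e-8)
    rep = coalsim.simulate_neutral(model, seq_len, seed=seed,
                                   samples=n_chroms)
    panel = rep.to_panel(cm_per_mb=1.0)
    scores = selscan.ihs(panel)
    scored = [s for s in scores if not s.unscored_reason]
    vals = np.array([s.standardized for s in scored])
    bins = np.clip((np.array([s.daf for s in scored]) * 50).astype(int),
                   0, 49)
    bin_means, bin_sds = [], []
    for b in np.unique(bins):
        v = vals[bins == b]
        if len(v) >= min_bin:
            bin_means.append(float(v.mean()))
            bin_sds.append(float(v.std()))
    frac_gt2 = float((np.abs(vals) > 2).mean())
    return dict(n_scored=len(scored), n_bins=len(bin_means),
                max_abs_bin_mean=max(abs(m) for m in bin_means),
                max_abs_bin_sd_err=max(abs(s - 1) for s in bin_sds),
                frac_abs_gt2=frac_gt2)


# ---------------------------------------------------------------------------
# Sweep power
# ---------------------------------------------------------------------------

#: frozen study conditions for the rescaled sweep locus (see methods note)
SWEEP_CONDITIONS = dict(N=1000, s=0.05, start_freq=0.005, current_freq=0.7,
                        seq_len=1_200_000, mu=4e-8, r=1.5e-7, n=100)
SWEEP_CM_PER_MB = 15.0
SWEEP_T_SPLIT = 300.0


def _neutral_pair_model():
    c = SWEEP_CONDITIONS
    return coalsim.DemographicModel(
        populations=[{"name": "focal", "initial_size": 2 * c["N"]},
                     {"name": "ref", "initial_size": 2 * c["N"]}],
        events=[{"type": "split", "time": SWEEP_T_SPLIT,
                 "derived": ["focal", "ref"], "ancestral": "anc",
                 "ancestral_size": 2 * c["N"]}],
        mutation_rate=c["mu"], recombination_rate=c["r"])


def _daf_bin_z(bg: np.ndarray, daf: float, val: float) -> float:
    """Standardise against the neutral background within 0.1-wide DAF bins."""
    b = int(daf * 10)
    sel = bg[(bg[:, 0] * 10).astype(int) == b, 1]
    if len(sel) < 5:            # fall back to the matched frequency band
        sel = bg[:, 1]
    return (val - sel.mean()) / sel.std()


def sweep_power_study(seed: int = 5, n_reps: int = 50,
                      n_neutral: int = 50, daf_band=(0.55, 0.85)) -> dict:
    """Detection power of iHS and XP-EHH at a partially swept locus.

    Sweep replicates (selection in the focal population only) are scored at
    the swept SNP; thresholds are the 95th percentiles of the same scores
    at frequency-matched central SNPs of neutral two-population replicates.
    iHS is standardised against the neutral background within DAF bins, as
    in a genome scan.
    """
    c = SWEEP_CONDITIONS
    rng = np.random.default_rng(seed)
    model = _neutral_pair_model()

    bg, neut_xp = [], []
    for _ in range(n_neutral):
        rep = coalsim.simulate_neutral(
            model, c["seq_len"], seed=int(rng.integers(1, 2**31 - 1)),
            samples={"focal": c["n"], "ref": c["n"]})
        panel = rep.to_panel(cm_per_mb=SWEEP_CM_PER_MB)
        focal, ref = panel.subset_pop("focal"), panel.subset_pop("ref")
        daf = focal.daf()
        mid = np.argsort(np.abs(rep.positions - c["seq_len"] / 2))
        cand = [int(j) for j in mid
                if daf_band[0] <= daf[j] <= daf_band[1]][:8]
        for s in selscan.ihs(focal, snps=cand):
            if not s.unscored_reason:
                bg.append((s.daf, s.unstandardized))
        if cand:
            sx = selscan.xpehh(focal, ref, normalize=False,
                               snps=[cand[0]])[0]
            if not sx.unscored_reason:
                neut_xp.append(sx.standardized)
    bg = np.asarray(bg)
    neut_z = np.array([_daf_bin_z(bg, d, v) for d, v in bg])
    thr_ihs = float(np.percentile(np.abs(neut_z), 95))
    thr_xp = float(np.percentile(neut_xp, 95))

    hits_ihs = hits_xp = 0
    for _ in range(n_reps):
        rep = coalsim.simulate_sweep_pair(
            seed=int(rng.integers(1, 2**31 - 1)),
            t_split_gens=SWEEP_T_SPLIT, **c)
        panel = rep.to_panel(cm_per_mb=SWEEP_CM_PER_MB)
        focal, ref = panel.subset_pop("focal"), panel.subset_pop("ref")
        j = int(np.searchsorted(rep.positions, rep.swept_pos))
        si = selscan.ihs(focal, snps=[j])[0]
        if not si.unscored_reason and \
                abs(_daf_bin_z(bg, si.daf, si.unstandardized)) > thr_ihs:
            hits_ihs += 1
        sx = selscan.xpehh(focal, ref, normalize=False, snps=[j])[0]
        if not sx.unscored_reason and sx.standardized > thr_xp:
            hits_xp += 1
    return dict(power_ihs=hits_ihs / n_reps, power_xpehh=hits_xp / n_reps,
                threshold_ihs=thr_ihs, threshold_xpehh=thr_xp,
                n_reps=n_reps)


# ---------------------------------------------------------------------------
# Genome-scan type-I error
# ---------------------------------------------------------------------------

def scan_type_i_error(seed: int = 6, n_reps: int = 200,
                      genome_len: float = 20_000_000,
                      n_per_pop: int = 30) -> dict:
    """How often a neutral focal window exceeds the 95th-percentile rank.

    Each replicate genome: three island populations, d_i per SNP for the
    first population, mean-d_i summaries in 200-kb windows binned by 20
    SNPs; the focal window is re-centred mid-genome.  Under neutrality the
    focal window is exchangeable with its bin, so the exceedance rate
    should sit near 5%.
    """
    rng = np.random.default_rng(seed)
    model = coalsim.DemographicModel(
        populations=[{"name": p, "initial_size": 10_000}
                     for p in ("A", "B", "C")],
        migration=[["A", "B", 1e-4], ["B", "C", 1e-4], ["A", "C", 1e-4]],
        mutation_rate=1.5e-9, recombination_rate=1.5e-9)
    hits = 0
    for _ in range(n_reps):
        rep = coalsim.simulate_neutral(
            model, genome_len, seed=int(rng.integers(1, 2**31 - 1)),
            samples={"A": n_per_pop, "B": n_per_pop, "C": n_per_pop})
        panel = rep.to_panel()
        scores = selscan.di_statistic(panel, "A")
        fw = selscan.focal_window(scores, "1",
                                  center_bp=int(genome_len / 2 + 100_000),
                                  bin_size=20, summary="mean")
        if fw.percentile_rank > 0.95:
            hits += 1
    rate = hits / n_reps
    se = math.sqrt(0.05 * 0.95 / n_reps)
    return dict(rate=rate, n_reps=n_reps, expected=0.05,
                band=(0.05 - 2.58 * se, 0.05 + 2.58 * se))


# ---------------------------------------------------------------------------
# Clopper-Pearson coverage
# ---------------------------------------------------------------------------

def clopper_pearson_coverage(seed: int = 7, n_draws: int = 10_000,
                             p_grid=(0.01, 0.05, 0.1, 0.2, 0.3, 0.5),
                             n_grid=(20, 126, 600)) -> dict:
    """Empirical coverage of the exact interval over a p x n grid."""
    rng = np.random.default_rng(seed)
    min_cov, results = 1.0, {}
    for n in n_grid:
        bounds = np.array([haplonet.binomial_ci(k, n) for k in range(n + 1)])
        for p in p_grid:
            ks = rng.binomial(n, p, size=n_draws)
            covered = (bounds[ks, 0] <= p) & (p <= bounds[ks, 1])
            cov = float(covered.mean())
            results[f"p={p},n={n}"] = cov
            min_cov = min(min_cov, cov)
    return dict(min_coverage=min_cov, grid=results, n_draws=n_draws)


# ---------------------------------------------------------------------------
# Rmin lower bound
# ---------------------------------------------------------------------------

def rmin_bound_check(seed: int = 8, n_reps: int = 100) -> dict:
    """Rmin never exceeds the number of recombination events in the ARG."""
    rng = np.random.default_rng(seed)
    model = coalsim.DemographicModel.constant(
        10_000, mutation_rate=2e-7, recombination_rate=2e-8)
    violations = 0
    rmins, events = [], []
    for _ in range(n_reps):
        rep = coalsim.simulate_neutral(
            model, 10_000, seed=int(rng.integers(1, 2**31 - 1)),
            samples=12, record_full_arg=True)
        rmin, _ = haplonet.rmin_hudson_kaplan(rep.geno)
        rmins.append(rmin)
        events.append(rep.n_crossovers)
        if rmin > rep.n_crossovers:
            violations += 1
    return dict(violations=violations, n_reps=n_reps,
                mean_rmin=float(np.mean(rmins)),
                mean_true_events=float(np.mean(events)))
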