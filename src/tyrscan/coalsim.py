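"""Synthetic-data generators: coalescent and forward-in-time simulation.

Four generators cover every input the analyses consume:

* :func:`simulate_neutral` — Hudson-style neutral coalescent with
  recombination under a configurable demography (piecewise sizes, splits,
  bottlenecks, growth, migration), infinite-sites mutation.  This is the
  engine behind the demography-aware Tajima's D null.
* :func:`simulate_fixed_s` — equilibrium coalescent genealogies with exactly
  ``S`` mutations placed proportionally to branch length (the classical
  fixed-S neutrality null).
* :func:`simulate_sweep` — coalescent-initialised forward Wright-Fisher
  simulation with additive selection on one site, conditioned on the
  beneficial allele reaching a target frequency (selection-scan power
  fixtures).
* :func:`ascertain_array` — SNP-array emulation: density thinning, missing
  calls, call-rate and MAF ascertainment, uniform genetic map.

The neutral engine stands on msprime/tskit; the fixed-S and forward samplers
are implemented here because they condition on quantities (segregating-site
count, sweep trajectory) that a theta-parameterised coalescent does not
expose.  Same seed implies an identical replicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .exceptions import ConfigError
from .io import Alignment, HaplotypePanel, RegionInterval

try:  # msprime is a hard dependency, but keep the import local-failure honest
    import msprime
    import tskit
except ImportError as exc:  # pragma: no cover
    raise ImportError("tyrscan.coalsim requires msprime/tskit") from exc

__all__ = [
    "DemographicModel", "SimReplicate", "load_best_fit_model",
    "simulate_neutral", "simulate_fixed_s", "simulate_sweep",
    "ascertain_array",
]

NUCS = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Demographic model
# ---------------------------------------------------------------------------

@dataclass
class DemographicModel:
    """Piecewise population histories driving the neutral simulator.

    ``populations``: list of dicts ``{name, initial_size[, growth_rate]}``
    (sizes in haploid chromosomes; the simulator samples chromosomes, i.e.
    ploidy 1).  ``events`` (time in generations, backwards):

    * ``{"type": "split", "time", "derived": [...], "ancestral"}``
    * ``{"type": "size_change", "time", "population", "size"[, "growth_rate"]}``
    * ``{"type": "bottleneck", "time", "population", "size", "duration"}``
    * ``{"type": "migration_change", "time", "rate"[, "source", "dest"]}``

    ``migration``: list of ``[pop_a, pop_b, rate]`` (symmetric, per
    generation).  ``mutation_rate`` / ``recombination_rate`` are per site per
    generation.
    """

    populations: list[dict]
    events: list[dict] = field(default_factory=list)
    migration: list[list] = field(default_factory=list)
    mutation_rate: float = 3.0e-8
    recombination_rate: float = 1.0e-8
    generation_time: float = 29.0
    description: str = ""

    def __post_init__(self):
        names = [p["name"] for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate population names")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ConfigError("rates must be >= 0")
        times = [e.get("time", 0) for e in self.events]
        if any(t < 0 for t in times):
            raise ConfigError("event times must be >= 0")

    @property
    def population_names(self) -> list[str]:
        return [p["name"] for p in self.populations]

    # -- serialisation -----------------------------------------------------
    @classmethod
    def from_json(cls, path) -> "DemographicModel":
        cfg = json.loads(Path(path).read_text())
        return cls(**cfg)

    def to_json(self, path) -> None:
        cfg = dict(populations=self.populations, events=self.events,
                   migration=self.migration, mutation_rate=self.mutation_rate,
                   recombination_rate=self.recombination_rate,
                   generation_time=self.generation_time,
                   description=self.description)
        Path(path).write_text(json.dumps(cfg, indent=2))

    @classmethod
    def constant(cls, N: float, mutation_rate=3.0e-8, recombination_rate=0.0,
                 name="pop0") -> "DemographicModel":
        """Single constant-size population of ``N`` chromosomes."""
        return cls(populations=[{"name": name, "initial_size": N}],
                   mutation_rate=mutation_rate,
                   recombination_rate=recombination_rate)

    # -- msprime conversion -------------------------------------------------
    def to_demography(self) -> "msprime.Demography":
        dem = msprime.Demography()
        for p in self.populations:
            dem.add_population(name=p["name"],
                               initial_size=p["initial_size"],
                               growth_rate=p.get("growth_rate", 0.0))
        for a, b, rate in self.migration:
            dem.set_symmetric_migration_rate([a, b], rate)
        for ev in sorted(self.events, key=lambda e: e["time"]):
            kind = ev["type"]
            if kind == "split":
                # ancestral pop may be new
                if ev["ancestral"] not in [p.name for p in dem.populations]:
                    dem.add_population(name=ev["ancestral"],
                                       initial_size=ev.get("ancestral_size", 1e4))
                dem.add_population_split(time=ev["time"],
                                         derived=ev["derived"],
                                         ancestral=ev["ancestral"])
            elif kind == "size_change":
                dem.add_population_parameters_change(
                    time=ev["time"], population=ev["population"],
                    initial_size=ev["size"],
                    growth_rate=ev.get("growth_rate", 0.0))
            elif kind == "bottleneck":
                dem.add_population_parameters_change(
                    time=ev["time"], population=ev["population"],
                    initial_size=ev["size"], growth_rate=0.0)
                dem.add_population_parameters_change(
                    time=ev["time"] + ev["duration"],
                    population=ev["population"],
                    initial_size=ev["recovery_size"], growth_rate=0.0)
            elif kind == "migration_change":
                if "source" in ev:
                    dem.add_migration_rate_change(
                        time=ev["time"], rate=ev["rate"],
                        source=ev["source"], dest=ev["dest"])
                else:
                    dem.add_migration_rate_change(time=ev["time"],
                                                  rate=ev["rate"])
            else:
                raise ConfigError(f"unknown event type {kind!r}")
        dem.sort_events()
        return dem


def load_best_fit_model() -> DemographicModel:
    """The shipped out-of-Africa-style demography (editable JSON).

    Structure follows the classical calibrated human model: an African
    population, an out-of-Africa bottleneck, European and Asian daughter
    populations with their own bottlenecks and recent growth, and symmetric
    migration between extant populations.  Constants live in
    ``tyrscan/data/best_fit_demography.json`` so users can substitute
    published values.
    """
    with resources.files("tyrscan.data").joinpath(
            "best_fit_demography.json").open() as fh:
        return DemographicModel(**json.load(fh))


#: population used as demographic proxy when a sampled group has no
#: calibrated history of its own (America and Oceania -> Asian model).
PROXY_POPULATION = {
    "Africa": "AFR", "Europe": "EUR", "EastAsia": "ASIA",
    "SouthAsia": "ASIA", "Oceania": "ASIA", "America": "ASIA",
}


# ---------------------------------------------------------------------------
# Replicate container
# ---------------------------------------------------------------------------

@dataclass
class SimReplicate:
    """One simulated dataset: 0/1 haplotypes (0 = ancestral) plus summaries."""

    geno: np.ndarray              # (n_haps, n_sites) int8
    positions: np.ndarray         # integer bp, strictly increasing
    pop_labels: list[str]
    seq_len: float
    tmrca: float                  # generations
    n_crossovers: int
    seed: int
    swept_pos: int | None = None  # bp of the selected site, if any

    @property
    def n_haps(self) -> int:
        return self.geno.shape[0]

    @property
    def n_sites(self) -> int:
        return self.geno.shape[1]

    def pairwise_diversity(self) -> float:
        """Mean pairwise differences per sequence (sum over sites)."""
        n = self.n_haps
        if n < 2 or self.n_sites == 0:
            return 0.0
        c = self.geno.sum(axis=0)
        return float((c * (n - c)).sum() / (n * (n - 1) / 2))

    def to_panel(self, chrom="1", cm_per_mb=1.0) -> HaplotypePanel:
        """Panel view with a uniform genetic map of ``cm_per_mb``."""
        return HaplotypePanel(
            hap_ids=[f"hap{i}" for i in range(self.n_haps)],
            pop_labels=list(self.pop_labels),
            geno=self.geno.astype(np.int8),
            pos_bp=self.positions,
            pos_cM=self.positions * cm_per_mb * 1e-6,
            chrom=np.full(self.n_sites, chrom, dtype=object),
            snp_ids=[f"snp{i}" for i in range(self.n_sites)])

    def to_alignment(self, outgroup_row: np.ndarray | None = None,
                     seed: int | None = None,
                     regions: list[RegionInterval] | None = None) -> Alignment:
        """Nucleotide alignment view: random ref/alt bases per site.

        Only variable sites are materialised (positions are kept in the
        genomic coordinate of the simulated region); invariant sequence
        between SNPs carries no information for the statistics computed here
        and is omitted, so per-site denominators must use :attr:`seq_len`.
        """
        rng = np.random.default_rng(self.seed if seed is None else seed)
        anc = rng.choice(4, size=self.n_sites)
        shift = rng.integers(1, 4, size=self.n_sites)
        der = (anc + shift) % 4
        seqs = np.where(self.geno == 1, NUCS[der], NUCS[anc])
        out = None
        if outgroup_row is not None:
            out = np.where(outgroup_row == 1, NUCS[der], NUCS[anc])
        return Alignment(
            sample_ids=[f"hap{i}" for i in range(self.n_haps)],
            pop_labels=list(self.pop_labels),
            seqs=seqs, outgroup=out, outgroup_id="outgroup",
            genomic_start=1, regions=regions or [])


def _discretize_positions(raw: np.ndarray, seq_len: float,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Continuous -> integer bp (1-based), collisions re-drawn by nudging.

    Returns (positions, order) where ``order`` sorts the original sites.
    """
    order = np.argsort(raw, kind="stable")
    pos = np.floor(raw[order]).astype(np.int64) + 1
    L = max(int(seq_len), pos.size)
    for i in range(1, pos.size):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    if pos.size and pos[-1] > L:
        # fold overflow back by shifting the whole tail left
        excess = pos[-1] - L
        pos = np.maximum(pos - excess, np.arange(1, pos.size + 1))
    return pos, order


# ---------------------------------------------------------------------------
# Neutral coalescent (msprime engine)
# ---------------------------------------------------------------------------

def _ts_to_replicate(ts: "tskit.TreeSequence", seq_len, seed,
                     pop_names: dict[int, str], rng) -> SimReplicate:
    geno = ts.genotype_matrix().T.astype(np.int8)
    raw = np.array([s.position for s in ts.sites()])
    pos, order = _discretize_positions(raw, seq_len, rng)
    geno = geno[:, order]
    labels = [pop_names.get(ts.node(u).population, "pop0")
              for u in ts.samples()]
    return SimReplicate(
        geno=geno, positions=pos, pop_labels=labels, seq_len=seq_len,
        tmrca=float(ts.max_root_time), n_crossovers=int(ts.num_trees - 1),
        seed=int(seed))


def _check_coalescable(model: DemographicModel, sampled: list[str]) -> None:
    """Reject models whose sampled populations can never share an ancestor
    (no split lineage and no migration connecting them)."""
    parent: dict[str, str] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for a, b, rate in model.migration:
        if rate > 0:
            union(a, b)
    for ev in model.events:
        if ev["type"] == "split":
            for d in ev["derived"]:
                union(d, ev["ancestral"])
        elif ev["type"] == "migration_change" and ev.get("rate", 0) > 0:
            if "source" in ev:
                union(ev["source"], ev["dest"])
            else:
                for p in model.population_names:
                    union(p, model.population_names[0])
    roots = {find(p) for p in sampled}
    if len(roots) > 1:
        raise ConfigError(
            "sampled populations cannot coalesce: no migration or split "
            f"connects {sorted(sampled)}")


def simulate_neutral(model: DemographicModel, seq_len: float, seed: int,
                     samples: dict[str, int] | int | None = None,
                     record_full_arg: bool = False) -> SimReplicate:
    """One neutral replicate under ``model`` (infinite-sites, 0 = ancestral).

    ``samples`` maps population name -> number of chromosomes (an int means
    that many chromosomes from the first population).  ``record_full_arg``
    makes :attr:`SimReplicate.n_crossovers` the exact number of recombination
    events in the sample's ancestry instead of the breakpoint count.
    """
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = {model.population_names[0]: 10}
    elif isinstance(samples, int):
        samples = {model.population_names[0]: samples}
    _check_coalescable(model, list(samples))
    dem = model.to_demography()
    sample_sets = [msprime.SampleSet(n, population=p, ploidy=1)
                   for p, n in samples.items()]
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
    try:
        ts = msprime.sim_ancestry(
            samples=sample_sets, demography=dem, sequence_length=seq_len,
            recombination_rate=model.recombination_rate, ploidy=1,
            discrete_genome=False, random_seed=int(anc_seed),
            record_full_arg=record_full_arg)
    except Exception as exc:     # isolated lineages cannot find a common
        raise ConfigError(f"invalid demographic model: {exc}") from exc
    n_events = None
    if record_full_arg:
        flags = ts.tables.nodes.flags
        n_events = int((flags & msprime.NODE_IS_RE_EVENT).astype(bool).sum()) // 2
        ts = ts.simplify()
    ts = msprime.sim_mutations(
        ts, rate=model.mutation_rate, model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=int(mut_seed))
    pop_names = {i: p.name for i, p in enumerate(dem.populations)}
    rep = _ts_to_replicate(ts, seq_len, seed, pop_names, rng)
    if n_events is not None:
        rep.n_crossovers = n_events
    return rep


def simulate_neutral_sfs_stats(model: DemographicModel, seq_len: float,
                               seed: int, samples, n_reps: int,
                               population: str | None = None):
    """Fast path: (S, pi_total, n) per replicate for many neutral replicates.

    Uses msprime's replicate stream; statistics are computed on the tree
    sequence without materialising genotype matrices.  This backs the
    demography-aware Tajima's D null.
    """
    rng = np.random.default_rng(seed)
    if isinstance(samples, int):
        samples = {model.population_names[0]: samples}
    dem = model.to_demography()
    sample_sets = [msprime.SampleSet(n, population=p, ploidy=1)
                   for p, n in samples.items()]
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
    reps = msprime.sim_ancestry(
        samples=sample_sets, demography=dem, sequence_length=seq_len,
        recombination_rate=model.recombination_rate, ploidy=1,
        discrete_genome=False, random_seed=int(anc_seed),
        num_replicates=n_reps)
    out = []
    mut_rng = np.random.default_rng(mut_seed)
    pop_index = None
    for ts in reps:
        ts = msprime.sim_mutations(
            ts, rate=model.mutation_rate, model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(mut_rng.integers(1, 2**31 - 1)))
        if population is not None:
            if pop_index is None:
                pop_index = {p.metadata.get("name", str(p.id)): p.id
                             for p in ts.populations()}
            focal = ts.samples(population=pop_index[population])
        else:
            focal = ts.samples()
        n = len(focal)
        S = int(ts.segregating_sites(sample_sets=[focal],
                                     span_normalise=False)[0])
        pi = float(ts.diversity(sample_sets=[focal], span_normalise=False)[0])
        out.append((S, pi, n))
    return out


# ---------------------------------------------------------------------------
# Fixed-S equilibrium null (native Kingman sampler)
# ---------------------------------------------------------------------------

def _kingman_genealogy(n: int, rng):
    """Sample a standard n-coalescent: (intervals, membership).

    ``intervals``: list of (duration, lineage_ids alive) from the present
    back to the MRCA; ``members``: lineage id -> list of sample indices.
    """
    lineages = list(range(n))
    members = {i: [i] for i in range(n)}
    next_id = n
    intervals = []
    t = 0.0
    k = n
    while k > 1:
        rate = k * (k - 1) / 2.0
        dt = rng.exponential(1.0 / rate)
        intervals.append((dt, list(lineages)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        members[next_id] = members[a] + members[b]
        lineages = [x for x in lineages if x not in (a, b)] + [next_id]
        next_id += 1
        k -= 1
        t += dt
    return intervals, members, t


def simulate_fixed_s(n: int, S: int, seed: int) -> SimReplicate:
    """Equilibrium genealogy with exactly ``S`` mutations on its branches.

    Mutations are dropped with probability proportional to branch length
    (infinite sites, one column each); site positions are uniform on [0, 1)
    scaled to ``S`` bp for bookkeeping.  Time is in 2N-generations.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    intervals, members, tmrca = _kingman_genealogy(n, rng)
    durations = np.array([dt for dt, lin in intervals])
    ks = np.array([len(lin) for dt, lin in intervals])
    weights = durations * ks
    geno = np.zeros((n, S), dtype=np.int8)
    if S > 0 and weights.sum() > 0:
        which = rng.choice(len(intervals), size=S, p=weights / weights.sum())
        for s, idx in enumerate(which):
            lin = intervals[idx][1]
            carrier = lin[rng.integers(len(lin))]
            geno[members[carrier], s] = 1
    seq_len = max(S, 1)
    raw = rng.uniform(0, seq_len, size=S)
    pos, order = _discretize_positions(raw, seq_len, rng)
    return SimReplicate(geno=geno[:, order], positions=pos,
                        pop_labels=["pop0"] * n, seq_len=seq_len,
                        tmrca=tmrca, n_crossovers=0, seed=int(seed))


# ---------------------------------------------------------------------------
# Forward Wright-Fisher sweep
# ---------------------------------------------------------------------------

class SweepConvergenceError(ConfigError):
    """Beneficial allele failed to reach the target frequency."""

    def __init__(self, attempts):
        super().__init__(f"sweep conditioning failed after {attempts} attempts")
        self.attempts = attempts


def _recombine_rows(h1, h2, n_cross, positions, rng):
    """Mosaic of two haplotype rows with ``n_cross`` crossovers."""
    if n_cross == 0:
        return h1.copy() if rng.integers(2) == 0 else h2.copy()
    L = positions[-1] + 1 if positions.size else 1
    breaks = np.sort(rng.uniform(0, L, size=n_cross))
    seg = np.searchsorted(breaks, positions)     # segment index per site
    start_with_first = rng.integers(2) == 0
    take_first = (seg % 2 == 0) if start_with_first else (seg % 2 == 1)
    return np.where(take_first, h1, h2)


def simulate_sweep(N: int, s: float, start_freq: float, current_freq: float,
                   seq_len: float, mu: float, r: float, n: int, seed: int,
                   max_attempts: int = 200,
                   max_generations: int = 100_000) -> SimReplicate:
    """Forward Wright-Fisher diploid sweep, coalescent-initialised.

    The standing population of ``2N`` haplotypes starts from a neutral
    coalescent replicate of the same ``N``, ``mu`` and ``r`` (so linked
    diversity is at equilibrium without a forward burn-in).  One site near
    the region midpoint is made beneficial with genic selection (fitnesses
    1, 1+s, 1+2s); generations then run forward with per-haplotype Poisson
    recombination and infinite-sites mutation until the allele count reaches
    ``current_freq * 2N`` (success: sample ``n`` haplotypes) or the allele is
    lost (the attempt restarts).  ``s = 0`` is the neutral limit: the run is
    then conditioned only on the drift trajectory.
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    if not (0 <= start_freq < current_freq <= 1):
        raise ValueError("need 0 <= start_freq < current_freq <= 1")
    rng = np.random.default_rng(seed)
    twoN = 2 * N
    base_model = DemographicModel.constant(twoN, mutation_rate=mu,
                                           recombination_rate=r)
    target = max(int(round(current_freq * twoN)), 1)
    start_count = max(int(round(start_freq * twoN)), 1)

    total_cross = 0
    for attempt in range(1, max_attempts + 1):
        init = simulate_neutral(base_model, seq_len,
                                seed=int(rng.integers(1, 2**31 - 1)),
                                samples=twoN)
        geno = init.geno.astype(np.int8)
        positions = init.positions.astype(np.int64)
        # selected site: existing site closest to the target start frequency
        # near the midpoint, else a fresh column at the midpoint
        counts = geno.sum(axis=0)
        candidates = np.flatnonzero(
            np.abs(counts - start_count) <= max(1, int(0.2 * start_count)))
        if candidates.size:
            mid = seq_len / 2.0
            sel_idx = candidates[np.argmin(np.abs(positions[candidates] - mid))]
        else:
            col = np.zeros((twoN, 1), dtype=np.int8)
            col[rng.choice(twoN, size=start_count, replace=False), 0] = 1
            insert_pos = int(seq_len // 2)
            at = int(np.searchsorted(positions, insert_pos))
            geno = np.concatenate([geno[:, :at], col, geno[:, at:]], axis=1)
            positions = np.concatenate(
                [positions[:at], [insert_pos], positions[at:]])
            sel_idx = at
        sel_pos = int(positions[sel_idx])

        ok, geno, positions, cross = _run_forward(
            geno, positions, sel_pos, N, s, target, seq_len, mu, r,
            rng, max_generations)
        total_cross += cross
        if ok:
            order = np.argsort(positions)
            geno, positions = geno[:, order], positions[order]
            pick = rng.choice(twoN, size=n, replace=False)
            sample = geno[pick]
            seg = (sample.sum(axis=0) % sample.shape[0]) != 0
            seg |= positions == sel_pos          # keep the swept column
            sample = sample[:, seg]
            positions = positions[seg]
            return SimReplicate(
                geno=sample, positions=positions, pop_labels=["pop0"] * n,
                seq_len=seq_len, tmrca=float("nan"),
                n_crossovers=total_cross, seed=int(seed), swept_pos=sel_pos)
    raise SweepConvergenceError(max_attempts)


def simulate_sweep_pair(N: int, s: float, start_freq: float,
                        current_freq: float, seq_len: float, mu: float,
                        r: float, n: int, seed: int,
                        t_split_gens: float | None = None,
                        max_attempts: int = 200,
                        max_generations: int = 100_000) -> SimReplicate:
    """Sweep in a focal population with a neutral sister population.

    Both populations (``2N`` haplotypes each) are initialised from one
    two-population coalescent replicate (split ``t_split_gens`` ago, default
    ``N``), so they share a SNP coordinate set — the input XP-EHH needs.
    Selection acts only in the focal population; the run is conditioned on
    the focal beneficial-allele frequency reaching ``current_freq``.
    Returns ``n`` haplotypes from each population, labelled 'focal'/'ref'.
    """
    if not (0 <= start_freq < current_freq <= 1):
        raise ValueError("need 0 <= start_freq < current_freq <= 1")
    rng = np.random.default_rng(seed)
    twoN = 2 * N
    t_split = N if t_split_gens is None else t_split_gens
    model = DemographicModel(
        populations=[{"name": "focal", "initial_size": twoN},
                     {"name": "ref", "initial_size": twoN}],
        events=[{"type": "split", "time": t_split,
                 "derived": ["focal", "ref"], "ancestral": "anc",
                 "ancestral_size": twoN}],
        mutation_rate=mu, recombination_rate=r)
    target = max(int(round(current_freq * twoN)), 1)
    start_count = max(int(round(start_freq * twoN)), 1)
    total_cross = 0
    for attempt in range(1, max_attempts + 1):
        init = simulate_neutral(model, seq_len,
                                seed=int(rng.integers(1, 2**31 - 1)),
                                samples={"focal": twoN, "ref": twoN})
        focal_rows = np.array([lab == "focal" for lab in init.pop_labels])
        order = np.argsort(~focal_rows, kind="stable")  # focal block first
        geno = init.geno[order].astype(np.int8)
        positions = init.positions.astype(np.int64)
        counts = geno[:twoN].sum(axis=0)
        candidates = np.flatnonzero(
            (counts > 0)
            & (np.abs(counts - start_count) <= max(1, int(0.2 * start_count))))
        if candidates.size:
            mid = seq_len / 2.0
            sel_idx = candidates[np.argmin(np.abs(positions[candidates] - mid))]
        else:
            col = np.zeros((2 * twoN, 1), dtype=np.int8)
            col[rng.choice(twoN, size=start_count, replace=False), 0] = 1
            insert_pos = int(seq_len // 2)
            at = int(np.searchsorted(positions, insert_pos))
            geno = np.concatenate([geno[:, :at], col, geno[:, at:]], axis=1)
            positions = np.concatenate(
                [positions[:at], [insert_pos], positions[at:]])
            sel_idx = at
        sel_pos = int(positions[sel_idx])
        ok, geno, positions, cross = _run_forward(
            geno, positions, sel_pos, N, s, target, seq_len, mu, r,
            rng, max_generations, pop_slices=[slice(0, twoN),
                                              slice(twoN, 2 * twoN)],
            sel_pops=(0,))
        total_cross += cross
        if ok:
            order = np.argsort(positions)
            geno, positions = geno[:, order], positions[order]
            pick_f = rng.choice(twoN, size=n, replace=False)
            pick_r = twoN + rng.choice(twoN, size=n, replace=False)
            sample = geno[np.concatenate([pick_f, pick_r])]
            c = sample.sum(axis=0)
            seg = (c > 0) & (c < sample.shape[0])
            seg |= positions == sel_pos
            return SimReplicate(
                geno=sample[:, seg], positions=positions[seg],
                pop_labels=["focal"] * n + ["ref"] * n, seq_len=seq_len,
                tmrca=float("nan"), n_crossovers=total_cross,
                seed=int(seed), swept_pos=sel_pos)
    raise SweepConvergenceError(max_attempts)


def _run_forward(geno, positions, sel_pos, N, s, target, seq_len, mu, r,
                 rng, max_generations, pop_slices=None, sel_pops=None):
    """Advance the population(s) until the selected allele hits ``target``
    (in the selected population) or is lost there.

    ``pop_slices`` partitions the rows into independently mating
    populations; ``sel_pops`` indexes the slices under selection (default:
    the single whole-matrix population).
    """
    twoN_total = geno.shape[0]
    if pop_slices is None:
        pop_slices = [slice(0, twoN_total)]
    if sel_pops is None:
        sel_pops = (0,)
    exp_cross = r * seq_len
    exp_mut = mu * seq_len
    n_cross_total = 0
    sel_rows = np.zeros(twoN_total, dtype=bool)
    for k in sel_pops:
        sel_rows[pop_slices[k]] = True
    for gen in range(max_generations):
        sel_idx = int(np.flatnonzero(positions == sel_pos)[0])
        count = int(geno[sel_rows, sel_idx].sum())
        if count == 0:
            return False, geno, positions, n_cross_total
        if count >= target:
            return True, geno, positions, n_cross_total
        new = np.empty_like(geno)
        for k, sl in enumerate(pop_slices):
            sub = geno[sl]
            twoN = sub.shape[0]
            n_dip = twoN // 2
            pairs = rng.permutation(twoN).reshape(n_dip, 2)
            if k in sel_pops and s > 0:
                g_dip = sub[pairs[:, 0], sel_idx] + sub[pairs[:, 1], sel_idx]
                w = 1.0 + s * g_dip          # genic selection: 1, 1+s, 1+2s
                cdf = np.cumsum(w / w.sum())
                parent_dip = np.searchsorted(cdf, rng.random(twoN))
            else:
                parent_dip = rng.integers(n_dip, size=twoN)
            n_cross = rng.poisson(exp_cross, size=twoN)
            n_cross_total += int(n_cross.sum())
            pick = rng.integers(2, size=twoN)
            src = pairs[parent_dip, pick]
            offspring = sub[src]             # non-recombinant gametes
            one = np.flatnonzero(n_cross == 1)
            if one.size:                     # vectorised single-crossover path
                h1 = sub[pairs[parent_dip[one], 0]]
                h2 = sub[pairs[parent_dip[one], 1]]
                breaks = rng.uniform(0, seq_len, size=one.size)
                flip = rng.integers(2, size=one.size).astype(bool)
                left = positions[None, :] < breaks[:, None]
                take_h1 = left ^ flip[:, None]
                offspring[one] = np.where(take_h1, h1, h2)
            for i in np.flatnonzero(n_cross > 1):
                h1 = sub[pairs[parent_dip[i], 0]]
                h2 = sub[pairs[parent_dip[i], 1]]
                offspring[i] = _recombine_rows(h1, h2, int(n_cross[i]),
                                               positions, rng)
            new[sl] = offspring
        geno = new
        # new mutations (infinite sites)
        n_mut = rng.poisson(exp_mut * twoN_total)
        if n_mut:
            mut_pos = rng.integers(1, int(seq_len) + 1, size=n_mut)
            mut_pos = np.setdiff1d(np.unique(mut_pos), positions)
            if mut_pos.size:
                cols = np.zeros((twoN_total, mut_pos.size), dtype=np.int8)
                cols[rng.integers(twoN_total, size=mut_pos.size),
                     np.arange(mut_pos.size)] = 1
                # columns stay unsorted during the forward phase; the
                # recombination masks only need the breakpoint ordering
                geno = np.concatenate([geno, cols], axis=1)
                positions = np.concatenate([positions, mut_pos])
        # prune fixed/lost neutral columns every few generations
        if gen % 10 == 9:
            counts = geno.sum(axis=0)
            keep = (counts > 0) & (counts < twoN_total)
            keep |= positions == sel_pos
            geno = geno[:, keep]
            positions = positions[keep]
    return False, geno, positions, n_cross_total


# ---------------------------------------------------------------------------
# Array ascertainment
# ---------------------------------------------------------------------------

def ascertain_array(replicate: SimReplicate, maf_min: float = 0.05,
                    call_rate_noise: float = 0.0, seed: int = 0,
                    target_density: float | None = None,
                    min_call_rate: float = 0.95,
                    cm_per_mb: float = 1.0, chrom: str = "1") -> HaplotypePanel:
    """SNP-array emulation on a simulated genome.

    Thins sites to roughly ``target_density`` SNPs/bp (None keeps all),
    injects per-call missingness at rate ``call_rate_noise`` *before*
    filtering, then applies the array QC filters (call rate >=
    ``min_call_rate``, MAF strictly over ``maf_min``).  Emits a panel with a
    uniform genetic map.
    """
    rng = np.random.default_rng(seed)
    geno = replicate.geno.astype(np.int8).copy()
    pos = replicate.positions.copy()
    if target_density is not None and geno.shape[1] > 0:
        want = int(target_density * replicate.seq_len)
        if want < geno.shape[1]:
            keep = np.sort(rng.choice(geno.shape[1], size=want, replace=False))
            geno, pos = geno[:, keep], pos[keep]
    if call_rate_noise > 0:
        miss = rng.random(geno.shape) < call_rate_noise
        geno = np.where(miss, -1, geno).astype(np.int8)
    panel = HaplotypePanel(
        hap_ids=[f"hap{i}" for i in range(geno.shape[0])],
        pop_labels=list(replicate.pop_labels), geno=geno, pos_bp=pos,
        pos_cM=pos * cm_per_mb * 1e-6,
        chrom=np.full(pos.size, chrom, dtype=object))
    from .io import filter_panel
    report = filter_panel(panel, min_call_rate=min_call_rate, min_maf=maf_min)
    if report.panel.n_snps == 0:
        import logging
        logging.getLogger(__name__).warning("ascertainment emptied the panel")
    return report.panel
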