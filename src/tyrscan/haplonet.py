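"""Linkage structure, median-joining networks, rho dating and haplogroups.

The network pipeline mirrors the classical mtDNA-style workflow applied to
autosomal haplotype blocks: pairwise D'/r2 from phased haplotypes, Gabriel
confidence-interval haplotype blocks, a Bandelt median-joining network of
the block haplotypes rooted by an outgroup, and coalescent ages from the
rho statistic (mean mutational distance from a root node to the sampled
chromosomes) with the Saillard standard deviation:

    rho   = sum_tips m_t * d(root, t) / sum_tips m_t
    sigma = sqrt( sum_branches n_b^2 * l_b ) / n
    age   = rho / (mu_site * L) * generation_time

Also here: the Hudson-Kaplan four-gamete lower bound on recombination
events, hierarchical haplogroup-motif assignment and exact Clopper-Pearson
frequency confidence intervals.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .io import HaplotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "LdMatrix", "ld_pairwise", "find_blocks", "median_joining",
    "attach_outgroup", "RhoAge", "rho_age", "rmin_hudson_kaplan",
    "assign_haplogroups", "binomial_ci",
]


# ---------------------------------------------------------------------------
# Pairwise LD
# ---------------------------------------------------------------------------

@dataclass
class LdMatrix:
    snp_indices: np.ndarray
    pos_bp: np.ndarray
    dprime: np.ndarray           # (m, m), NaN on the diagonal/undefined
    r2: np.ndarray
    counts: dict = field(default_factory=dict)  # (i, j) -> 2x2 table


def _two_locus_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray | None:
    ok = (a != -1) & (b != -1)
    if not ok.any():
        return None
    a, b = a[ok], b[ok]
    t = np.zeros((2, 2))
    for x in (0, 1):
        for y in (0, 1):
            t[x, y] = np.sum((a == x) & (b == y))
    return t


def _d_stats(t: np.ndarray):
    n = t.sum()
    pa = (t[1, 0] + t[1, 1]) / n
    pb = (t[0, 1] + t[1, 1]) / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None
    d = t[1, 1] / n - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = d / dmax if dmax > 0 else 0.0
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return d, dprime, r2


def ld_pairwise(panel: HaplotypePanel, snp_subset=None) -> LdMatrix:
    """D' and r2 for every SNP pair from directly counted haplotypes.

    Monomorphic SNPs give undefined (NaN) entries.
    """
    idx = (np.arange(panel.n_snps) if snp_subset is None
           else np.atleast_1d(snp_subset))
    m = len(idx)
    dp = np.full((m, m), np.nan)
    r2 = np.full((m, m), np.nan)
    counts = {}
    for i, j in itertools.combinations(range(m), 2):
        t = _two_locus_counts(panel.geno[:, idx[i]], panel.geno[:, idx[j]])
        if t is None:
            continue
        res = _d_stats(t)
        if res is None:
            continue
        _, dprime, rr = res
        dp[i, j] = dp[j, i] = dprime
        r2[i, j] = r2[j, i] = rr
        counts[(i, j)] = t
    return LdMatrix(snp_indices=np.asarray(idx), pos_bp=panel.pos_bp[idx],
                    dprime=dp, r2=r2, counts=counts)


# ---------------------------------------------------------------------------
# Gabriel blocks
# ---------------------------------------------------------------------------

def _dprime_ci(t: np.ndarray, grid_step=0.005):
    """Likelihood-profile 90% bounds (5th/95th) on |D'| from a 2x2 table.

    Allele frequencies are held at their MLEs; the likelihood is profiled
    over |D'| with the sign of D fixed at the observed sign (the Haploview
    convention).
    """
    n = t.sum()
    pa = (t[1, 0] + t[1, 1]) / n
    pb = (t[0, 1] + t[1, 1]) / n
    d_obs = t[1, 1] / n - pa * pb
    sign = 1.0 if d_obs >= 0 else -1.0
    if sign > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax <= 0:
        return 0.0, 0.0
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    ll = np.empty_like(grid)
    for k, dp in enumerate(grid):
        d = sign * dp * dmax
        p = np.array([
            [(1 - pa) * (1 - pb) + d, (1 - pa) * pb - d],
            [pa * (1 - pb) - d, pa * pb + d],
        ])
        p = np.clip(p, 1e-12, None)
        ll[k] = (t * np.log(p)).sum()
    like = np.exp(ll - ll.max())
    cum = np.cumsum(like) / like.sum()
    lo = grid[int(np.searchsorted(cum, 0.05))]
    hi = grid[min(int(np.searchsorted(cum, 0.95)), len(grid) - 1)]
    return float(lo), float(hi)


def _classify_pairs(panel, idx, strong_low=0.70, strong_high=0.98,
                    recomb_high=0.90):
    """Pair classification: +1 strong LD, -1 strong recombination, 0 neither."""
    m = len(idx)
    cls = np.zeros((m, m), dtype=int)
    for i, j in itertools.combinations(range(m), 2):
        t = _two_locus_counts(panel.geno[:, idx[i]], panel.geno[:, idx[j]])
        if t is None or _d_stats(t) is None:
            continue
        lo, hi = _dprime_ci(t)
        if lo >= strong_low and hi >= strong_high:
            cls[i, j] = cls[j, i] = 1
        elif hi < recomb_high:
            cls[i, j] = cls[j, i] = -1
    return cls


def find_blocks(panel: HaplotypePanel, maf_min=0.05,
                min_strong_fraction=0.95) -> list[tuple[int, int]]:
    """Gabriel-style haplotype blocks (pairs of SNP indices, inclusive).

    Only SNPs with MAF >= ``maf_min`` are considered.  A candidate block
    requires its outermost pair in strong LD (90% |D'| bounds >= 0.70 and
    >= 0.98) and >= ``min_strong_fraction`` of its informative pairs in
    strong LD; candidates are accepted longest-first without overlap.
    Returned indices refer to the original panel SNPs.
    """
    idx = np.flatnonzero(np.nan_to_num(panel.maf(), nan=0.0) >= maf_min)
    if len(idx) < 2:
        return []
    cls = _classify_pairs(panel, idx)
    m = len(idx)
    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if cls[i, j] != 1:
                continue
            block = cls[i:j + 1, i:j + 1]
            iu = np.triu_indices(j - i + 1, 1)
            informative = block[iu] != 0
            if informative.sum() == 0:
                continue
            frac = (block[iu] == 1).sum() / informative.sum()
            if frac >= min_strong_fraction:
                span = panel.pos_bp[idx[j]] - panel.pos_bp[idx[i]]
                candidates.append((span, i, j))
    candidates.sort(reverse=True)
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for _, i, j in candidates:
        if taken[i:j + 1].any():
            continue
        taken[i:j + 1] = True
        blocks.append((int(idx[i]), int(idx[j])))
    return sorted(blocks)


# ---------------------------------------------------------------------------
# Median-joining network
# ---------------------------------------------------------------------------

def _hamming(a, b, weights):
    return float(np.sum(weights * (np.asarray(a) != np.asarray(b))))


def _minimax_distances(nodes, dist):
    """Minimax path weight between all node pairs via the MST (Kruskal)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    for i, j in itertools.combinations(range(len(nodes)), 2):
        g.add_edge(i, j, weight=dist[i, j])
    mst = nx.minimum_spanning_tree(g)
    minimax = np.zeros_like(dist)
    for i in range(len(nodes)):
        # max edge weight along MST paths from i
        lengths = {}
        for j, path in nx.single_source_dijkstra_path(mst, i).items():
            if len(path) < 2:
                lengths[j] = 0.0
            else:
                lengths[j] = max(mst[u][v]["weight"]
                                 for u, v in zip(path, path[1:]))
        for j, w in lengths.items():
            minimax[i, j] = w
    return minimax


def _msn_edges(dist, epsilon):
    """Edges of the (epsilon-relaxed) minimum spanning network."""
    n = dist.shape[0]
    minimax = _minimax_distances(range(n), dist)
    edges = []
    for i, j in itertools.combinations(range(n), 2):
        if dist[i, j] <= minimax[i, j] + epsilon + 1e-9:
            edges.append((i, j))
    return edges


def median_joining(haplotypes, multiplicities=None, pops=None,
                   site_ids=None, weights=None, epsilon=0) -> nx.Graph:
    """Bandelt median-joining network of aligned haplotypes.

    ``haplotypes``: (n, m) array of small-integer character states (binary
    0/1 for SNP data).  Duplicate rows are collapsed into one node with
    summed multiplicity.  The algorithm alternates minimum-spanning-network
    construction with quasi-median insertion for connected triplets whose
    connection cost is within ``epsilon`` of the minimum, until stable;
    median vectors that end up unsampled with degree <= 2 are pruned (their
    through-edges are merged).  Ties are broken by lexicographic haplotype
    order so the network is reproducible.

    Node attributes: ``hap`` (tuple), ``kind`` ('sampled'/'median'),
    ``multiplicity``, ``pops`` (dict).  Edge attribute ``sites`` lists the
    mutated site identifiers, ``weight`` their (weighted) count.
    """
    H = np.asarray(haplotypes)
    if H.ndim != 2:
        raise ValueError("haplotypes must be 2-D")
    n, m = H.shape
    weights = np.ones(m) if weights is None else np.asarray(weights, float)
    site_ids = list(range(m)) if site_ids is None else list(site_ids)
    multiplicities = (np.ones(n, dtype=int) if multiplicities is None
                      else np.asarray(multiplicities))
    pops = ["all"] * n if pops is None else list(pops)

    # collapse duplicates; warn about duplicate (fully linked) columns
    for j, k in itertools.combinations(range(m), 2):
        if np.array_equal(H[:, j], H[:, k]) or \
                np.array_equal(H[:, j], 1 - H[:, k] if H.max() <= 1 else H[:, k]):
            logger.warning("median_joining: columns %s and %s are duplicates "
                           "(r2=1); consider collapsing them first",
                           site_ids[j], site_ids[k])
            break

    uniq: dict[tuple, dict] = {}
    for row, mult, pop in zip(H, multiplicities, pops):
        key = tuple(int(x) for x in row)
        rec = uniq.setdefault(key, {"multiplicity": 0, "pops": {}})
        rec["multiplicity"] += int(mult)
        rec["pops"][pop] = rec["pops"].get(pop, 0) + int(mult)

    sampled = sorted(uniq)          # lexicographic: deterministic order
    nodes: list[tuple] = list(sampled)
    node_set = set(nodes)

    def dmat():
        k = len(nodes)
        d = np.zeros((k, k))
        for i, j in itertools.combinations(range(k), 2):
            d[i, j] = d[j, i] = _hamming(nodes[i], nodes[j], weights)
        return d

    for _ in range(200):            # safety bound on iterations
        d = dmat()
        edges = _msn_edges(d, epsilon)
        adj: dict[int, set] = {i: set() for i in range(len(nodes))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        # candidate quasi-medians for linked triplets u - v - w
        cands = {}
        for v in range(len(nodes)):
            for u, w in itertools.combinations(sorted(adj[v]), 2):
                med = tuple(_majority(nodes[u][s], nodes[v][s], nodes[w][s])
                            for s in range(m))
                if med in node_set:
                    continue
                cost = (_hamming(med, nodes[u], weights)
                        + _hamming(med, nodes[v], weights)
                        + _hamming(med, nodes[w], weights))
                if med not in cands or cost < cands[med]:
                    cands[med] = cost
        if not cands:
            break
        lam = min(cands.values())
        new = sorted(med for med, c in cands.items()
                     if c <= lam + epsilon + 1e-9)
        nodes.extend(new)
        node_set.update(new)
    else:
        logger.warning("median_joining: iteration cap reached")

    # final network + pruning of obsolete medians
    g = nx.Graph()
    for key in nodes:
        rec = uniq.get(key)
        g.add_node(key, hap=key,
                   kind="sampled" if rec else "median",
                   multiplicity=rec["multiplicity"] if rec else 0,
                   pops=dict(rec["pops"]) if rec else {})
    d = dmat()
    for i, j in _msn_edges(d, epsilon):
        _add_edge(g, nodes[i], nodes[j], weights, site_ids)

    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if g.nodes[v]["kind"] != "median":
                continue
            deg = g.degree(v)
            if deg <= 1:
                g.remove_node(v)
                changed = True
            elif deg == 2:
                a, b = list(g.neighbors(v))
                if not g.has_edge(a, b):
                    sites = g[v][a]["sites"] + g[v][b]["sites"]
                    wsum = g[v][a]["weight"] + g[v][b]["weight"]
                    g.add_edge(a, b, sites=sites, weight=wsum)
                g.remove_node(v)
                changed = True
    g.graph["site_ids"] = site_ids
    return g


def _majority(a, b, c):
    if a == b or a == c:
        return a
    if b == c:
        return b
    return a        # all distinct (multistate): keep the first (deterministic)


def _add_edge(g, u, v, weights, site_ids):
    diff = [s for s in range(len(u)) if u[s] != v[s]]
    g.add_edge(u, v, sites=[site_ids[s] for s in diff],
               weight=float(sum(weights[s] for s in diff)))


def attach_outgroup(net: nx.Graph, outgroup_hap, weights=None,
                    label="outgroup") -> nx.Graph:
    """Root the network: connect the outgroup haplotype to its closest node.

    Outgroup-specific variants should be excluded beforehand (the outgroup
    vector is given over the same network sites).  Ties are broken by
    lexicographic node order.  Sets ``net.graph['root']``.
    """
    key = tuple(int(x) for x in outgroup_hap)
    m = len(key)
    weights = np.ones(m) if weights is None else np.asarray(weights, float)
    site_ids = net.graph.get("site_ids", list(range(m)))
    best = min(sorted(n for n in net.nodes),
               key=lambda n: _hamming(key, n, weights))
    if key in net.nodes:
        net.nodes[key]["kind"] = "root"
    else:
        net.add_node(label, hap=key, kind="root", multiplicity=0, pops={})
        diff = [s for s in range(m) if key[s] != best[s]]
        net.add_edge(label, best, sites=[site_ids[s] for s in diff],
                     weight=float(sum(weights[s] for s in diff)))
    net.graph["root"] = key if key in net.nodes else label
    return net


# ---------------------------------------------------------------------------
# Rho dating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RhoAge:
    rho: float
    sigma_rho: float
    mu_seq: float               # mutations per sequence per generation
    gen_time: float
    age_years: float
    sd_years: float
    n_tips: int


def rho_age(net: nx.Graph, root, tip_set=None, mu_site: float = 3.0e-8,
            seq_len: float = 1.0, gen_time: float = 29.0) -> RhoAge:
    """Coalescent age of a clade from the rho statistic.

    ``root`` is the designated ancestral node; ``tip_set`` the sampled nodes
    dated against it (default: every sampled node).  Mutational path lengths
    are shortest paths (a warning is emitted if reticulation makes a path
    ambiguous); branch counts for the Saillard SD come from the shortest-path
    tree.
    """
    if mu_site <= 0 or seq_len <= 0 or gen_time <= 0:
        raise ValueError("mu_site, seq_len and gen_time must be > 0")
    if root not in net.nodes:
        raise KeyError(f"root {root!r} not in network")
    if tip_set is None:
        tip_set = [v for v in net.nodes
                   if net.nodes[v].get("multiplicity", 0) > 0]
    if net.number_of_edges() > net.number_of_nodes() - 1:
        logger.warning("rho_age: network is reticulate; shortest paths used")
    dist, paths = nx.single_source_dijkstra(net, root, weight="weight")
    missing = [t for t in tip_set if t not in dist]
    if missing:
        raise ConfigError(f"{len(missing)} tips unreachable from root")
    mult = {t: max(net.nodes[t].get("multiplicity", 0), 1) for t in tip_set}
    n = sum(mult.values())
    rho = sum(mult[t] * dist[t] for t in tip_set) / n

    # Saillard: shortest-path tree, n_b = tips below each branch
    below: dict[tuple, int] = {}
    lengths: dict[tuple, float] = {}
    for t in tip_set:
        path = paths[t]
        for u, v in zip(path, path[1:]):
            e = (u, v)
            below[e] = below.get(e, 0) + mult[t]
            lengths[e] = net[u][v]["weight"]
    var = sum((below[e] ** 2) * lengths[e] for e in below) / (n ** 2)
    sigma = math.sqrt(var)
    mu_seq = mu_site * seq_len
    age = rho / mu_seq * gen_time
    sd = sigma / mu_seq * gen_time
    return RhoAge(rho=rho, sigma_rho=sigma, mu_seq=mu_seq, gen_time=gen_time,
                  age_years=age, sd_years=sd, n_tips=n)


# ---------------------------------------------------------------------------
# Hudson-Kaplan Rmin
# ---------------------------------------------------------------------------

def rmin_hudson_kaplan(geno_or_panel) -> tuple[int, list[tuple[int, int]]]:
    """Four-gamete lower bound on recombination events.

    Returns (Rmin, disjoint incompatible intervals as site-index pairs).
    Incompatible pairs are those displaying all four gametes; Rmin is the
    maximum number of pairwise-disjoint *open* intervals among them (greedy
    scan over right endpoints).
    """
    geno = (geno_or_panel.geno if isinstance(geno_or_panel, HaplotypePanel)
            else np.asarray(geno_or_panel))
    n, m = geno.shape
    intervals = []
    for i, j in itertools.combinations(range(m), 2):
        a, b = geno[:, i], geno[:, j]
        ok = (a != -1) & (b != -1)
        gametes = {(int(x), int(y)) for x, y in zip(a[ok], b[ok])}
        if len(gametes) == 4:
            intervals.append((i, j))
    intervals.sort(key=lambda iv: (iv[1], -iv[0]))
    chosen = []
    last_right = -1
    for left, right in intervals:
        if left >= last_right:      # open intervals: may share an endpoint
            chosen.append((left, right))
            last_right = right
    return len(chosen), chosen


# ---------------------------------------------------------------------------
# Haplogroup motifs
# ---------------------------------------------------------------------------

def read_motif_table(path) -> pd.DataFrame:
    """Motif TSV: haplogroup, parent, snp_id, required_allele."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    need = {"haplogroup", "parent", "snp_id", "required_allele"}
    if not need.issubset(tab.columns):
        raise ConfigError(f"motif table needs columns {sorted(need)}")
    return tab


def assign_haplogroups(panel: HaplotypePanel, motif_table: pd.DataFrame,
                       root_label="root", rare_freq=0.01) -> pd.DataFrame:
    """Deepest-matching haplogroup label per chromosome.

    The motif table defines a rooted hierarchy (``parent`` empty or 'root'
    at the top); a chromosome matches a haplogroup when it carries the
    required alleles of the haplogroup *and all its ancestors*.  Chromosomes
    matching no motif get ``root_label``; whole haplotypes with panel
    frequency < ``rare_freq`` are flagged rare.  Conflicting deepest matches
    raise :class:`ConfigError` listing the candidates.
    """
    snp_pos = {s: k for k, s in enumerate(panel.snp_ids)}
    motifs: dict[str, dict] = {}
    for hg, sub in motif_table.groupby("haplogroup"):
        parents = set(sub["parent"].fillna(""))
        if len(parents) != 1:
            raise ConfigError(f"haplogroup {hg} has multiple parents")
        req = {}
        for _, row in sub.iterrows():
            if row["snp_id"] not in snp_pos:
                raise ConfigError(f"motif SNP {row['snp_id']} not in panel")
            req[snp_pos[row["snp_id"]]] = int(row["required_allele"])
        motifs[hg] = {"parent": parents.pop() or "root", "req": req}

    def depth(hg):
        d, cur = 0, hg
        seen = set()
        while motifs.get(cur, {}).get("parent", "root") != "root":
            if cur in seen:
                raise ConfigError("motif hierarchy contains a cycle")
            seen.add(cur)
            cur = motifs[cur]["parent"]
            d += 1
        return d

    def matches(hap, hg):
        cur = hg
        while cur in motifs:
            for j, allele in motifs[cur]["req"].items():
                if hap[j] != allele:
                    return False
            cur = motifs[cur]["parent"]
        return True

    # haplotype frequency for the rare flag
    hap_keys = [tuple(row) for row in panel.geno]
    freq = pd.Series(hap_keys).value_counts(normalize=True)

    rows = []
    for i, hap in enumerate(panel.geno):
        hits = [hg for hg in motifs if matches(hap, hg)]
        if hits:
            dmax = max(depth(h) for h in hits)
            deepest = [h for h in hits if depth(h) == dmax]
            if len(deepest) > 1:
                raise ConfigError(
                    f"ambiguous haplogroup for {panel.hap_ids[i]}: "
                    f"{sorted(deepest)}")
            label = deepest[0]
        else:
            label = root_label
        rows.append(dict(hap_id=panel.hap_ids[i],
                         population=panel.pop_labels[i],
                         haplogroup=label,
                         rare=bool(freq[hap_keys[i]] < rare_freq)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clopper-Pearson
# ---------------------------------------------------------------------------

def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson confidence interval for a binomial proportion."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper
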