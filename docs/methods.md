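# Methods

`tyrscan` re-creates, as a reusable library, the complete analysis pipeline
of a candidate-gene population-genetic study: a ~20 kb resequencing
alignment of a pigmentation gene in a worldwide sample with a chimpanzee
outgroup, combined with a genome-wide phased SNP-array panel.  This note
records the models, the defaults and the reasoning behind the open design
choices; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Data models and missing data

An `Alignment` is a sample × site nucleotide matrix with per-column genomic
coordinates, positions relative to the first codon (0 at the A of the start
codon, negative upstream), and region labels (5'flank, exon_k, intron_k,
3'flank) that partition the columns.  A `HaplotypePanel` is a phased,
outgroup-polarised 0/1 matrix with physical and genetic-map positions.

**Complete deletion.**  Alignment columns carrying a gap or `N` in any
sample are excluded both from variable-site calls and from diversity
denominators.  Pairwise deletion would use more data but makes per-site
denominators depend on the pair, so identical inputs could give different
π depending on traversal order of missing patterns; complete deletion is
reproducible and is what the per-region/whole-alignment additivity
invariant assumes.  The number of masked columns is logged.  Because the
original study does not state its missing-data rule, small discrepancies
against its printed π values are possible; the choice is isolated in
`Alignment.analyzable` for sensitivity analysis.

**Polarity.**  The outgroup allele defines the ancestral state where it
matches one of the human alleles.  Columns where the outgroup carries a
third allele stay in diversity calculations but are excluded from
polarity-dependent statistics (derived-allele counts, iHS, allele ages).

## Diversity, divergence and Ka/Ks

π is the mean number of pairwise differences per site; the Jukes–Cantor
correction −(3/4)·ln(1 − 4p/3) maps it to substitutions per site (domain
p < 3/4, enforced).  Sliding windows are 1,500 bp advanced by 375 bp on the
relative-to-first-codon axis, half-open, anchored at the 5'-most annotated
column; windows with fewer than 10 analyzable columns are reported missing
rather than as unstable small-denominator values.

Divergence is the JC distance between the column-majority human consensus
and the outgroup; consensus ties are broken toward the outgroup allele (the
conservative choice: it can only lower apparent divergence).  The local
per-generation mutation rate follows from a split time T and generation
time g as μ = d·g/(2T); defaults T = 7×10⁶ years, g = 29 years.  With the
published human–chimp divergence of 0.01447 this gives 3.0×10⁻⁸ per site
per generation, the rate also used to convert network rho values to years.

Ka/Ks uses the Nei–Gojobori (1986) method: per-codon synonymous site counts
as the synonymous fraction of the three possible changes at each position
(changes to stop codons count as nonsynonymous), averaged over the two
sequences; observed differences resolved by averaging over all minimal
mutational pathways with equal weight, excluding pathways through stop
codons (all pathways are used in the degenerate case where every pathway is
blocked); proportions JC-corrected.  The implementation is checked
codon-by-codon against an independent brute-force enumeration of
substitution orderings for all 61×61 sense-codon pairs.

## Tajima's D and its two nulls

D = (π_total − S/a₁)/√(e₁S + e₂S(S−1)) with the 1989 constants; S = 0
yields an undefined (not zero) result, multiallelic columns are excluded
from S (logged) to match the biallelic framing of the genotype-based tests.

*Equilibrium null*: our own Kingman sampler draws a constant-size,
recombination-free genealogy and places exactly the observed S mutations
proportionally to branch length.  Conditioning on S (rather than θ)
removes the nuisance mutation rate, the classical fixed-S convention.
Under this null the mean of D over 10,000 replicates at n = 20, S = 20 is
≈ −0.08 (checked against the (−0.3, 0.1) bias band).

*Demography-aware null*: msprime simulates the editable out-of-Africa-style
model shipped in `tyrscan/data/best_fit_demography.json` (African,
European, Asian histories with an out-of-Africa bottleneck, daughter
bottlenecks, recent growth and symmetric migration; sizes in chromosomes).
The constants are plausible round numbers in the published range for such
calibrated models and live in JSON precisely so users can substitute
published values; populations without a calibrated history (America,
Oceania) are run under the Asian model as proxy.  p-values applied to
draws from the null itself are uniform (KS test, α = 0.01).

Both nulls report a **two-sided** empirical p = 2·min(lower, upper tail),
capped at 1, as an explicit `EmpiricalP`; zero exceedances are reported as
the bound 2/n_sims with `is_upper_bound` set, so "< 2×10⁻⁴ at 10,000
simulations" is representable without fabricating a point estimate.  A
one-sided convention would halve these values; the choice is localised in
`neutrality.empirical_p`.

AMOVA partitions the pairwise nucleotide-difference matrix into among- and
within-subpopulation components (SSD = Σd/n convention); F_ST =
σ²_a/(σ²_a+σ²_w), significance by label permutation with add-one
correction.  Bonferroni flags use α/6 by default (six population groups).

## Haplotype scans

EHH(x) is the probability that two distinct carrier haplotypes are
identical over [core, x], computed by outward partition refinement;
missing calls form their own allele class and hence break homozygosity.
iHH is the trapezoid integral of EHH over genetic distance, truncated by
linear interpolation at the 0.05 crossing (the classical cutoff).  A SNP is
left unscored when the tracked EHH has not decayed below 0.05 before the
chromosome end or before an assembly gap larger than 200 kb.

iHS = ln(iHH_ancestral/iHH_derived) for cores with derived-allele frequency
in [0.05, 0.95], standardised within 50 equal-width DAF bins and then
z-normalised per chromosome.  The double normalisation is deliberately
redundant on a single chromosome (the second step is then an identity up to
global centring) but honours genome-wide scans where chromosome-level
means drift; the order can be swapped via `standardize_order`.  On a
neutral 5 Mb panel with ≥ 5,000 scored SNPs the per-bin means are ~0, the
per-bin SDs ~1, and |iHS| > 2 occurs at ≈ 5%.

XP-EHH integrates EHH over *all* haplotypes of each population, stops when
the pooled two-population EHH drops below 0.05, takes
ln(iHH_focal/iHH_ref), and z-normalises per chromosome.

Weir–Cockerham θ is computed from haploid allele counts (two samples, no
heterozygosity term); negative estimates are retained.  d_i for a focal
population is the sum over the other populations of the pairwise θ
standardised by its genome-wide mean and SD; pairs with undefined θ at a
SNP drop out of that SNP's sum (recorded in `n_pairs`).

**Windows and ranks.**  Scores are summarised in non-overlapping 200-kb
windows anchored at coordinate 0 of each chromosome (maximum for XP-EHH,
mean for d_i, fraction |iHS| > 2 for iHS), binned by floor(SNP count/bin
size) with bin size 20 (XP-EHH, d_i) or 15 (iHS), and ranked as the
fraction of same-bin windows with a value ≤ their own — ties count ≤, so a
strict maximum attains rank 1.0.  The focal-gene window is re-centred on
the gene midpoint and ranked against the anchored genome-wide grid.  With
this (inclusive, discrete) rank convention the probability that a neutral
focal window exceeds the 0.95 rank threshold is slightly above 1/20 for
bins of fewer than ~100 windows (e.g. 3/50 = 6% for a 50-window bin); the
type-I error study measures the realised rate over 200 neutral replicate
genomes and checks it against the binomial 99% band around 5%.

## Networks and dating

Pairwise D′ and r² come from directly counted two-locus haplotype
frequencies.  Haplotype blocks follow the Gabriel confidence-interval
rules with the published default thresholds (likelihood-profile 5th/95th
bounds on |D′|; strong LD when ≥ 0.70/≥ 0.98, strong recombination when
the upper bound < 0.90; a block needs its outermost pair strong and ≥ 95%
of informative pairs strong), candidates accepted longest-first without
overlap, on MAF ≥ 0.05 SNPs.

The median-joining network alternates ε-relaxed minimum-spanning-network
construction with quasi-median insertion for linked triplets until stable,
then prunes unsampled median vectors of degree ≤ 2 (merging their
through-edges).  All ties — node order, candidate medians — are broken by
lexicographic haplotype order so networks are reproducible.  On
recombination-free data the sampled haplotypes are always nodes and
perfect-phylogeny inputs return their tree.  The network is rooted by
connecting the outgroup haplotype (restricted to the network's sites,
outgroup-specific variants excluded) to its closest node.

Rho dating: rho is the multiplicity-weighted mean mutational path length
from a designated root to the sampled tips (shortest paths, with a warning
under reticulation); the standard deviation follows Saillard's estimator
σ = √(Σ n_b² l_b)/n on the shortest-path tree; age = rho/(μ_site·L)·g
years.  For allele ages the root is the ancestral node of the
allele-defined clade.  On simulated star genealogies rho is unbiased for
t·μ_seq (3-SE check over 1,000 replicates).

Hudson–Kaplan R_min: four-gamete-incompatible site pairs define open
intervals; the greedy scan over sorted right endpoints returns the maximum
disjoint set.  R_min never exceeded the true recombination-event count of
the simulated ancestry in 100 checked replicates (events counted from the
full ancestral recombination graph).

Haplogroups are assigned by deepest-matching motif in a rooted hierarchy
(a match requires the motif alleles of the group and all its ancestors);
chromosomes matching nothing get the root label, whole haplotypes below 1%
panel frequency are flagged rare.  Frequency intervals are exact
Clopper–Pearson (beta quantiles); the method is not named in the source
study, and the exact interval is preferred because its coverage is
guaranteed ≥ 95% — verified empirically over p ∈ {0.01…0.5},
n ∈ {20, 126, 600}.

## The simulator

`simulate_neutral` wraps msprime (Hudson coalescent with recombination,
infinite-sites binary mutations, ancestral allele 0); population sizes are
expressed in chromosomes and sampling is haploid, so E[π] = θ = 2Nμ L and
E[TMRCA] = 2(1 − 1/n)·N generations — both recovered within 3 SE over
2,000 replicates, as is E[S] = θ·a₁(n).  Continuous mutation positions are
discretised to strictly increasing integer base pairs on output.
`simulate_fixed_s` is our own Kingman sampler (described above).  Same
seed, same replicate, for every generator.

`simulate_sweep` is a coalescent-initialised forward Wright–Fisher
simulation: the standing population of 2N haplotypes starts from a neutral
coalescent replicate with the same N, μ and r (avoiding a ~10N-generation
forward burn-in), one site near the region midpoint becomes beneficial
with genic selection (fitnesses 1, 1+s, 1+2s), and generations run forward
with per-haplotype Poisson recombination and infinite-sites mutation until
the allele reaches the target frequency; lost alleles restart the attempt
(rejection sampling, attempt count capped).  The two-population variant
evolves a neutral sister population in parallel from a shared two-deme
initial condition, giving the common SNP coordinate set XP-EHH requires.

**Sweep power fixture (rescaled locus).**  A literal human-scale forward
simulation (N ≈ 10⁴) is unnecessary for a power study; instead the locus
is rescaled while keeping the selection coefficient at its nominal
s = 0.05 and the sweep frequency at 0.7: N = 1,000 diploids (4Ns = 200, a
firmly selective trajectory), 1.2 Mb at μ = 4×10⁻⁸ and r = 1.5×10⁻⁷
(15 cM/Mb), sweep from 0.5% standing copies, n = 100 sampled chromosomes
per population, reference split 300 generations before present.  The
region is long enough that the swept haplotype's EHH decays below the 0.05
cutoff inside it (so swept cores are scorable under the edge rule), and
the footprint-to-neutral-haplotype-length ratio is large, as at a real
selected locus.  Power is measured at the swept SNP against the 95th
percentile of frequency-matched central SNPs from matched neutral
replicates, with iHS standardised against the neutral background within
0.1-wide DAF bins — the statistic's own genome-scan convention.

`ascertain_array` emulates the SNP-array pipeline: optional density
thinning, per-call missingness injected *before* filtering, then the array
QC rules — call rate ≥ 0.95 and minor-allele frequency strictly over 0.05
— leaving a left-truncated frequency spectrum, plus a uniform genetic map.

## Study sizes

Monte-Carlo sizes used by the test suite and acceptance script: 2,000
replicates for the closed-form coalescent checks (3-SE bands); 10,000 for
the fixed-S bias band; 999 null + 200 observed draws for p-value
uniformity (KS at α = 0.01); one 5 Mb/120-chromosome panel (≈ 5,000 scored
SNPs) for iHS calibration; 50 sweep + 50 neutral replicates for power
(threshold = neutral 95th percentile, success bar 80%); 200 neutral
genomes of 20 Mb for scan type-I error; 10,000 draws per grid point for
interval coverage; 100 full-ARG replicates for the R_min bound.  These
sizes keep every check's statistical band meaningful while the whole
validation layer completes in minutes on one core.

## Known limitations

* The synthetic data are infinite-sites and error-free: no sequencing
  error, no genotyping error beyond injected missingness, no gene
  conversion, and array ascertainment is a simple MAF/call-rate filter
  rather than a discovery-panel model.  Passing tests demonstrate
  correctness of the statistics and calibration of the machinery under the
  stated models, not robustness to real-data artefacts.
* The shipped demographic constants are structural stand-ins; analyses of
  real data should substitute published calibrated values in the JSON.
* The Gabriel block finder considers contiguous candidate intervals and
  resolves overlaps greedily by span, which can differ from other
  implementations' tie-breaking on pathological inputs.
* Statistical phasing, genotype calling, liftover, Bayesian dating and
  full minimal-ARG reconstruction are out of scope; R_min is the
  recombination lower bound offered instead of a full ARG.
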