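# Methods

`hapnet` implements the classical workflow for dating beta-globin
gene-cluster RFLP haplotypes: estimate haplotype frequencies from
unphased diploid genotypes, connect the haplotypes in a median-joining
network, and estimate each haplotype's age with the rho statistic,
converted to years under a mutation-rate calibration. This note records
the models, the parameters that matter, and the design choices made
where the published workflow leaves the procedure open.

## Data model

A haplotype is an ordered binary vector over L polymorphic restriction
sites (`+` = enzyme cuts, `-` = no cut). The default site map is the
seven classical beta-globin cluster sites, 5' to 3': HincII 5' to
epsilon, HindIII G-gamma, HindIII A-gamma, HincII psi-beta, HincII 3' to
psi-beta, AvaII beta, HinfI 3' to beta. Site order is positional and
fixed; there is no strand or coordinate logic, because the markers are
pure presence/absence calls. Input tables accept both the Unicode minus
(used in published tables) and the ASCII hyphen; output is always ASCII.
Frequency-table columns are validated to sum to 1 within 0.005 — the
slack absorbs the 3–4 significant digits of published tables, whose
columns sum to ≈ 0.9997. All-zero columns are allowed and skipped.

## EM haplotype-frequency estimation

Observed data are site-wise diploid counts (0/1/2 copies of `+`, or
missing) with unknown gametic phase. A genotype heterozygous at k sites
is compatible with max(1, 2^(k-1)) unordered haplotype pairs. Under
Hardy–Weinberg equilibrium the log-likelihood is

    l(p) = sum_g log sum_{(h1,h2) ~ g} (2 - delta_{h1,h2}) p_{h1} p_{h2}

The E-step distributes each individual over its compatible pairs with
weights proportional to (2 - delta) p_{h1} p_{h2}; the M-step sets each
p_i to its expected chromosome count over 2n. Design choices:

* **Support restriction.** Only haplotypes compatible with at least one
  individual enter the model; this keeps the support far below 2^L and
  matches how standard phasing software behaves.
* **Missing data** are summed over inside the pair enumeration, so
  partially typed individuals still contribute to the sites they have.
* **Restarts.** The likelihood surface has saddle points (a lone
  double heterozygote has a symmetric fixed point at the uniform
  distribution). Restart 1 starts uniform (deterministic); the remaining
  restarts (default 20) draw Dirichlet(1) starting points from the
  configured seed. The best final log-likelihood wins, ties by first
  occurrence.
* **Convergence** on absolute log-likelihood change below `tol`
  (default 1e-8), capped at 10,000 iterations. Frequencies below 1e-12
  are dropped from the reported support and the rest renormalised.

The ascent property (log-likelihood never decreases) is asserted
iteration by iteration in tests, and the maximised likelihood is checked
against a direct numerical search over the frequency simplex on small
instances.

## Median-joining network

Construction follows the standard two-phase median-joining scheme for
binary characters:

1. **Minimum spanning network.** Pairwise weighted Hamming distances are
   processed in increasing length classes; a link of length d is kept
   iff its endpoints are not already connected by kept links of length
   < d - epsilon. With epsilon = 0 this keeps exactly the links that
   occur in at least one minimum spanning tree (verified in tests
   against exhaustive spanning-tree enumeration).
2. **Median insertion.** For every triple of mutually linked nodes the
   median vector (site-wise majority — for binary states the quasi-
   median) is computed; among medians not yet present, all whose
   connection cost (sum of distances to the defining triple) is within
   epsilon of the round's minimum are added, and the MSN is rebuilt.
   This repeats until no median can be added.
3. **Pruning.** Unsampled nodes of degree ≤ 2 that lie on no shortest
   path between sampled nodes are deleted one at a time (lexicographic
   order), rebuilding the MSN after each deletion. A degree-2 median on
   a sampled-to-sampled geodesic is deliberately kept: removing it could
   lengthen displayed alternative paths.

Defaults are epsilon = 0 and unit site weights (commercial defaults of
10 per site differ only by a constant factor). Every tie-prone step
iterates nodes in lexicographic pattern order, so construction is
deterministic without a seed; median vectors are named mv1, mv2, … in
insertion order. Frequency weights never affect topology — they are
carried for node rendering and for dating multiplicities.

A note on what the final network guarantees: the MSN stage equals the
union of all minimum spanning trees, but median insertion intentionally
*replaces* long sampled-to-sampled links with shorter paths through
inferred intermediates (three haplotypes mutually two steps apart
collapse to a star of three unit links through their median). The
invariant tested is therefore that the final network is connected and
that its cheapest subtree spanning the sampled haplotypes costs no more
than a minimum spanning tree of those haplotypes.

## Rho dating

Given a network and a designated ancestral root (default the all-minus
pattern, following the classical inference that it is the ancestral
human beta-globin cluster haplotype), a rooted genealogy is extracted as
the Dijkstra shortest-path tree with a deterministic parent rule:
highest sampled weight first, then lexicographic pattern. An
`all-shortest-paths-average` mode records each node's mean root distance
over all shortest paths; with additive edge lengths this coincides with
the shortest-path distance, and the mode exists for schema clarity.

For a node v, rho is the multiplicity-weighted mean mutational distance
from v to every sampled chromosome in v's clade (v's own chromosomes
count at distance 0). The standard error uses the branch formula

    sigma^2 = (1/n^2) * sum_branches n_b^2 * l_b

with n_b the sampled chromosomes below a branch of length l_b. On a
star every branch subtends one chromosome, so sigma^2 = rho/n exactly;
this identity is asserted on constructed stars. Ages in years are
rho (or sigma) times the calibration rate.

Two dating modes are provided because published per-haplotype tables in
this literature are often produced interactively and do not pin down the
procedure: `descendant-rho` (default) applies the clade-mean estimator
at each node; `root-path` reports each node's mutational distance from
the root, with sigma = sqrt(distance), the single-lineage Poisson
standard error. The pipeline logs the non-default mode's table at DEBUG
level so the two readings can be compared. The published per-haplotype
rho values themselves are *not* a reproduction target: several are
consistent with neither reading of the text (one haplotype two steps
from the root is printed with rho = 1), because they depend on the
interactive node selection and exact figure topology of the original
analysis. The conversion of any printed rho/sigma to years, however, is
exact and is asserted.

* **Calibration.** Default 20,180 years per mutation, as used in the
  source analysis; this is an mtDNA control-region calibration applied
  to beta-globin RFLP haplotypes, so the rate is exposed everywhere
  (`CalibrationRate`, `--rate`) for users dating other loci.
* **Multiplicities.** Dating weights descendants by sampled chromosome
  counts. When populations are pooled without per-population sizes, the
  pooled frequencies are scaled to a nominal 100 chromosomes (logged;
  rho and sigma are invariant to this scaling).
* **Rounding.** Years to 0.1, rho/sigma to 3 decimals in output tables,
  matching the precision of published tables.

The expansion-time helper implements t = tau/(2u) for a mismatch-
distribution mode tau and per-sequence per-generation mutation rate u,
times an optional generation-length factor. Estimating tau or u from
data is out of scope — it requires sequence-level mismatch
distributions, not RFLP haplotype counts.

## Synthetic data

`simulate_genotypes` draws two haplotypes per individual independently
from a frequency vector and erases phase — exactly the HWE sampling
model the EM stage assumes. `simulate_star` gives each of n lineages a
Poisson(lambda) mutation count; with the default infinite-sites
approximation mutated sites are drawn without replacement within a
lineage, so observed distance equals the true count and rho validation
is exact. When a lineage draws more mutations than sites (or the flag is
off), sites are drawn with replacement and a back-mutation warning is
logged. Both generators are byte-deterministic under their seed.

What the generators deliberately do not emulate: recombination across
the cluster (relevant to real beta-globin haplotypes, where the known
recombination hot spot decouples the 5' and 3' sub-haplotypes),
population structure and demography, genotyping error, and
ascertainment of carriers through a disease variant. Passing recovery
tests on these simulations therefore demonstrates correctness of the
estimators under their own assumptions, not robustness of the
assumptions for any particular real cohort.

Simulation scales used by the test suite — 20 replicates of n = 500
individuals for EM recovery, 1,000 star genealogies of 20 chromosomes
for rho calibration, 200 randomized instances of ≤ 8 haplotypes for the
network oracles — were chosen as the smallest sizes at which the
sampling-noise bounds quoted in the tests are comfortably diagnostic.

## Known limitations

* The per-haplotype ages reproduce the published *method*, not the
  published table rows (see above); both dating modes are emitted so
  users can compare.
* EM standard errors and linkage-disequilibrium statistics are not
  computed.
* Reduced-median networks and maximum-parsimony post-processing of the
  network are not implemented.
* Pooling populations defaults to equal weights because per-population
  chromosome counts are rarely published; the manifest records this
  assumption on every run.
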