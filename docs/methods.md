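# Methods

This note documents the models, estimators and numerical choices behind
`introland`, and what the built-in simulator does and does not emulate.

## The synthetic-data generator

`simcoal` draws genotype data under a multispecies coalescent
(msprime) on a user-specified rooted species tree with branch-specific
diploid effective sizes, a per-site per-generation mutation rate, and
dated admixture pulses. Two conventions shape everything downstream:

- **One genealogy per window.** Windows (default 10 kb) are independent
  and carry no intra-window recombination. The analyses operate on
  10 kb windows as atomic units, so a single marginal genealogy per
  window preserves every statistic under test while keeping simulation
  desk-scale. Consequences: linkage *within* a window is total (sites
  share one tree), linkage *between* windows is absent. Real genomes
  interpolate between these extremes; block-jackknife machinery is
  therefore exercised under the harshest within-block linkage.
- **rho is a covariate, not a coalescent parameter.** The per-window
  population-scaled recombination rate is drawn (default lognormal,
  median 5, log-sd 1) or supplied, and is exported as ground truth. It
  never enters the genealogy; it can drive the *retention* device below.
  This mirrors analyses in which recombination maps are produced by an
  external estimator and correlated against window statistics.

**Pulses.** An admixture pulse (time, donor, recipient, fraction f)
reroutes each recipient-branch lineage to the donor branch with
probability f at the pulse time, backwards in time — the standard
instantaneous-pulse convention and the estimand of f_hom. Pulse times
must fall in the co-existence interval of donor and recipient branches
(validated). A window is labeled introgressed when at least one of its
lineages actually took the pulse route (from the migration records), so
the realized introgressed fraction reflects lineage routing, not just f.

**Retention.** With a monotone map retention(rho) in [0,1], each
introgressed window survives with probability retention(rho) and is
otherwise replaced by a fresh pulse-free draw and relabeled. This is a
phenomenological stand-in for selection against introgressed ancestry
being most effective where linkage is strong; it produces the
qualitative signal (introgression concentrated in high-recombination
windows) without modeling selection explicitly. `apply_retention`
applies the same rule to truth labels only, for label-level experiments.

**Mutations** are infinite-sites (binary model, continuous positions
floored to integers; collisions, which are rare at the default
theta, keep the first site). The outgroup is used only for polarization
downstream. There is no sequencing error, missingness, or depth
variation; VCF depth filters are exercised as no-ops on simulated data.

**Canned demographies.** `ladder_model()`: ((((P1,P2),P3),P4),O), splits
at 10/20/30 kgen, outgroup at 120 kgen, Ne 10,000, mu 1e-8 — internal
branches of 0.5 coalescent units give heavy incomplete lineage sorting.
`symmetric_model()`: (((P1,P2),(P3,P4)),O) with splits 10/30/50/120
kgen; the long co-existence of the (P1,P2) ancestor with the P3/P4 tip
branches (10-30 kgen) is what gives ancestral pulses a detectable
D_FOIL footprint. These defaults, with 2 diploids per population
(4 + 2 outgroup samples for the landscape experiment), are the study
conditions of the test suite and acceptance script.

## Site statistics

**Polarization.** The ancestral allele is the allele fixed in the
outgroup (strict by default; a near-fixation threshold, e.g. 0.9, is
configurable). Outgroup-polymorphic or outgroup-missing sites are
dropped and counted. Derived frequencies are per-population dosage sums
over twice the genotyped diploids.

**D and the jackknife.** D = (ABBA-BABA)/(ABBA+BABA) with
frequency-weighted pattern sums. Significance comes from a delete-one
jackknife over 20 contiguous equal-site blocks. The p-value uses a
Student-t tail with g-1 degrees of freedom: with 20 blocks the normal
tail is measurably anti-conservative (simulated null false-positive
rate 0.095 at small replicate sizes; 0.04 with the t tail at the
default sizes). Trio arrangements are resolved by the minimum-|D| rule
(D_min), with the most-significant arrangement also reported; trio
tables are Benjamini-Hochberg corrected and gated at adjusted p < 0.01.

**f_hom.** The ratio S(P1,P2,P3,O)/S(P1,P3,P3,O) estimates the genomic
admixture proportion under the complete-homogenization yardstick. The
p3^2 term in the denominator uses the unbiased two-draw estimator
p(np-1)/(n-1) (n = donor haplotypes) — equivalent to the common
donor-splitting trick; with only 4 donor haplotypes the naive square
inflates the denominator and biases f_hom down by about a quarter of
its value. Recovery is accurate (within ±0.05 absolute, typically
±0.02) for recent pulses; pulses much older than ~half the recipient's
branch length are underestimated because the introgressed haplotypes
have drifted away from the donor — a property of the estimator, not of
the implementation.

**f_dM and pIRs.** Windowed f_dM uses the symmetric dynamic-donor
denominator: per site the donor is whichever of (P2,P3) — or (P1,P3) on
the negative branch — carries the larger derived frequency. Windows
with fewer than 10 usable SNPs are masked. A trio's pIRs are its top
100·f_hom % windows by f_dM (x = 0 when f_hom is negative: a negative
admixture fraction is uninterpretable); top-q cuts everywhere use
ceiling counts with ties broken by genomic order so flag counts are
exact and reproducible. The introgression index of a window is the
fraction of gate-passing trios whose pIR set contains it.

## D_FOIL

The four statistics (DFO, DIL, DFI, DOL) are contrasts of
frequency-weighted five-taxon site-pattern groups; each left/right pair
is exchanged by a null symmetry of the symmetric species tree (P3↔P4
for DFO/DIL, P1↔P2 for DFI/DOL), so all four have expectation zero
without gene flow, and the groups include the singleton patterns that
carry directional information. Under the relabeling (P1↔P2, P3↔P4) the
vector maps to (-DIL, -DFO, -DOL, -DFI), frozen as a regression test.

The sign-signature → scenario table was established by simulating every
directional and ancestral pulse scenario under the canned symmetric
demography and reading off the asymptotic signs; it is frozen in
`dfoil.SIGN_TABLE`, every signature outside the table maps to
`indeterminate`, and the classification is a pure function of the
signature. Structure: ancestral introgression into the (P1,P2) ancestor
moves DFO and DIL together (+ for P3, - for P4) and leaves DFI/DOL at
zero; flow into P1 or P2 moves DFI and DOL together (+ for P1, - for
P2) with exactly one of DFO/DIL responding; flow into P3 or P4 moves
DFO and DIL together with one weaker DFI/DOL marking the partner.

Per-statistic significance defaults to the block-jackknife t-test
above. The chi-square-on-sums convention of the reference
implementation is available (`method='chi2'`) but is strongly
anti-conservative when whole windows are single genealogies (~15%
spurious signs per statistic at alpha 0.01 in ancestral-pulse
simulations), which is why it is not the default here.

## Trees, weighting, quartet scores

Per-window trees are neighbor-joining on p-distances between diploid
dosage vectors (|d_i - d_j|/2 averaged over shared genotyped sites) — a
deterministic surrogate for per-window ML trees; externally inferred
newick trees are interchangeable. Q-matrix ties break on the smallest
label pair. Topology identity is the recursive sorted-newick normal
form after rooting on the outgroup edge; weighting enumerates (or
Monte-Carlo samples) one-tip-per-group combinations, prunes, collapses
to group labels and tallies — exhaustive when the combination count is
at most 10,000, at most 8 groups. The normalized quartet score is the
fraction of 4-tip subsets, over all gene trees, whose induced unrooted
quartet (four-point condition on topological path lengths) matches the
species tree.

Rooted topology counts use the (2k-3)!! double factorial on the k
ingroups (big-integer arithmetic), cross-checked against exhaustive
edge-attachment enumeration for small k. The bootstrap-support window
filter of ML workflows is represented only as the site-count /
parsimony-informative-site filter (defaults 200 sites, 20 PIS;
PIS = both alleles on at least two haplotype copies, computed from
dosages).

## Landscape

Windowed F_ST is Weir & Cockerham (1984) with the ratio-of-sums form
(sum a / sum (a+b+c) over sites); sites need at least two genotyped
diploids per population; negative values are reported unclamped.
Outlier indices flag the top 5% of each track; region classes are
high introgression (top ~5% of the introgression index, zeros never
eligible, realized cut reported), low introgression (index exactly 0)
and high F_ST (index > 1/3). Binned correlations use equal-count bins
(default 20 in the API; 15 in the landscape experiment, which has 3,000
windows) and report both the bin-mean Pearson r (as such figures are
usually drawn) and the raw per-window correlation; a constant response
returns r = 0 with a degenerate flag. Sweep intersection takes the
union of top-1% windows across reference comparisons and intersects it
with the top-5% of a second, independent score track.

## Mk model

The two-state continuous-time Markov chain (0 = self-compatible, 1 =
self-incompatible) uses closed-form 2x2 transition matrices,
Felsenstein pruning, and a root prior that defaults to the stationary
distribution (uniform optional). ML fits run L-BFGS-B on log-rates in
[1e-9, 1e3] with five starts around 1/tree-depth; the symmetric (1
parameter) and asymmetric (2 parameters) models are compared by a 1-df
LRT and AIC, with the nesting guarantee enforced (the asymmetric
likelihood is floored at the symmetric optimum). Marginal ancestral
probabilities use the standard up-down pass and are verified against
exhaustive enumeration over internal-state assignments. All tips in one
state flags the comparison degenerate. The null rejection rate of the
LRT is below nominal (boundary effects make the 1-df chi-square
conservative), which is the safe direction for claiming rate asymmetry.

## What passing tests do and do not show

The simulator's idealizations (free inter-window recombination, no
intra-window recombination, no selection, no error, equal sample sizes)
mean the suite demonstrates *estimator correctness and calibration
under the stated coalescent conditions*, not robustness to reference
bias, depth variation, or selection at linked sites. The retention
device produces the direction of the recombination-introgression
correlation by construction; the corresponding tests verify that the
pipeline recovers a planted signal, not that real genomes behave this
way. Problem sizes used throughout (150-5,000 windows, 2-4 diploids per
population, 25-200 replicates) were chosen as the smallest sizes at
which the tested properties are stable across seeds.
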