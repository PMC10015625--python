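# introland

Windowed introgression-landscape analysis for groups of closely related,
resequenced species — the kind of dataset where a handful of diploid
genomes per species are mapped to one reference, SNPs are called jointly,
and the questions are: *who exchanged genes with whom, how much of the
genome is introgressed, where does introgressed ancestry survive, and how
does that interact with recombination, differentiation and trait
evolution?*

The package bundles, behind one consistent window grid:

- **simcoal** — a multispecies-coalescent simulator (msprime) with dated
  admixture pulses, per-window recombination-rate covariates, optional
  recombination-dependent retention of introgressed ancestry, and full
  ground truth. Every statistical claim in the test suite is checked
  against data simulated here.
- **gio** — filtered VCF import (cyvcf2), outgroup polarization, 10 kb
  window tables, parsimony-informative-site filters, GFF3 gene density.
- **patstats** — ABBA-BABA machinery on derived-allele frequencies:
  the D statistic with block-jackknife significance and Benjamini-
  Hochberg correction, the conservative D_min over trio arrangements,
  the admixture-fraction estimator f_hom, windowed f_dM, putatively
  introgressed regions (pIRs), and the per-window introgression index.
- **dfoil** — five-taxon D_FOIL tests (DFO, DIL, DFI, DOL) whose joint
  sign pattern separates ancestral introgression from directional
  post-speciation gene flow, with the direction.
- **treekit** — neighbor-joining window trees, canonical topology IDs,
  Twisst-style topology weighting over taxon groups, topology counting,
  and normalized quartet scores of a species tree against gene trees.
- **landscape** — windowed Weir-Cockerham F_ST, top-quantile outlier
  indices, high/low-introgression and high-F_ST region classification,
  recombination quintiles, binned Pearson correlations, and sweep-track
  intersection.
- **traitmk** — two-state Mk ancestral-state reconstruction of a binary
  trait (self-incompatible vs self-compatible mating systems) on a dated
  tree, comparing symmetric and asymmetric transition rates by likelihood
  ratio and AIC.

## The statistics in brief

For a trio (P1, P2; P3) with outgroup O and derived frequencies
p1, p2, p3 per polarized site,

    ABBA = sum (1-p1) p2 p3        BABA = sum p1 (1-p2) p3
    D    = (ABBA - BABA) / (ABBA + BABA)

with Z and p from a delete-one block jackknife (20 contiguous site blocks
by default). The genome-wide admixture proportion is

    f_hom = S(P1, P2, P3, O) / S(P1, P3, P3, O),

the observed ABBA-BABA excess scaled by the excess under complete
homogenization of P2 by the donor; the squared donor frequency uses the
unbiased two-draw estimator so small donor samples do not deflate the
ratio. Windowed f_dM uses the symmetric dynamic-donor denominator and is
bounded in [-1, 1]; each trio's pIRs are its top 100·f_hom % f_dM
windows, and the introgression index of a window is the fraction of
significant trios calling it a pIR. D_FOIL forms four statistics from
frequency-weighted five-taxon site-pattern groups; each left/right group
pair is exchanged by a null symmetry of the species tree (P1↔P2 or
P3↔P4), and the signature of significant signs classifies the gene-flow
scenario. The Mk model is the standard 2-state CTMC with pruning
likelihoods, closed-form transition matrices, stationary (or uniform)
root prior and marginal ancestral reconstruction.

## Worked example

Simulate four species and an outgroup on the ladder tree
((((P1,P2),P3),P4),O) with a recent P3→P2 pulse of 15%, then run the full
scan:

```bash
introland run-all --outdir demo --seed 3 --n-windows 120
```

which prints (abridged):

```json
{
  "n_sites": 6830,
  "n_polarized_sites": 5949,
  "n_trios": 4,
  "n_significant_trios": 1,
  "region_counts": {"low_introgression": 104, "other": 10,
                    "high_introgression": 6},
  "main_topologies": [
    {"topology": "((((P1,P2),P3),P4),O);", "frequency": 0.3375},
    {"topology": "((((P1,P2),P4),P3),O);", "frequency": 0.13125}
  ]
}
```

Reading: of the four possible trios only the one containing the simulated
P3→P2 pulse passes the Benjamini-Hochberg gate (`n_significant_trios`);
its pIRs mark 6 of 120 windows as high-introgression regions; and the
generating species tree is the modal window topology (weighting 0.34)
despite heavy incomplete lineage sorting — the per-window trees disagree
with it two times out of three. Individual stages are available as
`introland simulate | filter | dstats | dfoil | weight | landscape | mk`,
and every stage is an importable function with the same defaults.

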