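# Methods

## Model of a multiclonal cell line

The package treats a cell line as a rooted clonal tree under the
infinite-sites assumption: every somatic mutation arises exactly once, on
one edge, and is never lost. The root is the wild-type (pre-neoplastic)
cell; the single edge below it carries the trunk mutations of the founder
("mother") clone; the mother's children are the diverging clonal lineages;
chained deeper nodes are later stages of a lineage. Consequences used
throughout:

- the carrier sets of any two mutations are nested or disjoint (a laminar
  family), which is what the four-gamete test checks pair by pair;
- a cell's genotype is the union of mutations on its root path;
- with universal heterozygosity and diploidy, a mutation carried by a
  fraction *f* of cells has bulk VAF *f*/2; trunk mutations have VAF 0.5.

Homozygous and CNV-affected sites are deliberately outside the generative
model (downstream parsers tolerate them; quantification excludes annotated
CNV sites by omission from the input): the single-cell-clone data this
workflow rests on showed wild-type alleles retained at every tested site.

## Tree reconstruction

`build_clonal_tree` implements the classic radix/laminar-family
construction. Pairwise relations between mutation columns are derived from
the gametes observed among complete cases: equal carrier sets merge onto
one edge, strict containment defines ancestry (the parent of an edge group
is its smallest strict superset), mutations with no observed absent call
form the trunk. Any pair exhibiting all three of (1,0), (0,1), (1,1) aborts
reconstruction with a `PhylogenyConflictError` carrying the full conflict
report. Clones are assigned to the node whose root-path mutation set is
consistent with their non-missing calls; with complete data this match is
exact and unique. A clone matching no node (or matching ambiguously under
missingness) is reported unassigned rather than forced to a nearest node —
forcing would hide assay error.

Missing calls: the default `strict` policy excludes missing entries from
carrier sets and pair tests; `impute-absent` treats missing as absent,
reading ARMS dropout as signal failure. Determinism: mutations are ordered
by (carrier count desc, mutation id asc) and nodes are named after their
representative mutation, so output is reproducible byte for byte.

Mutation classes: `private` (exactly one carrying clone) takes precedence;
otherwise `trunk` (mother edge), `lineage-defining` (edge below the
mother), `stage-specific` (deeper). Stage indices within a lineage are
ranks of distinct root-path mutation counts, so "early" clones are those
with fewer mutations.

## IGHV hypermutation and the subclone rule

Colonies are globally aligned to germline (affine gaps, free end gaps so
truncated amplicons align; Biopython `PairwiseAligner`). Only substitution
columns count: gap and N columns are excluded from both numerator and
denominator of the mutation level, and a colony covering under 50% of
germline is excluded as unalignable. The per-set mutation level is the
median across colonies (robust to PCR errors; the summary statistic is not
prescribed by the underlying assay convention), and a culture is
hypermutated when that level is strictly above 2%.

Substitutions are classed universal (all colonies), shared-subset (≥ 2 but
not all) or singleton (one colony — treated as a PCR artifact, which is
exactly the noise mode of colony sequencing: polymerase errors are private
to one molecule). Colonies group by their shared-subset signature; a
signature that is a strict subset of exactly one other merges into it
(earlier-stage molecules of the same lineage); a group supports a subclone
when its size strictly exceeds `min_support × n_colonies / n_reference`
(default: more than 3 per 10 sequenced, read literally from the strict
inequality; the inclusive variant is available by lowering `min_support`).

Primer margins: the `primer_margin` parameter can exclude primer-encoded
end positions from counting. The default is 0 — the mutation-level
arithmetic is then exactly |substitutions|/|evaluable columns| over the
full amplicon, which keeps worked examples auditable by hand; set 20 nt for
primer-masked amplicons.

## Variant consensus filtering

Two callers' records are matched on (chrom, pos, ref, alt); numeric fields
come from caller A. The four filters — depth > 20, alt fraction > 0.25,
consequence containing "missense", strand-bias statistic < 0.05 — are a
conjunction of strict inequalities, hence order-invariant and idempotent
(both property-tested). The 0.25 threshold is read as an alt-read
*fraction* (25%): a literal 0.25% cutoff would sit below exome noise and
contradicts selecting clonal heterozygous mutations, whose expected
fraction in a pure single-cell clone is ~0.5; the literal reading remains
selectable in `FilterConfig`. The strand-bias field is a configuration knob
(`SBP` INFO key by default) since callers encode it differently. Records
missing a needed annotation are dropped and counted `unannotated` rather
than silently passed.

## Lineage quantification

Per mutation, cell fraction = 2 × alt/depth. A lineage's point estimate
pools its lineage-defining-edge mutations by inverse-variance weights
(binomial variance of the doubled fraction, 4·v(1−v)/depth); Wilson 95%
intervals are computed on pooled read counts (the underlying assay reported
no uncertainty; the interval treatment is this package's addition).
Stage-specific mutations mark only part of a lineage, so they enter as
lower bounds — except when a lineage has *only* stage-level evidence, where
the bound doubles as a conservative point estimate. Determined estimates
are rescaled to sum to 1 (disable with `normalize=False` to inspect the raw
sum); lineages without usable mutations stay NaN. `ddct_fold_change`
computes 2^−((Ct_t−Ct_c)_sample − (Ct_t−Ct_c)_calibrator).

## Bimodality and sort stability

Intensities are fitted on the log scale (flow-cytometry convention;
non-positive values are shifted by a pseudo-offset before the log). The
verdict requires all three of: ΔBIC = BIC(1-comp) − BIC(2-comp) ≥ 10
(strong evidence on the Bayes-factor scale), Ashman's
D = √2·|μ₁−μ₂|/√(σ₁²+σ₂²) ≥ 2 (clearly separated modes), and both mixture
weights ≥ 0.05 (a sub-5% mode is indistinguishable from staining noise).
These thresholds operationalize what a cytometrist calls a double peak by
eye; all are configurable. EM uses 5 fixed-seed starts. Measured on 400
seeded samples of 1000 cells each, the detector's false-bimodal rate on
unimodal Gaussians and its miss rate at D = 3 with a 30% minority mode are
both 0 (asserted at ≤ 5% type-I and ≥ 95% power in the test suite).

Sort-and-regrow: the simulator advances a sorted population in discrete
generation steps (convention: 1 step ≈ 1 day, so the 1–2 week regrowth
window of a sorting experiment is 7–14 steps). Under the subclone model
the latent mode is heritable; under the activation model each cell re-draws
its state from Bernoulli(π) with probability *s* per step, giving the
two-state Markov closed form fₖ = π + (1−π)(1−s)ᵏ for the sorted-mode
fraction, which the simulator matches within Monte-Carlo error (tested).
`classify_stability` calls "activation" when the minority-mode fraction at
the final step exceeds 0.15 — the population has visibly regained its
second mode — and "subclone" otherwise; s = 0 makes the two models
coincide, and the classifier agrees.

## Omics concordance

Clones are clustered hierarchically (average linkage, correlation distance
— the standard choice for expression arrays) and cut at the known lineage
count when labels are provided, otherwise at the silhouette-best k ∈ 2..6;
agreement is the adjusted Rand index. Per-gene lineage specificity is the
max between-lineage mean difference standardized by pooled within-lineage
SD. The methylation flag requires Pearson r ≤ −0.7 between beta and
expression across ≥ 4 clones *and* an expression dynamic range above 1.0
(log units): a strong negative correlation on a flat gene is noise, not
regulation.

## Synthetic-data generator: what it emulates and what it does not

Defaults encode the three-lineage study scenario: 60 single-cell clones, a
dominant lineage at 50% with two minor lineages at 25% each, one of which
carries a deeper late stage; 10 sequenced IG colonies; bulk depth 2000;
stage proportions uniform within a lineage. All draws flow from one numpy
`default_rng(seed)`, so outputs are bit-identical across runs.

Real data differ in ways the generator deliberately omits: no read-level
sequencing error or mapping artifacts (genotypes are sampled directly), no
CNV or homozygosity, no doublets or cross-contamination, no indels in IG
sequences, no batch effects in the omics matrices, and marker intensities
are clean two-Gaussian mixtures without autofluorescence tails or
compensation spill. Passing tests therefore demonstrate correctness of the
*inference rules* under their stated assumptions, not robustness to every
artifact of wet-lab data; the unassigned-clone and conflict-report paths
exist precisely to surface assumption violations on real inputs.

## Problem sizes and numerical choices

Test and acceptance runs use the study-scale sizes throughout (60 clones ×
9-site-scale matrices, 10–20 colonies, depth 2000, 400 seeded samples per
detector error-rate estimate, 500 bulk replicates for estimator bias) —
these match the data volumes the workflow targets, and the exhaustive
perfect-phylogeny oracle enumerates all 4096 3×4 binary matrices plus 300
random 8×6 matrices. Tolerances: simplex sums to 1 within 1e-9; Monte-Carlo
assertions use 2–3 standard errors; EM is seeded and multi-started;
zero-variance inputs short-circuit to "unimodal"/"not evaluable" rather
than fitting degenerate models.

## Known limitations

- Perfect phylogeny is exact but brittle: one genotyping error at an
  informative site aborts with a conflict report instead of producing a
  tree; there is no probabilistic error model (by design — out of scope).
- Under heavy dropout the `strict` policy can leave many clones unassigned;
  `impute-absent` trades that for a bias toward absence.
- Quantification assumes diploid heterozygous sites; CNV-overlapping
  markers must be excluded by the user.
- The subclone rule's support threshold generalizes the more-than-3-in-10
  reading proportionally; very small colony counts (< 5) carry little
  power either way.
- Cross-contamination as a cause of bimodal markers is not modeled; the
  stability classifier only separates heritable subclones from transient
  activation.
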