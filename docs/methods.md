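# Methods

This note records the models, parameter choices and numerical decisions
behind `clonetrace`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Allele-frequency correction

The correction model assumes each somatic mutation is heterozygous on a
single copy in an otherwise diploid background, and that any copy-number
aberration affects the mutated allele "to the largest extent": a gain
duplicates the mutated copy, a loss removes the reference copy. The four
count-correction rules (AMP: Alt'=Alt/2; DEL: Ref'=Ref+Alt; CN-LOH:
Ref'=Ref+Alt/2, Alt'=Alt/2; male X: Ref'=Ref·2+Alt) follow from that
assumption. Adjusted counts are exact rationals (`fractions.Fraction`) so
halving odd counts loses nothing; only the final frequency is a float.

Purity correction divides the adjusted VAF by the histology-estimated
tumor content and caps at 1 (flag `CAPPED`). This is the simplest scale
correction; a cellular-prevalence transform that models purity jointly
with copy number would differ for subclonal mutations in aberrant
regions. Relatedly, the AMP/DEL rules invert the forward model exactly
only for mutations clonal within the tumor; NEUTRAL and CN-LOH invert
exactly at any subclonal proportion (the aberration rescales both alleles
symmetrically). The inversion tests assert exactly that identity and no
more. Reports expose both `corrected_vaf` and
`cellular_proportion = min(2·corrected_vaf, 1)` so the factor-of-two
convention is always explicit; clustering uses `corrected_vaf`.

Rule precedence on the male X: the hemizygous rule replaces the segment
rule (no composed formula is defined); X variants inside a non-neutral
segment are flagged `AMBIGUOUS`. X variants with unknown patient sex, and
all Y/MT variants, are excluded with a per-variant reason rather than
guessed at.

## Copy-state calling

Classification uses two observed-scale statistics per segment or arm:
mean folded BAF deviation `mean(|BAF − 0.5|)` over het SNPs, and mean
coverage relative to a genome-wide baseline. Defaults:
`baf_dev_min = 0.10`, `cov_gain_min = 1.15`, `cov_loss_max = 0.85`,
`min_snps = 10`, arm majority 80% of callable length. Fixed thresholds
replace an unspecified "significant change" test: they are reproducible,
config-exposed, and adequate for arm-scale events. Purity attenuates both
statistics (at purity π an AMP arm sits at BAF deviation
`(1+π)/(2(2+π))·2 − ...` ≈ 0.13 and coverage ratio `(2+π)/2` ≈ 1.35 for
π = 0.7), so with the default thresholds calls are reliable for π ≳ 0.5;
below that the BAF gate fails first and arms degrade to NEUTRAL, never to
a wrong aberrant state. Classification runs on observed values without
purity back-correction. Segmentation is not performed; segments come from
input tables or fixed GRCh37 arm boundaries (packaged table of
chromosome lengths and approximate centromere midpoints — arm
aggregation only, not breakpoint-accurate).

## EM clustering

A diagonal-covariance Gaussian mixture on the 2-D corrected-VAF
coordinates of a lesion pair, fit by standard EM: k-means++ seeding from
an explicit seed, log-sum-exp E step, variance floor 1e-5, convergence
when the log-likelihood improves by less than 1e-8 (trace recorded;
monotonicity is asserted in tests to a relative 1e-6). Model selection is
BIC over k = 1..6 with 5 restarts per k, `p = k(2d+1) − 1` free
parameters. Mutations absent from one lesion but covered there sit at
coordinate 0 — they are the signal for lost/emergent clones — and are
dropped only when a per-site depth map shows < 10× coverage. Clusters are
re-indexed by lexicographically sorted centers for cross-seed stability;
posterior ties break toward the lower index. All-identical inputs return
a single `DEGENERATE` component. The resolution limit is real: planted
centers ~0.005 apart collapse to one component, and the tests document
this. Gaussian components on frequencies (rather than binomial mixtures)
mean very low-depth samples are under-modelled; at WES depths ≥ ~60× the
normal approximation is adequate.

For patients with more than two lesions, every later lesion is paired
with the first (the primary when available) plus consecutive metastasis
pairs.

## Clone fates and reporting

Fate is a pure function of per-lesion presence flags
(center coordinate ≥ `presence_min = 0.05`): both → MAINTAINED, earlier
only → LOST, later only → EMERGENT. A cluster below the floor in both
lesions (possible noise artifact) is assigned LOST or EMERGENT by its
larger coordinate so fates always partition the k components. Whether a
lost cluster reflects therapy-driven elimination, dormancy, or sampling
is left to the analyst: the report carries interval-therapy flags next to
the quantitative fates and never infers causality. Driver presence uses
alt reads ≥ 3 and VAF ≥ 2% on non-silent variants, a floor matched to
ultra-deep targeted sensitivity; hypermutation is ≥ 1000 exonic
mutations. All thresholds live in one `PipelineThresholds` namespace and
are recorded in every run manifest.

## Signature refitting

Profiles are 96-bin counts in the canonical pyrimidine-frame ordering
(substitution class, then 5' base, then 3' base); purine-reference
records are reverse-complemented, malformed records are counted as
invalid rather than dropped. Exposures are nonnegative-least-squares
weights of the normalized profile on the reference columns, iteratively
discarding signatures below `min_weight = 0.06` and refitting until
stable, then renormalizing to sum ≤ 1. Profiles under 20 mutations are
flagged `LOW_COUNT`. The packaged synthetic signatures (random sparse
distributions, optionally with disjoint support) exist for tests and
simulations only; real reference matrices (e.g. COSMIC) are user-supplied
input.

## Synthetic data: what it does and does not emulate

The generator draws, per mutation and lesion, depth ~
Poisson(assay mean × locus coverage ratio) and alt reads ~
Binomial(depth, v) with
`v = π·p·m / (π·C + 2(1−π))`, where (C, m) is (2,1) NEUTRAL, (3,2) AMP,
(1,1) DEL, (2,2) CN-LOH — the same largest-extent convention the
corrector assumes, so the two are mutually consistent by construction
(`amp_on_mutated_allele=False` switches AMP to (3,1) for robustness
checks). Het SNPs share loci and B-allele homolog assignments across
lesions, with B fractions and coverage implied by the same copy states.
Defaults mirror the study conditions: WES depth 95×, targeted depth
25000×, purities 0.3–0.8 (0.6/0.55 in the canonical scenario), 200 het
SNPs per arm, clone trees validated for nesting consistency.

Not emulated: sequencing error and mapping artifacts, FFPE damage,
subclonal or focal CNAs, multi-region heterogeneity within one lesion,
germline contamination of somatic calls, and overdispersion beyond
Poisson/binomial. Passing recovery tests therefore demonstrate the
correctness of the inference machinery under the stated model, not
robustness to every artifact of real FFPE exome data.

## Problem sizes in tests and the acceptance script

The canonical clustering scenario uses 100 mutations per clone at 100×
across 10 seeds; arm recovery uses 200 SNPs/arm at 60×, purity 0.7,
across 20 seeds; signature recovery uses 1000 draws from a 0.6/0.4
two-signature mixture; EM monotonicity uses 100 random fixtures; the
rule oracle is exhaustive over all read-count pairs up to depth 200.
These sizes match the per-lesion mutation counts and depths the pipeline
targets while keeping the full suite under a minute of compute.

## Known limitations

- Purity is an input (histology), never estimated from data; a biased
  estimate biases every cellular proportion linearly.
- No mutation-multiplicity estimation: a clonal mutation on both copies
  of a neutral region will appear at proportion > 1 and be capped.
- Arm-level CNA only; focal events inside an arm dilute into the arm
  average and can be missed.
- 2-D pairwise clustering does not enforce consistency across the pairs
  of a multi-lesion patient; no phylogeny is reconstructed.
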