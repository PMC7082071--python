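# Methods

## The discovery problem

In a closed breed, a fully recessive disease allele sits on a haplotype
that may be much older than the mutation itself. Every affected animal is
then homozygous not only for the causal allele but for the whole segment
and every old variant riding on it, while some healthy animals are
homozygous for the segment *without* the causal allele. Case/control
filtering alone therefore yields a list of candidates that all "associate"
with the disease at incomplete penetrance. The decisive observation is an
obligate carrier: an unaffected parent of a case must be heterozygous for
the causal allele, but can be (and in the motivating scenario is)
homozygous for the old passengers. `homrec` encodes this chain of
reasoning as a pipeline with testable stages.

## Association scan

* **Statistic.** The 2×2 allelic χ² on alternate/reference allele counts,
  1 df, no continuity correction: χ² = N(ad−bc)²/(r₁r₂c₁c₂). This choice is
  pinned down by the published segregation p-values it must reproduce from
  genotype counts (1.6×10⁻¹³ from controls 41/22/4 and 4.0×10⁻²⁵ from
  58/9/0 against 12 homozygous cases); the Yates-corrected variant does
  not reproduce them. Monomorphic tables return χ² = 0, p = 1.
* **Allele counting.** Per sample and marker, alternate count =
  dosage × ploidy/2 and total = ploidy, so hemizygous males (ploidy 1 on X,
  dosage stored as 0/2) contribute exactly one allele. Missing dosages are
  excluded marker-wise.
* **QC.** Filters apply in the fixed order call-rate → MAF → HWE so that
  each removed marker is attributed to exactly one filter. Defaults:
  call rate ≥ 0.95, MAF ≥ 0.05, HWE exact p ≥ 10⁻⁴ computed in controls
  only (the common GWAS practice) and over diploid samples only. The HWE
  exact test uses the standard conditional distribution of the heterozygote
  count given the allele counts, evaluated by the mid-point recurrence;
  the p-value sums all outcomes no more probable than the observed one.
* **Permutation.** Max-T: case/control labels are permuted among the
  included samples while sex (and hence X ploidy) stays with the sample.
  p_point = (r+1)/(n+1) against the marker's own permutation distribution;
  p_genome uses the per-permutation maximum statistic, giving
  p_genome ≥ p_point ≥ 1/(n_perm+1) by construction. An exhaustive mode
  enumerates all label assignments for tiny cohorts (used by tests as the
  oracle comparison). The field-standard 100,000 permutations is a flag;
  examples and tests use 50–4,000 to keep runtimes in seconds.
* **Genomic control.** λ = median(χ²)/0.4549 (the 1-df χ² median);
  adjusted p-values divide χ² by max(λ, 1).

## Critical-region delimitation

Block extension starts at an anchor (by default the top association
marker; if the cases are not homozygous-concordant there — the signal can
peak just outside the shared segment — the pipeline walks down the χ²
ranking until the anchor precondition holds and logs the substitution).
Extension proceeds marker-by-marker in both directions while every case is
homozygous, or hemizygous on the male X, for the same allele, and stops
*before* the first discordant marker: the reported bounds are the
positions of the outermost concordant markers, matching the convention of
reporting SNP positions rather than midpoints. Missing genotypes do not
break extension by default (array missingness should not truncate a true
block); a strict mode requires complete data. Spans are reported in Mb
rounded half-up to one decimal: (end − start + 1)/10⁶.

Carrier classification against the block pattern is exact for unphased
data in one direction: a sample opposite-homozygous at any block marker
carries zero copies of the risk haplotype (`non_carrier`); a sample
matching homozygously everywhere is `risk_homozygous`; anything else
(heterozygous somewhere, never opposite-homozygous) is compatible with one
copy and labelled `heterozygous_or_partial`.

## Recessive filtering and carrier refinement

A variant survives when (a) every case is homozygous alternate, (b) no
control is homozygous alternate (unless explicitly allowed), (c) the
heterozygous-control count is ≤ max_control_het_frac × n_controls as a
strict real-valued bound (1 het of 100 controls passes 1%; 2 do not), and
(d) it lies in the critical region when one is supplied. A missing case
genotype fails the variant by default (a case not demonstrably homozygous
cannot support the recessive model); `exclude_sample` relaxes this for
sparse data.

The library default (1% hets, no hom-alt controls) models filtering
against an *external* control panel that does not segregate the risk
haplotype. The discovery pipeline's default is deliberately looser
(hom-alt controls allowed, het fraction ≤ 0.5) because inside the breed
cohort unaffected haplotype homozygotes and heterozygous carriers — the
obligate carrier among them — are expected and informative; the carrier
constraint and the segregation ranking, not the control counts, do the
discrimination there. Obligate carriers must be heterozygous; a missing
carrier genotype keeps the variant with a warning (configurable to drop).

Penetrance is the affected fraction of all alternate homozygotes with
known phenotype, undefined (flagged, not erroring) when no homozygote
exists. Candidates are ranked by segregation p ascending, ties broken by
penetrance (complete first) then position; the winner's report includes
the p-ratio to the runner-up, the "N times stronger association" figure.

## Motif scanning

JASPAR PFMs are parsed label-driven (rows in any order; bare rows assumed
A,C,G,T), then converted to log₂-odds with a background-distributed
pseudocount: p = (count + pc·bg)/(colsum + pc), default pc = 0.8 and
uniform background — the defaults of the common R scanning tools, both
configurable. Relative score normalizes a window's score between the
matrix minimum and maximum; the default reporting threshold is 0.8, the
convention of those tools (the source analysis does not state one).
Promoter windows are TSS ± 500 bp (1-based inclusive), reverse-complemented
for minus-strand genes and clipped (with a flag) at contig ends. Windows
containing N are skipped rather than scored against background — a
conservative choice. Strand symmetry (the minus-strand score at an offset
equals the plus-strand score of the reverse complement) is exact because
the minus scan uses the row- and column-reversed matrix. Target genes are
ranked by best relative score but gated on mean expression in the target
tissue: a perfect motif in a silent gene cannot mediate the phenotype.

## Assay statistics

* **Efficiency.** Ct regressed on log₁₀ template; E = 10^(−1/slope); a
  non-negative slope flags an invalid assay.
* **ΔΔCT.** Technical replicates averaged arithmetically per (gene,
  sample); multiple reference genes combined by the arithmetic mean of
  their Cts (equivalently the geometric mean of linear quantities — the
  combination rule is not standardized, this is the simplest consistent
  one). ΔCT = target − reference per sample; ΔΔCT = mean ΔCT(case) −
  mean ΔCT(control); fold = 2^(−ΔΔCT). Error bars are per-group SDs of
  ΔCT. An efficiency-corrected mode (fold = E_t^(−ΔCt_t)/Ē_ref^(−ΔCt_ref),
  Pfaffl-style) sits behind a flag; the classic 2^(−ΔΔCT) is the default
  because measured efficiencies near 2 make the two indistinguishable in
  practice.
* **Group tests.** Welch's two-sided t on ΔCT (the group test is not named
  in the motivating analysis; Welch is the robust default). Degenerate
  identical groups return p = 1. Luciferase ratios are compared with
  one-way ANOVA and all pairwise Welch t-tests multiplied by the number of
  pairs (Bonferroni), capped at 1. Assay repetitions are analyzed per run,
  never pooled across runs.

## The synthetic cohort generator

`simulate_breed_population` is a founder-haplotype pool model with random
union of gametes — deliberately *not* a coalescent or pedigree-recombination
simulator, because the single structure the analysis exploits is the
discordance between an old segment and a young allele, which the pool model
creates directly and controllably:

* Per chromosome, 30 founder haplotypes drawn per-marker from MAF ~
  U(0.05, 0.5); markers at uniform random positions (defaults: 500 on two
  autosome-scale chromosomes of 120/64 Mb, 250 on a 124 Mb X).
* Founder 0 donates the **risk segment** (default 0.2–7.4 Mb on
  chromosome "15", i.e. ~7.2 Mb): any gamete drawn as a risk copy
  (probability `risk_hap_freq`, default 0.15) carries founder 0's alleles
  across the segment and a random founder's elsewhere. Optional
  recombination (off by default) mosaics two founders per gamete.
* Four **decoy variants** sit on *every* risk copy; the **causal variant**
  (default at 1.43 Mb) on a `recent_fraction` (default 0.6) Bernoulli
  subset of them — decoys are therefore always at least as common among
  homozygotes as the causal allele, and with recent_fraction < 1 the
  generator retries (bounded) until at least one control is risk-homozygous
  without the causal allele, reporting failure in the truth record
  otherwise. Twenty unlinked background variants at random population
  frequencies give the filters something to reject.
* Phenotypes are fully penetrant: causal homozygote ⇒ type-1 case; an
  independent X-linked risk segment (hemizygous males / homozygous
  females) ⇒ type-2 case; phenocopies (default rate 0) present as type-2,
  never type-1, so the truth invariant "every type-1 case is causal-
  homozygous" holds unconditionally. Cohort sizes default to the
  discovery-cohort conditions: 12 type-1 cases, 6 type-2 cases, 67
  controls.
* The **obligate carrier** is constructed, not rejection-sampled: a
  control attached in the pedigree as the dam of the first case, with one
  risk+causal haplotype and (when recent_fraction < 1) one old risk
  haplotype without the causal allele — heterozygous for the causal
  variant, homozygous for every decoy.
* Genotypes get i.i.d. missingness at rate 0.005; male X calls are stored
  at dosage 0/2 (ploidy 1). A fixed config (seed included) is
  byte-deterministic.

**What the generator does not emulate:** linkage-disequilibrium decay,
mutation-age and recombination-clock structure, relatedness beyond the one
constructed parent link, genotyping batch effects, multi-breed control
panels, and variant-calling artifacts. Passing recovery tests therefore
demonstrates the *logic* of the pipeline — that the carrier constraint
separates a recent causal allele from old passengers under realistic
frequencies and cohort sizes — not robustness to real-data noise sources.

## Numerical and interface choices

* Coordinates are 1-based inclusive everywhere; the only half-open 0-based
  output is BED.
* Dosage counts copies of the marker map's allele_b. A 4-column PLINK .map
  carries no allele labels, so on reading, allele order is taken in order
  of first appearance in the .ped unless pinned explicitly — orientation
  does not affect any downstream statistic (χ², homozygosity, HWE are
  orientation-symmetric), and exact dosage round-trips pin the order.
* Missing genotypes use a single sentinel (−1) distinct from 0; every
  counting routine states its missing-data handling.
* Heterozygous male-X calls in input are set missing and *counted* in a
  returned tally rather than silently dropped, so QC problems surface.
* Empirical p-values use (r+1)/(n+1), never 0.
* Reports contain no timestamps (logs do), so identical config + seed
  gives byte-identical outputs; every output file carries the package
  version, seed and a config hash.
* Test and acceptance problem sizes (10,000 null markers; 20 simulated
  cohorts of ~1,250 markers × 86 dogs; 50–4,000 permutations) were chosen
  as the smallest sizes at which the calibration and recovery claims are
  statistically meaningful; all complete in seconds.

## Known limitations

Single-threaded by design (results must not depend on parallelism). No
mixed-model or relatedness-corrected association; no phasing or IBD
inference — the block detector assumes homozygosity-by-descent is visible
directly in unphased genotypes, which holds for recent recessive disease
in closed breeds but not in outbred populations. The multi-breed
filtering-panel structure of real studies is reduced to a single control
set; printed genome-scale figures that depend on the original array/WGS
data (total SNP counts, specific λ values, genome-wide hit counts) are
represented by calibration and recovery properties rather than numeric
reproduction.
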