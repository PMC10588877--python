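# Methods

## The biallelic alloantigen model

The package models a hypothesized maternal-fetal alloimmune disease
mechanism at a single autosomal biallelic locus. Let `q` be the population
frequency of the minor allele and `P = 1 - q` the major-allele frequency,
with genotypes at Hardy-Weinberg proportions (`P²`, `2Pq`, `q²`). A mother
homozygous for the minor allele does not express the major-allele antigen
and can become immunized against it; a fetus expresses the antigen — and is
at risk — iff it inherits the major allele from the father. An at-risk
fetus manifests disease with probability `penetrance` (default 1.0, the
assumption under which the headline numbers are derived; an 80–95%
epidemiological recurrence range can alternatively be absorbed into
`penetrance < 1`, a choice the model leaves to the caller).

Quantities implemented in `alloscreen.model`:

- **Incompatibility probability** `p²(1 − p)`: the chance that a random
  couple presents the incompatible constellation (mother homozygous for an
  allele at frequency `p`, fetus carrying the contrasting allele). Zero at
  both endpoints, maximal at `p = 2/3` (value 4/27).
- **Recurrence, random father** `penetrance · P`: each pregnancy draws one
  paternal allele from the population. This is the mapping used to read a
  minor-allele frequency off an observed recurrence rate (95% recurrence ↔
  q = 0.05; q = 0.30 ↔ 70% recurrence).
- **Recurrence, same father given an index case**
  `penetrance · (P + q/2)`: the father's genotype distribution is updated
  by the fact that he has already fathered one affected child (posterior
  weights `P²·1` and `2Pq·½` for hom-major and het), then the
  next-pregnancy risk is averaged over it. Conditioning can only raise the
  risk, so this always dominates the random-father value. The random-father
  scheme is the default and is what all headline-number checks use; the
  same-father variant documents the subtlety that the population-level
  mapping ignores ascertainment.
- **Library clone number** `ceil(ln(1−P_detect) / ln(1−f))`: clones to
  screen to find a target of abundance `f` with probability `P_detect`
  (460,515 at `P=0.99`, `f=10⁻⁵`). A count of physical clones must be a
  positive integer, hence the ceiling and the convention that `f = 1`
  returns 1.

`invert_recurrence` solves the recurrence mapping for `q` by bracketed
root-finding (Brent, tolerance 1e-12) rather than the closed form, so it
works for either mating scheme unchanged.

## The cohort simulator

`alloscreen.simulate` emulates an affected-family sequencing cohort:
couples (optionally some mother-only families), each family ascertained
because the mother has had at least one affected pregnancy. Defaults follow
a genome-cohort design of 26 families of which 4 lack the father (26 women,
22 men), no genotyped children unless overridden per family, 5,000
independent background variants with ALT frequencies uniform on
(0.01, 0.99), and a 2% missing-call rate. Background genotypes are
Hardy-Weinberg draws (binomial(2, AF)); children receive one allele from
each parent uniformly at random; there is no linkage disequilibrium, no
genotyping-error model beyond missingness, and no sex chromosomes.
Consequence classes are simulator-assigned labels with a rough coding
spectrum (40% missense, 30% synonymous, 12% other, 6% each frameshift /
splice loss / in-frame indel); no annotation tool runs.

The **planted causal locus** realises the alloantigen hypothesis: every
mother is homozygous-minor; fathers are forced homozygous-major
(`force_father_hom_major`) or drawn from the ascertainment-conditioned
Hardy-Weinberg posterior. Conditioning multiplies each paternal genotype's
prior weight by its major-allele transmission probability (1, ½, 0) once
per affected pregnancy: one for the index case
(`ascertain_index_case=True`) and one per genotyped child when children are
modelled as affected subsequent pregnancies (`children_affected=True`,
the default — a family reaches a sequencing study because the disease
recurred). An affected child necessarily received the paternal major
allele, so every genotyped affected child of a hom-minor mother is
heterozygous. Missing calls are never placed on mothers at the planted
locus (their homozygosity is the ascertained fact the cohort is built on).

In simulated VCFs the planted minor allele is encoded as ALT, but the
screens never rely on encoding: `shuffle_ref_alt` re-encodes a random half
of all variants with REF/ALT swapped and the AF re-expressed, and the
orientation-invariance tests require identical screen output. The one
genuinely ambiguous case is an AF of exactly 0.5, where the minor allele is
undefined and the tie-break (ALT-as-minor) is a convention; continuous AF
draws make this a measure-zero event.

`simulate_pregnancies` is the forward model for recurrence: one paternal
allele per pregnancy, at-risk iff it is the major allele, affected with
probability `penetrance`. With `father_genotype=None` each pregnancy draws
a fresh Hardy-Weinberg father, which reproduces the random-father closed
form at large n (the tie between the simulator and the model that the
acceptance checks exercise at n = 100,000).

## The screens

All screens operate on minor-allele dosages derived per variant from the
population AF annotation (sidecar TSV takes precedence over INFO/AF).
Multiallelic records are split into biallelic records on read, with
per-sample dosages recomputed per ALT.

- **Couple incompatibility filter**: a variant survives iff in every family
  where both parents are called, the mother is homozygous-minor, the father
  homozygous-major, and (when `require_child_het`, the default) every
  called child heterozygous; the consequence class must be protein-altering
  (`allowed_consequences`). Families with a missing parental call neither
  support nor veto; they are counted, and candidates carry both the
  supporting-family list and an `all_families_support` flag so a caller can
  impose the stricter all-families rule. At least one supporting family is
  required.
- **Cohort homozygous screen**: variants with population minor-AF < 10%
  (configurable), consequence in {missense} ∪ {frameshift, splice loss}
  (LoF-only mode available), at which at least one case mother is
  homozygous-minor. Variants without an AF annotation fail the AF stage —
  a conservative choice for a screen whose point is rarity.
- **Gene recurrence**: from the homozygous screen's candidates, a gene is
  flagged when the identical coordinate or the identical amino-acid change
  is carried homozygous by ≥ 3 distinct women (configurable, minimum 2).
- **Trio screens**: per genotyped child — *de novo*: the child carries an
  allele absent from the mother's call and, when the father is called, from
  his; *recessive-hom*: child homozygous-minor with minor-AF < 2%;
  *compound-het*: ≥ 2 distinct rare (< 2%) heterozygous variants in one
  gene with, when both parents are genotyped, at least one variant
  attributable to each parent. Phase is not inferred: a variant carried by
  both parents may count for either side, and candidates carry
  `phase_known=False` unless a strictly-maternal and a strictly-paternal
  variant coexist; with an ungenotyped parent the rule degrades to
  "≥ 2 rare hets in one gene". All three sets are restricted to
  protein-altering consequences; the MAF bound applies to the recessive
  classes only, matching the thresholds as stated for each class.
- **Sex-stratified counts and exclusion**: genotype tallies
  (hom-minor / het / hom-major / missing) computed separately for the
  pedigree's men (fathers), women (mothers) and children. A candidate is
  EXCLUDED by the deterministic contradiction rule — any man in an affected
  family homozygous for the putative maternal minor allele could not have
  transmitted the contrasting major allele — and RETAINED otherwise. The
  two-sided Fisher exact p-value on hom-minor versus rest between the sexes
  is reported as description, never as the decision.

Stage counts along each filter cascade are monotone non-increasing, and an
empty candidate list is a valid screen outcome. Every filter is checked
against an exhaustive brute-force re-evaluation of its predicate on
randomized small cohorts (≤ 20 variants × ≤ 5 families, 120 seeds).

## Screen power

`screen_power` estimates the probability that the planted causal variant
survives the couple filter: each replicate simulates a cohort of couples
with one genotyped affected child per family (index-case ascertainment on),
runs the filter, and scores retention. Retention requires every father to
be homozygous-major; under the two-conditioning-events design the
per-family probability is `P² / (P² + 2Pq·¼) = P/(P + q/2)`, so e.g.
(2/3)⁵ ≈ 0.132 at q = 0.5 with five families (`analytic_couple_power`).
Power decreases in `q` — the quantitative form of the argument that only a
mother homozygous for a *rare* allele is compatible with a rare disease
recurring in nearly every pregnancy. The Monte-Carlo standard error
`sqrt(p(1−p)/n)` is reported alongside; all replicates derive their seeds
from one `SeedSequence`, so results are reproducible bit-for-bit.

## What passing tests do and do not show

The simulator realises the model's own assumptions (independent sites, HWE,
Mendelian transmission, simulator-assigned annotations, missingness
completely at random). Passing screens on simulated cohorts therefore
demonstrates correctness of the filtering logic and the model arithmetic,
not robustness to the pathologies of real sequencing data: genotyping
error, population stratification and relatedness, AF misannotation,
multi-nucleotide variants, or phasing errors are all out of scope. Problem
sizes in the test and acceptance runs (cohorts of ≤ 26 families, thousands
of background variants, 10⁵ simulated pregnancies, 10³ power replicates)
were chosen as the smallest sizes at which the Monte-Carlo checks have the
stated 3-standard-error resolution.
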