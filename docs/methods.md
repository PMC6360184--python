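# Methods

`famvar` implements the discovery workflow used when a multiplex disease
family is exome-sequenced alongside a sporadic case cohort and in-house
control exomes: prioritize family variants through a filtering cascade under
a dominant model, confirm cosegregation (inferring genotypes for deceased
relatives), test candidate-gene variants for allelic association in the
sporadic cohort, test region-restricted rare-variant burden, and summarize
tissue expression specificity. This note records the models, the defaults
and their rationale, the numerical choices, and the limitations — in
particular what the synthetic generators do and do not emulate.

## The filtering cascade

Input is a multi-sample VCF, a 6-column PED pedigree, a per-variant
annotation table and a BED file of linkage regions. Stages run in a fixed
order and each variant's fate is recorded once in an audit trail:

1. **Consequence** — keep nonsynonymous SNVs, splice-site variants,
   stop-gains and coding indels; drop synonymous and noncoding variants.
2. **Database membership** — three nested stages (dbSNP 135; + 1000
   Genomes; + NHLBI ESP) plus an optional fourth adding non-psychiatric
   ExAC. A variant is kept only if absent from every database of the
   stage. A variant with no annotation record is treated as novel and
   logged at WARN: the discovery intent argues for keeping it, the logging
   guards against silently inflated candidate lists.
3. **Segregation (dominant, full penetrance)** — keep variants heterozygous
   in every listed affected individual and homozygous-reference in every
   listed unaffected individual. Homozygous-alternate calls fail the rule:
   a fully penetrant dominant variant segregating from one ancestor is
   expected in single copy. A missing call removes the variant
   (conservative default; `missing_genotype_compatible=True` inverts this
   for sparser call sets).
4. **Control frequency** — keep variants with in-house control MAF at or
   under the threshold (default 1%, inclusive; the comparator is
   configurable because "≤ 1%" and "< 1%" both circulate as conventions).
   The subset never observed in controls (MAF 0 or missing) is tracked
   separately and is the default survivor set for the final stages.
5. **Predictor consensus** — under the default `all_three` rule a variant
   needs a deleterious/damaging call from each of PROVEAN, SIFT and
   PolyPhen-2, with no missing call ("predicted deleterious by all three"
   requires three calls). `any` and `majority` are available.
6. **Linkage intersection** — keep variants whose position falls inside a
   previously reported linkage interval. VCF positions are 1-based; BED
   intervals 0-based half-open; the conversion happens only here.

Stage counts per column (each affected exome, shared-by-affected, shared
het under the MAF cut, shared het absent from controls) are non-increasing
down the cascade by construction, which the result object can assert.

## Genotype inference for untyped relatives

For an untyped individual the package applies the classic obligate-carrier
deduction under two explicit assumptions: no de novo events at the site,
and the rare allele enters a nuclear family through at most one parent. A
child heterozygous for the allele while the typed co-parent is
homozygous-reference makes the untyped parent an **obligate heterozygote**
(`inferred_het`); this deduction is exact for a rare allele and is the one
case the workflow relies on. If every child is typed homozygous-reference
and a spouse is typed, the individual is called `inferred_noncarrier`;
anything else is `indeterminate`. Trio patterns impossible under the
assumptions (a carrier child of two typed homozygous-reference parents, a
homozygous-alternate child with a homozygous-reference co-parent) raise a
Mendelian-inconsistency error rather than silently producing an inference.

Two limitations are worth stating plainly. The non-carrier call is a
deterministic convention, not a proof: a heterozygous parent transmits to
none of *k* typed children with probability 2⁻ᵏ, so on random data a small,
quantifiable fraction of non-carrier inferences are wrong (the property
tests characterize exactly this error mode). And for a *common* allele the
obligate-carrier deduction guarantees carrier status but not heterozygosity
— the parent could be homozygous-alternate. Probabilistic (likelihood)
imputation, reduced penetrance and phenocopies are out of scope.

The cosegregation verdict is separate from inference: true iff every
affected individual is heterozygous (typed or inferred) and every typed
unaffected individual is homozygous-reference. Untyped unaffected members
are skipped with a warning; an affected member whose genotype cannot be
established fails the verdict with reason "insufficient genotypes"; a
pedigree with no affected members fails explicitly.

## Allelic association

Genotype count triplets (n_MM/n_Mm/n_mm per cohort) are converted to allele
counts (minor = n_Mm + 2·n_mm, total = 2·N). Non-NA control cohorts are
pooled element-wise; the 2×2 table is oriented to the minor allele decided
from the pooled case+control counts, which keeps reported MAFs in [0, ½]
and makes the orientation deterministic and symmetric.

The two-sided Fisher exact p-value follows the point-probability
convention: the sum over the hypergeometric support of all point
probabilities not exceeding the observed one. Probabilities are compared
with a relative tolerance of 1e-7 so that mirror tables, equal in exact
arithmetic, are not excluded by floating-point rounding (the same guard R
and scipy use). When every table in the support is included the p-value is
returned as exactly 1. The log-pmf is computed from a cached log-factorial
table. One-sided alternatives are available behind a flag. The test suite
checks the implementation against exhaustive exact-integer enumeration for
every 2×2 table with grand total ≤ 60 and against scipy on random larger
tables; the implementation itself never calls either oracle.

## Domain-restricted burden

Residue indices parsed from HGVS p. strings map onto a domain architecture
(ordered 1-based inclusive residue intervals; teneurin-style classes:
N-terminal, transmembrane, EGF-like, NHL, YD-repeat). Mapping is total:
every in-range residue returns exactly one region or "other/inter-domain".
Qualifying variants are protein-altering, predictor-consensus deleterious,
novel (or under a configurable control-MAF cap), and inside the requested
region class. The burden statistic is a **carrier-level** two-sided Fisher
exact test on the table [case carriers, case non-carriers; control
carriers, control non-carriers] — delegating to the same Fisher machinery.
The family contributes its index case only (e.g. 120 sporadic cases + 1
index = 121), which avoids pseudo-replication from related carriers.
Because published sources disagree on the control denominator, it is an
explicit parameter rather than a constant. Allele-level and
variance-component (SKAT-style) tests are out of scope.

The bundled TENM4 architecture TSV is a clearly labelled **synthetic
stand-in**: a 2769-residue protein whose region boundaries reproduce the
published qualitative assignments (R325 in the N-terminal domain, E1098
between the EGF-like and NHL blocks, I1913/R2242/D2294 inside the YD block,
Q2735 C-terminal of it) without claiming curated coordinates. Replace the
TSV for real analyses.

## Expression specificity

Each gene × species FPKM row is normalized by its maximum over the profiled
tissues, so the top tissue scores exactly 1; ties at the maximum all map
to 1 (normalization is by value, not rank), and the output is invariant to
positive rescaling of the row. Tissue labels are opaque strings — the
package does not adjudicate naming conventions. The cross-species report
flags whether the same tissue is maximal in every species. An all-zero row
is an error, not a zero vector.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, with recorded
ground truth, under one integer seed fanned out to named sub-streams (so
the family, cohort and expression generators are independently
reproducible). All writers emit fixed headers and fixed float formats;
identical spec + seed yields byte-identical files.

* **Family** — a three-generation pedigree shaped like the motivating study
  design: generation I unexamined, an affected untyped founder-spouse
  (II-2), her unaffected typed spouse (II-1), one unaffected (III-1) and
  three affected (III-2/3/4) typed children. One fully penetrant dominant
  heterozygous missense causal variant is planted inside the designated
  linkage interval of a toy two-chromosome genome (2 Mb each; linkage
  region 1.0–1.5 Mb on chromosome 2) and transmitted to all affected, no
  unaffected. Background variants (default 5000, approximating the coding
  variant yield of an exome) draw population MAFs from a Beta(0.3, 3)
  spectrum rescaled to (0, 0.5) — a site-frequency-like choice, made once —
  with genotypes gene-dropped from Hardy–Weinberg founders; 95% are flagged
  as database members, and 60% of novel background variants are absent from
  the simulated control exomes so the later stages are actually exercised.
* **Cohorts** — Table-style genotype count tables for 120 sporadic cases,
  1136 control exomes and 205 Sanger-screened controls. Three hotspot
  (YD-region) missense variants carry a per-variant case carrier rate of
  1/120 and a control rate of 0 (the study-design scale: a couple of
  sporadic carriers, none in controls); background synonymous variants draw
  Hardy–Weinberg counts in every cohort, with ~30% of them NA in the small
  Sanger cohort.
* **Expression** — the target gene's brain FPKM is exactly `brain_factor`
  (default 4) times the maximum of the other tissues in each of four
  species; background genes are unconstrained lognormal.

Not emulated: linkage disequilibrium, population stratification,
read-level errors and coverage structure, genotyping error, relatedness
beyond the one pedigree, and realistic per-gene mutation rates. Passing
the pipeline on this synthetic data therefore demonstrates the *logic* of
the cascade, inference and statistics — not robustness to the noise
structure of real exomes.

## Problem sizes and numerical choices

Unit and property tests run the generators at a few hundred background
variants and 100 seeds, chosen so the whole suite stays interactive; the
acceptance script runs 25 replicates at the full 5000-variant scale.
Published-table computations (Fisher p-values, MAFs, burden) are exact
single calls. The burden power property uses a planted enrichment chosen by
an explicit power calculation: detection against 0 control carriers needs
at least 3 case carriers, so the scenario plants an expected carrier total
of ~10.8 (3% per-variant rate across three variants), putting the miss
probability near 0.3%. Degenerate inputs are errors, not silent defaults:
all-zero contingency tables, zero total alleles, all-NA control cohorts,
all-zero FPKM rows, empty/inverted intervals, cyclic pedigrees and
half-specified parent pairs all raise typed exceptions.
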